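"""Axis transformations and BIC search over the transformation grid.

Fitting on transformed axes changes what the size/timing/intensity effects
mean: on the identity scales they are absolute shifts (cm, years), on the
log scales proportional ones, and the square root is intermediate.  This
module applies and inverts the three transforms, scans the (age transform,
size transform, df) grid by BIC, and maps fitted curves and effects back to
natural units.

BIC comparability
-----------------
Log-likelihoods computed on different *size* scales refer to densities of
different variables.  Before comparing across size transforms, the
log-Jacobian sum log|dg(y)/dy| of the transform is added to the
transformed-scale log-likelihood so all densities refer to the natural
measurement scale.  Within one size transform the correction is a constant
and the ranking is unaffected, so the scan reports both the corrected
overall ranking and per-stratum rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScaleSpec",
    "ScaleScan",
    "apply_scale",
    "invert_scale",
    "scale_deriv",
    "inverse_scale_deriv",
    "log_jacobian",
    "scan_scales",
    "backtransform_curve",
    "timing_in_years",
]

TRANSFORMS = ("identity", "sqrt", "log")


@dataclass(frozen=True)
class ScaleSpec:
    """The (age, size) axis-transformation pair used for one fit."""

    age_transform: str = "identity"
    size_transform: str = "identity"

    def __post_init__(self) -> None:
        for which in (self.age_transform, self.size_transform):
            if which not in TRANSFORMS:
                raise ValueError(f"unknown transform {which!r}; choose from {TRANSFORMS}")


def _check_positive(x: np.ndarray, which: str) -> None:
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise ValueError(
            f"{which} transform requires strictly positive input; "
            f"first offending index {bad[0]} (value {x.flat[bad[0]]})"
        )


def apply_scale(x, which: str):
    """Elementwise identity, sqrt or natural log."""
    x = np.asarray(x, dtype=float)
    if which == "identity":
        return x
    if which == "sqrt":
        _check_positive(x, "sqrt")
        return np.sqrt(x)
    if which == "log":
        _check_positive(x, "log")
        return np.log(x)
    raise ValueError(f"unknown transform {which!r}")


def invert_scale(x, which: str):
    """Inverse of :func:`apply_scale`; exact round trip to floating precision."""
    x = np.asarray(x, dtype=float)
    if which == "identity":
        return x
    if which == "sqrt":
        if np.any(x < 0):
            raise ValueError("cannot invert sqrt for negative transformed values")
        return x * x
    if which == "log":
        return np.exp(x)
    raise ValueError(f"unknown transform {which!r}")


def scale_deriv(x, which: str):
    """d g(x)/dx for the forward transform g."""
    x = np.asarray(x, dtype=float)
    if which == "identity":
        return np.ones_like(x)
    if which == "sqrt":
        return 0.5 / np.sqrt(x)
    if which == "log":
        return 1.0 / x
    raise ValueError(f"unknown transform {which!r}")


def inverse_scale_deriv(u, which: str):
    """d g^{-1}(u)/du as a function of the transformed value u."""
    u = np.asarray(u, dtype=float)
    if which == "identity":
        return np.ones_like(u)
    if which == "sqrt":
        return 2.0 * u
    if which == "log":
        return np.exp(u)
    raise ValueError(f"unknown transform {which!r}")


def log_jacobian(values, which: str) -> float:
    """Sum of log|dg(y)/dy| over the observed natural-scale values."""
    return float(np.sum(np.log(scale_deriv(values, which))))


# ---------------------------------------------------------------------------
# transformation-grid scan


@dataclass
class ScaleScan:
    """Result of fitting every (age transform, size transform, df) combination.

    ``entries`` has one row per combination with the raw and
    Jacobian-corrected log-likelihood and BIC.  ``best`` is the overall
    corrected-BIC minimizer; ``best_by_size_stratum`` keeps the per-stratum
    winners, where no density correction is needed.
    """

    entries: pd.DataFrame
    best: dict = field(default_factory=dict)
    best_by_size_stratum: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def scan_scales(
    table,
    df_range=(5, 6, 7, 8),
    age_transforms=TRANSFORMS,
    size_transforms=TRANSFORMS,
    settings=None,
):
    """Fit every transform x df combination and rank by BIC.

    Failures are recorded per combination, not raised, unless every
    combination fails.  The result is independent of the order in which
    combinations are tried.
    """
    from .sitar_model import bic, fit_sitar

    values = table.data["value"].to_numpy()
    n_obs = len(values)
    rows = []
    fits = {}
    for age_t in age_transforms:
        for size_t in size_transforms:
            jac = log_jacobian(values, size_t)
            for df in df_range:
                scale = ScaleSpec(age_transform=age_t, size_transform=size_t)
                row = {
                    "age_transform": age_t,
                    "size_transform": size_t,
                    "df": df,
                    "loglik": np.nan,
                    "loglik_corrected": np.nan,
                    "bic": np.nan,
                    "bic_corrected": np.nan,
                    "converged": False,
                    "error": "",
                }
                try:
                    fit = fit_sitar(table, df=df, scale=scale, settings=settings)
                except Exception as exc:  # noqa: BLE001 - scan records failures
                    row["error"] = f"{type(exc).__name__}: {exc}"
                else:
                    row["loglik"] = fit.loglik
                    row["loglik_corrected"] = fit.loglik + jac
                    row["bic"] = bic(fit)
                    row["bic_corrected"] = row["bic"] - 2.0 * jac
                    row["converged"] = fit.converged
                    fits[(age_t, size_t, df)] = fit
                rows.append(row)
    entries = pd.DataFrame(rows).sort_values(
        ["age_transform", "size_transform", "df"], kind="stable"
    ).reset_index(drop=True)
    ok = entries[entries["error"] == ""]
    if len(ok) == 0:
        raise RuntimeError(
            "all scale/df combinations failed; first error: "
            + entries["error"].iloc[0]
        )
    best_row = ok.loc[ok["bic_corrected"].idxmin()]
    best = {
        "age_transform": best_row["age_transform"],
        "size_transform": best_row["size_transform"],
        "df": int(best_row["df"]),
        "bic_corrected": float(best_row["bic_corrected"]),
        "fit": fits[(best_row["age_transform"], best_row["size_transform"], int(best_row["df"]))],
    }
    by_stratum = {}
    for size_t, grp in ok.groupby("size_transform"):
        r = grp.loc[grp["bic"].idxmin()]
        by_stratum[size_t] = {
            "age_transform": r["age_transform"],
            "df": int(r["df"]),
            "bic": float(r["bic"]),
        }
    return ScaleScan(entries=entries, best=best, best_by_size_stratum=by_stratum)


def backtransform_curve(fit, survey, ages):
    """Evaluate a fitted curve on a natural-age grid, in natural size units.

    ``survey`` may be a survey id or ``"mean"`` for the zero-random-effect
    mean curve.
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    x = apply_scale(ages, fit.scale.age_transform)
    yt = fit.predict_transformed(x, survey)
    return invert_scale(yt, fit.scale.size_transform)


def timing_in_years(fit) -> pd.Series:
    """Per-survey timing effects expressed in natural years.

    On the identity age scale this is the raw timing random effect beta_i.
    On transformed age scales a horizontal shift is age-varying in natural
    units, so timing is measured where it is defined — at the pubertal
    spurt — as the difference between the survey's and the mean curve's age
    at peak velocity.
    """
    from .trend_analysis import peak_velocity

    effs = fit.random_effects
    if fit.scale.age_transform == "identity":
        return pd.Series(effs["beta"].to_numpy(), index=effs["survey"], name="timing")
    mean_age, _ = peak_velocity(fit, "mean")
    out = {}
    for survey in effs["survey"]:
        age_i, _ = peak_velocity(fit, survey)
        out[survey] = age_i - mean_age
    return pd.Series(out, name="timing")
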