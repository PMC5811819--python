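"""Secular-trend outputs: velocity curves, age-specific increments, effect
trends and the period-vs-cohort comparison.

The velocity curve is the analytic first derivative of the back-transformed
distance curve (basis derivative plus the chain rule through both axis
transforms), so its trapezoid integral over an age interval reproduces the
distance increment over the same interval.  Increments over the study
period — last survey minus first, by age — summarize the secular trend:
the increment at the oldest age is the adult trend, the one at the youngest
age the infant trend, and the pubertal maximum reflects the timing and
intensity shifts rather than size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scale_selection import (
    apply_scale,
    backtransform_curve,
    inverse_scale_deriv,
    scale_deriv,
)
from .sitar_model import SitarFit

__all__ = [
    "IncrementProfile",
    "PeriodCohortComparison",
    "velocity_curve",
    "peak_velocity",
    "increment_profile",
    "effect_trend_summary",
    "compare_period_cohort",
]

logger = logging.getLogger("sitar")


def velocity_curve(fit: SitarFit, survey, ages) -> np.ndarray:
    """Growth velocity (cm/yr or kg/yr) on a natural-age grid.

    Chain rule: with age transform T, size transform G and fitted curve m on
    the transformed scales, d/dt G^{-1}(m(T(t))) =
    (G^{-1})'(m) * m'(T(t)) * T'(t).
    """
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    x = apply_scale(ages, fit.scale.age_transform)
    m = fit.predict_transformed(x, survey)
    slope = fit.curve_slope_transformed(x, survey)
    return (
        inverse_scale_deriv(m, fit.scale.size_transform)
        * slope
        * scale_deriv(ages, fit.scale.age_transform)
    )


def peak_velocity(fit: SitarFit, survey, age_range=(5.0, None), step=0.01):
    """Age and value of the pubertal velocity peak for one fitted curve.

    The search runs on a 0.01-year grid restricted to ages above 5 years
    (excluding the infancy velocity peak) and is refined by local quadratic
    interpolation.  A maximum on the grid boundary means there is no
    interior pubertal peak and raises.
    """
    lo = max(age_range[0], fit.age_range[0]) + step
    hi = age_range[1]
    if hi is None:
        hi = fit.age_range[1]
    grid = np.arange(lo, hi + step / 2, step)
    vel = velocity_curve(fit, survey, grid)
    i = int(np.argmax(vel))
    if i == 0 or i == len(grid) - 1:
        raise ValueError(
            f"velocity maximum for {survey!r} lies at the search boundary "
            f"({grid[i]:.2f} y): no interior pubertal peak"
        )
    # quadratic refinement through the three points around the grid argmax
    y0, y1, y2 = vel[i - 1], vel[i], vel[i + 1]
    denom = y0 - 2.0 * y1 + y2
    offset = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    age = grid[i] + offset * step
    value = y1 - 0.25 * (y0 - y2) * offset
    return float(age), float(value)


@dataclass
class IncrementProfile:
    """First-to-last-survey differences by age, observed and model-predicted."""

    ages: np.ndarray            # shared observed ages
    observed: np.ndarray        # last minus first at each shared age
    pred_ages: np.ndarray       # fine grid (empty when no fit supplied)
    predicted: np.ndarray
    adult_increment: float      # observed at the oldest shared age
    infant_increment: float     # observed at the youngest shared age

    def to_frame(self) -> pd.DataFrame:
        obs = pd.DataFrame({"age": self.ages, "observed": self.observed})
        if len(self.pred_ages):
            pred = pd.DataFrame({"age": self.pred_ages, "predicted": self.predicted})
            return obs.merge(pred, on="age", how="outer").sort_values("age")
        return obs


def increment_profile(
    first: pd.DataFrame,
    last: pd.DataFrame,
    fit: SitarFit | None = None,
    grid_step: float = 0.25,
) -> IncrementProfile:
    """Observed (and, with a fit, predicted) increments between two survey
    curves.

    ``first`` and ``last`` are single-survey slices (columns ``survey``,
    ``age``, ``value``).  Observed increments exist only at shared ages;
    predictions are evaluated on a ``grid_step`` grid over the shared span.
    Increments may be negative; swapping the curves flips the sign.
    """
    f = first.set_index("age")["value"]
    l = last.set_index("age")["value"]
    shared = f.index.intersection(l.index)
    if len(shared) == 0:
        raise ValueError("the two survey curves share no ages")
    shared = np.sort(shared.to_numpy(dtype=float))
    observed = l.loc[shared].to_numpy() - f.loc[shared].to_numpy()
    pred_ages = np.array([])
    predicted = np.array([])
    if fit is not None:
        s_first = first["survey"].iloc[0]
        s_last = last["survey"].iloc[0]
        pred_ages = np.arange(shared[0], shared[-1] + grid_step / 2, grid_step)
        predicted = backtransform_curve(fit, s_last, pred_ages) - backtransform_curve(
            fit, s_first, pred_ages
        )
    return IncrementProfile(
        ages=shared,
        observed=observed,
        pred_ages=pred_ages,
        predicted=predicted,
        adult_increment=float(observed[-1]),
        infant_increment=float(observed[0]),
    )


def effect_trend_summary(effects: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-country first-to-last changes and ranges of each fitted effect.

    ``effects`` is an :func:`sitar.sitar_model.effects_table` frame;
    ``meta`` maps survey -> (country, year) (see
    :func:`sitar.growth_tables.survey_metadata`).  Returns one row per
    (country, parameter) with the year-ordered series, the last-minus-first
    change and the max-minus-min range.
    """
    merged = effects.merge(meta, on="survey", validate="one_to_one")
    rows = []
    for country, grp in merged.groupby("country"):
        if len(grp) < 2:
            raise ValueError(f"country {country!r} has fewer than 2 surveys")
        grp = grp.sort_values("year")
        for param in ("size", "timing", "intensity_pct"):
            series = grp[param].to_numpy(dtype=float)
            rows.append(
                {
                    "country": country,
                    "parameter": param,
                    "years": list(grp["year"].astype(int)),
                    "series": list(series),
                    "change": float(series[-1] - series[0]),
                    "range": float(series.max() - series.min()),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PeriodCohortComparison:
    """Matched period/cohort effect series and their ranges per parameter.

    ``range_ratio`` is range(period) / range(cohort); a ratio near 2 for
    intensity with size and timing near 1 is the signature of a secular
    trend whose apparent pace depends on how the curves are assembled.
    """

    pairs: pd.DataFrame  # period_year, cohort_year, parameter, period, cohort
    ranges: pd.DataFrame  # parameter, range_period, range_cohort, range_ratio

    def to_csv(self, path) -> None:
        self.pairs.to_csv(path, index=False)


def compare_period_cohort(
    period_fit: SitarFit,
    cohort_fit: SitarFit,
    period_meta: pd.DataFrame,
    cohort_meta: pd.DataFrame,
    pairing=None,
) -> PeriodCohortComparison:
    """Compare fitted effects between period curves and the cohorts born 11
    years earlier.

    ``pairing`` maps period year -> birth year and defaults to the -11-year
    rule.  Period surveys without a fitted matching cohort are excluded with
    a warning.
    """
    from .growth_tables import match_period_to_cohort
    from .sitar_model import effects_table

    eff_p = effects_table(period_fit).merge(period_meta, on="survey")
    eff_c = effects_table(cohort_fit).merge(cohort_meta, on="survey")
    if pairing is None:
        pairing = {
            int(y): match_period_to_cohort(int(y)) for y in eff_p["year"]
        }
    if not pairing:
        raise ValueError("empty period-to-cohort pairing")
    by_cohort_year = {int(r.year): r for r in eff_c.itertuples()}
    rows = []
    for r in eff_p.itertuples():
        cohort_year = pairing.get(int(r.year))
        match = by_cohort_year.get(cohort_year)
        if match is None:
            logger.warning(
                "period %s has no fitted cohort born %s; excluded", r.year, cohort_year
            )
            continue
        for param in ("size", "timing", "intensity_pct"):
            rows.append(
                {
                    "period_year": int(r.year),
                    "cohort_year": cohort_year,
                    "parameter": param,
                    "period": float(getattr(r, param)),
                    "cohort": float(getattr(match, param)),
                }
            )
    if not rows:
        raise ValueError("no period survey could be matched to a cohort")
    pairs = pd.DataFrame(rows)
    ranges = (
        pairs.groupby("parameter")
        .agg(
            range_period=("period", lambda s: s.max() - s.min()),
            range_cohort=("cohort", lambda s: s.max() - s.min()),
        )
        .reset_index()
    )
    ranges["range_ratio"] = ranges["range_period"] / ranges["range_cohort"]
    return PeriodCohortComparison(pairs=pairs, ranges=ranges)
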