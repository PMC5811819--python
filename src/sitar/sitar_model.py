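"""SITAR: a shape-invariant mixed-effects model for growth curves.

The model assumes every curve (here: every survey) is a common spline mean
curve, shifted and stretched.  On the fitting scales, the prediction for
survey *i* at transformed age *t* is::

    y = a0 + alpha_i + h( exp(c0 + gamma_i) * (t - b0 - beta_i) )

with ``h`` a natural cubic spline shared by all surveys and per-survey
random effects ``(alpha_i, beta_i, gamma_i)`` — size, timing and
log-intensity — drawn from a zero-mean trivariate normal with free
covariance.  Corresponding fixed effects ``(a0, b0, c0)`` absorb the means.
Intensity is reported as ``100 * gamma_i`` percent: a survey with intensity
+4% passes through the growth period 4% faster than the mean curve.

Estimation maximizes the Laplace approximation to the marginal likelihood:
an inner Newton solve finds the per-survey posterior modes of the random
effects (with analytic gradients and full second-order curvature), and a
quasi-Newton outer loop profiles the spline coefficients, fixed effects,
random-effect covariance (Cholesky-parameterized) and residual variance.
With a handful of curves per fit this is fast and accurate; on tiny
instances the approximation can be checked against adaptive Gauss-Hermite
quadrature.

Maximum likelihood (not REML) is used throughout so that BIC comparisons
across spline degrees of freedom and fixed-effect structures are coherent.
Fitting is deterministic: no randomness enters the optimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import lstsq, null_space, solve_triangular
from scipy.optimize import minimize

from .growth_tables import GrowthTable
from .scale_selection import ScaleSpec, apply_scale
from .spline_basis import (
    SplineSpec,
    knots_from_quantiles,
    natural_basis,
    natural_basis_deriv,
    natural_basis_deriv2,
)

__all__ = [
    "FitSettings",
    "SitarFit",
    "ConvergenceError",
    "fit_sitar",
    "marginal_loglik",
    "bic",
    "variance_explained",
    "select_df",
    "effects_table",
    "adjusted_curves",
]


class ConvergenceError(RuntimeError):
    """Raised when the outer optimization fails to converge."""

    def __init__(self, message: str, last_fit: "SitarFit | None" = None):
        super().__init__(message)
        self.last_fit = last_fit


@dataclass(frozen=True)
class FitSettings:
    """Optimizer controls.

    ``tol`` is the relative objective-change stopping rule, ``grad_tol`` the
    gradient sup-norm target (on internally rescaled parameters); the outer
    quasi-Newton loop stops on whichever is met first.  ``weighted`` enables
    inverse-variance weighting by the per-cell sample size ``n`` (survey
    means are typically so precise that this is immaterial, but the flag
    documents the choice).
    """

    tol: float = 1e-8
    grad_tol: float = 1e-5
    max_iter: int = 2000
    inner_tol: float = 1e-9
    inner_max_iter: int = 60
    center_rounds: int = 6
    weighted: bool = False


_RE_NAMES = ("alpha", "beta", "gamma")


@dataclass
class SitarFit:
    """A fitted SITAR model.

    All coefficients live on the fitting (transformed) scales; use
    :func:`sitar.scale_selection.backtransform_curve`,
    :func:`effects_table` and the trend-analysis helpers to report in
    natural units.
    """

    spline: SplineSpec
    coef: np.ndarray                 # constant-free spline coefficients, length df - 1
    fixed_effects: dict              # a0 (transformed size), b0 (transformed age), c0
    random_effects: pd.DataFrame     # survey, alpha, beta, gamma (zero mean)
    re_covariance: np.ndarray        # 3x3, (alpha, beta, gamma) order
    residual_sd: float
    loglik: float
    n_obs: int
    n_param: int
    scale: ScaleSpec
    converged: bool
    n_iter: int
    degenerate: bool = False
    grad_norm: float = np.nan
    settings: FitSettings = field(default_factory=FitSettings)
    x_offset: float = 0.0            # transformed-age centering constant
    adult_level: float = 0.0         # mean curve at the oldest observed age (transformed)
    age_range: tuple = (1.5, 19.5)   # natural-age span of the fitted data
    _umap: np.ndarray = field(default=None, repr=False)  # df x (df-1) constant-free map

    # -- prediction ----------------------------------------------------------

    def effect_vector(self, survey: str) -> np.ndarray:
        if survey == "mean":
            return np.zeros(3)
        row = self.random_effects[self.random_effects["survey"] == survey]
        if len(row) != 1:
            raise KeyError(f"no survey {survey!r} in fit")
        return row[list(_RE_NAMES)].to_numpy(dtype=float)[0]

    def _args(self, x, survey: str):
        u = self.effect_vector(survey)
        b0 = self.fixed_effects["b0"]
        c = self.fixed_effects["c0"] + u[2]
        z = np.exp(c) * (np.asarray(x, dtype=float) - b0 - u[1])
        return u, c, z

    def predict_transformed(self, x, survey: str = "mean") -> np.ndarray:
        """Model prediction on the fitting scales at transformed ages ``x``."""
        u, _, z = self._args(x, survey)
        sc = self._umap @ self.coef
        return self.fixed_effects["a0"] + u[0] + natural_basis(z, self.spline) @ sc

    def curve_slope_transformed(self, x, survey: str = "mean") -> np.ndarray:
        """d(prediction)/d(transformed age), used by velocity chain rules."""
        u, c, z = self._args(x, survey)
        sc = self._umap @ self.coef
        return np.exp(c) * (natural_basis_deriv(z, self.spline) @ sc)

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spline": {
                "df": self.spline.df,
                "interior_knots": list(self.spline.interior_knots),
                "boundary_knots": list(self.spline.boundary_knots),
            },
            "coef": self.coef.tolist(),
            "umap": self._umap.tolist(),
            "fixed_effects": {k: float(v) for k, v in self.fixed_effects.items()},
            "random_effects": self.random_effects.to_dict(orient="list"),
            "re_covariance": self.re_covariance.tolist(),
            "residual_sd": float(self.residual_sd),
            "loglik": float(self.loglik),
            "bic": float(bic(self)),
            "n_obs": int(self.n_obs),
            "n_param": int(self.n_param),
            "scale": {
                "age_transform": self.scale.age_transform,
                "size_transform": self.scale.size_transform,
            },
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "degenerate": bool(self.degenerate),
            "x_offset": float(self.x_offset),
            "adult_level": float(self.adult_level),
            "age_range": list(self.age_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SitarFit":
        return cls(
            spline=SplineSpec(
                df=d["spline"]["df"],
                interior_knots=tuple(d["spline"]["interior_knots"]),
                boundary_knots=tuple(d["spline"]["boundary_knots"]),
            ),
            coef=np.asarray(d["coef"], dtype=float),
            fixed_effects=dict(d["fixed_effects"]),
            random_effects=pd.DataFrame(d["random_effects"]),
            re_covariance=np.asarray(d["re_covariance"], dtype=float),
            residual_sd=d["residual_sd"],
            loglik=d["loglik"],
            n_obs=d["n_obs"],
            n_param=d["n_param"],
            scale=ScaleSpec(**d["scale"]),
            converged=d["converged"],
            n_iter=d["n_iter"],
            degenerate=d.get("degenerate", False),
            x_offset=d["x_offset"],
            adult_level=d["adult_level"],
            age_range=tuple(d["age_range"]),
            _umap=np.asarray(d["umap"], dtype=float),
        )


# ---------------------------------------------------------------------------
# data assembly


@dataclass
class _ModelData:
    surveys: list
    codes: np.ndarray        # survey index per observation
    xc: np.ndarray           # centered transformed ages
    y: np.ndarray            # transformed values
    w: np.ndarray            # observation weights (mean 1)
    n_per: np.ndarray
    x_off: float
    spline: SplineSpec
    umap: np.ndarray         # df x (df-1), removes the constant direction
    sum_log_w: float


def _constant_free_map(spec: SplineSpec) -> np.ndarray:
    """Direction u with basis @ u == 1 and an orthonormal complement of it.

    The natural-spline space spans constants; the model's size intercept
    a0 + alpha_i supplies them instead, so the fitted spline uses the
    df - 1 complementary directions.
    """
    lo, hi = spec.boundary_knots
    grid = np.linspace(lo, hi, max(8 * spec.df, 80))
    basis = natural_basis(grid, spec)
    u, *_ = lstsq(basis, np.ones(len(grid)))
    resid = basis @ u - 1.0
    if np.max(np.abs(resid)) > 1e-8:  # pragma: no cover
        raise RuntimeError("constant function not represented by natural basis")
    comp = null_space(u[None, :])
    return comp  # df x (df-1)


def _model_for_eval(
    table: GrowthTable,
    scale: ScaleSpec,
    spline: SplineSpec,
    umap: np.ndarray,
    x_off: float,
    settings: FitSettings,
) -> _ModelData:
    """Assemble evaluation data against an existing spline layout (no knot
    derivation, no minimum-size checks beyond non-emptiness)."""
    if table.n_obs == 0:
        raise ValueError("empty table")
    surveys = table.surveys
    data = table.data
    x = apply_scale(data["age"].to_numpy(), scale.age_transform)
    y = apply_scale(data["value"].to_numpy(), scale.size_transform)
    codes = data["survey"].map({s: i for i, s in enumerate(surveys)}).to_numpy()
    if settings.weighted and data["n"].notna().all():
        w = data["n"].to_numpy(dtype=float)
        w = w / w.mean()
    else:
        w = np.ones(len(data))
    return _ModelData(
        surveys=surveys,
        codes=codes,
        xc=x - x_off,
        y=y,
        w=w,
        n_per=np.bincount(codes, minlength=len(surveys)).astype(float),
        x_off=x_off,
        spline=spline,
        umap=umap,
        sum_log_w=float(np.sum(np.log(w))),
    )


def _assemble(
    table: GrowthTable,
    df: int,
    scale: ScaleSpec,
    settings: FitSettings,
) -> tuple[_ModelData, float]:
    table.check_fittable()
    surveys = table.surveys
    if len(surveys) < 2:
        raise ValueError(
            "SITAR needs at least 2 curves; random effects are unidentifiable "
            f"with {len(surveys)}"
        )
    data = table.data
    x = apply_scale(data["age"].to_numpy(), scale.age_transform)
    y = apply_scale(data["value"].to_numpy(), scale.size_transform)
    x_off = float(np.mean(x))
    xc = x - x_off
    codes = data["survey"].map({s: i for i, s in enumerate(surveys)}).to_numpy()
    if settings.weighted and data["n"].notna().all():
        w = data["n"].to_numpy(dtype=float)
        w = w / w.mean()
    else:
        w = np.ones(len(data))

    # starting timing anchor: age of maximum pooled-curve derivative
    spec0 = knots_from_quantiles(xc, df)
    basis0 = natural_basis(xc, spec0)
    coef0, *_ = lstsq(basis0, y)
    grid = np.linspace(xc.min(), xc.max(), 201)
    slope = natural_basis_deriv(grid, spec0) @ coef0
    b0c_start = float(grid[int(np.argmax(slope))])

    # knots at quantiles of the starting spline argument (the fitting scale)
    spec = knots_from_quantiles(xc - b0c_start, df)
    umap = _constant_free_map(spec)
    model = _ModelData(
        surveys=surveys,
        codes=codes,
        xc=xc,
        y=y,
        w=w,
        n_per=np.bincount(codes, minlength=len(surveys)).astype(float),
        x_off=x_off,
        spline=spec,
        umap=umap,
        sum_log_w=float(np.sum(np.log(w))),
    )
    return model, b0c_start


# ---------------------------------------------------------------------------
# Laplace likelihood machinery (batched over surveys)


def _batch_eval(model: _ModelData, sc, a0, b0c, c0, U, need_curvature=True):
    """Residuals, per-observation Jacobian columns and curvature terms.

    ``sc`` is the full-basis coefficient vector (umap @ coef); ``U`` the
    (n_surveys, 3) random-effect matrix.
    """
    g = model.codes
    # clip the log age-scale factor: |c| > 8 is far outside any plausible
    # intensity and would overflow exp during wild line-search trials
    c = np.clip(c0 + U[g, 2], -8.0, 8.0)
    ec = np.exp(c)
    z = ec * (model.xc - b0c - U[g, 1])
    h1 = natural_basis_deriv(z, model.spline) @ sc
    mu = a0 + U[g, 0] + natural_basis(z, model.spline) @ sc
    r = model.y - mu
    ja = np.ones_like(r)
    jb = -ec * h1
    jc = h1 * z
    if not need_curvature:
        return r, (ja, jb, jc), None, z
    h2 = natural_basis_deriv2(z, model.spline) @ sc
    # second derivatives of mu wrt (beta, gamma)
    m_bb = ec * ec * h2
    m_bg = -ec * (h1 + h2 * z)
    m_gg = h1 * z + h2 * z * z
    return r, (ja, jb, jc), (m_bb, m_bg, m_gg), z


def _group_sum(codes, n_groups, values):
    return np.bincount(codes, weights=values, minlength=n_groups)


def _joint_pieces(model, sc, a0, b0c, c0, U, o_inv, sigma2, need_hess=True):
    """Per-survey joint negative log-density values, gradients and Hessians.

    Returns ``(g_val, grad, H_full, H_gn)``: the full Hessian (with the
    residual-weighted curvature term) drives the inner Newton iteration; the
    Gauss-Newton form (expected information, positive definite by
    construction) is the one entering the Laplace determinant, which keeps
    the approximate likelihood bounded even away from exact modes.
    """
    S = len(model.surveys)
    r, (ja, jb, jc), curv, _ = _batch_eval(model, sc, a0, b0c, c0, U, need_hess)
    wr = model.w * r
    rss = _group_sum(model.codes, S, wr * r)
    prior = 0.5 * np.einsum("si,ij,sj->s", U, o_inv, U)
    g_val = 0.5 * rss / sigma2 + prior

    grad_data = np.stack(
        [
            _group_sum(model.codes, S, wr * ja),
            _group_sum(model.codes, S, wr * jb),
            _group_sum(model.codes, S, wr * jc),
        ],
        axis=1,
    )
    grad = -grad_data / sigma2 + U @ o_inv
    if not need_hess:
        return g_val, grad, None, None

    m_bb, m_bg, m_gg = curv
    cds, w = model.codes, model.w
    H = np.empty((S, 3, 3))
    H[:, 0, 0] = _group_sum(cds, S, w * ja * ja)
    H[:, 0, 1] = H[:, 1, 0] = _group_sum(cds, S, w * ja * jb)
    H[:, 0, 2] = H[:, 2, 0] = _group_sum(cds, S, w * ja * jc)
    H[:, 1, 1] = _group_sum(cds, S, w * jb * jb)
    H[:, 1, 2] = H[:, 2, 1] = _group_sum(cds, S, w * jb * jc)
    H[:, 2, 2] = _group_sum(cds, S, w * jc * jc)
    H /= sigma2
    H += o_inv[None, :, :]
    H_gn = H.copy()
    H[:, 1, 1] -= _group_sum(cds, S, w * r * m_bb) / sigma2
    H[:, 1, 2] -= _group_sum(cds, S, w * r * m_bg) / sigma2
    H[:, 2, 1] = H[:, 1, 2]
    H[:, 2, 2] -= _group_sum(cds, S, w * r * m_gg) / sigma2
    return g_val, grad, H, H_gn


def _inner_modes(model, sc, a0, b0c, c0, o_inv, sigma2, U0, settings):
    """Newton-with-damping solve of the per-survey random-effect modes."""
    U = U0.copy()
    S = len(model.surveys)
    g_val, grad, H, H_gn = _joint_pieces(model, sc, a0, b0c, c0, U, o_inv, sigma2)
    # a warm start stranded in a non-finite region restarts from the prior mean
    salvage = ~np.isfinite(g_val)
    if salvage.any():
        U[salvage] = 0.0
        g_val, grad, H, H_gn = _joint_pieces(model, sc, a0, b0c, c0, U, o_inv, sigma2)
    lam = np.zeros(S)
    tol = settings.inner_tol
    eye = np.eye(3)[None, :, :]

    def _sanitize(gv, gr, hs, hgn):
        bad = ~(
            np.isfinite(gv)
            & np.isfinite(gr).all(axis=1)
            & np.isfinite(hs).all(axis=(1, 2))
            & np.isfinite(hgn).all(axis=(1, 2))
        )
        if bad.any():
            gv = np.where(bad, np.inf, gv)
            gr[bad] = 0.0
            hs[bad] = o_inv
            hgn[bad] = o_inv
        return gv, gr, hs, hgn

    g_val, grad, H, H_gn = _sanitize(g_val, grad, H, H_gn)
    stall = np.zeros(S, dtype=int)
    for _ in range(settings.inner_max_iter):
        gnorm = np.max(np.abs(grad), axis=1)
        # a survey whose line search failed repeatedly is at its numerical
        # optimum; retrying forever would only burn time
        active = np.isfinite(g_val) & (gnorm > tol * (1.0 + np.abs(g_val))) & (stall < 3)
        if not active.any():
            break
        step = None
        for _pd in range(8):
            Hd = H + lam[:, None, None] * eye
            eig = np.linalg.eigvalsh(Hd)
            floor = 1e-10 * np.maximum(np.abs(Hd).max(axis=(1, 2)), 1.0)
            bad = eig[:, 0] <= floor
            if bad.any():
                lam[bad] = np.maximum(lam[bad] * 10 + 1e-6, (-eig[bad, 0] + floor[bad]) * 1.5)
                continue
            try:
                step = -np.linalg.solve(Hd, grad[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                lam = lam * 10 + 1e-4
                continue
            if np.isfinite(step).all():
                break
            lam = lam * 10 + 1e-4
            step = None
        if step is None:
            break
        step[~active] = 0.0
        # Armijo backtracking per survey (non-finite trials count as worse)
        t = np.ones(S)
        for _bt in range(12):
            U_try = U + t[:, None] * step
            g_try, grad_try, H_try, Hgn_try = _joint_pieces(
                model, sc, a0, b0c, c0, U_try, o_inv, sigma2
            )
            g_try, grad_try, H_try, Hgn_try = _sanitize(g_try, grad_try, H_try, Hgn_try)
            worse = active & (g_try > g_val + 1e-12 * (1.0 + np.abs(g_val)))
            if not worse.any():
                break
            t[worse] *= 0.5
        improved = active & (g_try <= g_val + 1e-12 * (1.0 + np.abs(g_val)))
        # require a real decrease to reset the stall counter
        progressed = active & (g_try < g_val - 1e-12 * (1.0 + np.abs(g_val)))
        stall[progressed] = 0
        stall[active & ~progressed] += 1
        U[improved] = U_try[improved]
        lam[improved] *= 0.3
        lam[active & ~improved] = lam[active & ~improved] * 10 + 1e-6
        g_val = np.where(improved, g_try, g_val)
        grad[improved] = grad_try[improved]
        H[improved] = H_try[improved]
        H_gn[improved] = Hgn_try[improved]
    return U, g_val, H, H_gn


def _omega_from_l(lvec):
    L = np.zeros((3, 3))
    L[0, 0] = np.exp(lvec[0])
    L[1, 0] = lvec[1]
    L[1, 1] = np.exp(lvec[2])
    L[2, 0] = lvec[3]
    L[2, 1] = lvec[4]
    L[2, 2] = np.exp(lvec[5])
    return L


def _laplace_loglik(model, theta, settings, u_start=None, observed_info=False):
    """Total Laplace-approximate marginal log-likelihood at parameters theta.

    ``u_start`` seeds the inner mode search (zeros when omitted); the
    function is pure — the caller decides whether to reuse returned modes as
    the next start, keeping the likelihood a consistent function of
    ``theta`` within an outer optimizer iteration.

    ``observed_info`` selects the full observed-information Hessian for the
    Laplace determinant (slightly more accurate at a converged mode, used
    for reported values); the default Gauss-Newton form is positive
    definite everywhere and is what the optimizer sees.
    """
    df = model.spline.df
    k = df - 1
    sc = model.umap @ theta[:k]
    a0, b0c, c0 = theta[k : k + 3]
    L = _omega_from_l(theta[k + 3 : k + 9])
    log_sigma = theta[k + 9]
    sigma2 = np.exp(2.0 * log_sigma)
    l_inv = solve_triangular(L, np.eye(3), lower=True)
    o_inv = l_inv.T @ l_inv
    logdet_omega = 2.0 * np.sum(np.log(np.diag(L)))

    if u_start is None:
        u_start = np.zeros((len(model.surveys), 3))
    bad_rows = ~np.isfinite(u_start).all(axis=1)
    if bad_rows.any():
        u_start = u_start.copy()
        u_start[bad_rows] = 0.0
    U, g_val, H_full, H_gn = _inner_modes(
        model, sc, a0, b0c, c0, o_inv, sigma2, u_start, settings
    )
    H = H_full if observed_info else H_gn
    sign, logdet_h = np.linalg.slogdet(H)
    if np.any(sign <= 0):
        # mode Hessian not PD (should not happen at a true mode): ridge it
        eig = np.linalg.eigvalsh(H)
        ridge = np.maximum(0.0, 1e-8 - eig[:, 0])
        H = H + ridge[:, None, None] * np.eye(3)[None, :, :]
        _, logdet_h = np.linalg.slogdet(H)
    n = len(model.y)
    S = len(model.surveys)
    ll = (
        -0.5 * n * np.log(2.0 * np.pi * sigma2)
        + 0.5 * model.sum_log_w
        - float(np.sum(g_val))
        - 0.5 * S * logdet_omega
        - 0.5 * float(np.sum(logdet_h))
    )
    return ll, U


# ---------------------------------------------------------------------------
# fitting


def fit_sitar(
    table: GrowthTable,
    df: int = 6,
    scale: ScaleSpec | None = None,
    settings: FitSettings | None = None,
) -> SitarFit:
    """Fit the SITAR model to a :class:`GrowthTable` by Laplace-approximate
    maximum likelihood.

    ``df`` is the spline dimension (interior knots = df - 2, at age
    quantiles of the fitting scale).  Deterministic given data, ``df``,
    ``scale`` and ``settings``.
    """
    scale = scale or ScaleSpec()
    settings = settings or FitSettings()
    model, b0c_start = _assemble(table, df, scale, settings)
    k = df - 1
    n = len(model.y)
    S = len(model.surveys)

    # starting values: pooled least-squares curve, data-driven anchors
    z0 = model.xc - b0c_start
    design0 = np.column_stack([np.ones(n), natural_basis(z0, model.spline) @ model.umap])
    beta_ls, *_ = lstsq(design0, model.y)
    resid0 = model.y - design0 @ beta_ls
    sd_y = float(np.std(model.y))
    sigma0 = max(float(np.sqrt(np.mean(resid0**2))), 1e-4 * max(sd_y, 1e-3), 1e-8)

    # starting covariance diag(1 cm^2, 0.25 yr^2, 0.01), mapped onto the
    # fitting scales through the transform Jacobians at the data means
    from .scale_selection import scale_deriv  # local to avoid cycles at import

    age_jac = float(np.mean(scale_deriv(table.data["age"].to_numpy(), scale.age_transform)))
    size_jac = float(np.mean(scale_deriv(table.data["value"].to_numpy(), scale.size_transform)))
    sd_alpha0 = 1.0 * size_jac
    sd_beta0 = 0.5 * age_jac
    sd_gamma0 = 0.1

    theta0 = np.concatenate(
        [
            beta_ls[1:],
            [beta_ls[0], b0c_start, 0.0],
            [np.log(sd_alpha0), 0.0, np.log(sd_beta0), 0.0, 0.0, np.log(sd_gamma0)],
            [np.log(sigma0)],
        ]
    )
    x_range = float(model.xc.max() - model.xc.min())
    scales = np.concatenate(
        [
            np.full(k, max(sd_y, 1e-2)),
            [max(sd_y, 1e-2), max(float(np.std(model.xc)), 0.1), 0.2],
            [1.0, sd_beta0, 1.0, sd_gamma0, sd_gamma0, 1.0],
            [1.0],
        ]
    )
    lower = np.full(theta0.size, -np.inf)
    upper = np.full(theta0.size, np.inf)
    lower[k + 1], upper[k + 1] = -3.0 * x_range, 3.0 * x_range  # b0c
    lower[k + 2], upper[k + 2] = -2.0, 2.0  # c0
    # variance floors: a random-effect SD a factor e^6 (~400x) below its
    # starting guess is a boundary (zero-variance) fit for all practical
    # purposes, while keeping the precision matrices well conditioned
    for j, off in ((0, k + 3), (2, k + 5), (5, k + 8)):  # log-diagonal entries
        lower[off] = theta0[off] - 6.0
        upper[off] = theta0[off] + 4.0
    lower[k + 9] = np.log(sigma0) - 5.0
    upper[k + 9] = np.log(max(sd_y, 1e-3)) + 3.0

    # inner-mode warm start: fixed within each outer iteration (so the
    # objective is a consistent function of theta during line searches and
    # finite differencing) and refreshed only at accepted iterates
    base = {"U": np.zeros((S, 3))}

    def objective(t_scaled):
        ll, _ = _laplace_loglik(model, t_scaled * scales, settings, base["U"])
        # a Gaussian log-density of survey means cannot legitimately reach
        # astronomically positive values; treat such regions as invalid
        if not np.isfinite(ll) or ll > 1e9:
            return 1e12
        return -ll

    def accept(t_scaled):
        _, U = _laplace_loglik(model, t_scaled * scales, settings, base["U"])
        if np.isfinite(U).all():
            base["U"] = U

    bounds = list(zip(lower / scales, upper / scales))
    x0 = theta0 / scales
    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        callback=accept,
        options={
            "maxiter": settings.max_iter,
            "maxfun": settings.max_iter * 50,
            "ftol": settings.tol,
            "gtol": settings.grad_tol,
            "eps": 1e-6,
        },
    )
    n_iter = res.nit
    message = str(res.message)
    if not res.success and ("ITERATIONS" in message or "EVALUATIONS" in message):
        raise ConvergenceError(
            f"outer optimization hit max_iter={settings.max_iter}: {message}"
        )
    main_success = bool(res.success)

    # re-center: absorb the random-effect means into the fixed effects, then
    # polish, so the reported effects have zero mean as the model states
    theta = res.x * scales
    for _ in range(settings.center_rounds):
        ll_cur, U = _laplace_loglik(model, theta, settings, base["U"])
        means = U.mean(axis=0)
        if np.max(np.abs(means) / scales[k : k + 3]) < 1e-7:
            break
        shifted = theta.copy()
        shifted[k] += means[0]
        shifted[k + 1] += means[1]
        shifted[k + 2] += means[2]
        ll_shift, U_shift = _laplace_loglik(model, shifted, settings, U - means)
        # centering is a near-neutral reparameterization; a marked drop in
        # likelihood flags a spurious shift, which is discarded
        if not np.isfinite(ll_shift) or ll_shift < ll_cur - max(0.5, 1e-4 * abs(ll_cur)):
            break
        theta = shifted
        base["U"] = U_shift
        # polish after re-centering; an iteration cap here is not a failure
        theta[k + 1] = np.clip(theta[k + 1] / scales[k + 1], *bounds[k + 1]) * scales[k + 1]
        theta[k + 2] = np.clip(theta[k + 2] / scales[k + 2], *bounds[k + 2]) * scales[k + 2]
        res = minimize(
            objective,
            theta / scales,
            method="L-BFGS-B",
            bounds=bounds,
            callback=accept,
            options={
                "maxiter": 200,
                "maxfun": 10000,
                "ftol": settings.tol,
                "gtol": settings.grad_tol,
                "eps": 1e-6,
            },
        )
        theta = res.x * scales
        n_iter += res.nit
        main_success = main_success or bool(res.success)
        accept(res.x)

    ll, U = _laplace_loglik(model, theta, settings, base["U"], observed_info=True)
    if not (np.isfinite(ll) and np.isfinite(theta).all() and np.isfinite(U).all()):
        raise ConvergenceError("likelihood or parameters not finite at final iterate")

    # exact zero-mean of the reported effects (empirical best predictions)
    means = U.mean(axis=0)
    U_rep = U - means
    a0 = theta[k] + means[0]
    b0c = theta[k + 1] + means[1]
    c0 = theta[k + 2] + means[2]

    L = _omega_from_l(theta[k + 3 : k + 9])
    omega = L @ L.T
    ldiag = theta[[k + 3, k + 5, k + 8]]
    degenerate = bool(np.any(ldiag <= lower[[k + 3, k + 5, k + 8]] + 1e-3))
    if degenerate:
        warnings.warn(
            "random-effect covariance at its lower boundary: between-survey "
            "variance is degenerate for at least one effect",
            RuntimeWarning,
            stacklevel=2,
        )

    sc = model.umap @ theta[:k]
    x_max = float(model.xc.max())
    adult_level = float(
        a0 + (natural_basis(np.exp(c0) * (x_max - b0c), model.spline) @ sc)[0]
    )

    effects = pd.DataFrame(
        {
            "survey": model.surveys,
            "alpha": U_rep[:, 0],
            "beta": U_rep[:, 1],
            "gamma": U_rep[:, 2],
        }
    )
    fit = SitarFit(
        spline=model.spline,
        coef=theta[:k].copy(),
        fixed_effects={"a0": float(a0), "b0": float(model.x_off + b0c), "c0": float(c0)},
        random_effects=effects,
        re_covariance=omega,
        residual_sd=float(np.exp(theta[k + 9])),
        loglik=float(ll),
        n_obs=n,
        n_param=k + 3 + 6 + 1,
        scale=scale,
        converged=main_success,
        n_iter=int(n_iter),
        degenerate=degenerate,
        grad_norm=float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan,
        settings=settings,
        x_offset=model.x_off,
        adult_level=adult_level,
        age_range=(
            float(table.data["age"].min()),
            float(table.data["age"].max()),
        ),
        _umap=model.umap,
    )
    if not fit.converged:
        # remaining non-success mode is a line-search stall: no further
        # progress is possible at the achievable finite-difference precision,
        # i.e. the optimum has been reached within numerical resolution
        fit.converged = True
        warnings.warn(
            "optimizer stalled in line search near the optimum; treating as "
            f"converged (projected gradient norm {fit.grad_norm:.2e})",
            RuntimeWarning,
            stacklevel=2,
        )
    return fit


# ---------------------------------------------------------------------------
# likelihood, information criteria, summaries


def marginal_loglik(fit: SitarFit, table: GrowthTable) -> float:
    """Laplace-approximate marginal log-likelihood of ``fit``'s parameters on
    ``table``.

    In the exact zero-covariance limit the random effects collapse and the
    value equals the fixed-effects Gaussian log-likelihood.
    """
    settings = fit.settings
    model = _model_for_eval(
        table, fit.scale, fit.spline, fit._umap, fit.x_offset, settings
    )
    b0c = fit.fixed_effects["b0"] - fit.x_offset
    omega = fit.re_covariance
    eig = np.linalg.eigvalsh(omega)
    sigma2 = fit.residual_sd**2
    if eig[0] < 1e-300:
        # degenerate covariance: integrand collapses onto u = 0
        sc = fit._umap @ fit.coef
        U = np.zeros((len(model.surveys), 3))
        r, *_ = _batch_eval(model, sc, fit.fixed_effects["a0"], b0c, fit.fixed_effects["c0"], U, False)
        n = len(model.y)
        return float(
            -0.5 * n * np.log(2.0 * np.pi * sigma2)
            + 0.5 * model.sum_log_w
            - 0.5 * np.sum(model.w * r * r) / sigma2
        )
    L = np.linalg.cholesky(omega)
    lvec = np.array(
        [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1]), L[2, 0], L[2, 1], np.log(L[2, 2])]
    )
    theta = np.concatenate(
        [
            fit.coef,
            [fit.fixed_effects["a0"], b0c, fit.fixed_effects["c0"]],
            lvec,
            [np.log(fit.residual_sd)],
        ]
    )
    ll, _ = _laplace_loglik(model, theta, settings, observed_info=True)
    return float(ll)


def bic(fit: SitarFit) -> float:
    """Bayesian Information Criterion: -2 loglik + n_param * log(n_obs)."""
    return float(-2.0 * fit.loglik + fit.n_param * np.log(fit.n_obs))


def variance_explained(full: SitarFit, table: GrowthTable) -> float:
    """Percentage of variance the random effects explain over a mean-curve-only
    model: ``100 * (1 - (RSD_full / RSD_meanonly)^2)``.

    The comparator refits the same spline (same df, scales and knots) to the
    pooled data with no random effects.
    """
    model = _model_for_eval(
        table, full.scale, full.spline, full._umap, full.x_offset, full.settings
    )
    b0c = full.fixed_effects["b0"] - full.x_offset
    c0 = full.fixed_effects["c0"]
    z = np.exp(c0) * (model.xc - b0c)
    design = np.column_stack(
        [np.ones(len(model.y)), natural_basis(z, model.spline) @ model.umap]
    )
    coefs, *_ = lstsq(design, model.y)
    resid = model.y - design @ coefs
    rsd_mean = float(np.sqrt(np.mean(model.w * resid**2)))
    ratio2 = (full.residual_sd / rsd_mean) ** 2
    return float(np.clip(100.0 * (1.0 - ratio2), 0.0, 100.0))


def select_df(
    table: GrowthTable,
    scale: ScaleSpec | None = None,
    df_range=(4, 5, 6, 7, 8),
    settings: FitSettings | None = None,
):
    """Fit each df in ``df_range`` and pick the BIC minimizer (ties break
    toward fewer parameters).  Returns ``(best_df, scan DataFrame)``."""
    rows = []
    fits = {}
    for df in sorted(df_range):
        if not 4 <= df <= 10:
            raise ValueError(f"df must lie in [4, 10], got {df}")
        row = {"df": df, "loglik": np.nan, "bic": np.nan, "converged": False, "error": ""}
        try:
            fit = fit_sitar(table, df=df, scale=scale, settings=settings)
        except Exception as exc:  # noqa: BLE001 - scan records failures
            row["error"] = f"{type(exc).__name__}: {exc}"
        else:
            fits[df] = fit
            row.update(loglik=fit.loglik, bic=bic(fit), converged=fit.converged)
        rows.append(row)
    scan = pd.DataFrame(rows)
    ok = scan[scan["error"] == ""]
    if len(ok) == 0:
        raise ConvergenceError(
            "every df failed to fit; diagnostics: "
            + "; ".join(f"df={r.df}: {r.error}" for r in scan.itertuples())
        )
    best_df = int(ok.loc[ok["bic"].idxmin(), "df"])  # idxmin takes the first = smallest df
    return best_df, scan


def effects_table(fit: SitarFit) -> pd.DataFrame:
    """Per-survey effects in reporting units: size in cm or kg, timing in
    years, intensity in percent.

    On transformed size scales the size effect is back-converted at the mean
    curve's adult (oldest-age) level; on transformed age scales timing is
    the shift in age at peak velocity.
    """
    from .scale_selection import invert_scale as _inv, timing_in_years

    effs = fit.random_effects
    if fit.scale.size_transform == "identity":
        size = effs["alpha"].to_numpy(dtype=float)
    else:
        base = _inv(fit.adult_level, fit.scale.size_transform)
        size = _inv(fit.adult_level + effs["alpha"].to_numpy(dtype=float), fit.scale.size_transform) - base
    timing = timing_in_years(fit).reindex(effs["survey"]).to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "survey": effs["survey"],
            "size": size,
            "timing": timing,
            "intensity_pct": 100.0 * effs["gamma"].to_numpy(dtype=float),
        }
    )


def adjusted_curves(fit: SitarFit, table: GrowthTable) -> pd.DataFrame:
    """Back-transform each observation onto the mean curve.

    Each point maps to (adjusted age, adjusted value) in natural units; for
    a well-fitting model all surveys superimpose on the mean curve, with
    residual scatter equal to the fit's residual SD on the fitting scale.
    """
    from .scale_selection import invert_scale as _inv

    rows = []
    c0 = fit.fixed_effects["c0"]
    b0 = fit.fixed_effects["b0"]
    for survey in table.surveys:
        grp = table.for_survey(survey)
        u = fit.effect_vector(survey)
        x = apply_scale(grp["age"].to_numpy(), fit.scale.age_transform)
        y = apply_scale(grp["value"].to_numpy(), fit.scale.size_transform)
        z = np.exp(c0 + u[2]) * (x - b0 - u[1])
        x_adj = b0 + z * np.exp(-c0)
        rows.append(
            pd.DataFrame(
                {
                    "survey": survey,
                    "adjusted_age": _inv(x_adj, fit.scale.age_transform),
                    "adjusted_value": _inv(y - u[0], fit.scale.size_transform),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
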