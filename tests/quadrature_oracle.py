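"""Independent marginal-likelihood oracle: adaptive Gauss-Hermite quadrature.

Deliberately shares no code with the package's Laplace implementation: the
conditional mean is rebuilt from the fit's public coefficients, the mode is
found by derivative-free Nelder-Mead, the curvature by finite differences,
and the integral by tensor-product Gauss-Hermite centred at the mode.
"""

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize

from sitar.scale_selection import apply_scale
from sitar.spline_basis import natural_basis


def _conditional_mean(fit, ages, u):
    x = apply_scale(np.asarray(ages, dtype=float), fit.scale.age_transform)
    z = np.exp(fit.fixed_effects["c0"] + u[2]) * (x - fit.fixed_effects["b0"] - u[1])
    coefs = fit._umap @ fit.coef
    return fit.fixed_effects["a0"] + u[0] + natural_basis(z, fit.spline) @ coefs


def gh_marginal_loglik(fit, table, n_nodes=21):
    """Log marginal likelihood by adaptive Gauss-Hermite over the three
    random effects, survey by survey."""
    omega = fit.re_covariance
    o_inv = np.linalg.inv(omega)
    sigma2 = fit.residual_sd**2
    nodes, weights = hermegauss(n_nodes)
    idx = np.stack(np.meshgrid(*([range(n_nodes)] * 3), indexing="ij"), axis=-1)
    grid = nodes[idx].reshape(-1, 3)
    w3 = (weights[idx[..., 0]] * weights[idx[..., 1]] * weights[idx[..., 2]]).ravel()

    total = 0.0
    for survey in table.surveys:
        grp = table.for_survey(survey)
        ages = grp["age"].to_numpy()
        y = apply_scale(grp["value"].to_numpy(), fit.scale.size_transform)

        def neg_joint(u):
            r = y - _conditional_mean(fit, ages, u)
            return 0.5 * np.sum(r * r) / sigma2 + 0.5 * u @ o_inv @ u

        mode = minimize(
            neg_joint,
            np.zeros(3),
            method="Nelder-Mead",
            options={"xatol": 1e-11, "fatol": 1e-14, "maxiter": 20000},
        ).x
        h = 1e-4
        hess = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                ei, ej = np.zeros(3), np.zeros(3)
                ei[i], ej[j] = h, h
                hess[i, j] = (
                    neg_joint(mode + ei + ej)
                    - neg_joint(mode + ei - ej)
                    - neg_joint(mode - ei + ej)
                    + neg_joint(mode - ei - ej)
                ) / (4 * h * h)
        scale_chol = np.linalg.cholesky(np.linalg.inv(hess))
        g0 = neg_joint(mode)
        g_vals = np.array([neg_joint(mode + scale_chol @ n) for n in grid])
        integral = np.sum(w3 * np.exp(-(g_vals - g0) + 0.5 * np.sum(grid * grid, axis=1)))
        total += (
            -0.5 * len(y) * np.log(2 * np.pi * sigma2)
            - 1.5 * np.log(2 * np.pi)
            - 0.5 * np.linalg.slogdet(omega)[1]
            - g0
            + np.log(integral * np.abs(np.linalg.det(scale_chol)))
        )
    return total
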