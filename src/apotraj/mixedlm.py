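"""Two-level linear mixed models estimated by maximum likelihood.

Random-intercept model for measurement ``j`` of woman ``i``::

    y_ij = x_ij' beta + u_i + e_ij,   u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2)

ML estimation profiles the likelihood over the variance ratio
``psi = sigma_u^2 / sigma_e^2``: given ``psi`` the within-group
covariance is compound-symmetric, so the GLS solution for ``beta`` and
the profiled ``sigma_e^2`` have closed forms in per-group sufficient
statistics (cross-products and group sums).  The profiled deviance is
minimised on a log grid followed by bounded Brent refinement.  ML (not
REML) is used throughout so deviances are comparable across fixed-effect
structures during fractional-polynomial selection.

The random-slope variant adds a 2x2 unstructured random-effect
covariance (intercept, slope on a supplied covariate), parameterised by
the Cholesky factor of ``G / sigma_e^2`` so positive semi-definiteness
is maintained during optimisation; ``beta`` and ``sigma_e^2`` are again
profiled out via Woodbury identities on per-group statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .exceptions import BoundaryFitWarning, ConvergenceError, InputError, RankDeficiencyError

_LOG2PI = np.log(2.0 * np.pi)
_SIGMA2_FLOOR = 1e-12


@dataclass
class ModelFit:
    """Fitted two-level model: estimates, covariance, variance components."""

    beta: np.ndarray
    vcov_beta: np.ndarray
    sigma2_u: float
    sigma2_e: float
    deviance: float
    n_obs: int
    n_groups: int
    term_names: list[str]
    converged: bool = True
    boundary: bool = False
    # random-slope variant
    slope_var: float | None = None
    intercept_slope_cov: float | None = None

    @property
    def loglik(self) -> float:
        return -0.5 * self.deviance

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov_beta))

    def coef_frame(self) -> pd.DataFrame:
        se = self.se()
        return pd.DataFrame(
            {
                "term": self.term_names,
                "estimate": self.beta,
                "se": se,
                "ci_lower": self.beta - 1.96 * se,
                "ci_upper": self.beta + 1.96 * se,
            }
        )

    def report(self) -> str:
        lines = [
            "Two-level linear mixed model (ML)",
            f"  observations: {self.n_obs}   groups (women): {self.n_groups}",
            f"  deviance (-2 log L): {self.deviance:.4f}",
            f"  sigma^2_u (between-woman): {self.sigma2_u:.6g}",
            f"  sigma^2_e (residual):      {self.sigma2_e:.6g}",
        ]
        if self.slope_var is not None:
            lines.append(f"  slope variance: {self.slope_var:.6g}  "
                         f"intercept-slope cov: {self.intercept_slope_cov:.6g}")
        lines.append("  " + "-" * 60)
        for name, b, s in zip(self.term_names, self.beta, self.se()):
            lines.append(f"  {name:<32s} {b:>12.6g}  (SE {s:.6g})")
        return "\n".join(lines)


def _group_stats(design: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Sort by group and return per-group sufficient statistics."""
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if design.ndim != 2 or len(design) != len(y) or len(y) != len(groups):
        raise InputError("design, y and groups must be row-aligned")
    order = np.argsort(groups, kind="mergesort")
    x_s, y_s, g_s = design[order], y[order], groups[order]
    first = np.concatenate(([True], g_s[1:] != g_s[:-1]))
    starts = np.flatnonzero(first)
    n_g = np.diff(np.append(starts, len(g_s)))
    # group sums of X and y
    cum_x = np.vstack([np.zeros(design.shape[1]), np.cumsum(x_s, axis=0)])
    cum_y = np.concatenate(([0.0], np.cumsum(y_s)))
    ends = np.append(starts[1:], len(g_s))
    sx = cum_x[ends] - cum_x[starts]            # (G, p)
    sy = cum_y[ends] - cum_y[starts]            # (G,)
    xtx = x_s.T @ x_s
    xty = x_s.T @ y_s
    yty = float(y_s @ y_s)
    return x_s, y_s, n_g, sx, sy, xtx, xty, yty


def _profiled_deviance_ri(psi, n_g, sx, sy, xtx, xty, yty, n_obs):
    """Deviance profiled over beta and sigma_e^2 at a given variance ratio."""
    c = psi / (1.0 + n_g * psi)                 # (G,)
    a_mat = xtx - (sx.T * c) @ sx
    b_vec = xty - sx.T @ (c * sy)
    try:
        l_chol = np.linalg.cholesky(a_mat)
    except np.linalg.LinAlgError:
        raise RankDeficiencyError("design matrix is rank deficient under GLS weighting")
    beta = np.linalg.solve(l_chol.T, np.linalg.solve(l_chol, b_vec))
    q = yty - float(np.sum(c * sy * sy)) - 2.0 * float(beta @ b_vec) + float(beta @ (a_mat @ beta))
    sigma2_e = max(q / n_obs, _SIGMA2_FLOOR)
    logdet = float(np.sum(np.log1p(n_g * psi)))
    dev = n_obs * (_LOG2PI + np.log(sigma2_e) + 1.0) + logdet
    return dev, beta, sigma2_e, a_mat


def fit_random_intercept(design, y, groups, term_names=None, psi_max=1e6) -> ModelFit:
    """ML fit of the random-intercept model.

    Parameters
    ----------
    design : (n, p) array
        Observation-by-term fixed-effect matrix (full column rank).
    y : (n,) array
        Outcome values.
    groups : (n,) array
        Woman identifiers; single-observation groups are retained.
    """
    x_s, y_s, n_g, sx, sy, xtx, xty, yty = _group_stats(design, y, groups)
    n_obs = len(y_s)
    p = x_s.shape[1]
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    if np.linalg.matrix_rank(xtx) < p:
        raise RankDeficiencyError(f"design has rank < {p}")

    def dev_at(log_psi):
        return _profiled_deviance_ri(np.exp(log_psi), n_g, sx, sy, xtx, xty, yty, n_obs)[0]

    grid = np.log(np.geomspace(1e-8, psi_max, 81))
    dev_grid = np.array([dev_at(lp) for lp in grid])
    dev0 = _profiled_deviance_ri(0.0, n_g, sx, sy, xtx, xty, yty, n_obs)[0]
    k = int(np.argmin(dev_grid))
    boundary = False
    if dev0 <= dev_grid[k] + 1e-10:
        psi_hat = 0.0
        boundary = True
    else:
        lo = grid[max(k - 1, 0)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(dev_at, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-10})
        if not res.success:
            raise ConvergenceError("profile optimisation over the variance ratio failed")
        psi_hat = float(np.exp(res.x))
        if k == len(grid) - 1:
            boundary = True
    if boundary and psi_hat > 0:
        warnings.warn("variance ratio at the search boundary", BoundaryFitWarning)

    dev, beta, sigma2_e, a_mat = _profiled_deviance_ri(
        psi_hat, n_g, sx, sy, xtx, xty, yty, n_obs
    )
    vcov = sigma2_e * np.linalg.inv(a_mat)
    return ModelFit(
        beta=beta,
        vcov_beta=vcov,
        sigma2_u=psi_hat * sigma2_e,
        sigma2_e=sigma2_e,
        deviance=dev,
        n_obs=n_obs,
        n_groups=len(n_g),
        term_names=list(term_names),
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# random intercept + slope
# ---------------------------------------------------------------------------

def _slope_group_stats(design, y, groups, slope_cov):
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    z1 = np.asarray(slope_cov, dtype=float)
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="mergesort")
    x_s, y_s, g_s, z_s = design[order], y[order], groups[order], z1[order]
    zmat = np.column_stack([np.ones_like(z_s), z_s])  # (n, 2)
    first = np.concatenate(([True], g_s[1:] != g_s[:-1]))
    starts = np.flatnonzero(first)
    ends = np.append(starts[1:], len(g_s))

    def gsum(arr):
        cum = np.concatenate([np.zeros((1,) + arr.shape[1:]), np.cumsum(arr, axis=0)])
        return cum[ends] - cum[starts]

    ztx = gsum(zmat[:, :, None] * x_s[:, None, :])   # (G, 2, p)
    zty = gsum(zmat * y_s[:, None])                  # (G, 2)
    ztz = gsum(zmat[:, :, None] * zmat[:, None, :])  # (G, 2, 2)
    xtx = x_s.T @ x_s
    xty = x_s.T @ y_s
    yty = float(y_s @ y_s)
    return len(y_s), xtx, xty, yty, ztx, zty, ztz


def _profiled_deviance_rs(theta, stats):
    n_obs, xtx, xty, yty, ztx, zty, ztz = stats
    l11, l21, l22 = theta
    l_mat = np.array([[l11, 0.0], [l21, l22]])
    lam = l_mat @ l_mat.T                           # G / sigma_e^2
    eye = np.eye(2)
    m = eye[None, :, :] + ztz @ lam                 # (G, 2, 2)
    det = m[:, 0, 0] * m[:, 1, 1] - m[:, 0, 1] * m[:, 1, 0]
    if np.any(det <= 0):
        return np.inf, None, None, None
    inv = np.empty_like(m)
    inv[:, 0, 0], inv[:, 1, 1] = m[:, 1, 1], m[:, 0, 0]
    inv[:, 0, 1], inv[:, 1, 0] = -m[:, 0, 1], -m[:, 1, 0]
    inv /= det[:, None, None]
    k = lam[None, :, :] @ inv                       # (G, 2, 2); Lambda (I + W Lambda)^-1
    a_mat = xtx - np.einsum("gai,gab,gbj->ij", ztx, k, ztx)
    b_vec = xty - np.einsum("gai,gab,gb->i", ztx, k, zty)
    try:
        l_chol = np.linalg.cholesky(a_mat)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    beta = np.linalg.solve(l_chol.T, np.linalg.solve(l_chol, b_vec))
    q = (
        yty
        - float(np.einsum("ga,gab,gb->", zty, k, zty))
        - 2.0 * float(beta @ b_vec)
        + float(beta @ (a_mat @ beta))
    )
    sigma2_e = max(q / n_obs, _SIGMA2_FLOOR)
    dev = n_obs * (_LOG2PI + np.log(sigma2_e) + 1.0) + float(np.sum(np.log(det)))
    return dev, beta, sigma2_e, a_mat


def fit_random_slope(design, y, groups, slope_covariate, term_names=None) -> ModelFit:
    """ML fit with correlated random intercept and slope.

    ``slope_covariate`` is the per-observation variable (typically the
    transformed time axis) carrying the woman-specific random slope.
    Reduces to the random-intercept model when the slope variance is 0.
    """
    stats = _slope_group_stats(design, y, groups, slope_covariate)
    p = stats[1].shape[0]
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    if np.linalg.matrix_rank(stats[1]) < p:
        raise RankDeficiencyError(f"design has rank < {p}")

    # warm start from the random-intercept fit
    ri = fit_random_intercept(design, y, groups, term_names=term_names)
    l11_0 = np.sqrt(max(ri.sigma2_u / ri.sigma2_e, 1e-6))

    def objective(theta):
        return _profiled_deviance_rs(theta, stats)[0]

    best = None
    for x0 in ([l11_0, 0.0, 0.05], [l11_0, 0.0, 0.5], [0.5, 0.0, 0.05]):
        res = optimize.minimize(objective, x0=x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("random-slope optimisation failed")
    dev, beta, sigma2_e, a_mat = _profiled_deviance_rs(best.x, stats)
    # never report a worse fit than the nested random-intercept model
    if ri.deviance < dev - 1e-8:
        dev_ri, beta_ri = ri.deviance, ri.beta
        warnings.warn("random-slope fit at the intercept-only boundary", BoundaryFitWarning)
        return ModelFit(
            beta=beta_ri, vcov_beta=ri.vcov_beta, sigma2_u=ri.sigma2_u,
            sigma2_e=ri.sigma2_e, deviance=dev_ri, n_obs=ri.n_obs,
            n_groups=ri.n_groups, term_names=list(term_names),
            boundary=True, slope_var=0.0, intercept_slope_cov=0.0,
        )
    l11, l21, l22 = best.x
    l_mat = np.array([[l11, 0.0], [l21, l22]])
    g_mat = sigma2_e * (l_mat @ l_mat.T)
    vcov = sigma2_e * np.linalg.inv(a_mat)
    return ModelFit(
        beta=beta,
        vcov_beta=vcov,
        sigma2_u=float(g_mat[0, 0]),
        sigma2_e=sigma2_e,
        deviance=dev,
        n_obs=stats[0],
        n_groups=stats[4].shape[0],
        term_names=list(term_names),
        slope_var=float(g_mat[1, 1]),
        intercept_slope_cov=float(g_mat[0, 1]),
    )


def predict_mean(fit: ModelFit, x) -> tuple[float, float]:
    """Population-average prediction ``x' beta`` with its Wald SE."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(fit.beta),):
        raise InputError(
            f"term vector has length {x.shape}, model has {len(fit.beta)} terms"
        )
    est = float(x @ fit.beta)
    se = float(np.sqrt(max(x @ fit.vcov_beta @ x, 0.0)))
    return est, se


def dense_loglik(design, y, groups, beta, sigma2_u, sigma2_e) -> float:
    """Brute-force dense-covariance log-likelihood (oracle for small data)."""
    design = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    resid = y - design @ np.asarray(beta, dtype=float)
    ll = 0.0
    for g in np.unique(groups):
        m = groups == g
        r = resid[m]
        v = sigma2_e * np.eye(m.sum()) + sigma2_u * np.ones((m.sum(), m.sum()))
        sign, logdet = np.linalg.slogdet(v)
        ll += -0.5 * (m.sum() * _LOG2PI + logdet + r @ np.linalg.solve(v, r))
    return float(ll)
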