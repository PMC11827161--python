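"""Deterministic calibration of the APO generator to its prevalence targets.

The generator gives every woman a latent standard-normal frailty ``z``
that shifts the logits of all APO indicators, inducing the co-occurrence
seen in the published APO-count distribution.  Given the frailty
loadings, the per-APO base logits are solved here by quadrature +
root-finding so that the woman-level marginals match their configured
targets *by construction*:

* miscarriage: per-pregnancy probability ``expit(a + lam*z)``; ``(a, lam)``
  jointly solved from the any-miscarriage and 3+-miscarriage targets;
* birth-requiring indicators (PTB, SGA, LGA, stillbirth) are only drawn
  for women with at least one non-miscarried pregnancy, so their solve
  includes the birth-availability factor;
* the SGA/LGA and spontaneous/indicated-PTB pairs are drawn from a single
  uniform (mutually exclusive); the second member's probability is
  truncated at ``1 - p_first`` and the solve accounts for it.

The same quadrature model also yields the implied APO-count distribution
(:func:`implied_count_distribution`), which is what the frailty loadings
frozen in the default config were least-squares calibrated against.
"""

from __future__ import annotations

from functools import lru_cache
from math import comb

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .config import SimConfig

N_QUAD = 61


@lru_cache(maxsize=None)
def _gauss_hermite(n: int = N_QUAD) -> tuple[np.ndarray, np.ndarray]:
    """Nodes/weights for E[f(Z)], Z ~ N(0,1)."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n)
    return nodes, weights / weights.sum()


# ---------------------------------------------------------------------------
# age at first pregnancy: truncated normal whose *realised* mean/SD match
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def solve_truncnorm_params(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float]:
    """Parent (mu, sigma) such that the [lo, hi]-truncated normal has the
    target mean and SD."""

    def resid(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.fsolve(resid, x0=[mean, np.log(sd)], full_output=False)
    mu, sigma = float(sol[0]), float(np.exp(sol[1]))
    return mu, sigma


# ---------------------------------------------------------------------------
# miscarriage model
# ---------------------------------------------------------------------------

def solve_miscarriage(
    any_target: float,
    multiple_target: float,
    parity_levels: tuple[int, ...],
    parity_probs: tuple[float, ...],
) -> tuple[float, float]:
    """Base logit and frailty loading of the per-pregnancy miscarriage
    probability, matching the any-miscarriage and 3+-miscarriage targets."""
    if any_target == 0.0:
        return -np.inf, 0.0
    z, w = _gauss_hermite()
    n_arr = np.asarray(parity_levels)
    pn = np.asarray(parity_probs)

    def moments(a, lam):
        q = expit(a + lam * z)  # (z,)
        none_n = (1 - q)[:, None] ** n_arr[None, :]  # P(no miscarriage in n pregnancies)
        p_any = float(np.sum(w[:, None] * pn[None, :] * (1 - none_n)))
        # P(Bin(n, q) >= 3)
        p3 = np.zeros((z.size, n_arr.size))
        for j, n in enumerate(n_arr):
            if n < 3:
                continue
            tail = np.zeros_like(z)
            for k in range(3, n + 1):
                tail += comb(n, k) * q**k * (1 - q) ** (n - k)
            p3[:, j] = tail
        p_mult = float(np.sum(w[:, None] * pn[None, :] * p3))
        return p_any, p_mult

    def solve_a(lam):
        # base logit matching the any-miscarriage target at this loading
        return optimize.brentq(
            lambda a: moments(a, lam)[0] - any_target, -20.0, 5.0, xtol=1e-12
        )

    def mult_gap(lam):
        return moments(solve_a(lam), lam)[1] - multiple_target

    lo, hi = 1e-3, 6.0
    if mult_gap(lo) > 0:
        lam = lo  # even a near-degenerate frailty overshoots; accept boundary
    else:
        lam = optimize.brentq(mult_gap, lo, hi, xtol=1e-10)
    return float(solve_a(lam)), float(lam)


def birth_availability(a_m: float, lam_m: float, parity_levels, parity_probs) -> np.ndarray:
    """P(at least one non-miscarried pregnancy | z) at the quadrature nodes."""
    z, _ = _gauss_hermite()
    q = expit(a_m + lam_m * z)
    n_arr = np.asarray(parity_levels)
    pn = np.asarray(parity_probs)
    return np.sum(pn[None, :] * (1 - q[:, None] ** n_arr[None, :]), axis=1)


# ---------------------------------------------------------------------------
# woman-level APO indicator base logits
# ---------------------------------------------------------------------------

def solve_flag_logit(
    target: float,
    lam: float,
    avail: np.ndarray | None = None,
    truncate_against: np.ndarray | None = None,
) -> float:
    """Base logit ``a`` with ``E[g(z) * p(z)] = target`` where
    ``p(z) = expit(a + lam*z)`` (optionally truncated at ``1 - p_other``)
    and ``g`` is the birth-availability factor (or 1)."""
    if target == 0.0:
        return -np.inf
    z, w = _gauss_hermite()
    g = np.ones_like(z) if avail is None else avail

    def marginal(a):
        p = expit(a + lam * z)
        if truncate_against is not None:
            p = np.minimum(p, 1.0 - truncate_against)
        return float(np.sum(w * g * p)) - target

    return float(optimize.brentq(marginal, -30.0, 10.0, xtol=1e-12))


def flag_prob_at_nodes(a: float, lam: float) -> np.ndarray:
    z, _ = _gauss_hermite()
    if np.isneginf(a):
        return np.zeros_like(z)
    return expit(a + lam * z)


# ---------------------------------------------------------------------------
# full generator parameter set
# ---------------------------------------------------------------------------

class GeneratorParams:
    """All solved logits/loadings for one configuration (deterministic)."""

    def __init__(self, config: SimConfig):
        apo = config.apo
        prev = {k: float(v) for k, v in apo["prevalence"].items()}
        levels, probs = config.parity_support
        self.parity_levels = tuple(levels)
        self.parity_probs = tuple(probs)
        self.hes_rate = float(config.cohort["hes_linkage_rate"])
        self.lam_hm = float(apo["loadings"]["hypertensive_metabolic"])
        self.lam_bo = float(apo["loadings"]["birth_outcome"])

        self.a_misc, self.lam_misc = solve_miscarriage(
            float(apo["miscarriage"]["any"]),
            float(apo["miscarriage"]["multiple"]),
            self.parity_levels,
            self.parity_probs,
        )
        avail = birth_availability(
            self.a_misc, self.lam_misc, self.parity_levels, self.parity_probs
        )
        self.mean_avail = float(np.sum(_gauss_hermite()[1] * avail))

        self.logits: dict[str, float] = {}
        for name in ("gestational_hypertension", "preeclampsia", "gestational_diabetes"):
            self.logits[name] = solve_flag_logit(prev[name], self.lam_hm)
        self.logits["stillbirth"] = solve_flag_logit(prev["stillbirth"], self.lam_bo, avail)
        # exclusive pairs: first member plain, second truncated against it
        self.logits["ptb_spontaneous"] = solve_flag_logit(
            prev["ptb_spontaneous"], self.lam_bo, avail
        )
        self.logits["ptb_indicated"] = solve_flag_logit(
            prev["ptb_indicated"], self.lam_bo, avail,
            truncate_against=flag_prob_at_nodes(self.logits["ptb_spontaneous"], self.lam_bo),
        )
        self.logits["sga"] = solve_flag_logit(prev["sga"], self.lam_bo, avail)
        self.logits["lga"] = solve_flag_logit(
            prev["lga"], self.lam_bo, avail,
            truncate_against=flag_prob_at_nodes(self.logits["sga"], self.lam_bo),
        )
        # congenital anomalies: no frailty loading, birth-requiring
        self.p_anomaly = float(apo.get("congenital_anomaly", 0.0)) / self.mean_avail

    def loading(self, flag: str) -> float:
        if flag in ("gestational_hypertension", "preeclampsia", "gestational_diabetes"):
            return self.lam_hm
        return self.lam_bo


_PARAMS_CACHE: dict[str, GeneratorParams] = {}


def generator_params(config: SimConfig) -> GeneratorParams:
    """Solved generator parameters, cached on the relevant config blocks."""
    import json

    key = json.dumps(
        {"apo": config.apo, "cohort": config.cohort, "parity": config.covariates["parity"]},
        sort_keys=True, default=str,
    )
    if key not in _PARAMS_CACHE:
        _PARAMS_CACHE[key] = GeneratorParams(config)
    return _PARAMS_CACHE[key]


# ---------------------------------------------------------------------------
# implied APO-count distribution (quadrature mirror of the sampler)
# ---------------------------------------------------------------------------

def _bernoulli_convolve(pmf: np.ndarray, p: float) -> np.ndarray:
    """Convolve a count pmf (categories 0..3 with 3 absorbing) with Bern(p)."""
    out = pmf * (1 - p)
    out[1:] += pmf[:-1] * p
    out[3] += pmf[3] * p  # absorbing 3+
    return out


def implied_count_distribution(config: SimConfig) -> np.ndarray:
    """Model-implied P(APO count = 0, 1, 2, 3+) under the generator."""
    gp = generator_params(config)
    z, w = _gauss_hermite()
    q = expit(gp.a_misc + gp.lam_misc * z)
    p_flags = {k: flag_prob_at_nodes(a, gp.loading(k)) for k, a in gp.logits.items()}
    # exclusive-pair event probabilities (count contributes once per pair member)
    p_sga = p_flags["sga"]
    p_lga = np.minimum(p_flags["lga"], 1 - p_sga)
    p_ps = p_flags["ptb_spontaneous"]
    p_pi = np.minimum(p_flags["ptb_indicated"], 1 - p_ps)

    cells = np.zeros(4)
    for j, n in enumerate(gp.parity_levels):
        pn = gp.parity_probs[j]
        for b in range(n + 1):
            w_b = comb(n, b) * (1 - q) ** b * q ** (n - b)  # (z,)
            m3 = (n - b) >= 3
            for linked, w_h in ((True, gp.hes_rate), (False, 1 - gp.hes_rate)):
                pmf = np.zeros((z.size, 4))
                pmf[:, 0] = 1.0
                terms = [
                    p_flags["gestational_hypertension"],
                    p_flags["preeclampsia"],
                    p_flags["gestational_diabetes"],
                ]
                if b >= 1:
                    terms.append(p_flags["stillbirth"])
                    if linked:
                        terms.append(p_ps + p_pi)
                        terms.append(p_sga + p_lga)
                for p in terms:
                    new = pmf * (1 - p)[:, None]
                    new[:, 1:] += pmf[:, :-1] * p[:, None]
                    new[:, 3] += pmf[:, 3] * p
                    pmf = new
                if m3:
                    shifted = np.zeros_like(pmf)
                    shifted[:, 1:] = pmf[:, :-1]
                    shifted[:, 3] += pmf[:, 3]
                    pmf = shifted
                cells += w_h * pn * np.sum((w * w_b)[:, None] * pmf, axis=0)
    return cells


def calibrate_loadings(
    config: SimConfig,
    bounds: tuple[float, float] = (0.1, 3.0),
) -> tuple[float, float, np.ndarray]:
    """Least-squares fit of the two frailty loadings to the configured
    APO-count distribution.  Used once to produce the frozen defaults."""
    targets = np.asarray(config.apo["count_targets"], dtype=float)
    weights = 1.0 / np.maximum(targets * (1 - targets), 1e-4)

    def resid(lams):
        cfg = config.updated(
            {"apo": {"loadings": {"hypertensive_metabolic": float(lams[0]),
                                  "birth_outcome": float(lams[1])}}}
        )
        cells = implied_count_distribution(cfg)
        return np.sqrt(weights) * (cells - targets)

    sol = optimize.least_squares(resid, x0=[0.9, 0.9], bounds=bounds, xtol=1e-10)
    lam_hm, lam_bo = map(float, sol.x)
    cfg = config.updated(
        {"apo": {"loadings": {"hypertensive_metabolic": lam_hm, "birth_outcome": lam_bo}}}
    )
    return lam_hm, lam_bo, implied_count_distribution(cfg)
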