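"""Synthetic primary-care-EHR cohort generator with known ground truth.

Generates three linked tables (women, pregnancies, long-format repeated
cardiometabolic measurements) whose covariate marginals, woman-level APO
prevalences, APO-count distribution and observation process are
calibrated to the published cohort description, and whose true group-mean
trajectories interpolate the published predicted systolic-BP values.

Ground-truth model for a measurement of outcome ``o`` on woman ``i`` of
APO-count group ``g`` at time ``t`` (years relative to first-pregnancy
start)::

    y = mu_g_o(t) + sum_c beta_c (x_ic - E[x_c]) + u_i + e,
    u_i ~ N(0, sigma_u^2),  e ~ N(0, sigma_e^2)

with mean-centred covariate effects, so ``mu_g_o`` *is* the
population-average curve of group ``g``.  Measurement times follow a
homogeneous Poisson process over the observation window whose rate is
multiplied by an APO-count-dependent propensity (women with APOs are
observed more).  Measurements falling inside a pregnancy interval are
generated and flagged ``in_pregnancy``; excluding them is the analysis
pipeline's job, not the generator's.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from . import apo as apo_mod
from ._calibrate import generator_params, solve_truncnorm_params
from .config import COUNT_GROUPS, HES_FLAGS, OUTCOMES, SimConfig, default_config
from .exceptions import ConfigError, DomainError

WOMEN_COLUMNS = [
    "woman_id", "age_first_pregnancy", "townsend_quintile", "ethnicity",
    "smoking_ever", "parity", "ever_nonsingleton", "med_antihypertensive",
    "med_lipid_lowering", "med_hypoglycaemic",
]
PREGNANCY_COLUMNS = [
    "woman_id", "preg_index", "t_start", "t_end", "outcome",
    "gestational_hypertension", "preeclampsia", "gestational_diabetes",
    "ptb_spontaneous", "ptb_indicated", "sga", "lga", "congenital_anomaly",
]
MEASUREMENT_COLUMNS = [
    "woman_id", "outcome_type", "value", "t_rel", "age", "in_pregnancy", "fasting",
]


# ---------------------------------------------------------------------------
# truth curves
# ---------------------------------------------------------------------------

class TruthCurves:
    """Group-specific true mean curves: one quadratic per pre/post segment.

    Each (outcome, group) anchor set must contain one pre-pregnancy
    anchor, an anchor at t=0 and two post-pregnancy anchors.  The post
    quadratic passes exactly through its three anchors; the pre quadratic
    matches the pre anchor and is value- and slope-continuous with the
    post segment at t=0.  The curve is therefore exact at every anchor
    and lies inside the degree-2 fractional-polynomial family that the
    trajectory models fit, so parameter-recovery checks measure
    estimation error rather than interpolation mismatch.
    """

    def __init__(self, config: SimConfig):
        self.window = config.window
        self._coef: dict[tuple[str, str], tuple[float, float, float, float]] = {}
        for outcome, groups in config.truth["anchors"].items():
            for group, anchors in groups.items():
                pts = sorted((float(t), float(v)) for t, v in anchors.items())
                pre = [p for p in pts if p[0] < 0]
                zero = [p for p in pts if p[0] == 0]
                post = [p for p in pts if p[0] > 0]
                if len(pre) != 1 or len(zero) != 1 or len(post) != 2:
                    raise ConfigError(
                        f"anchors for {outcome}/{group} must be one pre anchor, "
                        "one at t=0 and two post anchors"
                    )
                m = zero[0][1]
                (t1, v1), (t2, v2) = post
                # post segment: m + b t + c t^2 through both post anchors
                det = t1 * t2**2 - t2 * t1**2
                b = ((v1 - m) * t2**2 - (v2 - m) * t1**2) / det
                c = ((v2 - m) * t1 - (v1 - m) * t2) / det
                ta, va = pre[0]
                d = (va - m - b * ta) / ta**2  # pre curvature; shares slope b at 0
                self._coef[(outcome, str(group))] = (m, b, c, d)

    def __call__(self, group: str, outcome: str, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        lo, hi = self.window
        if np.any(t < lo) or np.any(t > hi):
            raise DomainError(f"truth curve evaluated outside the window [{lo}, {hi}]")
        key = (outcome, str(group))
        if key not in self._coef:
            raise ConfigError(f"no truth anchors configured for {outcome}/{group}")
        m, b, c, d = self._coef[key]
        curv = np.where(t < 0, d, c)
        return m + b * t + curv * t * t


def truth_curve(group: str, outcome_type: str, t_rel, config: SimConfig | None = None):
    """Evaluate the true group-mean curve (scalar in, scalar out)."""
    config = config or default_config()
    out = TruthCurves(config)(group, outcome_type, t_rel)
    return float(out[0]) if np.isscalar(t_rel) else out


# ---------------------------------------------------------------------------
# women
# ---------------------------------------------------------------------------

def simulate_women(n: int, config: SimConfig | None = None, seed=0) -> pd.DataFrame:
    """Draw ``n`` women with the configured covariate marginals."""
    config = config or default_config()
    if n < 1:
        raise ConfigError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    cov = config.covariates

    age_cfg = cov["age_first_pregnancy"]
    lo, hi = float(age_cfg["min"]), float(age_cfg["max"])
    # parent parameters chosen so the truncated draw realises the target mean/SD
    mu, sigma = solve_truncnorm_params(float(age_cfg["mean"]), float(age_cfg["sd"]), lo, hi)
    age = stats.truncnorm.rvs(
        (lo - mu) / sigma, (hi - mu) / sigma, loc=mu, scale=sigma, size=n, random_state=rng
    )

    tq = rng.choice(np.arange(1, 6), size=n, p=config.townsend_probs).astype(float)
    tq[rng.random(n) < config.townsend_missing] = np.nan
    eth_cfg = cov["ethnicity"]
    eth_levels = ["white", "non_white", "unknown"]
    eth_probs = np.array([eth_cfg[k] for k in eth_levels], dtype=float)
    ethnicity = rng.choice(eth_levels, size=n, p=eth_probs / eth_probs.sum())
    levels, probs = config.parity_support
    parity = rng.choice(levels, size=n, p=probs)

    return pd.DataFrame(
        {
            "woman_id": np.arange(1, n + 1),
            "age_first_pregnancy": age,
            "townsend_quintile": tq,
            "ethnicity": ethnicity,
            "smoking_ever": (rng.random(n) < float(cov["smoking_ever"])).astype(int),
            "parity": parity,
            "ever_nonsingleton": (rng.random(n) < float(cov["ever_nonsingleton"])).astype(int),
            "med_antihypertensive": (rng.random(n) < float(cov["med_antihypertensive"])).astype(int),
            "med_lipid_lowering": (rng.random(n) < float(cov["med_lipid_lowering"])).astype(int),
            "med_hypoglycaemic": (rng.random(n) < float(cov["med_hypoglycaemic"])).astype(int),
        },
        columns=WOMEN_COLUMNS,
    )


# ---------------------------------------------------------------------------
# pregnancies
# ---------------------------------------------------------------------------

def _attach_rows(rng, flagged: np.ndarray, counts: np.ndarray, offsets: np.ndarray,
                 row_index: np.ndarray) -> np.ndarray:
    """Uniformly pick one eligible row for each flagged woman."""
    idx = np.flatnonzero(flagged)
    pick = offsets[idx] + np.floor(rng.random(idx.size) * counts[idx]).astype(np.int64)
    return row_index[pick]


def simulate_pregnancies(women: pd.DataFrame, config: SimConfig | None = None, seed=0) -> pd.DataFrame:
    """Draw each woman's pregnancies with APO flags and timings.

    A shared latent standard-normal frailty per woman shifts all APO
    logits (inducing the published APO co-occurrence); per-APO base
    logits are solved from the configured prevalence targets at call
    time, so woman-level marginals match by construction.  Preterm-birth
    and SGA/LGA flags are set missing for women without hospital-episode
    linkage.
    """
    config = config or default_config()
    gp = generator_params(config)
    rng = np.random.default_rng(seed)
    n = len(women)
    parity = women["parity"].to_numpy(dtype=int)
    if np.any(parity < 1):
        raise ConfigError("every woman must have parity >= 1")

    z = rng.standard_normal(n)
    hes = rng.random(n) < gp.hes_rate

    total = int(parity.sum())
    widx = np.repeat(np.arange(n), parity)
    offsets_all = np.concatenate(([0], np.cumsum(parity)[:-1]))
    preg_index = np.arange(total) - offsets_all[widx] + 1

    q = expit(gp.a_misc + gp.lam_misc * z)
    misc = rng.random(total) < q[widx]
    outcome = np.where(misc, "miscarriage", "live birth").astype(object)

    birth_rows = np.flatnonzero(~misc)
    n_births = np.bincount(widx[~misc], minlength=n)
    birth_offsets = np.concatenate(([0], np.cumsum(n_births)[:-1]))
    has_birth = n_births >= 1

    def p(flag):
        a = gp.logits[flag]
        return expit(a + gp.loading(flag) * z) if np.isfinite(a) else np.zeros(n)

    gh_w = rng.random(n) < p("gestational_hypertension")
    pe_w = rng.random(n) < p("preeclampsia")
    gd_w = rng.random(n) < p("gestational_diabetes")
    sb_w = (rng.random(n) < p("stillbirth")) & has_birth
    u_ptb = rng.random(n)
    ps_w = (u_ptb < p("ptb_spontaneous")) & has_birth
    pi_w = (~ps_w) & (u_ptb < p("ptb_spontaneous") + p("ptb_indicated")) & has_birth
    u_sl = rng.random(n)
    sga_w = (u_sl < p("sga")) & has_birth
    lga_w = (~sga_w) & (u_sl < p("sga") + p("lga")) & has_birth
    an_w = (rng.random(n) < gp.p_anomaly) & has_birth

    flags = {name: np.zeros(total) for name in apo_mod.ALL_FLAGS}
    all_rows = np.arange(total)
    for name, w_flag in (
        ("gestational_hypertension", gh_w),
        ("preeclampsia", pe_w),
        ("gestational_diabetes", gd_w),
    ):
        rows = _attach_rows(rng, w_flag, parity, offsets_all, all_rows)
        flags[name][rows] = 1.0
    for name, w_flag in (
        ("ptb_spontaneous", ps_w),
        ("ptb_indicated", pi_w),
        ("sga", sga_w),
        ("lga", lga_w),
        ("congenital_anomaly", an_w),
    ):
        rows = _attach_rows(rng, w_flag, n_births, birth_offsets, birth_rows)
        flags[name][rows] = 1.0
    sb_rows = _attach_rows(rng, sb_w, n_births, birth_offsets, birth_rows)
    outcome[sb_rows] = "stillbirth"

    unlinked_rows = ~hes[widx]
    for name in HES_FLAGS:
        flags[name][unlinked_rows] = np.nan

    gest = np.where(misc, float(config.timing["gestation_miscarriage"]),
                    float(config.timing["gestation_birth"]))
    gap = rng.uniform(float(config.timing["gap_min"]), float(config.timing["gap_max"]), total)
    first = preg_index == 1
    gap[first] = 0.0
    prev_gest = np.roll(gest, 1)
    prev_gest[first] = 0.0
    seq = gap + prev_gest
    cs = np.cumsum(seq)
    t_start = cs - np.repeat(cs[np.flatnonzero(first)], parity)
    t_end = t_start + gest

    out = pd.DataFrame(
        {
            "woman_id": women["woman_id"].to_numpy()[widx],
            "preg_index": preg_index,
            "t_start": t_start,
            "t_end": t_end,
            "outcome": outcome,
            **flags,
        },
        columns=PREGNANCY_COLUMNS,
    )
    return out


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def simulate_measurements(
    women: pd.DataFrame,
    pregnancies: pd.DataFrame,
    config: SimConfig | None = None,
    seed=0,
    outcomes: list[str] | None = None,
) -> pd.DataFrame:
    """Generate the long-format repeated-measurements table."""
    config = config or default_config()
    truth = TruthCurves(config)
    outcomes = list(outcomes) if outcomes is not None else list(OUTCOMES)
    for o in outcomes:
        if o not in OUTCOMES:
            raise ConfigError(f"unknown outcome '{o}'")
        if o not in config.truth["anchors"]:
            raise ConfigError(f"no truth curves configured for outcome '{o}'")

    n = len(women)
    profiles = apo_mod.derive_apo_profiles(pregnancies)
    group = (
        women[["woman_id"]]
        .merge(profiles[["woman_id", "n_apos"]], on="woman_id", how="left")["n_apos"]
        .to_numpy()
    )
    group_codes = np.array([COUNT_GROUPS.index(g) for g in group])
    mult_map = config.observation["group_multipliers"]
    mult = np.array([float(mult_map[g]) for g in group])

    cov_cfg = config.covariates
    smoking = women["smoking_ever"].to_numpy(dtype=float)
    town = women["townsend_quintile"].to_numpy(dtype=float)
    town_probs = np.asarray(config.townsend_probs)
    e_town = float(np.sum(np.arange(1, 6) * town_probs))
    town_centered = np.where(np.isnan(town), 0.0, town - e_town)
    smoke_centered = smoking - float(cov_cfg["smoking_ever"])
    afp = women["age_first_pregnancy"].to_numpy(dtype=float)

    lo, hi = config.window
    fast_prob = float(config.observation["fasting_prob"])
    fast_eff = float(config.truth["fasting_effect"])

    # independent child streams per outcome, stable under outcome subsetting
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(OUTCOMES))
    frames = []
    for o_i, outcome in enumerate(OUTCOMES):
        if outcome not in outcomes:
            continue
        rng = np.random.default_rng(children[o_i])
        lam = float(config.observation["base_counts"][outcome]) * mult
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            continue
        widx = np.repeat(np.arange(n), counts)
        t = rng.uniform(lo, hi, total)

        mu = np.empty(total)
        for g_i, g in enumerate(COUNT_GROUPS):
            mask = group_codes[widx] == g_i
            if mask.any():
                mu[mask] = truth(g, outcome, t[mask])

        effects = config.truth["covariate_effects"].get(outcome, {})
        cov_eff = (
            float(effects.get("smoking_ever", 0.0)) * smoke_centered
            + float(effects.get("townsend_quintile", 0.0)) * town_centered
        )
        su, se = config.noise_sd(outcome)
        u = rng.normal(0.0, su, n) if su > 0 else np.zeros(n)
        e = rng.normal(0.0, se, total) if se > 0 else np.zeros(total)
        value = mu + cov_eff[widx] + u[widx] + e

        fasting = np.full(total, np.nan)
        if outcome == "glucose":
            fast = (rng.random(total) < fast_prob).astype(float)
            value = value + fast_eff * (fast - fast_prob)
            fasting = fast

        b_lo, b_hi = (float(x) for x in config.truth["bounds"][outcome])
        bad = (value < b_lo) | (value > b_hi)
        tries = 0
        while bad.any():
            if se <= 0 or tries > 100:
                raise ConfigError(
                    f"{outcome}: cannot satisfy plausibility bounds by residual rejection"
                )
            e_new = rng.normal(0.0, se, int(bad.sum()))
            value[bad] = mu[bad] + cov_eff[widx[bad]] + u[widx[bad]] + e_new
            if outcome == "glucose":
                value[bad] += fast_eff * (fasting[bad] - fast_prob)
            bad = (value < b_lo) | (value > b_hi)
            tries += 1

        frames.append(
            pd.DataFrame(
                {
                    "woman_id": women["woman_id"].to_numpy()[widx],
                    "outcome_type": outcome,
                    "value": value,
                    "t_rel": t,
                    "age": afp[widx] + t,
                    "fasting": fasting,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    meas = pd.concat(frames, ignore_index=True)
    meas = meas.sort_values(["woman_id", "outcome_type", "t_rel"], kind="mergesort").reset_index(drop=True)
    meas["in_pregnancy"] = apo_mod.in_pregnancy_flags(meas, pregnancies).astype(int)
    return meas[MEASUREMENT_COLUMNS]


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    women: pd.DataFrame
    pregnancies: pd.DataFrame
    measurements: pd.DataFrame
    config: SimConfig
    seed: int

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("women", self.women),
            ("pregnancies", self.pregnancies),
            ("measurements", self.measurements),
        ):
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = str(path)
        return paths


def simulate_cohort(
    n: int,
    config: SimConfig | None = None,
    seed: int = 0,
    outcomes: list[str] | None = None,
) -> SimulatedCohort:
    """Simulate the full three-table cohort with one master seed."""
    config = config or default_config()
    ss = np.random.SeedSequence(seed)
    s_women, s_preg, s_meas = ss.spawn(3)
    women = simulate_women(n, config, seed=s_women)
    pregnancies = simulate_pregnancies(women, config, seed=s_preg)
    measurements = simulate_measurements(women, pregnancies, config, seed=s_meas, outcomes=outcomes)
    return SimulatedCohort(women, pregnancies, measurements, config, seed)


def load_cohort(indir) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read the three delimited-text tables written by :meth:`SimulatedCohort.write`."""
    indir = Path(indir)
    women = pd.read_csv(indir / "women.csv")
    pregnancies = pd.read_csv(indir / "pregnancies.csv")
    measurements = pd.read_csv(indir / "measurements.csv")
    return women, pregnancies, measurements


# ---------------------------------------------------------------------------
# simple FP-truth generator (selection-consistency experiments)
# ---------------------------------------------------------------------------

def simulate_fp_dataset(
    n_women: int,
    powers: tuple[float, ...],
    coef: tuple[float, ...],
    intercept: float = 0.0,
    intercept_sd: float = 1.0,
    residual_sd: float = 2.0,
    obs_per_woman: float = 3.0,
    window: tuple[float, float] = (-10.0, 15.0),
    seed=0,
) -> pd.DataFrame:
    """Repeated measures whose mean is a known fractional polynomial of time.

    Used to study power-selection consistency; returns a minimal
    analysis-style frame (woman_id, value, t_rel, post, exposure).  The
    positivity transform matches the one the trajectory pipeline fits
    with, so the generating powers are inside the candidate family.
    """
    from .fp import TIME_FP_MARGIN, FPSpec, fp_transform, make_positive

    rng = np.random.default_rng(seed)
    counts = np.maximum(rng.poisson(obs_per_woman, n_women), 1)
    widx = np.repeat(np.arange(n_women), counts)
    total = int(counts.sum())
    t = rng.uniform(window[0], window[1], total)
    shift, scale = make_positive(np.asarray(window), margin=TIME_FP_MARGIN)
    spec = FPSpec(powers=powers, shift=shift, scale=scale)
    mu = intercept + fp_transform(t, spec) @ np.asarray(coef, dtype=float)
    u = rng.normal(0.0, intercept_sd, n_women)
    y = mu + u[widx] + rng.normal(0.0, residual_sd, total)
    return pd.DataFrame(
        {
            "woman_id": widx + 1,
            "value": y,
            "t_rel": t,
            "age": 27.0 + t,
            "post": (t > 0).astype(float),
            "exposure": "all",
        }
    )
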