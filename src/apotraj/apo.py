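"""Woman-level APO exposure derivation and analysis-table construction.

Implements the exposure-coding rules of the trajectory analysis:

* any-pregnancy APO flags are the OR over a woman's pregnancies (missing
  where underivable for every pregnancy, e.g. without hospital linkage);
* the APO count sums, over all pregnancies, occurrences of gestational
  hypertension, preeclampsia, gestational diabetes, preterm birth (either
  type), SGA, LGA and stillbirth — a pregnancy with both PE and SGA
  contributes two — plus one if the woman had 3+ miscarriages; 1–2
  miscarriages and congenital anomalies never contribute;
* the any-APO contrast classifies women as APO (count >= 1), healthy-only
  (count 0, all pregnancies live births, no anomaly) or unclassifiable;
* comparator masks implement the published exclusions (LGA women removed
  from the SGA comparator and vice versa; three-group preterm-birth
  coding; unclassifiable women dropped from the any-APO contrast);
* the analysis table drops in-pregnancy and out-of-window measurements,
  applies the eligibility mode and attaches exposure and covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyAnalysisError, InputError

#: per-pregnancy flags that contribute to the APO count
COUNTED_FLAGS = (
    "gestational_hypertension",
    "preeclampsia",
    "gestational_diabetes",
    "ptb_spontaneous",
    "ptb_indicated",
    "sga",
    "lga",
)

ALL_FLAGS = COUNTED_FLAGS + ("congenital_anomaly",)

#: exposures accepted by :func:`comparator_mask`
EXPOSURES = (
    "gestational_hypertension",
    "preeclampsia",
    "gestational_diabetes",
    "ptb",
    "sga",
    "lga",
    "miscarriage_any",
    "miscarriage_multiple",
    "stillbirth",
    "congenital_anomaly",
    "any_apo",
    "n_apos",
)


def derive_apo_profiles(pregnancies: pd.DataFrame, distinct_types: bool = False) -> pd.DataFrame:
    """Derive one :class:`APOProfile` row per woman from the pregnancies table.

    Parameters
    ----------
    pregnancies
        One row per pregnancy with columns ``woman_id``, ``outcome`` and
        the per-pregnancy APO flag columns (missing values allowed where
        a flag is underivable).
    distinct_types
        If True, a recurring APO type counts once toward the APO count
        (default counts every per-pregnancy occurrence).
    """
    if len(pregnancies) == 0:
        raise InputError("empty pregnancies table")
    df = pregnancies
    grouped = df.groupby("woman_id", sort=True)

    flags = grouped[list(ALL_FLAGS)].max()  # NaN iff all-missing for the woman
    out = flags.copy()

    is_misc = (df["outcome"] == "miscarriage").astype(int)
    is_sb = (df["outcome"] == "stillbirth").astype(int)
    is_live = (df["outcome"] == "live birth").astype(int)
    per_woman = pd.DataFrame(
        {
            "woman_id": df["woman_id"],
            "n_misc": is_misc,
            "n_sb": is_sb,
            "n_live": is_live,
            "n_preg": 1,
        }
    ).groupby("woman_id", sort=True).sum()

    out["stillbirth"] = (per_woman["n_sb"] > 0).astype(float)
    out["miscarriage_any"] = (per_woman["n_misc"] > 0).astype(float)
    out["miscarriage_multiple"] = (per_woman["n_misc"] >= 3).astype(float)

    counted = df[list(COUNTED_FLAGS)].fillna(0.0)
    if distinct_types:
        woman_any = counted.groupby(df["woman_id"], sort=True).max()
        ptb_any = woman_any[["ptb_spontaneous", "ptb_indicated"]].max(axis=1)
        others = woman_any.drop(columns=["ptb_spontaneous", "ptb_indicated"])
        raw = others.sum(axis=1) + ptb_any + (per_woman["n_sb"] > 0)
    else:
        raw = counted.sum(axis=1).groupby(df["woman_id"], sort=True).sum() + per_woman["n_sb"]
    raw = raw + out["miscarriage_multiple"]
    out["n_apos_raw"] = raw.astype(int)
    out["n_apos"] = pd.cut(
        out["n_apos_raw"], bins=[-0.5, 0.5, 1.5, 2.5, np.inf], labels=["0", "1", "2", "3+"]
    ).astype(str)

    anomaly = flags["congenital_anomaly"].fillna(0.0)
    healthy = (
        (out["n_apos_raw"] == 0)
        & (per_woman["n_live"] == per_woman["n_preg"])
        & (anomaly == 0)
    )
    out["any_apo"] = np.where(
        out["n_apos_raw"] >= 1, "apo", np.where(healthy, "healthy", "unclassifiable")
    )
    return out.reset_index()


def derive_apo_profile(pregnancies: pd.DataFrame, distinct_types: bool = False) -> pd.Series:
    """Profile for a single woman (all rows must share one woman_id)."""
    if len(pregnancies) == 0:
        raise InputError("a woman must have at least one pregnancy")
    if pregnancies["woman_id"].nunique() != 1:
        raise InputError("derive_apo_profile expects one woman's pregnancies")
    return derive_apo_profiles(pregnancies, distinct_types=distinct_types).iloc[0]


def comparator_mask(exposure: str, profiles: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Per-woman group labels for an exposure contrast.

    Returns ``(labels, levels)`` where ``labels`` is a Series indexed by
    woman_id (NaN = excluded from the contrast) and ``levels`` lists the
    group labels with the comparator/reference level first.
    """
    if exposure not in EXPOSURES:
        raise InputError(f"unknown exposure '{exposure}'; expected one of {EXPOSURES}")
    p = profiles.set_index("woman_id")
    if exposure == "n_apos":
        labels = p["n_apos"].astype(object)
        return labels, ["0", "1", "2", "3+"]
    if exposure == "any_apo":
        labels = p["any_apo"].where(p["any_apo"] != "unclassifiable").astype(object)
        return labels, ["healthy", "apo"]
    if exposure == "ptb":
        ps, pi = p["ptb_spontaneous"], p["ptb_indicated"]
        labels = pd.Series(np.nan, index=p.index, dtype=object)
        known = ps.notna() & pi.notna()
        labels[known & (pi == 1)] = "indicated"
        labels[known & (pi == 0) & (ps == 1)] = "spontaneous"
        labels[known & (pi == 0) & (ps == 0)] = "no_ptb"
        return labels, ["no_ptb", "spontaneous", "indicated"]
    flag = p[exposure]
    labels = pd.Series(np.nan, index=p.index, dtype=object)
    labels[flag == 1] = "exposed"
    labels[flag == 0] = "comparator"
    if exposure == "sga":
        labels[(flag == 0) & (p["lga"] == 1)] = np.nan
    elif exposure == "lga":
        labels[(flag == 0) & (p["sga"] == 1)] = np.nan
    return labels, ["comparator", "exposed"]


@dataclass
class AnalysisTable:
    """Filtered long-format measurement table ready for model fitting."""

    df: pd.DataFrame
    outcome: str
    exposure: str
    levels: list[str]
    window: tuple[float, float]
    eligibility: str
    covariate_cols: list[str] = field(default_factory=list)
    n_excluded_comparator: int = 0

    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def n_women(self) -> int:
        return int(self.df["woman_id"].nunique())


def in_pregnancy_flags(measurements: pd.DataFrame, pregnancies: pd.DataFrame) -> np.ndarray:
    """Independent interval-overlap flag: t_rel inside any pregnancy window."""
    merged = measurements[["woman_id", "t_rel"]].reset_index().merge(
        pregnancies[["woman_id", "t_start", "t_end"]], on="woman_id", how="left"
    )
    hit = (merged["t_rel"] >= merged["t_start"]) & (merged["t_rel"] <= merged["t_end"])
    flags = hit.groupby(merged["index"]).any()
    out = np.zeros(len(measurements), dtype=bool)
    out[flags.index[flags.values]] = True
    return out


def build_analysis_table(
    measurements: pd.DataFrame,
    pregnancies: pd.DataFrame,
    profiles: pd.DataFrame,
    women: pd.DataFrame,
    outcome_type: str,
    exposure: str = "n_apos",
    window: tuple[float, float] = (-10.0, 15.0),
    eligibility: str = "any",
) -> AnalysisTable:
    """Build the per-outcome analysis table.

    Applies, in order: outcome selection, the in-pregnancy exclusion (by
    interval overlap against the pregnancies table), the analysis window,
    the comparator mask for ``exposure``, the eligibility mode, and
    attaches the post-pregnancy indicator (strictly ``t_rel > 0``) and
    baseline covariates.  Rows with a missing deprivation quintile are
    dropped (the covariate set adjusts for it).
    """
    if eligibility not in ("any", "pre_and_post"):
        raise InputError(f"unknown eligibility mode '{eligibility}'")
    meas = measurements[measurements["outcome_type"] == outcome_type].copy()
    meas = meas.reset_index(drop=True)
    if len(meas):
        meas = meas[~in_pregnancy_flags(meas, pregnancies)]
    lo, hi = window
    meas = meas[(meas["t_rel"] >= lo) & (meas["t_rel"] <= hi)]

    labels, levels = comparator_mask(exposure, profiles)
    meas["exposure"] = meas["woman_id"].map(labels)
    n_women_before = meas["woman_id"].nunique()
    meas = meas[meas["exposure"].notna()]
    n_excluded = int(n_women_before - meas["woman_id"].nunique())

    if eligibility == "pre_and_post":
        by_woman = meas.groupby("woman_id")["t_rel"]
        has_pre = by_woman.transform(lambda s: (s <= 0).any())
        has_post = by_woman.transform(lambda s: (s > 0).any())
        meas = meas[has_pre & has_post]

    cov = women.set_index("woman_id")
    meas = meas.join(
        cov[
            [
                "age_first_pregnancy",
                "townsend_quintile",
                "ethnicity",
                "smoking_ever",
                "parity",
                "ever_nonsingleton",
                "med_antihypertensive",
                "med_lipid_lowering",
                "med_hypoglycaemic",
            ]
        ],
        on="woman_id",
    )
    meas = meas[meas["townsend_quintile"].notna()]
    if len(meas) == 0:
        raise EmptyAnalysisError(
            f"no rows left for outcome={outcome_type}, exposure={exposure} after filtering"
        )
    present = set(meas["exposure"].unique())
    levels = [lv for lv in levels if lv in present]
    if len(levels) < 2:
        raise InputError(
            f"exposure '{exposure}' has fewer than two groups after filtering: {sorted(present)}"
        )

    meas["post"] = (meas["t_rel"] > 0).astype(float)

    cov_cols: list[str] = ["age_first_pregnancy"]
    # deprivation quintile indicators, most frequent level as reference
    tq = meas["townsend_quintile"].astype(int)
    ref_q = int(tq.value_counts().idxmax())
    for q in sorted(tq.unique()):
        if q == ref_q:
            continue
        col = f"townsend_q{q}"
        meas[col] = (tq == q).astype(float)
        cov_cols.append(col)
    eth = meas["ethnicity"].astype(str)
    ref_eth = eth.value_counts().idxmax()
    for lev in sorted(eth.unique()):
        if lev == ref_eth:
            continue
        col = f"ethnicity_{lev}"
        meas[col] = (eth == lev).astype(float)
        cov_cols.append(col)
    meas["parity_trunc"] = np.minimum(meas["parity"].astype(float), 5.0)
    cov_cols.append("parity_trunc")
    for col in (
        "smoking_ever",
        "ever_nonsingleton",
        "med_antihypertensive",
        "med_lipid_lowering",
        "med_hypoglycaemic",
    ):
        meas[col] = meas[col].astype(float)
        cov_cols.append(col)
    if outcome_type == "glucose":
        meas["fasting"] = meas["fasting"].fillna(0.0).astype(float)
        cov_cols.append("fasting")
    elif "fasting" in meas.columns:
        meas = meas.drop(columns=["fasting"])

    # constant columns (e.g. a medication nobody in the subgroup uses)
    # carry no information and would make the design rank deficient
    cov_cols = [c for c in cov_cols if meas[c].nunique() > 1]

    keep = ["woman_id", "value", "t_rel", "age", "post", "exposure"] + cov_cols
    df = meas[keep].reset_index(drop=True)
    return AnalysisTable(
        df=df,
        outcome=outcome_type,
        exposure=exposure,
        levels=levels,
        window=window,
        eligibility=eligibility,
        covariate_cols=cov_cols,
        n_excluded_comparator=n_excluded,
    )
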