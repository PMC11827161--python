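"""Life-course trajectory models by APO exposure.

The estimation pipeline for one outcome / exposure / axis combination:

1. select the fractional-polynomial (FP) degree and powers on a baseline
   random-intercept model (FP terms + exposure main effects + pre/post
   indicator + covariates), comparing the best degree-2 candidate with
   the best degree-1 candidate by the conventional FP deviance test
   (chi-square, 2 df); the chosen powers are then frozen;
2. build the interaction design — on the time axis, three-way
   interactions between each FP term, the exposure indicators and the
   pre/post-first-pregnancy indicator (plus all two-way margins); on the
   age axis, FP-by-exposure interactions only;
3. fit by ML with a woman-level random intercept (optionally a random
   slope), and
4. predict group-specific mean trajectories with 95% Wald confidence
   intervals at the average observed covariate levels.

Organised statsmodels-style: :class:`APOTrajectoryModel` holds the data
and design choices; ``fit()`` returns an :class:`APOTrajectoryResults`
carrying estimates, their covariance, variance components, deviance, a
``summary()`` table, and prediction/contrast/plot methods.  Thin
module-level functions (:func:`select_fp`, :func:`build_design`,
:func:`fit_trajectory`, :func:`predict_trajectories`,
:func:`contrast`) expose the same steps functionally.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .apo import AnalysisTable, build_analysis_table, derive_apo_profiles
from .exceptions import ConvergenceError, DomainError, InputError
from .fp import (
    TIME_FP_MARGIN,
    FPSpec,
    age_spec,
    enumerate_fp_models,
    fp_transform,
    make_positive,
)
from .mixedlm import ModelFit, fit_random_intercept, fit_random_slope, predict_mean

AXES = ("time_rel", "age")
#: critical chi-square (2 df, 5%) for preferring degree 2 over degree 1
FP_DEGREE_TEST_CRIT = float(chi2.ppf(0.95, 2))


def _axis_values(df: pd.DataFrame, axis: str) -> np.ndarray:
    if axis not in AXES:
        raise InputError(f"axis must be one of {AXES}, got '{axis}'")
    return df["t_rel" if axis == "time_rel" else "age"].to_numpy(dtype=float)


@dataclass
class TrajectoryDesign:
    """Deterministic design-matrix description for one fitted model."""

    fpspec: FPSpec
    axis: str
    levels: list[str]          # exposure levels, reference first
    covariate_cols: list[str]
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        fp_names = self.fpspec.term_names()
        nonref = self.levels[1:]
        names = ["intercept"] + fp_names
        names += [f"exp[{lv}]" for lv in nonref]
        if self.axis == "time_rel":
            names += ["post"]
            names += [f"{f}:exp[{lv}]" for f in fp_names for lv in nonref]
            names += [f"{f}:post" for f in fp_names]
            names += [f"exp[{lv}]:post" for lv in nonref]
            names += [f"{f}:exp[{lv}]:post" for f in fp_names for lv in nonref]
        else:
            names += [f"{f}:exp[{lv}]" for f in fp_names for lv in nonref]
        names += self.covariate_cols
        self.names = names

    def _rows(self, axis_vals: np.ndarray, group_idx: np.ndarray, post: np.ndarray,
              cov: np.ndarray) -> np.ndarray:
        f = fp_transform(axis_vals, self.fpspec)          # (n, d)
        nonref = self.levels[1:]
        a = np.column_stack([(group_idx == j + 1).astype(float) for j in range(len(nonref))]) \
            if nonref else np.empty((len(axis_vals), 0))
        cols = [np.ones(len(axis_vals))[:, None], f, a]
        if self.axis == "time_rel":
            p_col = post[:, None]
            cols.append(p_col)
            cols.append((f[:, :, None] * a[:, None, :]).reshape(len(axis_vals), -1))
            cols.append(f * p_col)
            cols.append(a * p_col)
            cols.append((f[:, :, None] * a[:, None, :]).reshape(len(axis_vals), -1) * p_col)
        else:
            cols.append((f[:, :, None] * a[:, None, :]).reshape(len(axis_vals), -1))
        cols.append(cov)
        return np.concatenate(cols, axis=1)

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        axis_vals = _axis_values(df, self.axis)
        group_idx = np.array([self.levels.index(g) for g in df["exposure"]])
        post = df["post"].to_numpy(dtype=float)
        cov = df[self.covariate_cols].to_numpy(dtype=float) if self.covariate_cols \
            else np.empty((len(df), 0))
        x = self._rows(axis_vals, group_idx, post, cov)
        # every exposure level must actually occur
        for j, lv in enumerate(self.levels):
            if not np.any(group_idx == j):
                raise InputError(f"exposure level '{lv}' has no observations")
        return x

    def prediction_row(self, group: str, axis_value: float, covariate_means: dict[str, float]
                       ) -> np.ndarray:
        if group not in self.levels:
            raise InputError(f"unknown group '{group}'; levels are {self.levels}")
        post = np.array([1.0 if (self.axis == "time_rel" and axis_value > 0) else 0.0])
        cov = np.array([[covariate_means[c] for c in self.covariate_cols]])
        return self._rows(
            np.array([axis_value]),
            np.array([self.levels.index(group)]),
            post,
            cov,
        )[0]


def _baseline_design(df: pd.DataFrame, fpspec: FPSpec, axis: str, levels: list[str],
                     covariate_cols: list[str]) -> tuple[np.ndarray, list[str]]:
    """Main-effects design used during FP selection (no interactions)."""
    f = fp_transform(_axis_values(df, axis), fpspec)
    group_idx = np.array([levels.index(g) for g in df["exposure"]])
    a_cols = [(group_idx == j + 1).astype(float) for j in range(len(levels) - 1)]
    cols = [np.ones(len(df)), *f.T, *a_cols]
    names = ["intercept"] + fpspec.term_names() + [f"exp[{lv}]" for lv in levels[1:]]
    if axis == "time_rel":
        post = df["post"].to_numpy(dtype=float)
        cols.append(post)
        names.append("post")
        # FP x post terms let candidate shapes differ before/after first
        # pregnancy during selection, mirroring the interaction model
        for k, fk in enumerate(f.T):
            cols.append(fk * post)
            names.append(f"{fpspec.term_names()[k]}:post")
    for c in covariate_cols:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
    return np.column_stack(cols), names


def _transform_for_axis(axis: str, window: tuple[float, float], axis_vals: np.ndarray,
                        powers: tuple[float, ...]) -> FPSpec:
    if axis == "time_rel":
        shift, scale = make_positive(np.asarray(window, dtype=float), margin=TIME_FP_MARGIN)
        return FPSpec(powers=powers, shift=shift, scale=scale)
    return age_spec(FPSpec(powers=powers))


def select_fp(
    table: AnalysisTable | pd.DataFrame,
    axis: str = "time_rel",
    max_degree: int = 2,
    min_rows: int = 50,
    levels: list[str] | None = None,
    covariate_cols: list[str] | None = None,
    window: tuple[float, float] | None = None,
    return_deviances: bool = False,
):
    """Choose the best-fitting FP powers on the baseline model.

    All degree-1 and (for ``max_degree=2``) degree-2 candidates are fitted
    with a random intercept; the best degree-2 spec is preferred over the
    best degree-1 spec only when its deviance improvement exceeds the
    chi-square(2 df, 5%) critical value, the conventional FP
    function-selection test.  Ties break deterministically toward lower
    degree and earlier enumeration order.
    """
    df, levels, covariate_cols, window = _unpack_table(table, levels, covariate_cols, window)
    if len(df) < min_rows:
        raise InputError(f"need at least {min_rows} rows for FP selection, got {len(df)}")
    y = df["value"].to_numpy(dtype=float)
    groups = df["woman_id"].to_numpy()
    axis_vals = _axis_values(df, axis)

    results = []
    for cand in enumerate_fp_models(max_degree):
        spec = _transform_for_axis(axis, window, axis_vals, cand.powers)
        try:
            x, names = _baseline_design(df, spec, axis, levels, covariate_cols)
            fit = fit_random_intercept(x, y, groups, term_names=names)
        except Exception as err:  # noqa: BLE001 - candidate failures are skipped
            warnings.warn(f"FP candidate {cand.powers} failed: {err}")
            continue
        results.append((spec, fit.deviance))
    if not results:
        raise ConvergenceError("all FP candidates failed to converge")

    best = {}
    for spec, dev in results:
        d = spec.degree
        if d not in best or dev < best[d][1] - 1e-9:
            best[d] = (spec, dev)
    if 2 in best and 1 in best and best[1][1] - best[2][1] > FP_DEGREE_TEST_CRIT:
        chosen = best[2][0]
    else:
        chosen = best[min(best)][0]
    if return_deviances:
        return chosen, [(s.powers, d) for s, d in results]
    return chosen


def _unpack_table(table, levels=None, covariate_cols=None, window=None):
    if isinstance(table, AnalysisTable):
        df = table.df
        levels = levels or table.levels
        covariate_cols = covariate_cols if covariate_cols is not None else table.covariate_cols
        window = window or table.window
    else:
        df = table
        if levels is None:
            levels = sorted(df["exposure"].unique())
        if covariate_cols is None:
            covariate_cols = []
        if window is None:
            t = df["t_rel"].to_numpy(dtype=float)
            window = (float(t.min()), float(t.max()))
    if len(levels) < 2:
        raise InputError("exposure must have at least two groups")
    return df, list(levels), list(covariate_cols), tuple(window)


def build_design(
    table: AnalysisTable | pd.DataFrame,
    fpspec: FPSpec,
    axis: str = "time_rel",
    levels: list[str] | None = None,
    covariate_cols: list[str] | None = None,
) -> tuple[np.ndarray, TrajectoryDesign]:
    """Interaction design matrix and its description."""
    df, levels, covariate_cols, _ = _unpack_table(table, levels, covariate_cols)
    design = TrajectoryDesign(fpspec=fpspec, axis=axis, levels=levels,
                              covariate_cols=covariate_cols)
    return design.matrix(df), design


class APOTrajectoryModel:
    """Fractional-polynomial multilevel trajectory model for one
    outcome/exposure/axis combination.

    Parameters
    ----------
    table
        An :class:`~apotraj.apo.AnalysisTable` built by
        :func:`~apotraj.apo.build_analysis_table`.
    axis
        ``"time_rel"`` (years relative to first-pregnancy start; the
        design then includes the three-way FP x exposure x pre/post
        interactions) or ``"age"`` (FP x exposure interactions only).
    """

    def __init__(self, table: AnalysisTable, axis: str = "time_rel"):
        if axis not in AXES:
            raise InputError(f"axis must be one of {AXES}")
        self.table = table
        self.axis = axis
        self.df = table.df
        self.levels = list(table.levels)
        self.covariate_cols = list(table.covariate_cols)
        self.window = tuple(table.window)
        axis_vals = _axis_values(self.df, axis)
        self.axis_range = (float(axis_vals.min()), float(axis_vals.max()))

    @classmethod
    def from_tables(
        cls,
        women: pd.DataFrame,
        pregnancies: pd.DataFrame,
        measurements: pd.DataFrame,
        outcome: str,
        exposure: str = "n_apos",
        axis: str = "time_rel",
        window: tuple[float, float] = (-10.0, 15.0),
        eligibility: str = "any",
        distinct_types: bool = False,
    ) -> "APOTrajectoryModel":
        """Build the model straight from the three raw tables."""
        profiles = derive_apo_profiles(pregnancies, distinct_types=distinct_types)
        table = build_analysis_table(
            measurements, pregnancies, profiles, women, outcome,
            exposure=exposure, window=window, eligibility=eligibility,
        )
        return cls(table, axis=axis)

    def fit(
        self,
        fp_powers: tuple[float, ...] | None = None,
        max_degree: int = 2,
        random_slope: bool = False,
    ) -> "APOTrajectoryResults":
        """Select FP powers (unless given), fit the interaction model by ML."""
        if fp_powers is not None:
            fpspec = _transform_for_axis(
                self.axis, self.window, _axis_values(self.df, self.axis), tuple(fp_powers)
            )
        else:
            fpspec = select_fp(
                self.table, axis=self.axis, max_degree=max_degree,
            )
        x, design = build_design(self.table, fpspec, axis=self.axis,
                                 levels=self.levels, covariate_cols=self.covariate_cols)
        y = self.df["value"].to_numpy(dtype=float)
        groups = self.df["woman_id"].to_numpy()
        if random_slope:
            slope_cov = fp_transform(_axis_values(self.df, self.axis), fpspec)[:, 0]
            fit = fit_random_slope(x, y, groups, slope_cov, term_names=design.names)
        else:
            fit = fit_random_intercept(x, y, groups, term_names=design.names)
        cov_means = {c: float(self.df[c].mean()) for c in self.covariate_cols}
        return APOTrajectoryResults(model=self, fpspec=fpspec, design=design,
                                    fit=fit, covariate_means=cov_means)


@dataclass
class APOTrajectoryResults:
    """Fitted trajectory model: estimates, uncertainty and predictions."""

    model: APOTrajectoryModel
    fpspec: FPSpec
    design: TrajectoryDesign
    fit: ModelFit
    covariate_means: dict[str, float]

    # -- basic accessors -------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit.beta, index=self.fit.term_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.fit.se(), index=self.fit.term_names)

    @property
    def deviance(self) -> float:
        return self.fit.deviance

    @property
    def levels(self) -> list[str]:
        return self.model.levels

    @property
    def n_obs(self) -> int:
        return self.fit.n_obs

    @property
    def n_women(self) -> int:
        return self.fit.n_groups

    # -- prediction ------------------------------------------------------
    def _check_grid(self, grid) -> np.ndarray:
        grid = np.atleast_1d(np.asarray(grid, dtype=float))
        lo, hi = (self.model.window if self.model.axis == "time_rel"
                  else self.model.axis_range)
        if np.any(grid < lo - 1e-9) or np.any(grid > hi + 1e-9):
            raise DomainError(f"prediction grid outside the fitted range [{lo}, {hi}]")
        return grid

    def predict_trajectories(self, grid, groups: list[str] | None = None) -> pd.DataFrame:
        """Predicted mean with 95% Wald CI per group over the grid,
        at average levels of the included covariates."""
        grid = self._check_grid(grid)
        groups = list(groups) if groups is not None else list(self.levels)
        rows = []
        for g in groups:
            for v in grid:
                x = self.design.prediction_row(g, float(v), self.covariate_means)
                est, se = predict_mean(self.fit, x)
                rows.append((g, float(v), est, se, est - 1.96 * se, est + 1.96 * se))
        return pd.DataFrame(
            rows, columns=["group", "axis_value", "estimate", "se", "lower", "upper"]
        )

    def predict_at(self, group: str, axis_value: float) -> tuple[float, float]:
        """(estimate, SE) for one group at one axis value."""
        x = self.design.prediction_row(group, float(self._check_grid(axis_value)[0]),
                                       self.covariate_means)
        return predict_mean(self.fit, x)

    def contrast(self, group_a: str, group_b: str, grid) -> pd.DataFrame:
        """Difference curve (a minus b) with 95% CI; covariate means cancel."""
        grid = self._check_grid(grid)
        rows = []
        for v in grid:
            xa = self.design.prediction_row(group_a, float(v), self.covariate_means)
            xb = self.design.prediction_row(group_b, float(v), self.covariate_means)
            d = xa - xb
            est, se = predict_mean(self.fit, d)
            rows.append((float(v), est, se, est - 1.96 * se, est + 1.96 * se))
        return pd.DataFrame(rows, columns=["axis_value", "difference", "se", "lower", "upper"])

    # -- reporting -------------------------------------------------------
    def summary(self) -> str:
        t = self.model.table
        head = [
            "APO trajectory model",
            f"  outcome: {t.outcome}   exposure: {t.exposure}   axis: {self.model.axis}",
            f"  FP spec: {self.fpspec.describe()}",
            f"  window: {self.model.window}   eligibility: {t.eligibility}",
        ]
        return "\n".join(head) + "\n" + self.fit.report()

    def coefficients_frame(self) -> pd.DataFrame:
        return self.fit.coef_frame()

    def manifest(self) -> dict:
        t = self.model.table
        return {
            "outcome": t.outcome,
            "exposure": t.exposure,
            "axis": self.model.axis,
            "fp_powers": list(self.fpspec.powers),
            "fp_shift": self.fpspec.shift,
            "fp_scale": self.fpspec.scale,
            "window": list(self.model.window),
            "eligibility": t.eligibility,
            "n_obs": self.n_obs,
            "n_women": self.n_women,
            "n_excluded_comparator": t.n_excluded_comparator,
            "deviance": self.deviance,
            "sigma2_u": self.fit.sigma2_u,
            "sigma2_e": self.fit.sigma2_e,
            "groups": self.levels,
        }

    def save(self, outdir, grid=None, stem: str | None = None) -> dict[str, str]:
        """Write trajectory CSV, coefficients CSV and a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        t = self.model.table
        stem = stem or f"{t.outcome}_{t.exposure}_{self.model.axis}"
        if grid is None:
            lo, hi = (self.model.window if self.model.axis == "time_rel"
                      else self.model.axis_range)
            grid = np.linspace(lo, hi, 51)
        paths = {}
        traj = self.predict_trajectories(grid)
        paths["trajectories"] = str(outdir / f"{stem}_trajectories.csv")
        traj.to_csv(paths["trajectories"], index=False)
        paths["coefficients"] = str(outdir / f"{stem}_coefficients.csv")
        self.coefficients_frame().to_csv(paths["coefficients"], index=False)
        paths["manifest"] = str(outdir / f"{stem}_manifest.json")
        with open(paths["manifest"], "w", encoding="utf-8") as fh:
            json.dump(self.manifest(), fh, indent=2)
        return paths

    def plot(self, grid=None, ax=None, **kwargs):
        from .plotting import plot_trajectories

        if grid is None:
            lo, hi = (self.model.window if self.model.axis == "time_rel"
                      else self.model.axis_range)
            grid = np.linspace(lo, hi, 101)
        return plot_trajectories(self, grid, ax=ax, **kwargs)


def fit_trajectory(table: AnalysisTable, axis: str = "time_rel", **fit_kwargs
                   ) -> APOTrajectoryResults:
    """Functional wrapper: build the model from an analysis table and fit."""
    return APOTrajectoryModel(table, axis=axis).fit(**fit_kwargs)


def predict_trajectories(results: APOTrajectoryResults, grid, groups=None) -> pd.DataFrame:
    return results.predict_trajectories(grid, groups=groups)


def contrast(results: APOTrajectoryResults, group_a: str, group_b: str, grid) -> pd.DataFrame:
    return results.contrast(group_a, group_b, grid)
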