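"""FP selection, interaction designs and trajectory prediction."""

import numpy as np
import pandas as pd
import pytest

import apotraj
from apotraj.apo import AnalysisTable, build_analysis_table, derive_apo_profiles
from apotraj.exceptions import DomainError, InputError
from apotraj.fp import FPSpec
from apotraj.simulate import TruthCurves, simulate_fp_dataset
from apotraj.trajectory import (
    APOTrajectoryModel,
    build_design,
    fit_trajectory,
    select_fp,
)


def _table_from(df, levels, window=(-10.0, 15.0), covs=None, outcome="sbp",
                exposure="dummy"):
    return AnalysisTable(df=df, outcome=outcome, exposure=exposure, levels=levels,
                         window=window, eligibility="any",
                         covariate_cols=covs or [])


def _two_group_fp_df(n_women=400, offset=5.0, powers=(1.0,), coef=(3.0,), seed=0):
    """Two exposure groups sharing one FP shape, separated by a constant."""
    a = simulate_fp_dataset(n_women // 2, powers, coef, intercept=100.0,
                            intercept_sd=0.5, residual_sd=1.0, seed=seed)
    b = simulate_fp_dataset(n_women // 2, powers, coef, intercept=100.0 + offset,
                            intercept_sd=0.5, residual_sd=1.0, seed=seed + 1)
    b = b.assign(woman_id=b["woman_id"] + n_women, exposure="exposed")
    a = a.assign(exposure="comparator")
    return pd.concat([a, b], ignore_index=True)


class TestBuildDesign:
    def test_time_axis_column_count_binary_exposure_degree2(self):
        """2 FP + 1 exposure + 1 post + (2+2+1) two-way + 2 three-way = 11
        trajectory columns, plus the intercept."""
        df = _two_group_fp_df(n_women=60, powers=(1.0, 2.0), coef=(3.0, 1.0))
        table = _table_from(df, ["comparator", "exposed"])
        spec = FPSpec(powers=(1.0, 2.0), shift=-15.0, scale=12.0)
        x, design = build_design(table, spec)
        assert len(design.names) == 12
        assert x.shape[1] == 12

    def test_time_axis_four_level_exposure_degree1(self):
        """3 exposure indicators, 3 f.A, 1 f.P, 3 A.P, 3 f.A.P columns."""
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "woman_id": np.arange(400),
                "value": rng.normal(size=400),
                "t_rel": rng.uniform(-10, 15, 400),
                "post": 0.0,
                "exposure": np.repeat(["0", "1", "2", "3+"], 100),
            }
        )
        df["post"] = (df["t_rel"] > 0).astype(float)
        table = _table_from(df, ["0", "1", "2", "3+"])
        spec = FPSpec(powers=(1.0,), shift=-15.0, scale=12.0)
        x, design = build_design(table, spec)
        # intercept + 1 FP + 3 A + 1 P + 1 f.P + 3 f.A + 3 A.P + 3 f.A.P
        assert x.shape[1] == 1 + 1 + 3 + 1 + 3 + 1 + 3 + 3
        assert sum(":post" in n for n in design.names) == 1 + 3 + 3

    def test_age_axis_has_no_post_terms(self):
        df = _two_group_fp_df(n_women=60)
        table = _table_from(df, ["comparator", "exposed"])
        spec = FPSpec(powers=(1.0,), shift=0.0, scale=10.0)
        _, design = build_design(table, spec, axis="age")
        assert not any("post" in n for n in design.names)

    def test_degenerate_group_raises(self):
        df = _two_group_fp_df(n_women=60)
        table = _table_from(df[df["exposure"] == "comparator"],
                            ["comparator", "exposed"])
        spec = FPSpec(powers=(1.0,), shift=-15.0, scale=12.0)
        with pytest.raises(InputError):
            build_design(table, spec)


class TestSelectFP:
    def test_linear_truth_matches_linear_candidate(self):
        """When the truth is a straight line, the selected spec fits at
        least as well as powers (1): the truth is in the candidate set."""
        df = simulate_fp_dataset(800, (1.0,), (4.0,), intercept=100.0,
                                 intercept_sd=0.5, residual_sd=1.0, seed=7)
        df["exposure"] = np.where(df["woman_id"] % 2 == 0, "a", "b")
        table = _table_from(df, ["a", "b"])
        chosen, devs = select_fp(table, return_deviances=True)
        dev_by_powers = dict(devs)
        assert min(d for _, d in devs) >= dev_by_powers[chosen.powers] - 5.992
        assert dev_by_powers[chosen.powers] <= dev_by_powers[(1.0,)] + 1e-6

    def test_parsimony_prefers_degree_one_for_linear_truth(self):
        df = simulate_fp_dataset(800, (1.0,), (4.0,), intercept=100.0,
                                 intercept_sd=0.5, residual_sd=1.0, seed=8)
        df["exposure"] = np.where(df["woman_id"] % 2 == 0, "a", "b")
        chosen = select_fp(_table_from(df, ["a", "b"]))
        assert chosen.degree == 1

    def test_min_rows_enforced(self):
        df = _two_group_fp_df(n_women=6)
        with pytest.raises(InputError):
            select_fp(_table_from(df.head(10), ["comparator", "exposed"]))


class TestPipelineRecovery:
    def test_noise_free_pipeline_reproduces_truth_curves(self, noisefree_cohort):
        """Zero variance components: the full pipeline returns the
        generator's curves at the published anchor times to 0.1 units."""
        cohort, cfg = noisefree_cohort
        profiles = derive_apo_profiles(cohort.pregnancies)
        table = build_analysis_table(cohort.measurements, cohort.pregnancies,
                                     profiles, cohort.women, "sbp")
        res = APOTrajectoryModel(table).fit()
        curves = TruthCurves(cfg)
        for g in res.levels:
            for t in (-10.0, -5.0, 2.0, 10.0, 15.0):
                est, _ = res.predict_at(g, t)
                assert est == pytest.approx(curves(g, "sbp", t)[0], abs=0.1)

    def test_constant_group_offset_recovered_by_contrast(self):
        df = _two_group_fp_df(n_women=600, offset=5.0, seed=3)
        table = _table_from(df, ["comparator", "exposed"])
        res = fit_trajectory(table, fp_powers=(1.0,))
        grid = np.linspace(-9, 14, 12)
        con = res.contrast("exposed", "comparator", grid)
        assert np.all(np.abs(con["difference"] - 5.0) < 0.35)

    def test_contrast_identities(self, small_sbp_table):
        res = fit_trajectory(small_sbp_table, fp_powers=(1.0, 2.0))
        grid = np.array([-8.0, 0.0, 7.5])
        same = res.contrast("1", "1", grid)
        assert np.allclose(same["difference"], 0.0)
        assert np.allclose(same["se"], 0.0)
        con = res.contrast("2", "0", grid)
        t2 = res.predict_trajectories(grid, groups=["2"])["estimate"].to_numpy()
        t0 = res.predict_trajectories(grid, groups=["0"])["estimate"].to_numpy()
        np.testing.assert_allclose(con["difference"].to_numpy(), t2 - t0, atol=1e-10)
        with pytest.raises(InputError):
            res.contrast("2", "nope", grid)

    def test_ci_halfwidth_shrinks_with_cohort_size(self):
        halfwidths = {}
        for n in (500, 5000):
            c = apotraj.simulate_cohort(n, seed=777, outcomes=["sbp"])
            profiles = derive_apo_profiles(c.pregnancies)
            table = build_analysis_table(c.measurements, c.pregnancies, profiles,
                                         c.women, "sbp", exposure="any_apo")
            res = fit_trajectory(table, fp_powers=(1.0, 2.0))
            _, se = res.predict_at("apo", 10.0)
            halfwidths[n] = 1.96 * se
        assert halfwidths[5000] < halfwidths[500]

    def test_eligibility_filter_monotone_in_women(self, small_cohort):
        c = small_cohort
        profiles = derive_apo_profiles(c.pregnancies)
        t_any = build_analysis_table(c.measurements, c.pregnancies, profiles,
                                     c.women, "sbp", eligibility="any")
        t_pp = build_analysis_table(c.measurements, c.pregnancies, profiles,
                                    c.women, "sbp", eligibility="pre_and_post")
        assert t_pp.n_women <= t_any.n_women
        assert t_pp.n_obs <= t_any.n_obs

    def test_glucose_design_has_fasting_sbp_does_not(self, small_cohort):
        c = apotraj.simulate_cohort(800, seed=55)
        profiles = derive_apo_profiles(c.pregnancies)
        t_glu = build_analysis_table(c.measurements, c.pregnancies, profiles,
                                     c.women, "glucose", exposure="any_apo")
        t_sbp = build_analysis_table(c.measurements, c.pregnancies, profiles,
                                     c.women, "sbp", exposure="any_apo")
        r_glu = fit_trajectory(t_glu, fp_powers=(1.0,))
        r_sbp = fit_trajectory(t_sbp, fp_powers=(1.0,))
        assert "fasting" in r_glu.design.names
        assert "fasting" not in r_sbp.design.names

    def test_interaction_model_nests_baseline(self, small_sbp_table):
        """Deviance of the three-way interaction model never exceeds the
        no-interaction model on the same data."""
        from apotraj.mixedlm import fit_random_intercept
        from apotraj.trajectory import _baseline_design, _transform_for_axis

        df = small_sbp_table.df
        spec = _transform_for_axis("time_rel", small_sbp_table.window, None, (1.0, 2.0))
        x0, _ = _baseline_design(df, spec, "time_rel", small_sbp_table.levels,
                                 small_sbp_table.covariate_cols)
        base = fit_random_intercept(x0, df["value"].to_numpy(), df["woman_id"].to_numpy())
        full = fit_trajectory(small_sbp_table, fp_powers=(1.0, 2.0))
        assert full.deviance <= base.deviance + 1e-8

    def test_covariate_rescaling_leaves_predictions_invariant(self, small_sbp_table):
        res = fit_trajectory(small_sbp_table, fp_powers=(1.0, 2.0))
        scaled = small_sbp_table.df.copy()
        scaled["age_first_pregnancy"] = scaled["age_first_pregnancy"] * 10.0 + 3.0
        table2 = AnalysisTable(df=scaled, outcome="sbp", exposure="n_apos",
                               levels=small_sbp_table.levels,
                               window=small_sbp_table.window, eligibility="any",
                               covariate_cols=small_sbp_table.covariate_cols)
        res2 = fit_trajectory(table2, fp_powers=(1.0, 2.0))
        g = np.array([-5.0, 5.0])
        np.testing.assert_allclose(
            res.predict_trajectories(g)["estimate"],
            res2.predict_trajectories(g)["estimate"],
            atol=1e-6,
        )

    def test_grid_outside_window_raises(self, small_sbp_table):
        res = fit_trajectory(small_sbp_table, fp_powers=(1.0,))
        with pytest.raises(DomainError):
            res.predict_trajectories([16.0])

    def test_age_axis_fit_runs(self, small_sbp_table):
        res = APOTrajectoryModel(small_sbp_table, axis="age").fit(fp_powers=(1.0, 2.0))
        lo, hi = res.model.axis_range
        traj = res.predict_trajectories(np.linspace(lo + 1, hi - 1, 5))
        assert (traj["lower"] <= traj["estimate"]).all()
        assert (traj["estimate"] <= traj["upper"]).all()

    def test_summary_and_save(self, small_sbp_table, tmp_path):
        res = fit_trajectory(small_sbp_table, fp_powers=(1.0, 2.0))
        text = res.summary()
        assert "sbp" in text and "deviance" in text.lower()
        paths = res.save(tmp_path, grid=np.linspace(-10, 15, 11))
        traj = pd.read_csv(paths["trajectories"])
        assert set(traj["group"]) == {"0", "1", "2", "3+"}
        assert (traj["lower"] <= traj["upper"]).all()
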