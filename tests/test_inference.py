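"""Slope estimation, paired contrasts, Williams test, behavior statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import loomlab as ll
from loomlab.inference import (
    MagnitudeSlopeModel,
    behavior_summary,
    compare_dependent_correlations,
    correlate_slope_profiles,
    fit_magnitude_slope,
    one_sample_t,
    paired_slope_test,
    williams_test,
)


def _records(y, x, g, **extra):
    df = pd.DataFrame({"outcome_eda": y, "magnitude_pence": x, "participant_id": g})
    for k, v in extra.items():
        df[k] = v
    return df


class TestMagnitudeSlopeModel:
    def test_noise_free_data_recovers_slope_to_six_digits(self):
        """Exact interpolation: no noise, no participant effects."""
        rng = np.random.default_rng(0)
        x = rng.choice(np.arange(100.0, 1000.0, 100.0), size=200)
        g = np.repeat([f"p{i}" for i in range(10)], 20)
        slope, intercept = 8.35e-5, 0.15
        rec = _records(intercept + slope * x, x, g)
        fit = fit_magnitude_slope(rec, "outcome_eda", "magnitude_pence")
        assert fit.b == pytest.approx(slope, rel=1e-7)
        assert fit.intercept == pytest.approx(intercept, rel=1e-7)

    def test_balanced_design_matches_within_participant_ols(self):
        """With intercept heterogeneity and balanced x, the REML fixed slope
        equals the demeaned (within-participant) OLS slope."""
        rng = np.random.default_rng(1)
        n_p, x_levels = 15, np.arange(100.0, 1000.0, 100.0)
        x = np.tile(x_levels, n_p)
        g = np.repeat([f"p{i}" for i in range(n_p)], len(x_levels))
        b_i = rng.normal(0, 0.2, n_p)[np.repeat(np.arange(n_p), len(x_levels))]
        y = 0.1 + b_i + 5e-5 * x + rng.normal(0, 0.05, len(x))
        rec = _records(y, x, g)
        fit = fit_magnitude_slope(rec, "outcome_eda", "magnitude_pence")
        assert fit.method == "mixed_reml"
        # within estimator on demeaned data
        df = pd.DataFrame({"y": y, "x": x, "g": g})
        dem = df.groupby("g").transform(lambda s: s - s.mean())
        within = np.dot(dem.x, dem.y) / np.dot(dem.x, dem.x)
        assert fit.b == pytest.approx(within, abs=1e-6 * abs(within))

    def test_condition_filter_and_filler_exclusion(self, summary_cohort):
        fit = fit_magnitude_slope(
            summary_cohort, "outcome_eda", "magnitude_pence", condition="loss"
        )
        n_loss = (summary_cohort.condition == "loss").sum()
        assert fit.n_obs == n_loss
        assert fit.n_participants == summary_cohort.participant_id.nunique()
        sel = MagnitudeSlopeModel.from_dataframe(
            summary_cohort, "selection_eda", "bet_pence"
        )
        assert sel.n_obs == int(summary_cohort["included"].sum())

    def test_participant_slopes_are_per_participant_ols(self, summary_cohort):
        fit = fit_magnitude_slope(
            summary_cohort, "outcome_eda", "magnitude_pence", condition="win"
        )
        pid = fit.participant_slopes.index[0]
        grp = summary_cohort[
            (summary_cohort.participant_id == pid) & (summary_cohort.condition == "win")
        ]
        expect = np.polyfit(grp["magnitude_pence"], grp["outcome_eda"], 1)[0]
        assert fit.participant_slopes.loc[pid] == pytest.approx(expect, rel=1e-9)

    def test_summary_renders(self, summary_cohort):
        fit = fit_magnitude_slope(
            summary_cohort, "outcome_eda", "magnitude_pence", condition="loss"
        )
        text = fit.summary()
        assert "b =" in text and "REML" in text or "OLS" in text
        d = fit.to_dict()
        assert d["t"] == pytest.approx(d["b"] / d["se"])

    def test_plot_smoke(self, summary_cohort):
        import matplotlib
        matplotlib.use("Agg")
        fit = fit_magnitude_slope(
            summary_cohort, "outcome_eda", "magnitude_pence", condition="loss"
        )
        ax = fit.plot()
        assert ax.get_xlabel() == "magnitude_pence"

    def test_too_few_participants_rejected(self):
        rec = _records([1.0, 2.0], [1.0, 2.0], ["a", "a"])
        with pytest.raises(ValueError):
            MagnitudeSlopeModel.from_dataframe(rec, "outcome_eda", "magnitude_pence")


class TestOneSampleT:
    def test_hand_computed_example(self):
        res = one_sample_t([1.0, 2.0, 3.0], 0.0)
        assert res.statistic == pytest.approx(2.0 * np.sqrt(3.0))
        assert res.df == 2

    def test_zero_when_mean_equals_null(self):
        res = one_sample_t([-1.0, 0.0, 1.0], 0.0)
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    @given(st.integers(min_value=2, max_value=40))
    def test_df_is_n_minus_one(self, n):
        values = np.arange(n, dtype=float)
        assert one_sample_t(values, 0.0).df == n - 1

    def test_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(4)
        v = rng.normal(0.3, 1.0, 25)
        res = one_sample_t(v, 0.1)
        ref = stats.ttest_1samp(v, 0.1)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)


class TestPairedSlopeTest:
    def test_identical_inputs_give_zero(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        res = paired_slope_test(s, s.copy())
        assert res.statistic == 0.0

    def test_constant_nonzero_difference_degenerate(self):
        a = pd.Series([2.0, 3.0, 4.0, 5.0], index=list("abcd"))
        b = a - 1.0
        res = paired_slope_test(a, b)
        assert res.degenerate and res.p == 0.0 and np.isinf(res.statistic)

    def test_mismatched_participants_rejected(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("abd"))
        with pytest.raises(ValueError):
            paired_slope_test(a, b)

    def test_alignment_by_participant_not_position(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        b = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("dcba"))
        res = paired_slope_test(a, b)  # pairs are equal after alignment
        assert res.statistic == 0.0

    def test_matches_scipy_ttest_rel(self):
        from scipy import stats
        rng = np.random.default_rng(5)
        a = pd.Series(rng.normal(0, 1, 20), index=range(20))
        b = pd.Series(rng.normal(0.4, 1, 20), index=range(20))
        res = paired_slope_test(a, b)
        ref = stats.ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_power_exceeds_size_under_slope_asymmetry(self):
        """Cohorts generated with loss > win slopes reject more often than
        matched cohorts generated under equal slopes."""
        from dataclasses import replace
        import loomlab.pipeline as pl
        base = ll.RunConfig(n_participants=50, synthesis="summary")
        null = pl.paired_test_type1_study(base, n_reps=400, seed=21)
        alt_amp = base.amplitude  # defaults already asymmetric
        # reuse the study machinery with the asymmetric amplitudes
        alt_cfg = replace(base, amplitude=replace(alt_amp, win_slope=alt_amp.win_slope))
        # direct power estimate over 60 small replicate cohorts
        reject = 0
        reps = 60
        for rep in range(reps):
            rec = pd.concat(
                [pl.simulate_participant_records(alt_cfg, i, replicate=rep + 1)
                 for i in range(20)],
                ignore_index=True,
            )
            fw = fit_magnitude_slope(rec, "outcome_eda", "magnitude_pence", condition="win")
            fl = fit_magnitude_slope(rec, "outcome_eda", "magnitude_pence", condition="loss")
            if paired_slope_test(fl.participant_slopes, fw.participant_slopes).p < 0.05:
                reject += 1
        assert reject / reps > null["rejection_rate"]


class TestWilliamsTest:
    def test_zero_when_correlations_equal(self):
        for r23 in (-0.3, 0.0, 0.6):
            assert williams_test(0.5, 0.5, r23, 50).t == 0.0

    def test_df_is_n_minus_three(self):
        assert williams_test(0.76, 0.55, 0.5, 50).df == 47

    def test_frozen_high_precision_value(self):
        """Independent exact-rational evaluation of the formula gives
        t = 2.2263695294 for (r12, r13, r23, n) = (.76, .55, .50, 50)."""
        res = williams_test(0.76, 0.55, 0.50, 50)
        assert res.t == pytest.approx(2.2263695294, abs=1e-9)
        assert res.p == pytest.approx(0.030820, abs=1e-5)

    def test_antisymmetric_in_r12_r13(self):
        a = williams_test(0.7, 0.2, 0.4, 30)
        b = williams_test(0.2, 0.7, 0.4, 30)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_non_psd_triple_rejected(self):
        with pytest.raises(ValueError, match="positive-semidefinite"):
            williams_test(0.9, 0.9, -0.9, 50)

    def test_boundary_and_small_n_rejected(self):
        with pytest.raises(ValueError):
            williams_test(1.0, 0.5, 0.3, 50)
        with pytest.raises(ValueError):
            williams_test(0.5, 0.4, 0.3, 3)

    def test_type1_error_calibrated(self):
        study = ll.williams_type1_study(n_reps=2000, n=50, rho=0.5, rho23=0.3, seed=1)
        assert study["rejection_rate"] == pytest.approx(0.05, abs=0.015)

    def test_vectorized_study_matches_scalar_test(self):
        """The vectorized calibration replicates the scalar Williams test."""
        rng = np.random.default_rng(8)
        z = rng.standard_normal((40, 3)) @ np.linalg.cholesky(
            np.array([[1, 0.5, 0.5], [0.5, 1, 0.3], [0.5, 0.3, 1]])
        ).T
        r = np.corrcoef(z, rowvar=False)
        res = williams_test(r[0, 1], r[0, 2], r[1, 2], 40)
        # manual formula evaluation as in the study
        n, r12, r13, r23 = 40, r[0, 1], r[0, 2], r[1, 2]
        detR = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23
        rbar = (r12 + r13) / 2
        t = (r12 - r13) * np.sqrt(
            (n - 1) * (1 + r23) / (2 * (n - 1) / (n - 3) * detR + rbar**2 * (1 - r23) ** 3)
        )
        assert res.t == pytest.approx(t)


class TestSlopeCorrelations:
    def test_self_correlation_is_one(self, summary_cohort):
        fit = fit_magnitude_slope(
            summary_cohort, "outcome_eda", "magnitude_pence", condition="loss"
        )
        r, n = correlate_slope_profiles(fit, fit)
        assert r == pytest.approx(1.0)
        assert n == fit.n_participants

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(11)
        n = 400
        x, y = rng.normal(size=n), rng.normal(size=n)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(r) < 3.0 / np.sqrt(n)

    def test_shared_gain_induces_positive_correlation(self):
        """A common participant gain factor couples selection and outcome
        slopes: the correlation is positive in a majority of replicates."""
        import loomlab.pipeline as pl
        cfg = ll.RunConfig(n_participants=30, synthesis="summary", master_seed=13)
        positive = 0
        reps = 20
        for rep in range(reps):
            rec = pd.concat(
                [pl.simulate_participant_records(cfg, i, replicate=rep + 1)
                 for i in range(cfg.n_participants)],
                ignore_index=True,
            )
            sel = fit_magnitude_slope(rec, "selection_eda", "bet_pence")
            loss = fit_magnitude_slope(rec, "outcome_eda", "magnitude_pence", condition="loss")
            r, _ = correlate_slope_profiles(sel, loss)
            positive += r > 0
        assert positive / reps > 0.5

    def test_williams_from_fits(self, summary_cohort):
        sel = fit_magnitude_slope(summary_cohort, "selection_eda", "bet_pence")
        fl = fit_magnitude_slope(summary_cohort, "outcome_eda", "magnitude_pence", condition="loss")
        fw = fit_magnitude_slope(summary_cohort, "outcome_eda", "magnitude_pence", condition="win")
        comp = compare_dependent_correlations(sel, fl, fw)
        assert comp.df == summary_cohort.participant_id.nunique() - 3
        r, _ = correlate_slope_profiles(sel, fl)
        assert comp.r12 == pytest.approx(r)


class TestBehaviorSummary:
    def test_constant_bets_give_zero_changes(self):
        rec = pd.DataFrame(
            {
                "participant_id": "p0",
                "trial_index": range(6),
                "condition": ["win", "loss", "win", "loss", "filler", "win"],
                "bet_pence": 50.0,
                "outcome_pence": [500, -500, 500, -500, 0, 500],
            }
        )
        out = behavior_summary(rec)
        assert out["post_win_change"] == 0.0
        assert out["post_loss_change"] == 0.0
        assert out["mean_bet"] == 50.0

    def test_all_null_session_has_zero_winnings(self):
        rec = pd.DataFrame(
            {
                "participant_id": "p0",
                "trial_index": range(4),
                "condition": ["near_win", "near_loss", "filler", "filler"],
                "bet_pence": [10.0, 20.0, 30.0, 40.0],
                "outcome_pence": 0.0,
            }
        )
        out = behavior_summary(rec)
        assert out["total_winnings"] == 0.0
        assert np.isnan(out["post_win_change"])

    def test_change_conditioning_on_previous_outcome(self):
        rec = pd.DataFrame(
            {
                "participant_id": "p0",
                "trial_index": range(4),
                "condition": ["win", "filler", "loss", "win"],
                "bet_pence": [50.0, 40.0, 40.0, 60.0],
                "outcome_pence": [500, 0, -400, 600],
            }
        )
        out = behavior_summary(rec)
        assert out["post_win_change"] == -10.0  # only the first win precedes a trial
        assert out["post_loss_change"] == 20.0
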