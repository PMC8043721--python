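"""Session-wise stability statistics, bootstrap CIs and group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import probdistort as pdst
from probdistort.data import DataError
from probdistort.stability import (
    ParameterError,
    bias_timing_correlation,
    bootstrap_ci,
    early_late_correlation,
    median_split_anova,
    sessionwise_fits,
    timing_summary,
    variance_decomposition,
    wilcoxon_signed_rank,
    within_between_ttest,
    _closed_form_llo,
)


def _session_table(values_by_subject):
    """Build a session-fit table with given per-subject beta paths."""
    rows = []
    for subj, vals in values_by_subject.items():
        for sess, v in enumerate(vals, start=1):
            rows.append(
                {"subject_id": subj, "session": sess, "alpha": v / 10,
                 "beta": v, "sigma": abs(v) + 0.5}
            )
    return pd.DataFrame(rows)


class TestSessionwiseFits:
    def test_one_row_per_subject_session(self, small_cohort):
        table = sessionwise_fits(small_cohort["sample"])
        assert len(table) == 3 * 2
        assert set(zip(table.subject_id, table.session)) == {
            (s, k) for s in (1, 2, 3) for k in (1, 2)
        }

    def test_single_session_equals_direct_fit(self, small_cohort):
        sample = small_cohort["sample"]
        g = sample[(sample.subject_id == 2) & (sample.session == 1)]
        table = sessionwise_fits(g)
        a, b, s = _closed_form_llo(
            g[g.adjusted]["y"].to_numpy(), g[g.adjusted]["x"].to_numpy()
        )
        row = table.iloc[0]
        assert (row.alpha, row.beta, row.sigma) == pytest.approx((a, b, s))

    def test_sparse_session_withheld_with_warning(self, small_cohort):
        sample = small_cohort["sample"].copy()
        sel = (sample.subject_id == 1) & (sample.session == 1)
        sample.loc[sel, "adjusted"] = False
        with pytest.warns(RuntimeWarning, match="withheld"):
            table = sessionwise_fits(sample)
        assert len(table) == 5

    def test_session_betas_cluster_by_subject(self):
        """Stable profiles: within-subject spread below between-subject."""
        cfg = pdst.TaskConfig(3, 3, 500, seed=29)
        profiles = [
            pdst.SubjectProfile(beta=b, sigma=0.6, adjust_rate=0.3)
            for b in (0.4, 1.0, 1.8)
        ]
        data = pdst.generate_cohort(cfg, profiles)
        fc = pdst.forecast_dataset(data, cfg.hazard)
        table = sessionwise_fits(pdst.extract_adjustments(data, fc))
        decomp = {d.parameter: d for d in variance_decomposition(table, b=500)}
        assert decomp["beta"].within_var < decomp["beta"].between_var


class TestBootstrapCi:
    def test_deterministic_under_seed(self, small_cohort):
        one = bootstrap_ci(small_cohort["sample"], b=200, seed=5)
        two = bootstrap_ci(small_cohort["sample"], b=200, seed=5)
        pd.testing.assert_frame_equal(one, two)

    def test_minimum_iterations_enforced(self, small_cohort):
        with pytest.raises(ParameterError):
            bootstrap_ci(small_cohort["sample"], b=50)

    def test_noiseless_line_gives_zero_width(self):
        x = np.linspace(-2, 2, 30)
        sample = pd.DataFrame(
            {"subject_id": "a", "session": 1, "trial": np.arange(30),
             "x": x, "y": 0.3 + 1.1 * x, "adjusted": True}
        )
        ci = bootstrap_ci(sample, b=200, seed=0)
        for _, row in ci.iterrows():
            assert row.ci_high - row.ci_low == pytest.approx(0.0, abs=1e-9)

    def test_percentile_monotone(self, small_cohort):
        ci = bootstrap_ci(small_cohort["sample"], b=300, seed=1)
        # percentile interval brackets the point estimate (generic case)
        inside = (ci.ci_low <= ci.estimate) & (ci.estimate <= ci.ci_high)
        assert inside.mean() >= 0.99 - 1e-9


class TestVarianceDecomposition:
    def test_degenerate_table_flagged(self):
        table = _session_table({s: [1.0] * 4 for s in "abc"})
        out = variance_decomposition(table, b=100)
        assert all(d.degenerate for d in out)

    def test_separated_subjects_give_small_ratio(self):
        rng = np.random.default_rng(0)
        table = _session_table(
            {s: (10.0 * i + rng.normal(0, 0.1, 8)).tolist()
             for i, s in enumerate("abcde")}
        )
        out = {d.parameter: d for d in variance_decomposition(table, b=500)}
        assert out["beta"].ratio < 0.01

    def test_twofold_between_spread_detected(self):
        """CI for the within/between ratio excludes 1 for most replicates."""
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            w = 0.3
            means = rng.normal(1.0, 3 * w, size=11)
            table = _session_table(
                {f"s{i}": (means[i] + rng.normal(0, w, 10)).tolist()
                 for i in range(11)}
            )
            d = {x.parameter: x for x in variance_decomposition(table, b=2000, seed=rep)}
            hits += d["beta"].ci_high < 1.0
        assert hits >= 12

    def test_ttest_variant_reports_all_parameters(self):
        rng = np.random.default_rng(3)
        table = _session_table(
            {f"s{i}": rng.normal(i, 0.5, 6).tolist() for i in range(6)}
        )
        out = within_between_ttest(table)
        assert list(out.parameter) == ["alpha", "beta", "sigma"]
        assert out.t.notna().all()


class TestMedianSplitAnova:
    def test_hand_computed_f_statistic(self):
        # low half: sessions {1,2,3}, {2,3,4}, {3,4,5} -> F = 3.0, df (2, 6)
        rows = []
        for subj, path in {"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5],
                           "d": [9, 9, 9], "e": [9, 9, 9], "f": [9, 9, 9]}.items():
            for sess, v in enumerate(path, start=1):
                rows.append({"subject_id": subj, "session": sess,
                             "alpha": 0.0, "beta": v, "sigma": 1.0})
        out = median_split_anova(pd.DataFrame(rows), "beta")
        low = out[out.half == "low"].iloc[0]
        assert low.F == pytest.approx(3.0)
        assert (low.df1, low.df2) == (2, 6)

    def test_null_p_values_uniform(self):
        """Under exchangeable sessions the ANOVA p-value is uniform."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(500):
            table = _session_table(
                {f"s{i}": rng.normal(0, 1, 5).tolist() for i in range(6)}
            )
            out = median_split_anova(table, "beta")
            pvals.append(out[out.half == "low"].iloc[0].p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_shifted_sessions_give_large_f(self):
        table = _session_table(
            {f"s{i}": [0.0, 5.0, 10.0] for i in range(6)}
        )
        out = median_split_anova(table, "beta")
        assert (out.F > 100).all()

    def test_half_sizes_match_median_split(self):
        rng = np.random.default_rng(0)
        table = _session_table(
            {f"s{i}": (i + rng.normal(0, 0.1, 10)).tolist() for i in range(11)}
        )
        out = median_split_anova(table, "beta")
        # 11 subjects, 10 sessions: 6 low -> F(9, 50); 5 high -> F(9, 40)
        assert out[out.half == "low"].iloc[0].df1 == 9
        assert out[out.half == "low"].iloc[0].df2 == 50
        assert out[out.half == "high"].iloc[0].df2 == 40


class TestEarlyLateCorrelation:
    def _table_from_means(self, early, late):
        rows = []
        for i, (e, l) in enumerate(zip(early, late)):
            rows.append({"subject_id": f"s{i}", "session": 1, "alpha": e,
                         "beta": e, "sigma": abs(e) + 1})
            rows.append({"subject_id": f"s{i}", "session": 2, "alpha": l,
                         "beta": l, "sigma": abs(l) + 1})
        return pd.DataFrame(rows)

    def test_identity_and_sign_flip(self):
        vals = [0.2, 0.8, 1.4, 2.0]
        table = self._table_from_means(vals, vals)
        out = early_late_correlation(table, split_session=1)
        assert out[out.parameter == "beta"].iloc[0].r == pytest.approx(1.0)
        table = self._table_from_means(vals, [-v for v in vals])
        out = early_late_correlation(table, split_session=1)
        assert out[out.parameter == "beta"].iloc[0].r == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        table = self._table_from_means([1, 2, 3, 4], [1, 2, 3, 5])
        out = early_late_correlation(table, split_session=1)
        assert out[out.parameter == "beta"].iloc[0].r == pytest.approx(
            0.9827, abs=1e-4
        )

    def test_default_split_is_first_half(self, small_cohort):
        table = sessionwise_fits(small_cohort["sample"])
        out = early_late_correlation(table)
        assert out.r.notna().all()


class TestTiming:
    def test_every_trial_adjustment_gives_unit_lag(self):
        cfg = pdst.TaskConfig(1, 1, 100, seed=2)
        env = pdst.generate_environment(cfg)
        B = pdst.observer.forecast_environment(env, cfg.hazard)
        prof = pdst.SubjectProfile(sigma=0.5, adjust_rate=1.0)
        d = pdst.simulate_subject(env, prof, B, seed=0)
        sample = pdst.extract_adjustments(d, B.ravel())
        out = timing_summary(d, sample)
        assert out["mean_adjust_lag"].iloc[0] == pytest.approx(1.0)

    def test_geometric_waiting_time(self):
        cfg = pdst.TaskConfig(1, 10, 1000, seed=4)
        env = pdst.generate_environment(cfg)
        B = pdst.observer.forecast_environment(env, cfg.hazard)
        prof = pdst.SubjectProfile(sigma=0.8, adjust_rate=0.1)
        d = pdst.simulate_subject(env, prof, B, seed=1)
        sample = pdst.extract_adjustments(d, B.ravel())
        out = timing_summary(d, sample)
        lag = out["mean_adjust_lag"].iloc[0]
        assert lag == pytest.approx(10.0, abs=1.0)

    def test_negative_rt_coupling_yields_negative_correlation(self):
        cfg = pdst.TaskConfig(n_subjects=6, n_sessions=2,
                              trials_per_session=400, seed=19)
        profiles = [
            pdst.SubjectProfile(beta=b, sigma=0.6, adjust_rate=0.15)
            for b in np.linspace(0.4, 1.8, 6)
        ]
        data = pdst.generate_cohort(cfg, profiles)
        fc = pdst.forecast_dataset(data, cfg.hazard)
        sample = pdst.extract_adjustments(data, fc)
        fits = pdst.LinearLogOddsModel.from_sample(sample, pdst.ModelSpec()).fit()
        subj = fits.params_frame().reset_index(names="subject_id")
        timing = timing_summary(data, sample)
        out = bias_timing_correlation(subj, timing, "beta")
        rt_row = out[out.against == "mean_rt_s"].iloc[0]
        assert rt_row.r < 0


class TestWilcoxon:
    def test_all_positive_exact_p(self):
        stat, p = wilcoxon_signed_rank([1.0, 2.0, 0.5, 3.0, 1.5], 0.0)
        assert p == pytest.approx(1 / 16)

    def test_symmetric_values_near_central(self):
        vals = [-2.0, -1.0, -0.5, 0.5, 1.0, 2.0]
        _, p = wilcoxon_signed_rank(vals, 0.0)
        assert p > 0.5

    def test_ties_with_null_dropped(self):
        with pytest.raises(DataError):
            wilcoxon_signed_rank([1.0, 1.0, 1.0], 1.0)
        with pytest.raises(DataError):
            wilcoxon_signed_rank([1.1, 0.9, 1.0, 1.2], 1.0)

    def test_group_level_report_shapes(self, small_cohort):
        fits = pdst.LinearLogOddsModel.from_sample(
            small_cohort["sample"], pdst.ModelSpec()
        ).fit()
        # only 3 subjects here: pad with session-wise betas for a n>=5 check
        table = sessionwise_fits(small_cohort["sample"])
        stat, p = wilcoxon_signed_rank(table["beta"].to_numpy(), 1.0)
        assert 0.0 <= p <= 1.0
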