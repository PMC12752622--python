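import numpy as np
import pandas as pd
import pytest

from ctdnatrack.outcome_stats import (
    bh_adjust,
    cox_fit,
    group_compare,
    interaction_fit,
    km_estimate,
    logrank_test,
    subgroup_forest,
)
from ctdnatrack.synthetic_cohort import simulate_stratum_survival


class TestKaplanMeier:
    def test_matches_hand_product_limit(self):
        """n=3, events at 1, 2, 3: S = 2/3, 1/3, 0."""
        est = km_estimate([1, 2, 3], [1, 1, 1])
        assert est.survival_at(1) == pytest.approx(2 / 3)
        assert est.survival_at(2) == pytest.approx(1 / 3)
        assert est.survival_at(3) == pytest.approx(0.0)
        assert est.median == pytest.approx(2.0)

    def test_brute_force_product_over_event_times(self, rng):
        times = rng.integers(1, 15, size=40).astype(float)
        events = rng.integers(0, 2, size=40)
        est = km_estimate(times, events)
        for t in np.unique(times):
            s = 1.0
            for u in sorted(np.unique(times[(events == 1)])):
                if u > t:
                    break
                at_risk = np.sum(times >= u)
                d = np.sum((times == u) & (events == 1))
                s *= 1 - d / at_risk
            assert est.survival_at(t) == pytest.approx(s)

    def test_all_censored_flat_curve_undefined_median(self):
        est = km_estimate([5, 6, 7], [0, 0, 0])
        assert est.survival_at(7) == 1.0
        assert est.median is None

    def test_single_subject(self):
        est = km_estimate([5], [1])
        assert est.survival_at(5) == 0.0
        assert est.median == pytest.approx(5.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_table(self):
        """Two-group fixture small enough to tabulate observed minus
        expected and the hypergeometric variance by hand."""
        ta, ea = [1.0, 3.0], [1, 1]
        tb = [2.0, 4.0]
        eb = [1, 1]
        # event times 1,2,3,4; at risk (a,b): (2,2),(1,2),(1,1),(0,1)
        # O_a = 2; E_a = 2/4 + 1/3 + 1/2 + 0 = 4/3
        # V = sum n_a*n_b*d*(n-d)/(n^2*(n-1)) with d=1 each:
        #   (2*2)/(16)*(4-1)/(3) -> 4/16 = 0.25; (1*2)/9 = 2/9; (1*1)/4 = 0.25; 0
        o_minus_e = 2 - (2 / 4 + 1 / 3 + 1 / 2)
        var = 4 / 16 + 2 / 9 + 1 / 4
        expected_stat = o_minus_e**2 / var
        stat, _ = logrank_test(ta, ea, tb, eb)
        assert stat == pytest.approx(expected_stat, rel=1e-9)

    def test_power_against_a_true_hazard_ratio(self):
        """Exponential groups with true HR 2 at n=200/arm: the test should
        reject at alpha=0.05 in at least 90% of replicates."""
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(100):
            ta = rng.exponential(1.0, 200)
            tb = rng.exponential(0.5, 200)
            _, p = logrank_test(ta, np.ones(200), tb, np.ones(200))
            rejections += p < 0.05
        assert rejections >= 90

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [1])


class TestCox:
    def test_agrees_with_lifelines(self, rng):
        """Independent cross-check of the partial-likelihood fit against
        the lifelines implementation on tied exponential data."""
        from lifelines import CoxPHFitter

        n = 150
        x = rng.integers(0, 2, n)
        t = np.round(rng.exponential(1 / np.where(x, 0.6, 1.0)), 1) + 0.1
        df = pd.DataFrame({"t": t, "e": np.ones(n, int), "x": x})
        ours = cox_fit(df, "t", "e", ["x"])["x"]
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert ours.hr == pytest.approx(float(cph.hazard_ratios_["x"]), rel=1e-4)
        assert ours.p == pytest.approx(float(cph.summary.loc["x", "p"]), abs=1e-6)

    def test_duplicated_dataset_same_point_estimate(self, rng):
        """Duplicating every row leaves the Breslow partial-likelihood
        maximizer unchanged (Efron redistributes within the created ties,
        so the invariance is exact only under Breslow weighting)."""
        n = 80
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / np.where(x, 0.5, 1.0))
        df = pd.DataFrame({"t": t, "e": 1, "x": x})
        doubled = pd.concat([df, df], ignore_index=True)
        a = cox_fit(df, "t", "e", ["x"], ties="breslow")["x"].hr
        b = cox_fit(doubled, "t", "e", ["x"], ties="breslow")["x"].hr
        assert a == pytest.approx(b, rel=1e-8)

    def test_constant_covariate_named_in_error(self):
        df = pd.DataFrame({"t": [1.0, 2.0], "e": [1, 1], "x": [1, 1]})
        with pytest.raises(ValueError, match="x"):
            cox_fit(df, "t", "e", ["x"])

    def test_no_events_rejected(self):
        df = pd.DataFrame({"t": [1.0, 2.0], "e": [0, 0], "x": [0, 1]})
        with pytest.raises(ValueError):
            cox_fit(df, "t", "e", ["x"])

    def test_logrank_and_cox_agree_on_two_groups(self, rng):
        n = 120
        x = rng.integers(0, 2, n)
        t = rng.exponential(1 / np.where(x, 0.5, 1.0))
        df = pd.DataFrame({"t": t, "e": 1, "x": x})
        _, p_lr = logrank_test(t[x == 0], np.ones((x == 0).sum()),
                               t[x == 1], np.ones((x == 1).sum()))
        p_cox = cox_fit(df, "t", "e", ["x"])["x"].p
        assert round(p_lr, 2) == pytest.approx(round(p_cox, 2), abs=0.011)

    def test_null_coverage(self):
        """Under HR=1, the Wald 95% interval covers 1 in about 95% of
        replicates."""
        rng = np.random.default_rng(11)
        covered = 0
        reps = 200
        for _ in range(reps):
            df = simulate_stratum_survival(150, 1.0, 8.0, 30.0, rng)
            fit = cox_fit(df, "time", "event", ["treated"])["treated"]
            covered += fit.ci_low <= 1.0 <= fit.ci_high
        assert covered / reps == pytest.approx(0.95, abs=0.04)

    def test_log_hr_bias_shrinks_with_sample_size(self):
        """Consistency ladder: median |log HR error| decreases from n=100
        to n=1600 on exponential data with true HR 0.5."""
        rng = np.random.default_rng(13)
        med_err = {}
        for n in (100, 400, 1600):
            errs = []
            for _ in range(40):
                df = simulate_stratum_survival(n, 0.5, 8.0, 60.0, rng, (1, 1))
                fit = cox_fit(df, "time", "event", ["treated"])["treated"]
                errs.append(abs(np.log(fit.hr) - np.log(0.5)))
            med_err[n] = np.median(errs)
        assert med_err[1600] < med_err[400] < med_err[100]


class TestInteraction:
    @staticmethod
    def _cohort(rng, n_pos=300, n_neg=150, hr_pos=0.45, hr_neg=0.74):
        pos = simulate_stratum_survival(n_pos, hr_pos, 8.0, 30.0, rng)
        pos["bio"] = 1
        neg = simulate_stratum_survival(n_neg, hr_neg, 8.0, 30.0, rng)
        neg["bio"] = 0
        return pd.concat([pos, neg], ignore_index=True)

    def test_recovers_stratum_ratio(self):
        """Median interaction coefficient over replicates approximates
        log(hr_neg-stratum / hr_pos-stratum)... i.e. log(0.74/0.45)."""
        rng = np.random.default_rng(17)
        coefs, hr_pos, hr_neg = [], [], []
        for _ in range(60):
            df = self._cohort(rng)
            fit = interaction_fit(df, "time", "event", "bio", "treated")
            coefs.append(fit.interaction_coef)
            hr_pos.append(fit.hr_in_positive.hr)
            hr_neg.append(fit.hr_in_negative.hr)
        assert np.median(coefs) == pytest.approx(np.log(0.45 / 0.74), abs=0.1)
        assert np.median(hr_pos) == pytest.approx(0.45, abs=0.05)
        assert np.median(hr_neg) == pytest.approx(0.74, abs=0.08)

    def test_null_interaction_p_is_roughly_uniform(self):
        """Identical stratum effects: interaction p-values spread over
        (0,1) rather than piling near 0."""
        rng = np.random.default_rng(19)
        ps = []
        for _ in range(60):
            df = self._cohort(rng, hr_pos=0.6, hr_neg=0.6)
            ps.append(
                interaction_fit(df, "time", "event", "bio", "treated").p_interaction
            )
        ps = np.array(ps)
        assert (ps < 0.05).mean() < 0.2
        assert 0.2 < np.median(ps) < 0.8

    def test_wald_and_lrt_agree_in_magnitude(self, rng):
        df = self._cohort(rng)
        wald = interaction_fit(df, "time", "event", "bio", "treated", test="wald")
        lrt = interaction_fit(df, "time", "event", "bio", "treated", test="lrt")
        assert wald.p_interaction == pytest.approx(lrt.p_interaction, abs=0.05)

    def test_constant_biomarker_rejected(self, rng):
        df = self._cohort(rng)
        df["bio"] = 1
        with pytest.raises(ValueError):
            interaction_fit(df, "time", "event", "bio", "treated")


class TestSubgroups:
    def test_whole_cohort_subgroup_equals_plain_fit(self, rng):
        df = simulate_stratum_survival(200, 0.5, 8.0, 30.0, rng)
        table = subgroup_forest(
            df, {"all": pd.Series(True, index=df.index)},
            "time", "event", "treated",
        )
        direct = cox_fit(df, "time", "event", ["treated"])["treated"]
        assert table.iloc[0]["hr"] == pytest.approx(direct.hr, rel=1e-9)

    def test_partition_conserves_events(self, rng):
        df = simulate_stratum_survival(200, 0.5, 8.0, 30.0, rng)
        half = pd.Series(np.arange(len(df)) < 100, index=df.index)
        table = subgroup_forest(
            df, {"first": half, "second": ~half}, "time", "event", "treated",
            exclusive=True,
        )
        assert table["events"].sum() == df["event"].sum()

    def test_overlapping_exclusive_masks_rejected(self, rng):
        df = simulate_stratum_survival(50, 0.5, 8.0, 30.0, rng)
        all_true = pd.Series(True, index=df.index)
        with pytest.raises(ValueError):
            subgroup_forest(
                df, {"a": all_true, "b": all_true}, "time", "event", "treated",
                exclusive=True,
            )

    def test_small_subgroup_flagged(self, rng):
        df = simulate_stratum_survival(200, 0.5, 8.0, 30.0, rng)
        tiny = pd.Series(np.arange(len(df)) < 3, index=df.index)
        table = subgroup_forest(df, {"tiny": tiny}, "time", "event", "treated")
        assert not table.iloc[0]["tested"]


class TestGroupCompare:
    def test_identical_samples_mann_whitney_null(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        _, p = group_compare(a, a)
        assert p == pytest.approx(1.0)

    def test_chi_square_matches_textbook_formula(self):
        table = [[20, 10], [10, 20]]
        # expected counts all 15; chi2 = 4 * (5^2/15) = 20/3
        stat, _ = group_compare(table, kind="chi_square")
        assert stat == pytest.approx(20 / 3)

    def test_auto_routes_to_fisher_on_small_expected_cells(self):
        table = [[2, 8], [1, 9]]  # expected cell < 5
        stat_auto, p_auto = group_compare(table, kind="auto")
        stat_f, p_f = group_compare(table, kind="fisher")
        assert (stat_auto, p_auto) == (stat_f, p_f)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare([], [1.0])


class TestBhAdjust:
    def test_hand_computed_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_monotone_and_idempotent(self, rng):
        p = rng.random(25)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        np.testing.assert_allclose(bh_adjust(adj), adj)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
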