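import json

import numpy as np
import pytest
from scipy import stats

from ctdnatrack.detection_models import (
    LodSpec,
    NegativeClass,
    SheddingModel,
    classify_negative,
    detection_probability,
    fit_shedding_model,
    implied_min_reads,
    min_detectable_af,
    predict_msaf_interval,
)
from ctdnatrack.synthetic_cohort import generate_tracerx_standin


class TestBinomialLod:
    def test_closed_form_for_single_read(self):
        """For k=1, P(X>=1) = 1-(1-p)^N = confidence has the closed form
        p = 1 - (1-c)^(1/N)."""
        got = min_detectable_af(LodSpec(depth=10_000, min_reads=1))
        expected = 1 - 0.05 ** (1 / 10_000)
        assert got == pytest.approx(expected, rel=1e-5)
        assert expected == pytest.approx(2.996e-4, rel=1e-3)

    def test_zero_reads_boundary(self):
        with pytest.warns(UserWarning):
            assert min_detectable_af(LodSpec(depth=10_000, min_reads=0)) == 0.0

    @pytest.mark.parametrize("k", [2, 5, 8, 20])
    def test_returned_af_sits_on_the_confidence_crossing(self, k):
        p = min_detectable_af(LodSpec(depth=10_000, min_reads=k))
        assert detection_probability(p * (1 + 1e-4), 10_000, k) >= 0.95
        assert detection_probability(p * (1 - 1e-4), 10_000, k) < 0.95

    @pytest.mark.parametrize("depth,k", [(10_000, 3), (10_000, 8), (20_000, 12)])
    def test_matches_exhaustive_grid_oracle(self, depth, k):
        """The bisection answer agrees with a brute-force scan of the exact
        binomial survival function over a 1e-6 allele-fraction grid."""
        grid = np.arange(1e-6, 5e-3, 1e-6)
        sf = stats.binom.sf(k - 1, depth, grid)
        oracle = grid[np.argmax(sf >= 0.95)]
        got = min_detectable_af(LodSpec(depth=depth, min_reads=k))
        assert abs(got - oracle) <= 1e-6

    def test_monotone_in_reads_and_depth(self):
        by_k = [min_detectable_af(LodSpec(10_000, k)) for k in (1, 4, 8, 16)]
        assert by_k == sorted(by_k)
        by_depth = [min_detectable_af(LodSpec(d, 8)) for d in (5_000, 10_000, 20_000)]
        assert by_depth == sorted(by_depth, reverse=True)

    def test_implied_min_reads_round_trip(self):
        for k in range(1, 21):
            lod = min_detectable_af(LodSpec(10_000, k))
            assert implied_min_reads(10_000, lod) == k

    def test_implied_min_reads_validates_target(self):
        with pytest.raises(ValueError):
            implied_min_reads(10_000, 1.5)
        with pytest.raises(ValueError):
            implied_min_reads(10_000, 0.0)


class TestSheddingModel:
    BETA = (-3.0, 1.2, 0.4)

    def test_noiseless_data_recovers_coefficients_exactly(self):
        train = generate_tracerx_standin(n=100, beta=self.BETA, sigma=0.0, seed=3)
        model = fit_shedding_model(train)
        assert model.beta_intercept == pytest.approx(-3.0, abs=1e-9)
        assert model.beta_log10size == pytest.approx(1.2, abs=1e-9)
        assert model.beta_histology == pytest.approx(0.4, abs=1e-9)
        assert model.sigma == pytest.approx(0.0, abs=1e-7)

    def test_recovery_within_three_standard_errors(self):
        train = generate_tracerx_standin(n=521, beta=self.BETA, sigma=0.5, seed=7)
        model = fit_shedding_model(train)
        X = np.column_stack(
            [
                np.ones(len(train)),
                np.log10(train["tumor_size"]),
                (train["histology"] == "LUSC").astype(float),
            ]
        )
        se = model.sigma * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        for est, true, s in zip(model.beta, self.BETA, se):
            assert abs(est - true) < 3 * s

    def test_duplicated_training_set_gives_identical_coefficients(self):
        import pandas as pd

        train = generate_tracerx_standin(n=60, seed=11)
        doubled = pd.concat([train, train], ignore_index=True)
        m1 = fit_shedding_model(train)
        m2 = fit_shedding_model(doubled)
        np.testing.assert_allclose(m1.beta, m2.beta, atol=1e-10)

    def test_rejects_nonpositive_values_naming_rows(self):
        train = generate_tracerx_standin(n=20, seed=1)
        train.loc[4, "msaf"] = 0.0
        with pytest.raises(ValueError, match="5"):
            fit_shedding_model(train)

    def test_single_histology_level_drops_indicator_with_warning(self):
        train = generate_tracerx_standin(n=50, seed=5, lusc_fraction=0.0)
        with pytest.warns(UserWarning):
            model = fit_shedding_model(train)
        assert not model.has_histology
        assert model.beta_histology == 0.0
        # prediction still works for either histology label
        predict_msaf_interval(model, 40.0, "LUSC")

    def test_interval_matches_statsmodels_prediction_interval(self):
        """Cross-check the stored interval machinery against the OLS
        get_prediction machinery for a new observation."""
        import statsmodels.api as sm

        train = generate_tracerx_standin(n=200, seed=13)
        model = fit_shedding_model(train)
        X = np.column_stack(
            [
                np.ones(len(train)),
                np.log10(train["tumor_size"]),
                (train["histology"] == "LUSC").astype(float),
            ]
        )
        res = sm.OLS(np.log10(train["msaf"]), X).fit()
        x_new = np.array([[1.0, np.log10(35.0), 1.0]])
        frame = res.get_prediction(x_new).summary_frame(alpha=0.05)
        point, lower, upper = predict_msaf_interval(model, 35.0, "LUSC")
        assert np.log10(lower) == pytest.approx(frame["obs_ci_lower"][0], abs=1e-8)
        assert np.log10(upper) == pytest.approx(frame["obs_ci_upper"][0], abs=1e-8)
        assert np.log10(point) == pytest.approx(frame["mean"][0], abs=1e-8)

    def test_interval_orders_and_monotonicity(self):
        train = generate_tracerx_standin(n=200, seed=17)
        model = fit_shedding_model(train)
        p1, lo1, hi1 = predict_msaf_interval(model, 20.0, "NON_LUSC")
        p2, lo2, hi2 = predict_msaf_interval(model, 80.0, "NON_LUSC")
        assert lo1 < p1 < hi1
        assert p2 > p1  # positive size slope

    def test_prediction_interval_coverage(self):
        """~95% of new patients drawn from the generating law fall inside
        their own 95% prediction interval."""
        train = generate_tracerx_standin(n=521, beta=self.BETA, sigma=0.5, seed=19)
        model = fit_shedding_model(train)
        new = generate_tracerx_standin(n=2000, beta=self.BETA, sigma=0.5, seed=23)
        covered = 0
        for size, hist, msaf in new.itertuples(index=False):
            _, lo, hi = predict_msaf_interval(model, size, hist)
            covered += lo <= msaf <= hi
        assert covered / len(new) == pytest.approx(0.95, abs=0.02)

    def test_classification_threshold_boundary(self):
        """Lower bound strictly below 0.1% -> technical negative; at or
        above -> non-shedder (boundary resolved to non-shedder)."""
        point = SheddingModel(
            beta=np.array([np.log10(0.001), 0.0]),
            sigma=0.0,
            df_resid=10,
            xtx_inv=np.zeros((2, 2)),
            n_train=12,
            has_histology=False,
        )
        assert classify_negative(point, 40.0, "LUSC") == NegativeClass.NON_SHEDDER
        below = SheddingModel(
            beta=np.array([np.log10(0.0005), 0.0]),
            sigma=0.0,
            df_resid=10,
            xtx_inv=np.zeros((2, 2)),
            n_train=12,
            has_histology=False,
        )
        assert classify_negative(below, 40.0, "LUSC") == NegativeClass.TECHNICAL_NEGATIVE

    def test_classification_deterministic_under_training_permutation(self):
        train = generate_tracerx_standin(n=200, seed=29)
        permuted = train.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m1, m2 = fit_shedding_model(train), fit_shedding_model(permuted)
        for size in (10.0, 30.0, 90.0):
            for hist in ("LUSC", "NON_LUSC"):
                assert classify_negative(m1, size, hist) == classify_negative(
                    m2, size, hist
                )

    def test_json_round_trip(self):
        model = fit_shedding_model(generate_tracerx_standin(n=50, seed=31))
        back = SheddingModel.from_json(model.to_json())
        np.testing.assert_allclose(back.beta, model.beta)
        np.testing.assert_allclose(back.xtx_inv, model.xtx_inv)
        assert back.sigma == model.sigma
        assert json.loads(model.to_json())["n_train"] == 50
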