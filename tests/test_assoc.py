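"""Encoder/converter classification, odds ratios, and regression models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    balanced_anova_ml,
    bh_stepup,
    logistic_loglik,
    ols_normal_equations,
)
from sterolscreen.assoc import (
    ContingencyTable,
    SeparationError,
    adjust_bh,
    build_design,
    classify_samples,
    fit_linear,
    fit_logistic,
    fit_random_intercept,
    odds_ratio,
    transform_metabolite,
)


class TestClassifySamples:
    @staticmethod
    def _inputs(det_values):
        det = pd.DataFrame(det_values, index=["isma_c0", "isma_c1"],
                           columns=["S0", "S1"])
        calls = pd.Series([True, False], index=["S0", "S1"])
        meta = pd.DataFrame({"age": [40.0, 50.0]}, index=["S0", "S1"])
        return det, calls, meta

    def test_any_cluster_detection_makes_encoder(self):
        det, calls, meta = self._inputs([[True, False], [False, False]])
        out = classify_samples(det, calls, meta)
        assert bool(out.loc["S0", "encoder"]) is True
        assert bool(out.loc["S1", "encoder"]) is False
        assert bool(out.loc["S0", "converter"]) is True

    def test_missing_metadata_warns_and_excludes(self):
        det, calls, meta = self._inputs([[True, True], [False, False]])
        with pytest.warns(UserWarning, match="without metadata"):
            out = classify_samples(det, calls, meta.drop(index="S1"))
        assert list(out.index) == ["S0"]

    def test_matches_planted_truth_under_perfect_detection(self):
        from sterolscreen.seqcluster import AbundanceMatrix, compute_tpm, detection_matrix
        from sterolscreen.simdata import SimulationConfig, simulate_study
        from sterolscreen.workflow import planted_cluster_ids, run_discovery

        cfg = SimulationConfig(n_samples=60, n_species=8, encoder_species=2,
                               genes_per_species=3, detect_prob_delta=1.0,
                               background_fp_epsilon=0.0, sequencing_depth=3e5,
                               seed=23)
        study = simulate_study(cfg)
        result = run_discovery(study)
        ids = planted_cluster_ids(study, result.clusters)
        det = result.detection.loc[sorted(ids)]
        meta = pd.DataFrame({"age": 50.0}, index=study.counts.columns)
        out = classify_samples(det, study.metabolites["coprostanol_detected"], meta)
        truth_encoder = study.species_presence.loc[study.truth["encoder"]].any(axis=0)
        assert (out["encoder"] == truth_encoder.loc[out.index]).all()
        assert (out["converter"] == truth_encoder.loc[out.index]).all()


class TestOddsRatio:
    def test_arithmetic(self):
        res = odds_ratio(ContingencyTable(40, 15, 10, 89))
        assert res.odds_ratio == pytest.approx((40 * 89) / (15 * 10))
        assert not res.correction_applied

    def test_proportional_rows_give_unity(self):
        res = odds_ratio(ContingencyTable(10, 10, 5, 5))
        assert res.odds_ratio == pytest.approx(1.0)

    def test_haldane_anscombe_matches_hand_computation(self):
        res = odds_ratio(ContingencyTable(12, 3, 0, 20))
        a, b, c, d = 12.5, 3.5, 0.5, 20.5
        assert res.correction_applied
        assert res.odds_ratio == pytest.approx((a * d) / (b * c))
        half = 1.959963985 * np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert res.ci_low == pytest.approx(np.exp(np.log((a * d) / (b * c)) - half), rel=1e-6)
        assert res.ci_high == pytest.approx(np.exp(np.log((a * d) / (b * c)) + half), rel=1e-6)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            odds_ratio(ContingencyTable(0, 0, 5, 5))

    def test_ci_brackets_estimate(self):
        res = odds_ratio(ContingencyTable(40, 15, 10, 89))
        assert res.ci_low <= res.odds_ratio <= res.ci_high

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.tuples(*[st.integers(1, 60)] * 4))
    def test_symmetry_invariances(self, cells):
        a, b, c, d = cells
        base = odds_ratio(ContingencyTable(a, b, c, d)).odds_ratio
        # swapping both rows and both columns preserves the OR, as does
        # transposing the table; swapping a single margin inverts it
        both_swapped = odds_ratio(ContingencyTable(d, c, b, a)).odds_ratio
        transposed = odds_ratio(ContingencyTable(a, c, b, d)).odds_ratio
        row_swapped = odds_ratio(ContingencyTable(c, d, a, b)).odds_ratio
        col_swapped = odds_ratio(ContingencyTable(b, a, d, c)).odds_ratio
        assert both_swapped == pytest.approx(base, rel=1e-12)
        assert transposed == pytest.approx(base, rel=1e-12)
        assert row_swapped == pytest.approx(1 / base, rel=1e-12)
        assert col_swapped == pytest.approx(1 / base, rel=1e-12)


class TestTransformMetabolite:
    def test_zero_maps_to_minus_five_before_scaling(self):
        values = np.array([0.0, 1e-3, 1e-1])
        z = transform_metabolite(values)
        logged = np.log10(np.array([1e-5, 1e-3, 1e-1]))
        expected = (logged - logged.mean()) / logged.std(ddof=1)
        assert np.allclose(z, expected)

    def test_two_point_z_scores(self):
        z = transform_metabolite(np.array([1e-3, 1e-1]))
        assert z == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_standardization_identity(self, rng):
        z = transform_metabolite(rng.lognormal(0, 1, 50))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_shape(self, rng):
        """Standardizing already-standardized (exponentiated) data is stable."""
        z1 = transform_metabolite(rng.lognormal(0, 1, 80))
        z2 = transform_metabolite(np.power(10.0, z1))
        assert np.allclose(z1, z2)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            transform_metabolite(np.ones(5))


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        res = fit_linear(2 * x + 1, X)
        assert res.params["intercept"] == pytest.approx(1.0, abs=1e-10)
        assert res.params["x"] == pytest.approx(2.0, abs=1e-10)
        assert res.sigma2 == pytest.approx(0.0, abs=1e-18)

    def test_matches_normal_equations(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        X.insert(0, "intercept", 1.0)
        y = rng.normal(size=100)
        res = fit_linear(y, X)
        beta, se = ols_normal_equations(y, X.to_numpy())
        assert np.allclose(res.params.to_numpy(), beta, atol=1e-8)
        assert np.allclose(res.bse.to_numpy(), se, atol=1e-8)

    def test_rank_deficiency_names_columns(self, rng):
        X = pd.DataFrame({"intercept": np.ones(20), "x": rng.normal(size=20)})
        X["x_copy"] = X["x"]
        with pytest.raises(ValueError, match="x_copy"):
            fit_linear(rng.normal(size=20), X)


class TestFitLogistic:
    def test_null_slope(self, rng):
        X = pd.DataFrame({"intercept": np.ones(400), "x": rng.normal(size=400)})
        y = (rng.random(400) < 0.5).astype(float)
        res = fit_logistic(y, X)
        assert abs(res.params["x"]) < 3 * res.bse["x"]

    def test_separation_detected(self):
        X = pd.DataFrame({"intercept": np.ones(20),
                          "x": np.r_[np.zeros(10), np.ones(10)]})
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(SeparationError):
            fit_logistic(y, X)

    def test_single_class_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(5)})
        with pytest.raises(ValueError, match="classes"):
            fit_logistic(np.ones(5), X)

    def test_mle_beats_random_coefficients(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["x1", "x2"])
        X.insert(0, "intercept", 1.0)
        eta = 0.5 + X["x1"] - 0.7 * X["x2"]
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        res = fit_logistic(y, X)
        ll_hat = logistic_loglik(y, X.to_numpy(), res.params.to_numpy())
        for _ in range(1000):
            beta = rng.normal(scale=2.0, size=3)
            assert ll_hat >= logistic_loglik(y, X.to_numpy(), beta) - 1e-8


class TestFitRandomIntercept:
    def test_reduces_to_ols_when_between_variance_absent(self):
        # seeded data whose between-group spread is below the within-group
        # expectation, so the ML boundary estimate is tau2 = 0
        r = np.random.default_rng(2)
        k, n = 30, 4
        y = 2.0 + r.normal(0, 1.0, k * n)
        groups = np.repeat(np.arange(k), n)
        X = pd.DataFrame({"intercept": np.ones(k * n)})
        sigma2, tau2 = balanced_anova_ml(y.reshape(k, n))
        assert tau2 == 0.0  # the closed form confirms the boundary case
        res = fit_random_intercept(y, X, groups)
        ols = fit_linear(y, X)
        assert res.params["intercept"] == pytest.approx(ols.params["intercept"], abs=1e-6)
        assert res.tau2 < 1e-4

    def test_recovers_planted_variance_components(self):
        r = np.random.default_rng(12)
        k, n = 200, 5
        u = np.repeat(r.normal(0, np.sqrt(0.5), k), n)
        x = r.normal(size=k * n)
        y = 1.0 + 0.5 * x + u + r.normal(0, 1.0, k * n)
        X = pd.DataFrame({"intercept": np.ones(k * n), "x": x})
        res = fit_random_intercept(y, X, np.repeat(np.arange(k), n))
        assert res.params["x"] == pytest.approx(0.5, abs=0.15)
        assert res.sigma2 == pytest.approx(1.0, abs=0.15)
        assert res.tau2 == pytest.approx(0.5, abs=0.15)

    def test_matches_balanced_anova_closed_form(self):
        r = np.random.default_rng(7)
        k, n = 40, 5
        y = 3.0 + np.repeat(r.normal(0, np.sqrt(0.5), k), n) + r.normal(0, 1.0, k * n)
        X = pd.DataFrame({"intercept": np.ones(k * n)})
        res = fit_random_intercept(y, X, np.repeat(np.arange(k), n))
        sigma2, tau2 = balanced_anova_ml(y.reshape(k, n))
        assert res.sigma2 == pytest.approx(sigma2, rel=1e-3)
        assert res.tau2 == pytest.approx(tau2, rel=1e-3)

    def test_singleton_groups_rejected(self):
        X = pd.DataFrame({"intercept": np.ones(4)})
        with pytest.raises(ValueError, match="fit_linear"):
            fit_random_intercept(np.arange(4.0), X, np.arange(4))


class TestAdjustBh:
    def test_stepup_arithmetic(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_pvalues_unchanged(self):
        assert np.allclose(adjust_bh([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])

    def test_matches_stepup_oracle(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 30)))
            assert np.allclose(adjust_bh(p), bh_stepup(p))


class TestBuildDesign:
    def test_categorical_reference_is_first_alphabetical(self):
        df = pd.DataFrame({"disease": ["UC", "CD", "nonIBD", "CD"]})
        X = build_design(df, ["disease"])
        assert list(X.columns) == ["intercept", "disease[UC]", "disease[nonIBD]"]

    def test_booleans_become_indicators(self):
        df = pd.DataFrame({"statin": [True, False]})
        X = build_design(df, ["statin"])
        assert X["statin"].tolist() == [1.0, 0.0]
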