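"""Downstream analyses: fluid strategy bands, SOFA strata, stabilized IPW,
weighted interaction models, Kaplan-Meier curves, classifiers."""

import numpy as np
import pandas as pd
import pytest

from odtgc.downstream import (
    FluidRecord,
    fit_phenotype_classifier,
    fluid_effect_model,
    fluid_records,
    fluid_strategy,
    km_estimate,
    prognostic_compare,
    propensity_weights,
    sofa_stratum,
    survival_at,
)


class TestFluidStrategy:
    @pytest.mark.parametrize("volume,weight,expected", [
        (2000, 80, 0),    # 25 mL/kg -> low
        (3200, 80, 1),    # 40 mL/kg -> moderate
        (4800, 80, 2),    # 60 mL/kg -> high
        (2400, 80, 1),    # exactly 30 mL/kg -> closed middle band
        (4000, 80, 1),    # exactly 50 mL/kg -> closed middle band
        (0, 80, 0),
    ])
    def test_bands(self, volume, weight, expected):
        assert fluid_strategy(volume, weight) == expected

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            fluid_strategy(-1.0, 80.0)

    def test_record_derives_both_windows(self):
        rec = FluidRecord("p0", 2000.0, 4800.0, 80.0)
        assert rec.strategy_0_12h == 0 and rec.strategy_12_24h == 2


class TestSofaStratum:
    @pytest.mark.parametrize("score,expected", [
        (2, "2-6"), (6, "2-6"), (7, "7-10"), (8, "7-10"),
        (10, "7-10"), (11, ">=11"), (20, ">=11"),
    ])
    def test_bands(self, score, expected):
        assert sofa_stratum(score) == expected

    def test_below_cohort_entry_rejected(self):
        with pytest.raises(ValueError):
            sofa_stratum(1)


class TestFluidRecords:
    def test_early_deaths_filtered(self, default_cohort):
        rec = fluid_records(default_cohort.fluids, default_cohort.demographics,
                            default_cohort.outcomes, min_survival_days=1.0)
        oc = default_cohort.outcomes.set_index("patient_id")
        early = oc[(oc["death"] == 1) & (oc["time_to_event_days"] < 1.0)].index
        assert not set(rec["patient_id"]) & set(early)

    def test_all_strategies_populated(self, default_cohort):
        rec = fluid_records(default_cohort.fluids, default_cohort.demographics)
        assert set(rec["strategy_0_12h"].unique()) == {0, 1, 2}
        assert set(rec["strategy_12_24h"].unique()) == {0, 1, 2}


class TestPropensityWeights:
    def test_null_design_weights_near_one(self, rng):
        X = rng.normal(size=(2000, 4))
        t = rng.integers(0, 3, size=2000)      # independent of X
        w = propensity_weights(X, t)
        assert abs(w.mean() - 1.0) < 0.05
        assert np.percentile(np.abs(w - 1.0), 90) < 0.25
        assert np.all(w > 0)

    def test_mean_one_on_confounded_design(self, rng):
        n = 2000
        X = rng.normal(size=(n, 3))
        logits = np.column_stack(
            [np.zeros(n), 0.7 * X[:, 0], -0.7 * X[:, 0] + 0.4 * X[:, 1]]
        )
        p = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        t = np.array([rng.choice(3, p=pi) for pi in p])
        w = propensity_weights(X, t)
        assert abs(w.mean() - 1.0) < 0.05

    def test_weighting_balances_covariates(self, rng):
        n = 4000
        X = rng.normal(size=(n, 2))
        logits = np.column_stack([np.zeros(n), 0.8 * X[:, 0], -0.8 * X[:, 0]])
        p = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        t = np.array([rng.choice(3, p=pi) for pi in p])
        w = propensity_weights(X, t, truncate_percentile=None)
        # standardized difference of X0 between arms, before vs after weighting
        def std_diff(weights):
            m = [np.average(X[t == a, 0], weights=weights[t == a]) for a in (0, 1)]
            v = [np.average(
                    (X[t == a, 0] - m[i])**2, weights=weights[t == a]
                 ) for i, a in enumerate((0, 1))]
            return abs(m[0] - m[1]) / np.sqrt(np.mean(v))
        raw = std_diff(np.ones(n))
        weighted = std_diff(w)
        assert raw > 0.3
        assert weighted < 0.1

    def test_single_level_rejected(self, rng):
        with pytest.raises(ValueError):
            propensity_weights(rng.normal(size=(10, 2)), np.zeros(10))


class TestFluidEffectModel:
    @staticmethod
    def simulate(rng, n=1500, interaction=0.0):
        strategy = rng.integers(0, 3, size=n)
        phenotype = rng.choice(list("ABC"), size=n)
        x = rng.normal(size=n)
        lin = -1.5 + 0.3 * (strategy == 2) + 0.8 * (phenotype == "C") + 0.4 * x
        lin = lin + interaction * ((strategy == 2) & (phenotype == "C"))
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        cov = pd.DataFrame({"x": x})
        return y, strategy, phenotype, cov

    def test_result_contract(self, rng):
        y, s, p, cov = self.simulate(rng)
        res = fluid_effect_model(y, s, p, cov)
        assert res.lrt_stat >= 0.0
        assert res.lrt_df == 4          # 2 strategy dummies x 2 phenotype dummies
        assert (res.table["ci_low"] <= res.table["OR"]).all()
        assert (res.table["OR"] <= res.table["ci_high"]).all()

    def test_strong_interaction_detected(self, rng):
        y, s, p, cov = self.simulate(rng, n=4000, interaction=1.5)
        res = fluid_effect_model(y, s, p, cov)
        assert res.lrt_p < 0.01

    def test_single_phenotype_degenerates_to_zero_df(self, rng):
        y, s, _, cov = self.simulate(rng)
        res = fluid_effect_model(y, s, np.repeat("A", len(y)), cov)
        # no phenotype contrast -> no interaction terms -> LRT trivially 0
        assert res.lrt_df == 0
        assert res.lrt_stat == pytest.approx(0.0, abs=1e-6)

    def test_known_effect_recovered(self, rng):
        y, s, p, cov = self.simulate(rng, n=6000)
        res = fluid_effect_model(y, s, p, cov, weights=np.ones(len(y)))
        term = res.table.set_index("term").loc["strategy_2"]
        assert term["ci_low"] < np.exp(0.3) < term["ci_high"]


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        curves = km_estimate(np.array([5.0, 9.0, 28.0]), np.zeros(3, dtype=int))
        assert (curves["0"]["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        # n=2: death at 5 (S drops to 1/2), censoring at 10 (no drop)
        curves = km_estimate(np.array([5.0, 10.0]), np.array([1, 0]))
        c = curves["0"]
        assert survival_at(c, 4.9) == pytest.approx(1.0)
        assert survival_at(c, 5.0) == pytest.approx(0.5)
        assert survival_at(c, 10.0) == pytest.approx(0.5)

    def test_hand_product_limit_multistep(self):
        # deaths at 1 and 3 among 4 with a censoring at 2:
        # S(1) = 3/4; at t=3 risk set has 2 -> S(3) = 3/4 * 1/2 = 3/8
        curves = km_estimate(
            np.array([1.0, 2.0, 3.0, 4.0]), np.array([1, 0, 1, 0])
        )
        c = curves["0"]
        assert survival_at(c, 1.0) == pytest.approx(0.75)
        assert survival_at(c, 3.0) == pytest.approx(0.375)

    def test_synthetic_cohort_curves_ordered(self, default_cohort):
        merged = default_cohort.outcomes.merge(default_cohort.truth,
                                               on="patient_id")
        curves = km_estimate(
            merged["time_to_event_days"].to_numpy(),
            merged["death"].to_numpy(),
            merged["phenotype"].to_numpy(),
        )
        s28 = {g: survival_at(c, 28.0) for g, c in curves.items()}
        assert s28["A"] > s28["B"] > s28["C"]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(np.array([]), np.array([]), np.array([]))


class TestPhenotypeClassifier:
    def test_separable_features_near_perfect(self, rng):
        n = 300
        labels = rng.integers(0, 3, size=n)
        X = np.column_stack([labels + rng.normal(0, 0.05, n),
                             rng.normal(size=n)])
        res = fit_phenotype_classifier(X, labels, n_folds=5, seed=0,
                                       n_bootstrap=50, n_estimators=50)
        assert res["auroc"] > 0.99

    def test_shuffled_labels_near_chance(self, rng):
        n = 400
        X = rng.normal(size=(n, 5))
        labels = rng.integers(0, 3, size=n)
        res = fit_phenotype_classifier(X, labels, n_folds=5, seed=0,
                                       n_bootstrap=50, n_estimators=50)
        assert abs(res["auroc"] - 0.5) < 0.08

    def test_deterministic_for_seed(self, rng):
        X = rng.normal(size=(200, 4))
        labels = rng.integers(0, 3, size=200)
        a = fit_phenotype_classifier(X, labels, seed=1, n_bootstrap=10,
                                     n_estimators=30)
        b = fit_phenotype_classifier(X, labels, seed=1, n_bootstrap=10,
                                     n_estimators=30)
        assert a["auroc"] == b["auroc"]
        np.testing.assert_array_equal(a["oof_proba"], b["oof_proba"])

    def test_four_hour_features_predict_model_phenotypes(
        self, small_prepared, small_model
    ):
        """The planted structure is partially visible at 4 h: a boosted
        classifier on first-bin features recovers the model's phenotypes
        with macro AUROC above 0.8."""
        from odtgc.model import assign

        labels = assign(small_model, small_prepared.data)
        demo = small_prepared.cohort.demographics.set_index("patient_id").loc[
            small_prepared.data.patient_ids
        ]
        X4 = np.column_stack([
            small_prepared.tensor.values[:, 0, :],
            demo[["age", "gender", "weight_kg"]],
        ])
        res = fit_phenotype_classifier(X4, labels, n_folds=5, seed=0,
                                       n_bootstrap=20)
        assert res["auroc"] > 0.8

    def test_class_too_small_rejected(self, rng):
        X = rng.normal(size=(20, 2))
        labels = np.array([0] * 18 + [1] * 2)
        with pytest.raises(ValueError):
            fit_phenotype_classifier(X, labels, n_folds=5)


class TestPrognosticCompare:
    def test_perfect_predictor(self):
        y = np.array([0, 0, 0, 1, 1, 1] * 10)
        res = prognostic_compare({"oracle": y.astype(float)}, y)
        assert res.loc[0, "auroc"] == pytest.approx(1.0)

    def test_random_predictor_near_chance(self, rng):
        y = rng.integers(0, 2, size=600)
        res = prognostic_compare({"noise": rng.normal(size=600)}, y)
        assert abs(res.loc[0, "auroc"] - 0.5) < 0.08

    def test_phenotype_labels_beat_noisy_severity_proxy(self, default_cohort):
        merged = default_cohort.outcomes.merge(default_cohort.truth,
                                               on="patient_id")
        merged = merged.merge(default_cohort.demographics, on="patient_id")
        res = prognostic_compare(
            {
                "phenotype": merged["phenotype"],
                "sofa": merged["sofa"].astype(float),
            },
            merged["death"].to_numpy(),
        )
        res = res.set_index("predictor")
        assert res.loc["phenotype", "auroc"] > res.loc["sofa", "auroc"]

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            prognostic_compare({"const": np.ones(10)}, np.ones(10, dtype=int))
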