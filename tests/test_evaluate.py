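"""ROC/AUC oracles, Youden scan, forests, nested comparison, stepwise."""

import itertools

import numpy as np
import pandas as pd
import pytest

from polyfrac import (
    ConditionalLogisticRegression,
    DiffMatrix,
    external_validation,
    medcount_forest,
    nested_model_comparison,
    roc_auc,
    score_subjects,
    stepwise_logistic,
    youden_cutoff,
)
from polyfrac.synth import simulate_matched_pairs
from conftest import toy_dataset


def brute_auc(scores, labels):
    """Exhaustive concordant-pair enumeration, ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    total = wins = 0.0
    for c, k in itertools.product(scores[labels], scores[~labels]):
        total += 1
        wins += 1.0 if c > k else (0.5 if c == k else 0.0)
    return wins / total


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_auc([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0])
        assert roc.auc == 1.0

    def test_all_ties_gives_half(self):
        roc = roc_auc(np.ones(10), [1] * 5 + [0] * 5)
        assert roc.auc == 0.5

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])

    def test_six_point_fixture_matches_enumeration(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.1]
        labels = [0, 0, 1, 1, 1, 0]
        assert roc_auc(scores, labels).auc == pytest.approx(brute_auc(scores, labels))

    def test_random_fixture_matches_enumeration(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(0, 6, 40).astype(float)  # heavy ties
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]
        assert roc_auc(scores, labels).auc == pytest.approx(brute_auc(scores, labels))

    def test_delong_interval_matches_reference_implementation(self):
        # AUC and CI computed once with R pROC (DeLong) on this fixture
        scores = [0.3, -1.0, 0.8, 0.9, -2.0, -1.3, 0.1, -0.3, -0.0, -0.9, 0.9,
                  0.8, 0.1, 1.1, 0.5, -0.9, 0.4, -1.0, 0.9, -0.0, -0.2, -0.7,
                  1.2, -0.2, -0.4, -0.4, 0.5, 0.4, 0.4, 0.4, 2.1, -0.4, -0.5,
                  -0.8, 0.6, 1.1, -0.1, -0.8, -0.8, 0.7]
        labels = [1, 1, 1, 0, 0, 0, 1, 1, 0, 1, 1, 1, 0, 0, 0, 0, 1, 0, 1, 1,
                  0, 1, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 0, 1, 1, 1, 1, 0, 0, 0]
        roc = roc_auc(scores, labels)
        assert roc.auc == pytest.approx(0.6278195489, abs=1e-9)
        assert roc.ci_low == pytest.approx(0.4479712416, abs=1e-9)
        assert roc.ci_high == pytest.approx(0.8076678562, abs=1e-9)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.5
        labels[:2] = [True, False]
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(3 * scores) + 7, labels).auc
        assert a == pytest.approx(b)

    def test_bootstrap_interval_contains_point(self):
        rng = np.random.default_rng(2)
        scores = np.r_[rng.normal(1, 1, 40), rng.normal(0, 1, 40)]
        labels = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        roc = roc_auc(scores, labels, ci_method="bootstrap", n_boot=200, seed=0)
        assert roc.ci_low <= roc.auc <= roc.ci_high


class TestYouden:
    def test_separated_classes_reach_youden_one(self):
        roc = roc_auc([3, 4, 5, 0, 1, 2], [1, 1, 1, 0, 0, 0])
        m = youden_cutoff(roc)
        assert m.youden == pytest.approx(1.0)
        assert m.sensitivity == m.specificity == 1.0

    def test_all_ties_give_zero_youden(self):
        m = youden_cutoff(roc_auc(np.ones(10), [1] * 5 + [0] * 5))
        assert m.youden == pytest.approx(0.0)

    def test_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(3)
        scores = np.round(rng.normal(size=80), 1)
        labels = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        scores[:40] += 0.8
        m = youden_cutoff(roc_auc(scores, labels))
        best = max(
            (np.mean(scores[labels] >= c) + np.mean(scores[~labels] < c) - 1, -c)
            for c in np.unique(scores)
        )
        assert m.youden == pytest.approx(best[0])
        assert m.cutoff == pytest.approx(-best[1])  # ties -> lowest cutoff

    def test_ppv_npv_consistent_with_bayes_at_half_prevalence(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(0.7, 1, 60), rng.normal(0, 1, 60)]
        labels = np.r_[np.ones(60, bool), np.zeros(60, bool)]
        m = youden_cutoff(roc_auc(scores, labels))
        se, sp = m.sensitivity, m.specificity
        assert m.ppv == pytest.approx(se / (se + (1 - sp)))
        assert m.npv == pytest.approx(sp / (sp + (1 - se)))


class TestScoring:
    @staticmethod
    def _result(beta, names):
        from polyfrac.model import FitResult

        return FitResult(beta=np.asarray(beta, float), names=list(names),
                         lam=0.0, converged=True, n_iter=1)

    def test_zero_coefficients_score_zero(self):
        ds = toy_dataset(40, seed=5)
        fr = self._result(np.zeros(len(ds.variables)), ds.variables)
        assert (score_subjects(fr, ds)["score"] == 0).all()

    def test_single_variable_score_equals_covariate(self):
        ds = toy_dataset(30, seed=6)
        fr = self._result([1.0], ["med_count"])
        got = score_subjects(fr, ds)["score"].to_numpy()
        np.testing.assert_allclose(got, ds.data["med_count"].to_numpy(float))

    def test_score_is_dot_product(self):
        ds = toy_dataset(30, seed=6)
        rng = np.random.default_rng(7)
        beta = rng.normal(size=len(ds.variables))
        fr = self._result(beta, ds.variables)
        got = score_subjects(fr, ds)["score"].to_numpy()
        want = ds.data[ds.variables].to_numpy(float) @ beta
        np.testing.assert_allclose(got, want)

    def test_missing_variable_rejected(self):
        ds = toy_dataset(10, seed=8)
        from polyfrac.model import FitResult

        fr = FitResult(beta=np.zeros(1), names=["nope"], lam=0.0, converged=True, n_iter=1)
        with pytest.raises(ValueError, match="nope"):
            score_subjects(fr, ds)


class TestForest:
    def test_reference_category_is_unity(self):
        ds = toy_dataset(150, seed=9)
        forest = medcount_forest(ds, strata=("all",))
        ref = forest[forest["reference"]]
        assert (ref["odds_ratio"] == 1.0).all()
        assert ref["ci_low"].isna().all()

    def test_null_counts_cover_unity(self):
        # same count distribution in both roles: Wald CIs should cover 1 in
        # >= 90% of estimable category cells across replicates
        cover = total = 0
        for rep in range(30):
            ds = toy_dataset(500, beta_count=0.0, seed=100 + rep)
            forest = medcount_forest(ds, strata=("all",))
            est = forest[~forest["reference"]].dropna(subset=["ci_low"])
            cover += ((est["ci_low"] <= 1.0) & (est["ci_high"] >= 1.0)).sum()
            total += len(est)
        assert total > 0
        assert cover / total >= 0.90

    def test_positive_count_effect_yields_rising_trend(self):
        ors = []
        for rep in range(10):
            ds = toy_dataset(800, beta_count=np.log(1.25), seed=200 + rep)
            forest = medcount_forest(ds, strata=("all",))
            est = forest[~forest["reference"]].dropna(subset=["odds_ratio"])
            cats = est["category"].str.extract(r"(\d+)").astype(float)[0].to_numpy()
            ors.append(np.polyfit(cats, np.log(est["odds_ratio"].to_numpy()), 1)[0])
        assert np.mean(ors) > 0


class TestNestedComparison:
    def test_grid_is_complete(self):
        ds = toy_dataset(120, beta_rx=0.8, seed=10)
        out = nested_model_comparison(ds, seed=0, n_lambda=20, cv=3)
        assert len(out) == 12  # 4 variable sets x 3 strata
        assert set(out["stratum"]) == {"all", "early", "late"}
        assert out[out["stratum"] == "all"]["auc"].notna().all()

    def test_pure_noise_auc_near_half(self):
        ds = toy_dataset(400, seed=11)
        out = nested_model_comparison(ds, seed=1, strata=("all",), n_lambda=20, cv=4)
        row = out[out["variable_set"] == "count"].iloc[0]
        assert abs(row["auc"] - 0.5) < 0.08

    def test_signal_in_medication_flags_beats_count_alone(self):
        ds = toy_dataset(600, beta_rx=1.2, seed=12)
        out = nested_model_comparison(ds, seed=2, strata=("all",), n_lambda=25, cv=4)
        by = out.set_index("variable_set")["auc"]
        assert by["count+medications"] >= by["count"] - 0.02


class TestStepwise:
    def test_pure_noise_selects_almost_nothing(self):
        # with 6 null candidates the chance of > 2 spurious AIC entries per
        # replicate is ~6%, so 24/30 small selections is a safe floor
        small = 0
        for seed in range(30):
            D = simulate_matched_pairs(np.zeros(6), 150, seed=300 + seed)
            res = stepwise_logistic(DiffMatrix(D, [f"x{i}" for i in range(6)]))
            small += len(res.selected) <= 2
        assert small >= 24

    def test_strong_signal_is_selected(self):
        beta = np.zeros(6)
        beta[2] = 1.2
        D = simulate_matched_pairs(beta, 500, seed=13)
        res = stepwise_logistic(DiffMatrix(D, [f"x{i}" for i in range(6)]))
        assert "x2" in res.selected

    def test_empty_candidate_set(self):
        res = stepwise_logistic(DiffMatrix(np.zeros((20, 0)), []))
        assert res.selected == []
        assert res.aic == pytest.approx(2 * 20 * np.log(2))

    def test_auc_reported_when_dataset_given(self):
        ds = toy_dataset(200, beta_rx=1.0, seed=14)
        res = stepwise_logistic(ds)
        assert res.auc is None or 0.0 <= res.auc <= 1.0


class TestExternalValidation:
    def test_identity_validation_reproduces_training_auc(self):
        ds = toy_dataset(200, beta_rx=1.0, seed=15)
        from polyfrac.model import pair_difference

        fit = ConditionalLogisticRegression().fit(pair_difference(ds)).result()
        scored = score_subjects(fit, ds)
        train = roc_auc(scored["score"], scored["label"])
        val = external_validation(fit, ds)
        assert val.auc == pytest.approx(train.auc)

    def test_role_permuted_validation_is_noise(self):
        ds = toy_dataset(400, beta_rx=1.0, seed=16)
        from polyfrac.model import pair_difference

        fit = ConditionalLogisticRegression().fit(pair_difference(ds)).result()
        shuffled = ds.data.copy()
        rng = np.random.default_rng(0)
        shuffled["role"] = rng.permutation(shuffled["role"].to_numpy())
        # rebalance to keep both classes present
        perm_ds = type(ds)(shuffled, ds.variables, ds.labels)
        val = external_validation(fit, perm_ds)
        assert abs(val.auc - 0.5) < 0.08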