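"""ROC/AUC, DeLong comparison, calibration and predictive values."""

import numpy as np
import pytest

import turbt_complexity as tc


def brute_force_auc(scores, labels):
    """Concordant-pair count with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (pos.size * neg.size)


class TestROC:
    def test_perfect_separation_gives_unit_auc(self):
        r = tc.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0

    def test_constant_scores_give_half(self):
        r = tc.roc_auc([3.0] * 8, [0, 1] * 4)
        assert r.auc == pytest.approx(0.5)

    def test_trapezoid_equals_concordance_count(self, rng):
        """Trapezoid AUC matches exhaustive pair enumeration to 1e-12,
        including tied scores."""
        for _ in range(10):
            labels = rng.integers(0, 2, size=30)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 10, size=30).astype(float)  # many ties
            r = tc.roc_auc(scores, labels)
            assert abs(r.auc - brute_force_auc(scores, labels)) < 1e-12

    def test_auc_within_its_confidence_interval(self, rng):
        scores = rng.normal(size=60)
        labels = (scores + rng.normal(size=60) > 0).astype(int)
        r = tc.roc_auc(scores, labels)
        assert r.auc_ci[0] <= r.auc <= r.auc_ci[1]
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()

    def test_monotone_transform_leaves_auc_unchanged(self, rng):
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.4).astype(int)
        labels[0], labels[1] = 0, 1
        a = tc.roc_auc(scores, labels).auc
        b = tc.roc_auc(np.exp(2 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(tc.DegenerateOutcomeError):
            tc.roc_auc([1.0, 2.0], [1, 1])


class TestCompareAUC:
    def test_identical_scores_give_p_one(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[:2] = [0, 1]
        r = tc.compare_auc(scores, scores, labels)
        assert r.p_value == 1.0

    def test_monotone_transform_gives_p_one(self, rng):
        scores = rng.normal(size=40)
        labels = (rng.random(40) < 0.5).astype(int)
        labels[:2] = [0, 1]
        r = tc.compare_auc(scores, np.tanh(scores), labels)
        assert r.p_value == 1.0

    def test_type_one_error_is_calibrated(self):
        """Two independent noise scores on 400 cases: the DeLong test
        rejects at the nominal 5% rate (within Monte-Carlo slack)."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            labels = rng.integers(0, 2, size=400)
            if labels.min() == labels.max():
                continue
            a = rng.normal(size=400)
            b = rng.normal(size=400)
            if tc.compare_auc(a, b, labels).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_reps <= 0.07

    def test_length_mismatch_rejected(self):
        with pytest.raises(tc.InvalidInputError):
            tc.compare_auc([1, 2], [1, 2, 3], [0, 1])

    def test_bootstrap_agrees_with_delong_on_clear_difference(self, rng):
        n = 200
        signal = rng.normal(size=n)
        labels = (signal + rng.normal(scale=0.5, size=n) > 0).astype(int)
        labels[:2] = [0, 1]
        noise = rng.normal(size=n)
        delong = tc.compare_auc(signal, noise, labels)
        boot = tc.compare_auc_bootstrap(signal, noise, labels, n_boot=500, seed=5)
        assert delong.p_value < 0.01
        assert boot.p_value < 0.05


class TestCalibration:
    def _fit_and_predict(self, published_model, catalog, n, seed):
        scenarios = tc.generate_scenarios(
            catalog, n, rules=tc.default_consistency_rules(), seed=seed
        )
        truth = tc.GeneratingModel(
            intercept=published_model.intercept,
            domain_coefficients=dict(published_model.coefficients),
            seed=seed + 1,
        )
        outcomes = tc.simulate_outcomes(scenarios, truth)
        from turbt_complexity.scenario_builder import domain_score_frame

        scores = domain_score_frame(scenarios)
        model = tc.fit_logistic(scores, outcomes.to_numpy())
        return tc.predict_probabilities(model, scores), outcomes

    def test_in_sample_ml_fit_recalibrates_to_identity(
        self, published_model, catalog
    ):
        """Slope 1 and CITL 0 within 1e-6 for an in-sample ML logistic fit."""
        predicted, outcomes = self._fit_and_predict(published_model, catalog, 500, 11)
        result = tc.calibration_metrics(predicted.to_numpy(), outcomes.to_numpy())
        assert result.slope == pytest.approx(1.0, abs=1e-6)
        assert result.citl == pytest.approx(0.0, abs=1e-6)
        assert sum(n for _, _, n in result.bins) == 500

    def test_halved_logits_recalibrate_to_slope_two(self):
        """Predictions built with logits halved relative to the generating
        model recover a slope of about 2."""
        rng = np.random.default_rng(7)
        lp = rng.normal(scale=2.0, size=20_000)
        outcomes = (rng.random(20_000) < 1 / (1 + np.exp(-lp))).astype(int)
        halved = 1 / (1 + np.exp(-lp / 2))
        result = tc.calibration_metrics(halved, outcomes)
        assert result.slope == pytest.approx(2.0, abs=0.1)

    def test_constant_predictions_rejected(self):
        with pytest.raises(tc.InvalidInputError):
            tc.calibration_metrics([0.4] * 20, [0, 1] * 10)

    def test_boundary_probabilities_rejected(self):
        with pytest.raises(tc.InvalidInputError):
            tc.calibration_metrics([0.0, 0.5, 0.9, 0.2], [0, 1, 1, 0])

    def test_small_bins_are_merged(self, rng):
        predicted = rng.uniform(0.05, 0.95, size=23)
        outcomes = (rng.random(23) < predicted).astype(int)
        outcomes[:2] = [0, 1]
        result = tc.calibration_metrics(predicted, outcomes, n_bins=10, min_bin=5)
        assert sum(n for _, _, n in result.bins) == 23
        assert all(n >= 5 for _, _, n in result.bins)


class TestPredictiveValues:
    def test_all_positive_labels_give_unit_ppv(self):
        table = tc.predictive_values([1, 2, 3], [1, 1, 1], thresholds=[2])
        t, ppv, npv, n_above, n_below = table.rows[0]
        assert ppv == 1.0 and n_above == 2

    def test_threshold_above_maximum_is_undefined_above(self):
        table = tc.predictive_values([1, 2, 3], [0, 1, 1], thresholds=[10])
        t, ppv, npv, n_above, n_below = table.rows[0]
        assert ppv is None and n_above == 0
        assert npv == pytest.approx(1 / 3)

    def test_hand_counted_contingency_tables(self):
        """Ten cases, three thresholds, confusion tables counted by hand."""
        scores = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        labels = [0, 0, 1, 0, 0, 1, 1, 0, 1, 1]
        table = tc.predictive_values(scores, labels, thresholds=[3, 6, 9])
        # t=3: above = scores 3..10 (8 cases, 5 positive); below = {1,2} both negative
        assert table.rows[0][1] == pytest.approx(5 / 8)
        assert table.rows[0][2] == pytest.approx(1.0)
        # t=6: above = 5 cases with 4 positive; below = 5 cases with 4 negative
        assert table.rows[1][1] == pytest.approx(4 / 5)
        assert table.rows[1][2] == pytest.approx(4 / 5)
        # t=9: above = {9,10} both positive; below = 8 cases with 5 negative
        assert table.rows[2][1] == pytest.approx(1.0)
        assert table.rows[2][2] == pytest.approx(5 / 8)

    def test_ppv_rises_and_npv_falls_with_threshold_under_mlr(self):
        """With scores drawn from a monotone-likelihood-ratio model, PPV is
        non-decreasing and NPV non-increasing in the threshold."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            lp = rng.normal(size=3000)
            labels = (rng.random(3000) < 1 / (1 + np.exp(-2 * lp))).astype(int)
            thresholds = np.quantile(lp, np.linspace(0.1, 0.9, 9))
            table = tc.predictive_values(lp, labels, thresholds)
            ppvs = [r[1] for r in table.rows]
            npvs = [r[2] for r in table.rows]
            assert all(b >= a - 0.02 for a, b in zip(ppvs, ppvs[1:]))
            assert all(b <= a + 0.02 for a, b in zip(npvs, npvs[1:]))

    def test_empty_thresholds_rejected(self):
        with pytest.raises(tc.InvalidInputError):
            tc.predictive_values([1.0], [1], thresholds=[])
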