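"""Outcome metrics: classification threshold, TST, confidence thresholds,
uncertainty and transition metrics, ROC selection, kappa, screening rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from cardiosleep.errors import ParameterError, ThresholdError
from cardiosleep.metrics import (
    ConfidenceThresholds, PatientSummary, auroc, classify_epochs, cohen_kappa,
    detect_osa, estimate_tst, evaluate, fit_confidence_thresholds,
    select_threshold_roc, summarize_patient, transition_metric,
    uncertainty_metrics,
)
from cardiosleep.model import PosteriorSeries


def series(p_wake, valid=None):
    p = np.asarray(p_wake, dtype=float)
    v = np.ones(len(p), dtype=bool) if valid is None else np.asarray(valid)
    p = p.copy()
    p[~v] = np.nan
    return PosteriorSeries(p_wake=p, valid=v)


class TestClassify:
    def test_boundary_half_goes_to_wake(self):
        labels = classify_epochs(series([0.5, 0.49, 0.51]))
        assert labels.tolist() == [1, 0, 1]

    def test_all_zero_posterior_is_all_sleep(self):
        assert classify_epochs(series([0.0] * 5)).tolist() == [0] * 5

    def test_invalid_epochs_get_sentinel(self):
        labels = classify_epochs(series([0.9, 0.9], valid=[True, False]))
        assert labels.tolist() == [1, -1]


class TestTst:
    def test_full_night_asleep(self):
        assert estimate_tst(np.zeros(960), np.ones(960, bool)) == 480.0

    def test_partial_sleep(self):
        labels = np.r_[np.zeros(400), np.ones(560)]
        assert estimate_tst(labels, np.ones(960, bool)) == 200.0

    def test_only_valid_epochs_counted_and_extrapolation(self):
        labels = np.zeros(100)
        valid = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        assert estimate_tst(labels, valid) == 25.0
        assert estimate_tst(labels, valid, extrapolate=True) == 50.0

    def test_perfect_predictor_recovers_reference_tst(self, rng):
        truth = (rng.random(700) < 0.2).astype(int)
        ref_tst = 0.5 * np.sum(truth == 0)
        assert estimate_tst(truth, np.ones(700, bool)) == ref_tst


class TestConfidenceThresholds:
    def test_fitted_from_pool_median_minus_sd(self, rng):
        pw = np.concatenate([rng.uniform(0.55, 1.0, 300),   # predicted wake
                             rng.uniform(0.0, 0.45, 700)])  # predicted sleep
        t = fit_confidence_thresholds(series(pw))
        wake = pw[pw >= 0.5]
        sleep = 1 - pw[pw < 0.5]
        assert t.t_w == pytest.approx(np.median(wake) - np.std(wake))
        assert t.t_s == pytest.approx(np.median(sleep) - np.std(sleep))

    def test_zero_spread_pool_gives_common_value(self):
        t = fit_confidence_thresholds(series([0.9] * 10 + [0.1] * 10))
        assert t.t_w == pytest.approx(0.9)
        assert t.t_s == pytest.approx(0.9)

    def test_empty_predicted_class_raises(self):
        with pytest.raises(ThresholdError):
            fit_confidence_thresholds(series([0.9] * 10))

    def test_thresholds_must_exceed_half(self):
        with pytest.raises(ThresholdError):
            ConfidenceThresholds(t_s=0.5, t_w=0.8)


class TestUncertainty:
    T = ConfidenceThresholds(t_s=0.81, t_w=0.63)

    def test_confident_sleep_night_has_no_uncertain_epochs(self):
        use, _ = uncertainty_metrics(series([0.01] * 50), self.T)
        assert use == 0.0

    def test_hand_enumerated_four_epochs(self):
        # p_wake 0.45 -> sleep with p_sleep 0.55 < 0.81 (uncertain sleep)
        # p_wake 0.55 -> wake with 0.55 < 0.63 (uncertain wake)
        use, uwe = uncertainty_metrics(series([0.10, 0.45, 0.55, 0.90]), self.T)
        assert use == 25.0
        assert uwe == 25.0

    def test_everything_confident_at_tight_thresholds(self):
        t = ConfidenceThresholds(t_s=0.501, t_w=0.501)
        use, uwe = uncertainty_metrics(series([0.1, 0.9, 0.2, 0.8]), t)
        assert use == 0.0 and uwe == 0.0

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_percentages_bounded_and_disjoint(self, seed):
        r = np.random.default_rng(seed)
        p = series(r.random(40))
        t = ConfidenceThresholds(t_s=r.uniform(0.51, 1.0), t_w=r.uniform(0.51, 1.0))
        use, uwe = uncertainty_metrics(p, t)
        assert 0.0 <= use <= 100.0 and 0.0 <= uwe <= 100.0
        assert use + uwe <= 100.0


class TestTransitions:
    def test_hand_counted_sequence(self):
        assert transition_metric([0, 0, 1, 1, 0], np.ones(5, bool)) == 40.0

    def test_constant_labels(self):
        assert transition_metric([1] * 10, np.ones(10, bool)) == 0.0

    def test_alternating_worst_case(self):
        n = 9
        labels = [i % 2 for i in range(n)]
        assert transition_metric(labels, np.ones(n, bool)) == pytest.approx(
            100.0 * (n - 1) / n)

    def test_invalid_epochs_removed_before_pairing(self):
        # removing the invalid middle epoch joins 0|0: no transition there,
        # leaving one flip among the four remaining epochs
        labels = np.array([0, 1, 0, 1, 1])
        valid = np.array([True, False, True, True, True])
        assert transition_metric(labels, valid) == pytest.approx(100.0 * 1 / 4)

    def test_invariant_to_relabeling(self, rng):
        labels = (rng.random(200) < 0.4).astype(int)
        valid = rng.random(200) < 0.9
        assert transition_metric(labels, valid) == transition_metric(1 - labels, valid)


class TestDetect:
    def _summary(self, use, swt):
        return PatientSummary("p", 300.0, 310.0, use, 10.0, swt, 900, 960)

    @pytest.mark.parametrize("use, swt, expected", [
        (65.0, 10.0, True),    # uncertainty alone triggers
        (64.0, 24.0, False),   # boundary equality is negative ("exceeds")
        (10.0, 30.0, True),    # transitions alone trigger
        (10.0, 10.0, False),
    ])
    def test_rule_cases(self, use, swt, expected):
        assert detect_osa(self._summary(use, swt)) is expected

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0, 100), st.floats(0, 100), st.floats(0, 30), st.floats(0, 30))
    def test_monotone_in_both_metrics(self, use, swt, du, dswt):
        lo = detect_osa(self._summary(use, swt))
        hi = detect_osa(self._summary(min(use + du, 100.0), min(swt + dswt, 100.0)))
        assert hi or not lo


class TestRoc:
    def test_perfect_separation(self):
        sel = select_threshold_roc([1, 2, 3, 40, 50, 60], [0, 0, 0, 1, 1, 1])
        assert sel.auroc == 1.0
        assert sel.sensitivity == 1.0 and sel.specificity == 1.0
        assert 3 < sel.threshold < 40

    def test_four_patient_toy_enumeration(self):
        sel = select_threshold_roc([10, 20, 70, 80], [0, 0, 1, 1],
                                   min_specificity=0.95)
        assert 20 < sel.threshold < 70
        assert sel.sensitivity == 1.0 and sel.specificity == 1.0
        assert sel.specificity_floor_met

    def test_label_shuffled_distributions_give_chance_auroc(self, rng):
        v = rng.normal(size=200)
        y = rng.permutation([0] * 100 + [1] * 100)
        assert abs(auroc(v, y) - 0.5) < 0.1

    def test_unreachable_floor_flagged(self):
        # overlapping groups: no threshold reaches specificity 1.0
        sel = select_threshold_roc([1, 2, 3, 2, 3, 4], [0, 0, 0, 1, 1, 1],
                                   min_specificity=1.01)
        assert not sel.specificity_floor_met

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            select_threshold_roc([1, 2], [1, 1])

    def test_auroc_matches_sklearn_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            v = rng.normal(size=n)
            y = rng.integers(0, 2, size=n)
            if y.all() or not y.any():
                continue
            assert auroc(v, y) == pytest.approx(roc_auc_score(y, v), abs=1e-12)


class TestKappa:
    def test_balanced_confusion_matrix_value(self):
        # confusion matrix [[40,10],[10,40]]: po=0.8, pe=0.5 -> kappa 0.6
        y_true = np.r_[np.zeros(50), np.ones(50)]
        y_pred = np.r_[np.zeros(40), np.ones(10), np.zeros(10), np.ones(40)]
        assert cohen_kappa(y_true, y_pred) == pytest.approx(0.6)

    def test_perfect_agreement(self):
        assert cohen_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_matches_sklearn_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 80))
            a = rng.integers(0, 2, size=n)
            b = rng.integers(0, 2, size=n)
            assert cohen_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12)

    def test_chance_level_labels_give_near_zero_kappa(self, rng):
        a = rng.random(10_000) < 0.3
        b = rng.random(10_000) < 0.3
        assert abs(cohen_kappa(a, b)) < 0.05


class TestEvaluate:
    def test_tst_bias_and_rho(self):
        est = np.array([400.0, 350.0, 300.0, 410.0])
        ref = np.array([420.0, 360.0, 310.0, 400.0])
        rep = evaluate(tst_est=est, tst_ref=ref)
        assert rep.tst_bias_mean_min == pytest.approx(np.mean(est - ref))
        assert rep.tst_bias_sd_min == pytest.approx(np.std(est - ref, ddof=1))
        assert -1.0 <= rep.pearson_rho <= 1.0

    def test_constant_tst_vector_rejected(self):
        with pytest.raises(ParameterError):
            evaluate(tst_est=np.full(4, 300.0), tst_ref=np.arange(4.0))

    def test_detection_block(self):
        rep = evaluate(detect_pred=[True, True, False, False],
                       detect_true=[True, False, False, False],
                       detect_scores=[80.0, 70.0, 10.0, 20.0])
        assert rep.sensitivity == 1.0
        assert rep.specificity == pytest.approx(2 / 3)
        assert rep.accuracy == 0.75
        assert rep.auroc == 1.0


def test_summarize_patient_consistency():
    p = series([0.1, 0.2, 0.6, 0.4, 0.9, 0.05])
    t = ConfidenceThresholds(t_s=0.81, t_w=0.63)
    s = summarize_patient(p, t, patient_id="x")
    assert s.n_valid_epochs == 6
    assert s.tst_min == 0.5 * 4
    use, uwe = uncertainty_metrics(p, t)
    assert (s.pct_use, s.pct_uwe) == (use, uwe)
    assert s.pct_swt == transition_metric(classify_epochs(p), p.valid)
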