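import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ftirscreen as fs
from ftirscreen.consensus_predict import consensus_call, recall_at

from conftest import make_prediction


class TestConsensusRule:
    @pytest.mark.parametrize(
        "fracs,theta,expected",
        [
            ((0.9, 0.8, 0.2), 0.5, "positive"),   # 2 of 3 positive
            ((0.1, 0.2, 0.3), 0.5, "negative"),   # unanimous negative
            ((0.9, 0.1, 0.1), 0.5, "negative"),   # 2 of 3 negative
            ((0.1, 0.2, 0.3), 0.0, "positive"),   # theta=0: all replicates vote in
            ((0.6, 0.4), 0.5, "positive"),        # even count, tie breaks positive
        ],
    )
    def test_majority_calls(self, fracs, theta, expected):
        _, call = consensus_call(np.asarray(fracs), theta)
        assert call == expected

    def test_consensus_score_is_median_for_triplicates(self):
        p = make_prediction("P1", (0.9, 0.3, 0.6))
        assert p.consensus_score == 0.6
        assert p.patient_score == pytest.approx(0.6)

    def test_recall_at_changes_only_threshold(self):
        preds = [make_prediction("P1", (0.4, 0.5, 0.6))]
        low = recall_at(preds, 0.3)[0]
        high = recall_at(preds, 0.9)[0]
        assert low.call == "positive" and high.call == "negative"
        assert low.patient_score == high.patient_score


class TestPredictPatient:
    def test_vote_fractions_and_determinism(self, small_ensemble, small_cohort):
        rec = small_cohort.patients[0]
        a = fs.predict_patient(small_ensemble, rec, theta=0.5)
        b = fs.predict_patient(small_ensemble, rec, theta=0.5)
        assert len(a.replicate_votes) == 3
        assert all(0.0 <= v.vote_fraction <= 1.0 for v in a.replicate_votes)
        assert a.call == b.call
        assert [v.vote_fraction for v in a.replicate_votes] == [
            v.vote_fraction for v in b.replicate_votes
        ]

    def test_grid_mismatch_rejected(self, small_ensemble):
        wrong = fs.default_grid(3000.0, 600.0, 500)
        rec = fs.PatientRecord(
            "PX", "unknown",
            [fs.Spectrum(wrong, np.ones(500) + np.sin(np.linspace(0, 9, 500)))],
        )
        with pytest.raises(ValueError, match="grid"):
            fs.predict_patient(small_ensemble, rec, theta=0.5)

    def test_invalid_theta_rejected(self, small_ensemble, small_cohort):
        with pytest.raises(ValueError):
            fs.predict_patient(small_ensemble, small_cohort.patients[0], theta=1.5)


class TestRoc:
    def test_perfect_separation_auc_one(self):
        scores = [0.9, 0.8, 0.7, 0.2, 0.1]
        labels = [1, 1, 1, 0, 0]
        roc = fs.roc_from_scores(scores, labels)
        assert roc.auc == pytest.approx(1.0)

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(12)
        scores = rng.uniform(0, 1, 100)
        labels = rng.permutation([1] * 50 + [0] * 50)
        roc = fs.roc_from_scores(scores, labels)
        assert abs(roc.auc - 0.5) < 0.1

    def test_auc_equals_pair_counting_oracle(self):
        """Trapezoidal staircase AUC == Mann-Whitney pair counting, ties
        counted one half, on every random score vector (with ties)."""
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            labels = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
            # quantized scores to force ties
            scores = rng.integers(0, 6, size=n) / 5.0
            roc = fs.roc_from_scores(scores, labels)
            assert roc.auc == pytest.approx(
                fs.mannwhitney_auc(scores, labels), abs=1e-12
            )

    def test_patient_roc_equals_median_score_roc(self):
        """The consensus-rule theta sweep is the staircase of the median
        replicate vote fraction."""
        rng = np.random.default_rng(14)
        preds, labels = [], {}
        for i in range(40):
            pid = f"P{i}"
            preds.append(make_prediction(pid, rng.integers(0, 11, size=3) / 10.0))
            labels[pid] = "positive" if i % 2 else "negative"
        roc = fs.roc_curve(preds, labels)
        med = [p.consensus_score for p in preds]
        y = [1 if labels[p.patient_id] == "positive" else 0 for p in preds]
        assert roc.auc == pytest.approx(fs.mannwhitney_auc(med, y), abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        scores=st.lists(st.integers(0, 10), min_size=4, max_size=40),
        labels=st.data(),
    )
    def test_auc_pair_counting_property(self, scores, labels):
        y = labels.draw(
            st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
        )
        if min(y) == max(y):
            y[0] = 1 - y[0]
        s = np.asarray(scores) / 10.0
        roc = fs.roc_from_scores(s, y)
        assert roc.auc == pytest.approx(fs.mannwhitney_auc(s, y), abs=1e-12)

    def test_staircase_monotone(self):
        rng = np.random.default_rng(15)
        scores = rng.uniform(0, 1, 30)
        labels = rng.integers(0, 2, 30)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        roc = fs.roc_from_scores(scores, labels)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fs.roc_from_scores([0.1, 0.9], [1, 1])
        preds = [make_prediction("P1", (0.5, 0.5, 0.5))]
        with pytest.raises(ValueError):
            fs.roc_curve(preds, {"P1": "positive"})


class TestOperatingPoints:
    def _predictions(self, rng, n=40, gap=None, sd=0.15):
        """Moderately separated vote fractions (overlapping classes),
        the regime an informative ensemble produces."""
        preds, labels = [], {}
        for i in range(n):
            pid = f"P{i}"
            pos = i % 2 == 1
            if gap is not None:
                base, sd = (0.8 if pos else 0.2), 0.05
            else:
                base = 0.65 if pos else 0.35
            fracs = np.clip(base + rng.normal(0, sd, 3), 0, 1)
            preds.append(make_prediction(pid, fracs))
            labels[pid] = "positive" if pos else "negative"
        return preds, labels

    def test_clean_gap_modes_coincide(self):
        rng = np.random.default_rng(20)
        preds, labels = self._predictions(rng, gap=True)
        sens = fs.tune_operating_point(preds, labels, "sensitivity_tuned", 0.0)
        spec = fs.tune_operating_point(preds, labels, "specificity_tuned", 0.0)
        # perfectly separable: both achieve TPR=1, FPR=0 inside the gap
        assert sens.tpr == 1.0 and sens.fpr == 0.0
        assert spec.tpr == 1.0 and spec.fpr == 0.0

    def test_unconstrained_sensitivity_gives_tpr_one(self):
        rng = np.random.default_rng(21)
        preds, labels = self._predictions(rng)
        op = fs.tune_operating_point(preds, labels, "sensitivity_tuned", 1.0)
        assert op.tpr == 1.0
        assert op.feasible

    def test_infeasible_constraint_flagged(self):
        preds = [
            make_prediction("P1", (0.9, 0.9, 0.9)),
            make_prediction("P2", (0.9, 0.9, 0.9)),
        ]
        labels = {"P1": "positive", "P2": "negative"}
        op = fs.tune_operating_point(preds, labels, "specificity_tuned", 0.0)
        # identical scores: FNR=0 requires calling both positive -> FPR=1
        assert not op.feasible or op.fpr == 1.0

    def test_sensitivity_mode_at_least_as_sensitive_as_balanced(self):
        for seed in range(5):
            rng = np.random.default_rng(30 + seed)
            preds, labels = self._predictions(rng, n=60)
            sens = fs.tune_operating_point(preds, labels, "sensitivity_tuned", 0.45)
            bal = fs.tune_operating_point(preds, labels, "balanced", 0.45)
            assert sens.tpr >= bal.tpr

    def test_theta_frozen_deterministic(self):
        rng = np.random.default_rng(22)
        preds, labels = self._predictions(rng)
        a = fs.tune_operating_point(preds, labels, "sensitivity_tuned", 0.45)
        b = fs.tune_operating_point(preds, labels, "sensitivity_tuned", 0.45)
        assert a.theta == b.theta

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            fs.tune_operating_point([], {}, "magic")
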