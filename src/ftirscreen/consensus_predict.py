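"""Replicate-consensus prediction, patient-level ROC and operating points.

Each of a patient's replicate spectra is preprocessed independently and
scored by every ensemble member; a replicate's *vote fraction* is the
fraction of the 100 models calling it positive.  A replicate is called
positive when its vote fraction reaches the decision threshold theta, and
the patient is called positive when a majority of replicates are — for
triplicates, two or more (ties on even replicate counts break positive:
a screening test prefers the sensitive error).

Sweeping theta over the observed vote fractions traces a patient-level
ROC staircase; under the majority rule the patient call at theta equals
thresholding the patient's median replicate vote fraction, so the
staircase AUC coincides with the Mann-Whitney pair-counting statistic on
those consensus scores (ties counted one half).

Operating points:

* ``sensitivity_tuned`` — smallest theta maximizing TPR subject to
  FPR <= constraint (default 0.45);
* ``specificity_tuned`` — largest theta maximizing TNR subject to
  FNR <= constraint;
* ``balanced`` — Youden-J maximizer.

Thresholds are tuned on cross-validated training predictions only and
frozen before the test set is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .mc_ga_lda import Ensemble, GAConfig, McConfig, train_ensemble
from .preprocess import PreprocConfig, preprocess_spectrum
from .spectra_io import PatientRecord, SpectralDataset

MODES = ("sensitivity_tuned", "specificity_tuned", "balanced")
DEFAULT_CONSTRAINT = 0.45


@dataclass
class ReplicateVote:
    replicate_id: str
    vote_fraction: float
    call: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if not 0.0 <= self.vote_fraction <= 1.0:
            raise ValueError("vote_fraction must be in [0, 1]")


@dataclass
class PatientPrediction:
    patient_id: str
    replicate_votes: list
    patient_score: float  # mean replicate vote fraction
    call: str
    theta: float

    @property
    def consensus_score(self) -> float:
        """The threshold-equivalent patient score: the m-th largest
        replicate vote fraction, where m votes make a positive majority
        (the median, for triplicates)."""
        fracs = sorted((v.vote_fraction for v in self.replicate_votes), reverse=True)
        m = _majority_count(len(fracs))
        return fracs[m - 1]


def _majority_count(n_replicates: int) -> int:
    """Positive calls needed for a positive patient; even counts tie
    toward positive (n/2 suffices)."""
    if n_replicates % 2 == 1:
        return n_replicates // 2 + 1
    return max(1, n_replicates // 2)


def replicate_vote_fractions(ensemble: Ensemble, record: PatientRecord) -> np.ndarray:
    """Vote fraction per replicate, after per-replicate preprocessing
    with the ensemble's stored configuration."""
    if not record.replicates:
        raise ValueError(f"patient {record.patient_id} has no replicates")
    fracs = []
    for s in record.replicates:
        proc = preprocess_spectrum(s, ensemble.preproc)
        if proc.grid.n_points != ensemble.wavenumbers.size or not np.allclose(
            proc.grid.values, ensemble.wavenumbers, atol=1e-6, rtol=0.0
        ):
            raise ValueError(
                f"patient {record.patient_id}: preprocessed grid does not match "
                "the ensemble's training grid"
            )
        fracs.append(float(ensemble.vote_fractions(proc.absorbance)[0]))
    return np.asarray(fracs)


def consensus_call(vote_fracs: np.ndarray, theta: float) -> tuple:
    """(replicate calls, patient call) at threshold theta."""
    calls = vote_fracs >= theta
    positive = int(calls.sum()) >= _majority_count(vote_fracs.size)
    return calls, ("positive" if positive else "negative")


def predict_patient(
    ensemble: Ensemble, record: PatientRecord, theta: float = 0.5
) -> PatientPrediction:
    """Replicate-consensus prediction for one patient."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    fracs = replicate_vote_fractions(ensemble, record)
    calls, patient_call = consensus_call(fracs, theta)
    votes = [
        ReplicateVote(f"{record.patient_id}.r{i}", float(f),
                      "positive" if c else "negative")
        for i, (f, c) in enumerate(zip(fracs, calls))
    ]
    return PatientPrediction(
        record.patient_id, votes, float(fracs.mean()), patient_call, theta
    )


def predict_dataset(
    ensemble: Ensemble, dataset: SpectralDataset, theta: float = 0.5
) -> list:
    return [predict_patient(ensemble, p, theta) for p in dataset.patients]


def recall_at(predictions: list, theta: float) -> list:
    """Re-derive every patient call at a new theta from the stored vote
    fractions (no re-scoring of spectra)."""
    out = []
    for p in predictions:
        fracs = np.array([v.vote_fraction for v in p.replicate_votes])
        calls, patient_call = consensus_call(fracs, theta)
        votes = [
            replace(v, call="positive" if c else "negative")
            for v, c in zip(p.replicate_votes, calls)
        ]
        out.append(
            PatientPrediction(p.patient_id, votes, p.patient_score, patient_call, theta)
        )
    return out


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_from_scores(scores, labels) -> RocCurve:
    """ROC staircase from a patient-level score vector.

    Thresholds sweep the sorted set of observed scores union {0, 1}
    (plus an anchor above the maximum so the curve starts at (0, 0));
    a patient is called positive when score >= theta.  AUC by the
    trapezoidal rule — with ties credited one half, this equals the
    Mann-Whitney pair-counting statistic.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one patient per class")

    thetas = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    thetas = np.concatenate([[np.inf], thetas[::-1]])  # descending, (0,0) anchor
    fpr, tpr = [], []
    for th in thetas:
        calls = scores >= th
        tpr.append(float((calls & (y == 1)).sum()) / n_pos)
        fpr.append(float((calls & (y == 0)).sum()) / n_neg)
    fpr, tpr = np.asarray(fpr), np.asarray(tpr)
    if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
        raise AssertionError("ROC staircase is not monotone")
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr, tpr, thetas, auc)


def roc_curve(predictions: list, labels: dict) -> RocCurve:
    """Patient-level ROC: calls are recomputed by the full consensus rule
    at each theta in the sorted set of observed replicate vote fractions
    union {0, 1}."""
    y = np.array(
        [1 if labels[p.patient_id] == "positive" else 0 for p in predictions]
    )
    if y.size == 0 or y.min() == y.max():
        raise ValueError("ROC requires at least one patient per class")
    all_fracs = np.concatenate(
        [[v.vote_fraction for v in p.replicate_votes] for p in predictions]
    )
    thetas = np.unique(np.concatenate([all_fracs, [0.0, 1.0]]))
    thetas = np.concatenate([[np.inf], thetas[::-1]])

    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    fpr, tpr = [], []
    for th in thetas:
        calls = np.array(
            [
                consensus_call(
                    np.array([v.vote_fraction for v in p.replicate_votes]), th
                )[1]
                == "positive"
                for p in predictions
            ]
        )
        tpr.append(float((calls & (y == 1)).sum()) / n_pos)
        fpr.append(float((calls & (y == 0)).sum()) / n_neg)
    fpr, tpr = np.asarray(fpr), np.asarray(tpr)
    if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
        raise AssertionError("ROC staircase is not monotone")
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr, tpr, thetas, auc)


def mannwhitney_auc(scores, labels) -> float:
    """Pair-counting AUC: fraction of (positive, negative) pairs ranked
    correctly, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = scores[y == 1], scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes")
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (pos.size * neg.size)


# ---------------------------------------------------------------------------
# Operating points
# ---------------------------------------------------------------------------

@dataclass
class OperatingPoint:
    theta: float
    mode: str
    constraint: float
    tpr: float  # on the tuning predictions
    fpr: float
    feasible: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")


def tune_operating_point(
    predictions: list,
    labels: dict,
    mode: str = "balanced",
    constraint: float = DEFAULT_CONSTRAINT,
) -> OperatingPoint:
    """Choose a decision threshold on (cross-validated) training
    predictions; frozen before any test-set evaluation.

    Infeasible constraints yield the closest feasible point with
    ``feasible=False``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    roc = roc_curve(predictions, labels)
    # drop the synthetic (0,0) anchor; candidate thetas stay in [0, 1]
    cand = [
        (float(min(th, 1.0)), t, f)
        for th, t, f in zip(roc.thresholds, roc.tpr, roc.fpr)
        if np.isfinite(th)
    ]

    feasible = True
    if mode == "sensitivity_tuned":
        ok = [c for c in cand if c[2] <= constraint]
        if not ok:
            feasible = False
            best_fpr = min(c[2] for c in cand)
            ok = [c for c in cand if c[2] == best_fpr]
        best_tpr = max(c[1] for c in ok)
        theta, tpr, fpr = min(c for c in ok if c[1] == best_tpr)
    elif mode == "specificity_tuned":
        ok = [c for c in cand if 1.0 - c[1] <= constraint]
        if not ok:
            feasible = False
            best_fnr = min(1.0 - c[1] for c in cand)
            ok = [c for c in cand if 1.0 - c[1] == best_fnr]
        best_tnr = max(1.0 - c[2] for c in ok)
        theta, tpr, fpr = max(c for c in ok if 1.0 - c[2] == best_tnr)
    else:  # balanced: Youden J, ties toward the larger theta
        best_j = max(c[1] - c[2] for c in cand)
        theta, tpr, fpr = max(c for c in cand if c[1] - c[2] == best_j)

    return OperatingPoint(theta, mode, constraint, tpr, fpr, feasible)


# ---------------------------------------------------------------------------
# Cross-validated tuning predictions
# ---------------------------------------------------------------------------

def cross_validated_predictions(
    train_dataset: SpectralDataset,
    preproc_cfg: PreprocConfig,
    ga_cfg: GAConfig,
    mc_cfg: McConfig,
    n_folds: int = 5,
    seed: int = 0,
) -> list:
    """Stratified k-fold over training patients: a fresh ensemble per
    fold predicts its held-out patients, yielding unbiased training-side
    predictions for threshold tuning."""
    by_class: dict[str, list] = {}
    for p in train_dataset.patients:
        by_class.setdefault(p.label, []).append(p.patient_id)
    if len(by_class) < 2:
        raise ValueError("cross-validation needs both classes")
    min_class = min(len(v) for v in by_class.values())
    n_folds = min(n_folds, min_class)
    if n_folds < 2:
        raise ValueError("not enough patients per class for cross-validation")

    rng = np.random.default_rng(seed)
    folds: list[list] = [[] for _ in range(n_folds)]
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        perm = rng.permutation(len(ids))
        for j, i in enumerate(perm):
            folds[j % n_folds].append(ids[i])

    predictions = []
    for f, held_out in enumerate(folds):
        held = set(held_out)
        fold_train = train_dataset.subset(
            [p.patient_id for p in train_dataset.patients if p.patient_id not in held]
        )
        fold_mc = replace(mc_cfg, seed=int(rng.integers(0, 2**31)))
        ens = train_ensemble(fold_train, preproc_cfg, ga_cfg, fold_mc,
                             quarantined_ids=held)
        for pid in sorted(held):
            rec = next(p for p in train_dataset.patients if p.patient_id == pid)
            predictions.append(predict_patient(ens, rec, theta=0.5))
    return predictions
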