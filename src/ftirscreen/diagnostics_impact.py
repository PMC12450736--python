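"""Diagnostic metric panel and screening-impact arithmetic.

``compute_metrics`` turns a test-set confusion matrix into the standard
panel (sensitivity, specificity, accuracy, PPV, NPV, F1), reporting each
at full precision alongside a round-half-up integer percent; ratios with
a zero denominator are reported as absent rather than zero.

``screening_impact`` projects a tuned test onto a screening population:
given cohort size n, disease prevalence, the test's sensitivity and
specificity and the cost of the confirmatory scan, it computes expected
TP/FP/TN/FN counts (each rounded half-up independently), the number of
patients flagged for confirmatory imaging, the referral reduction versus
scanning everyone, and the resulting cost saving.  For a symptomatic
population of 1,000 at 30 % prevalence and a 93 %-sensitive /
57 %-specific test this yields 580 flagged, a 42 % referral reduction,
301 false positives, 21 false negatives and a saving of 420 scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def percent(x: float | None) -> int | None:
    """Round-half-up integer percent, or None for an undefined ratio."""
    return None if x is None else _round_half_up(100.0 * x)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, predictions, labels: dict) -> "ConfusionMatrix":
        tp = fp = tn = fn = 0
        for p in predictions:
            truth = labels[p.patient_id]
            if truth == "positive":
                tp += p.call == "positive"
                fn += p.call == "negative"
            elif truth == "negative":
                tn += p.call == "negative"
                fp += p.call == "positive"
        return cls(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


@dataclass
class DiagnosticReport:
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    auc: float | None = None

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv", "f1"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_percent(self) -> dict:
        return {
            name: percent(getattr(self, name))
            for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv", "f1")
        }

    def to_dict(self) -> dict:
        d = {
            name: getattr(self, name)
            for name in ("sensitivity", "specificity", "accuracy",
                         "ppv", "npv", "f1", "auc")
        }
        d["percent"] = self.as_percent()
        return d


def f1_score(sensitivity: float, ppv: float) -> float | None:
    """Harmonic mean of sensitivity (recall) and PPV (precision)."""
    if sensitivity is None or ppv is None or sensitivity + ppv == 0.0:
        return None
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def compute_metrics(cm: ConfusionMatrix, auc: float | None = None) -> DiagnosticReport:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    acc = _ratio(cm.tp + cm.tn, cm.total)
    f1 = None if (sens is None or ppv is None) else f1_score(sens, ppv)
    return DiagnosticReport(sens, spec, acc, ppv, npv, f1, auc)


# ---------------------------------------------------------------------------
# Screening impact
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreeningScenario:
    n: int
    prevalence: float
    sensitivity: float
    specificity: float
    cost_per_scan: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.cost_per_scan < 0:
            raise ValueError("cost_per_scan must be >= 0")
        for name in ("prevalence", "sensitivity", "specificity"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class ImpactReport:
    tp: int
    fp: int
    tn: int
    fn: int
    flagged: int
    referral_reduction: float
    savings: float
    residual: int  # (tp+fp+tn+fn) - n, from independent rounding
    scenario: ScreeningScenario

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "flagged": self.flagged,
            "referral_reduction": self.referral_reduction,
            "referral_reduction_percent": percent(self.referral_reduction),
            "savings": self.savings,
            "residual": self.residual,
            "scenario": {
                "n": self.scenario.n,
                "prevalence": self.scenario.prevalence,
                "sensitivity": self.scenario.sensitivity,
                "specificity": self.scenario.specificity,
                "cost_per_scan": self.scenario.cost_per_scan,
            },
        }


def screening_impact(sc: ScreeningScenario) -> ImpactReport:
    """Expected screening outcome for a tuned test on a population.

    Each expected count is rounded half-up independently (the residual
    against n, at most one patient, is reported).  Flagged patients
    (TP + FP) proceed to confirmatory imaging; everyone else is spared a
    scan, which is where the referral reduction and savings come from.
    """
    n, prev = sc.n, sc.prevalence
    tp = _round_half_up(n * prev * sc.sensitivity)
    fn = _round_half_up(n * prev * (1.0 - sc.sensitivity))
    fp = _round_half_up(n * (1.0 - prev) * (1.0 - sc.specificity))
    tn = _round_half_up(n * (1.0 - prev) * sc.specificity)
    flagged = tp + fp
    if flagged > n:
        raise ValueError("flagged exceeds cohort size")
    reduction = 0.0 if n == 0 else (n - flagged) / n
    savings = (n - flagged) * sc.cost_per_scan
    return ImpactReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        flagged=flagged,
        referral_reduction=reduction,
        savings=savings,
        residual=(tp + fp + tn + fn) - n,
        scenario=sc,
    )
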