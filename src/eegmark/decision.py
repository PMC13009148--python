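"""Clinical allocation outcomes from classifier performance.

Scenario: predicted SSRI responders receive the SSRI (and respond at the
positive predictive value of the marker); predicted non-responders receive
an alternative (SNRI) with a 50% response rate, against a 50% unselected
SSRI baseline.  Outputs: overall response rate, improvement over baseline in
percentage points, number needed to treat NNT = 1/improvement, PPV/NPV, and
the normalized PPV (nPPV = PPV / baseline response rate).

All arithmetic is exact (rational) internally; reports round NNT to two
decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from eegmark.evaluation import ConfusionMatrix

__all__ = [
    "DecisionScenario", "DecisionOutcome", "matrix_metrics",
    "allocation_from_matrix", "allocation_from_accuracy", "scenario_table",
]


@dataclass(frozen=True)
class DecisionScenario:
    matrix: ConfusionMatrix | None = None
    baseline_response: Fraction = Fraction(1, 2)   # unselected SSRI
    alternative_response: Fraction = Fraction(1, 2)  # SNRI for predicted NR

    def __post_init__(self) -> None:
        for r in (self.baseline_response, self.alternative_response):
            if not 0 <= r <= 1:
                raise ValueError("response rates must lie in [0, 1]")


@dataclass
class DecisionOutcome:
    """All rates as exact fractions of 1; None marks undefined quantities."""

    sensitivity: Fraction | None = None
    specificity: Fraction | None = None
    ppv: Fraction | None = None
    npv: Fraction | None = None
    accuracy: Fraction | None = None
    response_rate: Fraction | None = None
    improvement: Fraction | None = None      # percentage points / 100
    nnt: Fraction | None = None
    nppv: Fraction | None = None             # may exceed 1

    def as_percent(self, name: str, digits: int = 2) -> float | None:
        v = getattr(self, name)
        return None if v is None else round(float(v) * 100.0, digits)


def matrix_metrics(m: ConfusionMatrix) -> DecisionOutcome:
    """Sensitivity, specificity, PPV, NPV and accuracy as exact fractions.

    A metric whose denominator is zero is reported as None (undefined).
    """

    def frac(num: int, den: int) -> Fraction | None:
        return Fraction(num, den) if den > 0 else None

    return DecisionOutcome(
        sensitivity=frac(m.tp, m.tp + m.fn),
        specificity=frac(m.tn, m.tn + m.fp),
        ppv=frac(m.tp, m.tp + m.fp),
        npv=frac(m.tn, m.tn + m.fn),
        accuracy=frac(m.tp + m.tn, m.total),
    )


def allocation_from_matrix(s: DecisionScenario) -> DecisionOutcome:
    """Allocation outcome of a confusion-matrix scenario.

    Predicted positives (TP+FP) receive the SSRI: the TP respond.  Predicted
    negatives (TN+FN) receive the alternative and respond at its rate.
    """
    m = s.matrix
    if m is None or m.total == 0:
        raise ValueError("scenario requires a non-empty confusion matrix")
    out = matrix_metrics(m)
    out.response_rate = (m.tp + s.alternative_response * (m.tn + m.fn)) / Fraction(
        m.total)
    out.improvement = out.response_rate - s.baseline_response
    out.nnt = 1 / out.improvement if out.improvement > 0 else None
    if out.ppv is not None and s.baseline_response > 0:
        out.nppv = out.ppv / s.baseline_response
    return out


def allocation_from_accuracy(accuracy, s: DecisionScenario = DecisionScenario()
                             ) -> DecisionOutcome:
    """Parametric allocation outcome on a balanced cohort.

    With accuracy ``a`` and 50% prevalence: a/2 of all patients are correctly
    identified responders (and all respond on the SSRI); the remaining
    1 - a/2 receive the alternative.  Hence response rate = a/2 + alt*(1-a/2);
    with both baselines at 1/2 this is 1/2 + a/4, improvement a/4, NNT 4/a.
    """
    a = Fraction(accuracy).limit_denominator(10**6)
    if not 0 < a <= 1:
        raise ValueError("accuracy must lie in (0, 1]")
    identified = a / 2
    out = DecisionOutcome(accuracy=a)
    out.response_rate = identified + s.alternative_response * (1 - identified)
    out.improvement = out.response_rate - s.baseline_response
    out.nnt = 1 / out.improvement if out.improvement > 0 else None
    return out


def scenario_table(accuracies=(Fraction(7, 10), Fraction(3, 4), Fraction(4, 5)),
                   matrices: list[ConfusionMatrix] | None = None,
                   s: DecisionScenario = DecisionScenario()) -> pd.DataFrame:
    """One column per scenario, one row per reported metric (in percent;
    NNT in patients, rounded to 2 decimals).

    Parametric rows come from :func:`allocation_from_accuracy`; matrix rows
    (sensitivity ... nPPV) are appended for any supplied confusion matrices.
    The 'nPPV (as printed)' row emits the accuracy/0.6 sequence sometimes
    quoted for these scenarios, which does not follow from the PPV/baseline
    definition; it is included only for side-by-side comparison.
    """
    cols = {}
    for a in accuracies:
        out = allocation_from_accuracy(a, s)
        af = Fraction(a).limit_denominator(10**6)
        col = {
            "Accuracy": out.as_percent("accuracy"),
            "SSRI Responders Identified": out.as_percent("accuracy") / 2,
            "SSRI Non-Responders Identified": 100 - out.as_percent("accuracy") / 2,
            "SNRI Responders": float(s.alternative_response
                                     * (1 - af / 2)) * 100,
            "Total Response Rate": out.as_percent("response_rate"),
            "Improvement Over Baseline": out.as_percent("improvement"),
            "NNT": round(float(out.nnt), 2) if out.nnt is not None else None,
            "nPPV (as printed)": round(float(af / Fraction(3, 5)) * 100, 2),
        }
        cols[f"Accuracy {out.as_percent('accuracy'):g}%"] = col
    for m in matrices or []:
        out = allocation_from_matrix(DecisionScenario(
            matrix=m, baseline_response=s.baseline_response,
            alternative_response=s.alternative_response))
        cols[f"Matrix tp={m.tp},fp={m.fp},tn={m.tn},fn={m.fn}"] = {
            "Accuracy": out.as_percent("accuracy"),
            "Sensitivity": out.as_percent("sensitivity"),
            "Specificity": out.as_percent("specificity"),
            "PPV": out.as_percent("ppv"),
            "NPV": out.as_percent("npv"),
            "Total Response Rate": out.as_percent("response_rate"),
            "Improvement Over Baseline": out.as_percent("improvement"),
            "NNT": round(float(out.nnt), 2) if out.nnt is not None else None,
            "nPPV": out.as_percent("nppv"),
        }
    return pd.DataFrame(cols)
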