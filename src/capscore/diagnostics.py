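"""Diagnostic-accuracy evaluation of a severity criterion against an outcome.

Severity classifications are cross-tabulated against the six-week outcome
(death, or the death/ICU composite) into a 2×2 table; records excluded by the
missing-data bounds rule are dropped first and counted separately.  The four
standard accuracy metrics are reported with 95% confidence intervals.

The default interval is the Wilson score interval with continuity
correction (Newcombe's method 4): for successes *s* out of *n* with
:math:`\\hat p = s/n` and normal quantile *z*,

.. math::

    L, U = \\frac{2n\\hat p + z^2 \\mp 1 \\mp
        z\\sqrt{z^2 \\mp 2 - 1/n + 4\\hat p (n(1-\\hat p) \\pm 1)}}
        {2(n + z^2)}

clipped to [0, 1], with L = 0 when s = 0 and U = 1 when s = n.  Plain
Wilson and Clopper–Pearson intervals are available for sensitivity analysis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from scipy.stats import beta, norm

from .records import PatientRecord
from .scoring import ScoreResult, Severity

__all__ = [
    "OutcomeKind",
    "CiMethod",
    "ConfusionTable",
    "MetricEstimate",
    "DiagnosticSummary",
    "build_confusion_table",
    "accuracy_metrics",
    "wilson_cc_interval",
    "proportion_interval",
    "evaluate_criterion",
]


class OutcomeKind(str, enum.Enum):
    death = "death"
    death_or_icu = "death_or_icu"


class CiMethod(str, enum.Enum):
    wilson_cc = "wilson_cc"
    wilson = "wilson"
    clopper_pearson = "clopper_pearson"


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 counts of severity class vs outcome, plus excluded records."""

    tp: int  # severe, event
    fn: int  # non-severe, event
    fp: int  # severe, no event
    tn: int  # non-severe, no event
    excluded: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn, self.excluded) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_analysed(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_events(self) -> int:
        return self.tp + self.fn

    @property
    def n_severe(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its confidence interval and defining counts.

    ``estimate`` is ``None`` when the denominator is empty (the metric is
    undefined, not zero).
    """

    numerator: int
    denominator: int
    estimate: Optional[float]
    ci_lower: Optional[float]
    ci_upper: Optional[float]

    @property
    def defined(self) -> bool:
        return self.estimate is not None

    def as_percent(self) -> tuple[float, float, float]:
        if not self.defined:
            raise ValueError("metric undefined (zero denominator)")
        return (100 * self.estimate, 100 * self.ci_lower, 100 * self.ci_upper)


@dataclass(frozen=True)
class DiagnosticSummary:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    table: ConfusionTable

    def metrics(self) -> Mapping[str, MetricEstimate]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def _event(record: PatientRecord, outcome_kind: OutcomeKind) -> bool:
    if outcome_kind is OutcomeKind.death:
        return record.died_6wk
    return record.death_or_icu


def build_confusion_table(
    score_results: Sequence[ScoreResult],
    cohort: Sequence[PatientRecord],
    outcome_kind: OutcomeKind,
) -> ConfusionTable:
    """Cross-tabulate severity class against outcome.

    Records whose severity is indeterminate under the missing-data bounds
    rule are excluded from the 2×2 counts and tallied in ``excluded``.
    Raises if the score results and cohort do not cover the same patients.
    """
    by_id = {r.patient_id: r for r in cohort}
    if len(by_id) != len(cohort):
        raise ValueError("duplicate patient_id in cohort")
    score_ids = {s.patient_id for s in score_results}
    if score_ids != set(by_id):
        missing = sorted(score_ids ^ set(by_id))
        raise ValueError(f"patient sets differ between scores and cohort: {missing}")

    tp = fn = fp = tn = excluded = 0
    for s in score_results:
        if s.severity is Severity.excluded:
            excluded += 1
            continue
        event = _event(by_id[s.patient_id], outcome_kind)
        severe = s.severity is Severity.severe
        if severe and event:
            tp += 1
        elif severe:
            fp += 1
        elif event:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn, excluded=excluded)


def wilson_cc_interval(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Continuity-corrected Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    z = norm.ppf(1 - (1 - confidence) / 2)
    p = successes / n
    denom = 2 * (n + z * z)
    if successes == 0:
        lower = 0.0
    else:
        rad = z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1)
        lower = (2 * n * p + z * z - 1 - z * math.sqrt(max(0.0, rad))) / denom
    if successes == n:
        upper = 1.0
    else:
        rad = z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1)
        upper = (2 * n * p + z * z + 1 + z * math.sqrt(max(0.0, rad))) / denom
    return max(0.0, lower), min(1.0, upper)


def _wilson_interval(successes: int, n: int, confidence: float) -> tuple[float, float]:
    z = norm.ppf(1 - (1 - confidence) / 2)
    p = successes / n
    centre = (p + z * z / (2 * n)) / (1 + z * z / n)
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / (1 + z * z / n)
    return max(0.0, centre - half), min(1.0, centre + half)


def _clopper_pearson(successes: int, n: int, confidence: float) -> tuple[float, float]:
    alpha = 1 - confidence
    lower = 0.0 if successes == 0 else beta.ppf(alpha / 2, successes, n - successes + 1)
    upper = (
        1.0 if successes == n else beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return float(lower), float(upper)


def proportion_interval(
    successes: int,
    n: int,
    confidence: float = 0.95,
    method: CiMethod = CiMethod.wilson_cc,
) -> tuple[float, float]:
    """Binomial CI by the selected method (default: continuity-corrected Wilson)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if method is CiMethod.wilson_cc:
        return wilson_cc_interval(successes, n, confidence)
    if method is CiMethod.wilson:
        return _wilson_interval(successes, n, confidence)
    return _clopper_pearson(successes, n, confidence)


def _metric(
    numerator: int,
    denominator: int,
    confidence: float,
    method: CiMethod,
) -> MetricEstimate:
    if denominator == 0:
        return MetricEstimate(numerator, denominator, None, None, None)
    lo, hi = proportion_interval(numerator, denominator, confidence, method)
    return MetricEstimate(numerator, denominator, numerator / denominator, lo, hi)


def accuracy_metrics(
    table: ConfusionTable,
    confidence: float = 0.95,
    method: CiMethod = CiMethod.wilson_cc,
) -> DiagnosticSummary:
    """Sensitivity, specificity, PPV and NPV with confidence intervals."""
    return DiagnosticSummary(
        sensitivity=_metric(table.tp, table.tp + table.fn, confidence, method),
        specificity=_metric(table.tn, table.tn + table.fp, confidence, method),
        ppv=_metric(table.tp, table.tp + table.fp, confidence, method),
        npv=_metric(table.tn, table.tn + table.fn, confidence, method),
        table=table,
    )


def evaluate_criterion(
    cohort: Sequence[PatientRecord],
    criterion,
    outcome_kind: OutcomeKind,
    asi_mode=None,
    confidence: float = 0.95,
    ci_method: CiMethod = CiMethod.wilson_cc,
) -> DiagnosticSummary:
    """Score a cohort against one criterion and summarise its accuracy."""
    from .scoring import AsiMode, CRITERIA, CriterionName, score_cohort

    if not cohort:
        raise ValueError("cohort is empty")
    if isinstance(criterion, (str, CriterionName)):
        criterion = CRITERIA[CriterionName(criterion)]
    if asi_mode is None:
        asi_mode = AsiMode.continuous
    results = score_cohort(cohort, criterion, asi_mode)
    table = build_confusion_table(results, cohort, outcome_kind)
    return accuracy_metrics(table, confidence, ci_method)
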