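"""Severity criteria for community-acquired pneumonia.

Implements six criteria built from five component predicates scored one
point each:

* ``C``  — confusion present
* ``U``  — urea > 7 mmol/L (strict)
* ``R``  — respiratory rate ≥ 30 /min
* ``B``  — systolic BP < 90 mmHg or diastolic BP ≤ 60 mmHg (one point total)
* ``65`` — age ≥ 65 years
* ``SI`` — shock index (heart rate / systolic BP) > 1.0 (strict)
* ``ASI``— temperature-adjusted shock index > 1.0 (strict)

Criteria and severity cutoffs::

    CURB65 = C+U+R+B+65, severe if ≥ 3      CRB65 = C+R+B+65, severe if ≥ 3
    CURSI  = C+U+R+SI,   severe if ≥ 2      CRSI  = C+R+SI,   severe if ≥ 2
    CURASI = C+U+R+ASI,  severe if ≥ 2      CRASI = C+R+ASI,  severe if ≥ 2

The adjusted shock index deducts 10 beats/min from the heart rate per 1.0 °C
of temperature above 37.0 °C before taking the ratio; the deduction is never
negative (temperature below 37 °C does not raise the heart rate) and the
adjusted heart rate is floored at zero.

Missing data (confusion or urea not recorded) is handled with a bounds rule:
the score is computed twice, once treating every missing component as 0
(``score_lower``) and once as 1 (``score_upper``).  When both bounds fall on
the same side of the severity cutoff the patient keeps that class despite the
missing value; when the cutoff lies strictly between the bounds the class is
indeterminate and the patient is excluded from analysis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .records import PatientRecord

__all__ = [
    "AsiMode",
    "Component",
    "CriterionDefinition",
    "CRITERIA",
    "CriterionName",
    "ScoreResult",
    "Severity",
    "Disposition",
    "shock_index",
    "adjusted_shock_index",
    "component_flags",
    "score_criterion",
    "score_cohort",
]


class AsiMode(str, enum.Enum):
    """Reading of "10 beats per 1.0 °C above 37.0 °C".

    ``continuous`` deducts 10·(T − 37.0) for any fractional excess;
    ``whole_degree`` deducts 10 per completed whole degree.
    """

    continuous = "continuous"
    whole_degree = "whole_degree"


class Component(str, enum.Enum):
    C = "C"
    U = "U"
    R = "R"
    B = "B"
    AGE65 = "65"
    SI = "SI"
    ASI = "ASI"


class CriterionName(str, enum.Enum):
    CURB65 = "CURB65"
    CRB65 = "CRB65"
    CURSI = "CURSI"
    CURASI = "CURASI"
    CRSI = "CRSI"
    CRASI = "CRASI"


@dataclass(frozen=True)
class CriterionDefinition:
    name: CriterionName
    components: tuple[Component, ...]
    severe_cutoff: int

    def __post_init__(self) -> None:
        if not 0 < self.severe_cutoff <= self.max_score:
            raise ValueError("severe_cutoff must lie in (0, max_score]")

    @property
    def max_score(self) -> int:
        return len(self.components)


CRITERIA: Mapping[CriterionName, CriterionDefinition] = {
    CriterionName.CURB65: CriterionDefinition(
        CriterionName.CURB65,
        (Component.C, Component.U, Component.R, Component.B, Component.AGE65),
        3,
    ),
    CriterionName.CRB65: CriterionDefinition(
        CriterionName.CRB65,
        (Component.C, Component.R, Component.B, Component.AGE65),
        3,
    ),
    CriterionName.CURSI: CriterionDefinition(
        CriterionName.CURSI,
        (Component.C, Component.U, Component.R, Component.SI),
        2,
    ),
    CriterionName.CURASI: CriterionDefinition(
        CriterionName.CURASI,
        (Component.C, Component.U, Component.R, Component.ASI),
        2,
    ),
    CriterionName.CRSI: CriterionDefinition(
        CriterionName.CRSI, (Component.C, Component.R, Component.SI), 2
    ),
    CriterionName.CRASI: CriterionDefinition(
        CriterionName.CRASI, (Component.C, Component.R, Component.ASI), 2
    ),
}


class Severity(str, enum.Enum):
    severe = "severe"
    non_severe = "non_severe"
    excluded = "excluded"


class Disposition(str, enum.Enum):
    complete = "complete"
    allocated_despite_missing = "allocated_despite_missing"
    excluded_borderline = "excluded_borderline"


# tri-state component flag: 1, 0, or None (indeterminate, field missing)
Flag = Optional[int]


@dataclass(frozen=True)
class ScoreResult:
    """Outcome of scoring one patient against one criterion."""

    patient_id: str
    criterion: CriterionName
    component_flags: tuple[Flag, ...]
    score_lower: int  # missing components scored 0
    score_upper: int  # missing components scored 1
    severity: Severity
    disposition: Disposition

    def __post_init__(self) -> None:
        if not self.score_lower <= self.score_upper:
            raise ValueError("score_lower must not exceed score_upper")

    @property
    def score(self) -> int:
        """Definite score; only meaningful for complete records."""
        if self.score_lower != self.score_upper:
            raise ValueError("score is indeterminate (missing components)")
        return self.score_lower


def shock_index(heart_rate: float, sbp: float) -> float:
    """Shock index: heart rate (beats/min) over systolic pressure (mmHg)."""
    if heart_rate <= 0 or sbp <= 0:
        raise ValueError("heart_rate and sbp must be positive")
    return heart_rate / sbp


def adjusted_shock_index(
    heart_rate: float,
    sbp: float,
    temperature: float,
    mode: AsiMode = AsiMode.continuous,
) -> float:
    """Temperature-adjusted shock index.

    Deducts 10 beats/min per 1.0 °C of temperature above 37.0 °C — fever
    raises the heart rate physiologically, so the raw shock index overstates
    circulatory compromise in febrile patients.  No adjustment is made below
    37.0 °C and the adjusted heart rate is floored at zero.
    """
    if heart_rate <= 0 or sbp <= 0:
        raise ValueError("heart_rate and sbp must be positive")
    excess = max(0.0, temperature - 37.0)
    if mode is AsiMode.whole_degree:
        excess = math.floor(excess)
    effective_hr = max(0.0, heart_rate - 10.0 * excess)
    return effective_hr / sbp


def _component_flag(
    record: PatientRecord, component: Component, asi_mode: AsiMode
) -> Flag:
    if component is Component.C:
        return None if record.confusion is None else int(record.confusion)
    if component is Component.U:
        return None if record.urea is None else int(record.urea > 7.0)
    if component is Component.R:
        return int(record.resp_rate >= 30)
    if component is Component.B:
        return int(record.sbp < 90.0 or record.dbp <= 60.0)
    if component is Component.AGE65:
        return int(record.age >= 65)
    if component is Component.SI:
        return int(shock_index(record.heart_rate, record.sbp) > 1.0)
    if component is Component.ASI:
        asi = adjusted_shock_index(
            record.heart_rate, record.sbp, record.temperature, asi_mode
        )
        return int(asi > 1.0)
    raise ValueError(f"unknown component {component!r}")  # pragma: no cover


def component_flags(
    record: PatientRecord,
    criterion: CriterionDefinition,
    asi_mode: AsiMode = AsiMode.continuous,
) -> tuple[Flag, ...]:
    """Evaluate the criterion's component predicates on one record.

    Returns one flag per component, in the criterion's component order:
    ``1`` (met), ``0`` (not met), or ``None`` when the underlying field is
    missing.  Missingness never raises.
    """
    return tuple(_component_flag(record, c, asi_mode) for c in criterion.components)


def score_criterion(
    record: PatientRecord,
    criterion: CriterionDefinition,
    asi_mode: AsiMode = AsiMode.continuous,
) -> ScoreResult:
    """Score one patient, applying the missing-data bounds rule.

    ``severity`` is ``severe`` when even the pessimistic lower bound reaches
    the cutoff, ``non_severe`` when even the optimistic upper bound misses
    it, and ``excluded`` when the missing value could tip the class.
    """
    flags = component_flags(record, criterion, asi_mode)
    lower = sum(f for f in flags if f is not None)
    n_missing = sum(f is None for f in flags)
    upper = lower + n_missing

    if lower >= criterion.severe_cutoff:
        severity = Severity.severe
    elif upper < criterion.severe_cutoff:
        severity = Severity.non_severe
    else:
        severity = Severity.excluded

    if n_missing == 0:
        disposition = Disposition.complete
    elif severity is Severity.excluded:
        disposition = Disposition.excluded_borderline
    else:
        disposition = Disposition.allocated_despite_missing

    return ScoreResult(
        patient_id=record.patient_id,
        criterion=criterion.name,
        component_flags=flags,
        score_lower=lower,
        score_upper=upper,
        severity=severity,
        disposition=disposition,
    )


def score_cohort(
    cohort: Sequence[PatientRecord],
    criterion: CriterionDefinition,
    asi_mode: AsiMode = AsiMode.continuous,
) -> list[ScoreResult]:
    """Score every record in a cohort against one criterion."""
    return [score_criterion(r, criterion, asi_mode) for r in cohort]
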