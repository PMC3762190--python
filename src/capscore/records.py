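"""Patient-level record model for community-acquired pneumonia severity scoring.

A :class:`PatientRecord` holds one admission's vital signs, the urea
measurement, confusion status and the two six-week outcomes (death, ICU
admission).  Urea and confusion may be missing — they are the only fields the
severity criteria tolerate as absent; missingness propagates downstream as an
indeterminate component flag rather than an error.

Plausibility bounds are enforced at construction time: a value outside the
physiological window (e.g. temperature 50 °C) is a validation error, never a
silent clamp.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class PatientRecord(BaseModel):
    """One CAP admission: vitals, labs and six-week outcomes.

    ``confusion`` is tri-state (``True`` / ``False`` / ``None`` = not
    recorded); ``urea`` is in mmol/L and may be ``None``.  All other
    measurements are required.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str
    age: int
    sex: Sex
    confusion: Optional[bool]
    urea: Optional[float]
    resp_rate: int
    sbp: float
    dbp: float
    heart_rate: float
    temperature: float
    died_6wk: bool
    icu_6wk: bool

    # physiological plausibility windows (violations are load errors)
    _BOUNDS = {
        "age": (0, 120),
        "temperature": (25.0, 45.0),
        "heart_rate": (20.0, 250.0),
        "resp_rate": (4, 80),
        "sbp": (40.0, 300.0),
        "dbp": (10.0, 200.0),
        "urea": (0.0, 60.0),
    }

    @field_validator("urea")
    @classmethod
    def _urea_finite(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not math.isfinite(v):
            raise ValueError("urea must be finite or missing")
        return v

    @model_validator(mode="after")
    def _check_bounds(self) -> "PatientRecord":
        for field, (lo, hi) in self._BOUNDS.items():
            value = getattr(self, field)
            if value is None:
                continue
            if not (lo <= value <= hi):
                raise ValueError(
                    f"{field}={value!r} outside plausible range [{lo}, {hi}]"
                )
        if self.sbp <= self.dbp:
            raise ValueError(
                f"systolic pressure ({self.sbp}) must exceed diastolic ({self.dbp})"
            )
        return self

    @property
    def death_or_icu(self) -> bool:
        """Composite outcome: death and/or ICU admission within six weeks."""
        return self.died_6wk or self.icu_6wk
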