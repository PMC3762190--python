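"""Seedable synthetic CAP cohort generator.

Emulates the marginal structure of the study cohort the package's worked
examples are built around: 95 adult pneumonia admissions with median age 61,
28.4% confusion prevalence, right-skewed urea, and event rates near 8/95
deaths and 11–12/95 death-or-ICU within six weeks.

Continuous vitals are truncated normals; urea is a truncated log-normal
(median 6.65 < mean 7.9 indicates right skew).  The distribution parameters
in :class:`CohortSpec` are the *observed* (truncated-scale) moments, so the
parent parameters are solved by moment matching — naive truncation of a
normal with the target mean would bias the sample mean by more than the
Monte-Carlo error at the cohort sizes used for validation.

Outcomes follow a logistic model in a latent severity burden (standardised
combination of respiratory rate, log-urea, shock index, confusion and age).
ICU admission is drawn first; death is drawn with an extra shared term for
ICU patients, reproducing the strong death/ICU overlap seen clinically.
Intercepts are calibrated per cohort so the expected event rates hit the
targets whatever the slope.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.optimize import brentq, fsolve
from scipy.special import expit
from scipy.stats import lognorm, norm, truncnorm

from .records import PatientRecord, Sex

__all__ = [
    "TruncNormalSpec",
    "TruncLogNormalSpec",
    "OutcomeModel",
    "CohortSpec",
    "generate_cohort",
    "severity_burden",
    "draw_vitals",
    "attach_outcomes",
    "cohort_to_frame",
]


class TruncNormalSpec(BaseModel):
    """Truncated normal specified by its truncated-scale mean/sd and bounds."""

    model_config = ConfigDict(frozen=True)

    mean: float
    sd: float = Field(gt=0)
    lower: float
    upper: float

    @model_validator(mode="after")
    def _ordered(self) -> "TruncNormalSpec":
        if not self.lower < self.mean < self.upper:
            raise ValueError("bounds must bracket the mean")
        return self


class TruncLogNormalSpec(BaseModel):
    """Truncated log-normal specified by truncated-scale median/mean and bounds."""

    model_config = ConfigDict(frozen=True)

    median: float = Field(gt=0)
    mean: float = Field(gt=0)
    lower: float = Field(gt=0)
    upper: float

    @model_validator(mode="after")
    def _ordered(self) -> "TruncLogNormalSpec":
        if not self.lower < self.median < self.upper:
            raise ValueError("bounds must bracket the median")
        if self.mean <= self.median:
            raise ValueError("right skew requires mean > median")
        return self


class OutcomeModel(BaseModel):
    """Logistic outcome model in the latent severity burden.

    ``slope`` scales the association between burden and both events;
    ``icu_death_boost`` is the shared log-odds term added to the death model
    for ICU-admitted patients, producing the death/ICU overlap.  Intercepts
    are calibrated at generation time to the target rates.
    """

    model_config = ConfigDict(frozen=True)

    death_rate: float = Field(default=8 / 95, ge=0, le=1)
    icu_rate: float = Field(default=10 / 95, ge=0, le=1)
    slope: float = 1.0
    icu_death_boost: float = 4.0


class CohortSpec(BaseModel):
    """Everything needed to draw a cohort; defaults emulate the study cohort."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(default=95, ge=1)
    seed: int = 0
    age: TruncNormalSpec = TruncNormalSpec(mean=58.8, sd=18.75, lower=17, upper=96)
    male_fraction: float = Field(default=0.568, ge=0, le=1)
    confusion_rate: float = Field(default=0.284, ge=0, le=1)
    urea: TruncLogNormalSpec = TruncLogNormalSpec(
        median=6.65, mean=7.9, lower=1.0, upper=30.9
    )
    resp_rate: TruncNormalSpec = TruncNormalSpec(
        mean=24.2, sd=6.46, lower=10, upper=40
    )
    sbp: TruncNormalSpec = TruncNormalSpec(mean=130.8, sd=27.0, lower=75, upper=208)
    dbp: TruncNormalSpec = TruncNormalSpec(mean=72.9, sd=14.4, lower=40, upper=113)
    heart_rate: TruncNormalSpec = TruncNormalSpec(
        mean=101.9, sd=19.4, lower=56, upper=170
    )
    temperature: TruncNormalSpec = TruncNormalSpec(
        mean=37.78, sd=1.18, lower=33.4, upper=40.0
    )
    outcome: OutcomeModel = OutcomeModel()
    missing_urea_rate: float = Field(default=0.01, ge=0, le=1)
    missing_confusion_rate: float = Field(default=0.01, ge=0, le=1)


# ---------------------------------------------------------------------------
# parent-parameter solvers (moment matching under truncation)


@lru_cache(maxsize=64)
def _truncnorm_parent(mean: float, sd: float, lower: float, upper: float):
    """Parent (mu, sigma) whose [lower, upper]-truncation has the given moments."""

    def equations(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a, b = (lower - mu) / sigma, (upper - mu) / sigma
        dist = truncnorm(a, b, loc=mu, scale=sigma)
        return [dist.mean() - mean, dist.std() - sd]

    sol, info, ier, msg = fsolve(
        equations, x0=[mean, np.log(sd)], full_output=True
    )
    if ier != 1:
        raise ValueError(f"truncated-normal moment matching failed: {msg}")
    return float(sol[0]), float(np.exp(sol[1]))


@lru_cache(maxsize=16)
def _trunclognorm_parent(median: float, mean: float, lower: float, upper: float):
    """Parent (mu, sigma) of log X whose truncation has the given median/mean."""

    def equations(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        dist = lognorm(s=sigma, scale=np.exp(mu))
        fa, fb = dist.cdf(lower), dist.cdf(upper)
        trunc_median = dist.ppf(fa + 0.5 * (fb - fa))
        trunc_mean = dist.expect(lb=lower, ub=upper, conditional=True)
        return [trunc_median - median, trunc_mean - mean]

    # untruncated log-normal solution as the starting point
    sigma0 = np.sqrt(max(1e-4, 2 * np.log(mean / median)))
    sol, info, ier, msg = fsolve(
        equations, x0=[np.log(median), np.log(sigma0)], full_output=True
    )
    if ier != 1:
        raise ValueError(f"truncated-log-normal moment matching failed: {msg}")
    return float(sol[0]), float(np.exp(sol[1]))


def _sample_truncnorm(
    spec: TruncNormalSpec, size: int, rng: np.random.Generator
) -> np.ndarray:
    mu, sigma = _truncnorm_parent(spec.mean, spec.sd, spec.lower, spec.upper)
    a, b = (spec.lower - mu) / sigma, (spec.upper - mu) / sigma
    # inverse-CDF sampling keeps the draw count per variable fixed
    u = rng.uniform(norm.cdf(a), norm.cdf(b), size=size)
    return mu + sigma * norm.ppf(u)


def _sample_trunclognorm(
    spec: TruncLogNormalSpec, size: int, rng: np.random.Generator
) -> np.ndarray:
    mu, sigma = _trunclognorm_parent(spec.median, spec.mean, spec.lower, spec.upper)
    dist = lognorm(s=sigma, scale=np.exp(mu))
    u = rng.uniform(dist.cdf(spec.lower), dist.cdf(spec.upper), size=size)
    return dist.ppf(u)


# ---------------------------------------------------------------------------
# generation


def draw_vitals(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the per-patient vitals/labs table (no outcomes, no missingness)."""
    n = spec.n
    age = np.round(_sample_truncnorm(spec.age, n, rng)).astype(int)
    age = np.clip(age, int(spec.age.lower), int(spec.age.upper))
    sex = np.where(rng.uniform(size=n) < spec.male_fraction, "male", "female")
    confusion = rng.uniform(size=n) < spec.confusion_rate
    urea = _sample_trunclognorm(spec.urea, n, rng)
    resp = np.round(_sample_truncnorm(spec.resp_rate, n, rng)).astype(int)
    resp = np.clip(resp, int(spec.resp_rate.lower), int(spec.resp_rate.upper))
    sbp = _sample_truncnorm(spec.sbp, n, rng)
    dbp = _sample_truncnorm(spec.dbp, n, rng)
    # physiology: diastolic below systolic, enforced by per-record resampling
    for _ in range(1000):
        bad = dbp >= sbp
        if not bad.any():
            break
        dbp[bad] = _sample_truncnorm(spec.dbp, int(bad.sum()), rng)
    else:  # pragma: no cover - bounds make this unreachable in practice
        raise RuntimeError("could not satisfy dbp < sbp by resampling")
    heart_rate = _sample_truncnorm(spec.heart_rate, n, rng)
    temperature = _sample_truncnorm(spec.temperature, n, rng)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "confusion": confusion,
            "urea": urea,
            "resp_rate": resp,
            "sbp": sbp,
            "dbp": dbp,
            "heart_rate": heart_rate,
            "temperature": temperature,
        }
    )


def severity_burden(vitals: pd.DataFrame, spec: CohortSpec) -> np.ndarray:
    """Latent severity burden: standardised sum of risk-bearing features."""
    z = lambda x, m, s: (np.asarray(x, dtype=float) - m) / s  # noqa: E731
    log_urea_med = np.log(spec.urea.median)
    components = np.column_stack(
        [
            z(vitals["resp_rate"], spec.resp_rate.mean, spec.resp_rate.sd),
            z(np.log(vitals["urea"]), log_urea_med, 0.6),
            z(
                vitals["heart_rate"] / vitals["sbp"],
                spec.heart_rate.mean / spec.sbp.mean,
                0.25,
            ),
            1.5 * vitals["confusion"].to_numpy(dtype=float),
            z(vitals["age"], spec.age.mean, spec.age.sd),
        ]
    )
    return components.sum(axis=1) / np.sqrt(components.shape[1])


def _calibrate_intercept(target_rate: float, offsets: np.ndarray) -> float:
    """Intercept a such that mean(expit(a + offsets)) == target_rate."""
    if target_rate <= 0:
        return -np.inf
    if target_rate >= 1:
        return np.inf
    f = lambda a: expit(a + offsets).mean() - target_rate  # noqa: E731
    return brentq(f, -40, 40)


def attach_outcomes(
    vitals: pd.DataFrame, spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw six-week death and ICU outcomes for a vitals table.

    ICU admission is logistic in the burden; death is logistic in the burden
    plus a shared boost for ICU patients.  Intercepts are calibrated so the
    expected event counts match the spec's target rates.
    """
    burden = severity_burden(vitals, spec)
    om = spec.outcome
    icu_offsets = om.slope * burden
    a_icu = _calibrate_intercept(om.icu_rate, icu_offsets)
    icu = rng.uniform(size=len(vitals)) < expit(a_icu + icu_offsets)

    death_offsets = om.slope * burden + om.icu_death_boost * icu
    a_death = _calibrate_intercept(om.death_rate, death_offsets)
    died = rng.uniform(size=len(vitals)) < expit(a_death + death_offsets)

    out = vitals.copy()
    out["died_6wk"] = died
    out["icu_6wk"] = icu
    return out


def _apply_missingness(
    frame: pd.DataFrame, spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    out = frame.copy()
    out["urea"] = out["urea"].astype(object)
    out["confusion"] = out["confusion"].astype(object)
    miss_u = rng.uniform(size=len(out)) < spec.missing_urea_rate
    miss_c = rng.uniform(size=len(out)) < spec.missing_confusion_rate
    out.loc[miss_u, "urea"] = None
    out.loc[miss_c, "confusion"] = None
    return out


def generate_cohort(
    spec: CohortSpec, rng: Optional[np.random.Generator] = None
) -> list[PatientRecord]:
    """Generate a full synthetic cohort, deterministic given ``spec.seed``.

    Pipeline: vitals → outcomes → missing-completely-at-random masking →
    validated :class:`PatientRecord` objects.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    frame = draw_vitals(spec, rng)
    frame = attach_outcomes(frame, spec, rng)
    frame = _apply_missingness(frame, spec, rng)
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            PatientRecord(
                patient_id=row.patient_id,
                age=int(row.age),
                sex=Sex(row.sex),
                confusion=None if row.confusion is None else bool(row.confusion),
                urea=None if row.urea is None else float(row.urea),
                resp_rate=int(row.resp_rate),
                sbp=float(row.sbp),
                dbp=float(row.dbp),
                heart_rate=float(row.heart_rate),
                temperature=float(row.temperature),
                died_6wk=bool(row.died_6wk),
                icu_6wk=bool(row.icu_6wk),
            )
        )
    return records


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tabulate records; missing urea/confusion become NaN/None."""
    return pd.DataFrame([r.model_dump() for r in cohort]).assign(
        sex=lambda d: d["sex"].map(lambda s: s.value)
    )
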