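"""Per-eye visual-field progression: rate estimation and classification.

The worsening rate is the negated ordinary-least-squares slope of MD on
time in years, so a declining field yields a positive rate (dB of loss per
year).  Eyes are classified into the standard three rate bins (slow <0.5,
medium 0.5-1.5, fast >1.5 dB/year), five baseline-severity bins (cut at
-2/-6/-12/-18 dB), five age bins and five IOP bins, and each two-eyed
patient's eyes are designated better/worse by MD with randomised
designation when the eyes differ by less than a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Optional, Sequence

import numpy as np

from .cohort import Cohort, DAYS_PER_YEAR, EyeSeries, PatientRecord
from .errors import DegenerateDataError, InsufficientDataError

__all__ = [
    "ProgressionConfig", "ProgressionResult", "SkippedEye",
    "estimate_worsening_rate", "classify_rate", "classify_severity",
    "classify_age", "classify_iop", "designate_eyes", "run_progression",
    "RATE_BOUNDS", "SEVERITY_BOUNDS", "AGE_BOUNDS", "IOP_BOUNDS",
]

RATE_BOUNDS = (0.5, 1.5)
SEVERITY_BOUNDS = (-2.0, -6.0, -12.0, -18.0)
AGE_BOUNDS = (50.0, 60.0, 70.0, 80.0)
IOP_BOUNDS = (15.0, 20.0, 25.0, 30.0)

DESIGNATION_METHODS = ("baseline_md", "mean_followup_md", "alternating")


def _check_ordered(bounds: Sequence[float], descending: bool = False) -> None:
    pairs = zip(bounds, bounds[1:])
    ok = all(a > b for a, b in pairs) if descending else all(
        a < b for a, b in zip(bounds, bounds[1:]))
    if not ok:
        raise ValueError(f"bin bounds must be strictly ordered, got {bounds}")


@dataclass(frozen=True)
class ProgressionConfig:
    designation_method: str = "baseline_md"
    designation_threshold: float = 1.0   # dB; randomise below this inter-eye gap
    rng_seed: int = 0
    rate_bounds: tuple[float, float] = RATE_BOUNDS
    severity_bounds: tuple[float, ...] = SEVERITY_BOUNDS
    age_bounds: tuple[float, ...] = AGE_BOUNDS
    iop_bounds: tuple[float, ...] = IOP_BOUNDS

    def __post_init__(self) -> None:
        if self.designation_method not in DESIGNATION_METHODS:
            raise ValueError(
                f"designation_method must be one of {DESIGNATION_METHODS}")
        _check_ordered(self.rate_bounds)
        _check_ordered(self.severity_bounds, descending=True)
        _check_ordered(self.age_bounds)
        _check_ordered(self.iop_bounds)


@dataclass(frozen=True)
class ProgressionResult:
    patient_id: str
    eye: str
    baseline_md: float
    worsening_rate: float
    rate_category: str
    severity_group: int
    designation: str            # better / worse / single
    n_vfs: int
    age_group: Optional[int] = None
    iop_group: Optional[int] = None


@dataclass(frozen=True)
class SkippedEye:
    patient_id: str
    eye: str
    reason: str


def estimate_worsening_rate(series: EyeSeries) -> float:
    """OLS worsening rate in dB/year (positive = losing sensitivity).

    Time is measured in fractional years (days/365.25) from the first
    visit; the returned rate is the negated regression slope.
    """
    visits = series.visits
    if len(visits) < 2:
        raise InsufficientDataError(
            f"need >=2 visual fields to estimate a rate, got {len(visits)}")
    t0 = visits[0].visit_date
    t = np.array([(v.visit_date - t0).days / DAYS_PER_YEAR for v in visits])
    if np.ptp(t) == 0:
        raise DegenerateDataError("all visits on the same date")
    md = np.array([v.md for v in visits])
    t_centered = t - t.mean()
    slope = float(np.dot(t_centered, md - md.mean()) / np.dot(t_centered, t_centered))
    return -slope


def classify_rate(rate: float, bounds: tuple[float, float] = RATE_BOUNDS) -> str:
    """Three-bin rate class; the medium bin is closed on both ends and
    improving (negative) rates fall in ``slow``."""
    low, high = bounds
    if rate < low:
        return "slow"
    if rate <= high:
        return "medium"
    return "fast"


def classify_severity(baseline_md: float,
                      bounds: tuple[float, ...] = SEVERITY_BOUNDS) -> int:
    """Five-bin baseline severity group (1 = mildest); bins are half-open
    with the cut value belonging to the worse group."""
    for group, bound in enumerate(bounds, start=1):
        if baseline_md > bound:
            return group
    return len(bounds) + 1


def _classify_ascending(value: float, bounds: Sequence[float]) -> int:
    for group, bound in enumerate(bounds, start=1):
        if value < bound:
            return group
    return len(bounds) + 1


def classify_age(age: float, bounds: tuple[float, ...] = AGE_BOUNDS) -> int:
    """Five-bin age group with half-open [lower, upper) bins."""
    if age < 0:
        raise ValueError("age must be non-negative")
    return _classify_ascending(age, bounds)


def classify_iop(iop: float, bounds: tuple[float, ...] = IOP_BOUNDS) -> int:
    """Five-bin IOP group with half-open [lower, upper) bins."""
    if iop < 0:
        raise ValueError("IOP must be non-negative")
    return _classify_ascending(iop, bounds)


def _baseline_visit(series: EyeSeries, onset_year: Optional[int]):
    if onset_year is None:
        return series.visits[0]
    for visit in series.visits:
        if visit.visit_date.year == onset_year:
            return visit
    return None


def _comparison_stat(series: EyeSeries, other: EyeSeries, method: str,
                     onset_year: Optional[int]) -> float:
    if method == "baseline_md":
        visit = _baseline_visit(series, onset_year)
        if visit is None:
            raise InsufficientDataError(
                f"{series.eye} eye has no visual field in the onset year")
        return visit.md
    if method == "mean_followup_md":
        return fmean(v.md for v in series.visits)
    # alternating: compare per-visit labels on shared dates, summarised as
    # the mean inter-eye MD difference over those dates.
    own = {v.visit_date: v.md for v in series.visits}
    shared = [d for d in own if any(w.visit_date == d for w in other.visits)]
    if not shared:
        raise InsufficientDataError("no shared visit dates between the eyes")
    return fmean(own[d] for d in shared)


def designate_eyes(
    patient: PatientRecord,
    config: ProgressionConfig,
    rng: np.random.Generator,
    onset_year: Optional[int] = None,
) -> dict[str, str]:
    """Designate each eye ``better``/``worse`` (or ``single``).

    The comparison statistic depends on the configured method: onset-year
    MD, mean follow-up MD, or mean MD over shared visit dates (the
    alternating-eyes summary).  When the statistics differ by at least the
    threshold the higher (less negative) MD is ``better``; below the
    threshold a fair coin from ``rng`` decides.
    """
    if len(patient.eyes) == 1:
        return {patient.eyes[0].eye: "single"}
    if len(patient.eyes) != 2:
        raise InsufficientDataError(f"patient {patient.patient_id} has no eye data")
    first, second = patient.eyes
    stat_first = _comparison_stat(first, second, config.designation_method, onset_year)
    stat_second = _comparison_stat(second, first, config.designation_method, onset_year)
    delta = stat_first - stat_second
    if abs(delta) >= config.designation_threshold:
        first_is_better = delta > 0
    else:
        first_is_better = bool(rng.random() < 0.5)
    if first_is_better:
        return {first.eye: "better", second.eye: "worse"}
    return {first.eye: "worse", second.eye: "better"}


def run_progression(
    cohort: Cohort, config: ProgressionConfig
) -> tuple[list[ProgressionResult], list[SkippedEye]]:
    """Estimate and classify every eligible eye in the cohort.

    Eyes lacking an onset-year baseline or a second visual field are
    reported in the skip list instead of raising.  Deterministic for a
    given ``rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    onset_year = cohort.onset_year
    results: list[ProgressionResult] = []
    skipped: list[SkippedEye] = []
    for patient in cohort.patients:
        eligible: list[EyeSeries] = []
        for series in patient.eyes:
            if _baseline_visit(series, onset_year) is None:
                skipped.append(SkippedEye(patient.patient_id, series.eye,
                                          "no visual field in the onset year"))
            elif len(series.visits) < 2:
                skipped.append(SkippedEye(patient.patient_id, series.eye,
                                          "fewer than 2 visual fields"))
            else:
                eligible.append(series)
        if not eligible:
            continue
        if len(eligible) == 2:
            trimmed = PatientRecord(patient_id=patient.patient_id, eyes=eligible)
            try:
                designations = designate_eyes(trimmed, config, rng, onset_year)
            except InsufficientDataError as exc:
                for series in eligible:
                    skipped.append(SkippedEye(patient.patient_id, series.eye,
                                              f"designation failed: {exc}"))
                continue
        else:
            designations = {eligible[0].eye: "single"}
        for series in eligible:
            baseline = _baseline_visit(series, onset_year)
            rate = estimate_worsening_rate(series)
            age = patient.age_on(baseline.visit_date, onset_year)
            results.append(ProgressionResult(
                patient_id=patient.patient_id,
                eye=series.eye,
                baseline_md=baseline.md,
                worsening_rate=rate,
                rate_category=classify_rate(rate, config.rate_bounds),
                severity_group=classify_severity(baseline.md, config.severity_bounds),
                designation=designations[series.eye],
                n_vfs=len(series.visits),
                age_group=classify_age(age, config.age_bounds) if age is not None else None,
                iop_group=(classify_iop(baseline.iop, config.iop_bounds)
                           if baseline.iop is not None else None),
            ))
    return results, skipped
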