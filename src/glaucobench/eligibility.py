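"""Cohort selection rules and stage-by-stage attrition accounting.

Routine-care follow-up cohorts are defined here by three rules applied in
order: (1) exclude patients below the adult age cut-off at onset, (2) drop
unreliable visual fields (high false-positive rate) and with them any
patient whose onset-year fields all fail, and (3) keep patients with enough
reliable fields spanning the full follow-up window.  The attrition ledger
then reconciles the onset population against the analysed subset, with the
derived percentages a clinic would print in a benchmark report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from ._util import percent, round_half_away
from .cohort import Cohort, EyeSeries, PatientRecord
from .errors import InconsistencyError

__all__ = [
    "EligibilityConfig", "ExclusionReport", "AttritionLedger",
    "apply_exclusions", "select_followup", "build_attrition_ledger",
    "summarize_costs", "growth_percent",
]


@dataclass(frozen=True)
class EligibilityConfig:
    """Thresholds for cohort selection.

    fp_threshold is inclusive: a visual field with false-positive rate at or
    above it is considered unreliable and removed.
    """

    onset_year: int
    followup_years: int = 5
    min_vfs: int = 2
    min_age: float = 18.0
    fp_threshold: float = 15.0

    def __post_init__(self) -> None:
        if self.followup_years < 1:
            raise ValueError("followup_years must be >= 1")
        if min(self.min_vfs, self.min_age, self.fp_threshold) <= 0:
            raise ValueError("all eligibility thresholds must be positive")


@dataclass(frozen=True)
class ExclusionReport:
    """Per-rule exclusion counts."""

    excluded_age: int = 0
    excluded_fp_patients: int = 0
    removed_fp_visits: int = 0

    def as_dict(self) -> dict:
        return {
            "excluded_age": self.excluded_age,
            "excluded_fp_patients": self.excluded_fp_patients,
            "removed_fp_visits": self.removed_fp_visits,
        }


def _age_at_onset(patient: PatientRecord, onset_year: int) -> Optional[float]:
    if patient.age_at_onset is not None:
        return patient.age_at_onset
    onset_visits = sorted(
        (v.visit_date for _, v in patient.all_visits() if v.visit_date.year == onset_year)
    )
    if onset_visits and patient.birth_date is not None:
        return patient.age_on(onset_visits[0])
    if patient.birth_date is not None:
        from datetime import date

        return patient.age_on(date(onset_year, 1, 1))
    return None


def apply_exclusions(cohort: Cohort, config: EligibilityConfig) -> tuple[Cohort, ExclusionReport]:
    """Apply the age and reliability exclusion rules.

    Patients younger than ``min_age`` at onset are removed.  Visual fields
    with false-positive rate >= ``fp_threshold`` are removed everywhere; a
    patient is then removed only if this empties their onset-year fields
    (or their whole record).  Patients whose age cannot be established are
    retained.  The input cohort is not mutated.
    """
    kept: list[PatientRecord] = []
    excluded_age = excluded_fp = removed_visits = 0
    for patient in cohort.patients:
        age = _age_at_onset(patient, config.onset_year)
        if age is not None and age < config.min_age:
            excluded_age += 1
            continue
        onset_before = sum(
            1 for _, v in patient.all_visits()
            if v.visit_date.year == config.onset_year
        )
        eyes: list[EyeSeries] = []
        n_removed = 0
        for series in patient.eyes:
            reliable = [v for v in series.visits
                        if v.false_positive_rate < config.fp_threshold]
            n_removed += len(series.visits) - len(reliable)
            if reliable:
                eyes.append(EyeSeries(eye=series.eye, visits=reliable))
        removed_visits += n_removed
        onset_after = sum(
            1 for s in eyes for v in s.visits
            if v.visit_date.year == config.onset_year
        )
        if not eyes or (onset_before > 0 and onset_after == 0):
            excluded_fp += 1
            continue
        if n_removed:
            patient = replace(patient, eyes=eyes)
        kept.append(patient)
    report = ExclusionReport(
        excluded_age=excluded_age,
        excluded_fp_patients=excluded_fp,
        removed_fp_visits=removed_visits,
    )
    filtered = Cohort(patients=kept, onset_year=cohort.onset_year,
                      provenance=cohort.provenance)
    return filtered, report


def select_followup(cohort: Cohort, config: EligibilityConfig) -> Cohort:
    """Keep patients with full-span follow-up.

    A patient is retained when, after exclusions, they have at least
    ``min_vfs`` reliable visual fields overall, at least one in the onset
    calendar year, and at least one in calendar year
    ``onset_year + followup_years`` or later.  Patient order is preserved.
    """
    last_year = config.onset_year + config.followup_years
    kept = []
    for patient in cohort.patients:
        years = [v.visit_date.year for _, v in patient.all_visits()]
        if (len(years) >= config.min_vfs
                and any(y == config.onset_year for y in years)
                and any(y >= last_year for y in years)):
            kept.append(patient)
    return Cohort(patients=kept, onset_year=cohort.onset_year,
                  provenance=cohort.provenance)


@dataclass(frozen=True)
class AttritionLedger:
    """Stage-by-stage accounting from onset population to analysed subset.

    ``available`` counts patients alive and reachable in the final year;
    ``not_visited`` those available but not analysed (e.g. scheduled beyond
    the window under a 2-year recall interval).  ``fractions`` holds the
    integer percentages a report prints, including both the available and
    the with-baseline-VF denominators.
    """

    total_onset: int
    no_diagnosis: int
    lost_or_unfit: int
    deceased_estimate: int
    available: int
    analysed: int
    not_visited: int
    with_baseline_vf: int
    fractions: dict

    def check(self) -> None:
        counts = (self.total_onset, self.no_diagnosis, self.lost_or_unfit,
                  self.deceased_estimate, self.available, self.analysed,
                  self.not_visited, self.with_baseline_vf)
        if min(counts) < 0:
            raise InconsistencyError("negative count in attrition ledger")
        if self.available != (self.total_onset - self.no_diagnosis
                              - self.lost_or_unfit - self.deceased_estimate):
            raise InconsistencyError("available inconsistent with inputs")
        if self.analysed > self.available:
            raise InconsistencyError("analysed exceeds available")


def build_attrition_ledger(
    total_onset: int,
    no_diagnosis: int,
    lost_or_unfit: int,
    deceased_estimate: int,
    analysed: int,
    with_baseline_vf: int,
) -> AttritionLedger:
    """Derive the attrition ledger from stage counts.

    The deceased estimate is an input (typically derived from an external
    mortality registry rate), not computed here.
    """
    available = total_onset - no_diagnosis - lost_or_unfit - deceased_estimate
    not_visited = available - analysed
    ledger = AttritionLedger(
        total_onset=total_onset,
        no_diagnosis=no_diagnosis,
        lost_or_unfit=lost_or_unfit,
        deceased_estimate=deceased_estimate,
        available=available,
        analysed=analysed,
        not_visited=not_visited,
        with_baseline_vf=with_baseline_vf,
        fractions={
            "analysed_of_total_pct": percent(analysed, total_onset),
            "analysed_of_available_pct": percent(analysed, available),
            "analysed_of_baseline_vf_pct": percent(analysed, with_baseline_vf),
            "not_visited_of_total_pct": percent(not_visited, total_onset),
            "baseline_vf_of_total_pct": percent(with_baseline_vf, total_onset),
        },
    )
    ledger.check()
    return ledger


def summarize_costs(yearly_cost_per_patient: Sequence[float]) -> int:
    """Mean yearly cost per patient, rounded to the integer currency unit."""
    values = list(yearly_cost_per_patient)
    if not values:
        raise ValueError("need at least one yearly cost value")
    if min(values) < 0:
        raise ValueError("costs must be non-negative")
    return round_half_away(sum(values) / len(values))


def growth_percent(count_start: int, count_end: int) -> int:
    """Relative growth from ``count_start`` to ``count_end`` as an integer %."""
    if count_start <= 0:
        raise ValueError("count_start must be positive")
    return round_half_away(100.0 * (count_end - count_start) / count_start)
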