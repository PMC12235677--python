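"""Aggregated benchmark reports for peer-to-peer comparison of glaucoma care.

A report is a standardized, suppression-safe set of per-year distributions
(age, sex, diagnosis, acuity bands, IOP bins, baseline-severity bins,
worsening-rate bins per eye designation, treatments, costs) so that two
clinics can compare routine-care outcomes without exchanging any
patient-level data.  Cells backed by very few individuals can be masked
(small-cell suppression) to satisfy aggregated-data disclosure rules.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from ._util import round_half_away
from .cohort import Cohort, DIAGNOSES, PatientRecord
from .errors import ConfigurationError, SchemaVersionError
from .progression import ProgressionResult

__all__ = [
    "SCHEMA_VERSION", "Cell", "Section", "BenchmarkReport", "BenchmarkFilter",
    "apply_filter", "build_report", "suppress_small_cells", "compare_reports",
    "serialize_report", "report_to_json", "report_from_json", "report_to_table",
]

SCHEMA_VERSION = "aces-rwm-proto-1"

AGE_LABELS = ("<50", "50-59", "60-69", "70-79", ">=80")
IOP_LABELS = ("<15", "15-19", "20-24", "25-29", ">=30")
SEVERITY_LABELS = (">-2", "-2..-6", "-6..-12", "-12..-18", "<=-18")
RATE_LABELS = ("slow", "medium", "fast")
VA_LABELS = ("<0.3", "0.3-0.5", ">0.5")
SEX_LABELS = ("female", "male", "other")
PROGRESSION_LABELS = ("yes", "no", "cannot-be-assessed", "no-prior-tests")
TREATMENT_LABELS = ("none", "medication", "laser", "surgery")
QOL_LABELS = ("total-score", "vision-score", "responders")

EYE_RULES = ("better", "worse", "right", "left", "both")


@dataclass
class Cell:
    """One distribution cell: label, underlying count, one-decimal percent."""

    label: str
    count: Optional[int]
    pct: Optional[float]
    suppressed: bool = False


@dataclass
class Section:
    """One report distribution with its denominator; ``recorded=False``
    marks a section the contributing site does not collect ("NR")."""

    name: str
    n: int
    cells: list[Cell]
    recorded: bool = True


@dataclass
class BenchmarkReport:
    metadata: dict
    sections: dict[str, Section]
    schema_version: str = SCHEMA_VERSION


@dataclass(frozen=True)
class BenchmarkFilter:
    """Conjunctive subgroup filter mirroring the planned platform queries.

    All specified clauses must hold; ``None`` means no restriction.  Within
    the ``treatments`` clause any listed treatment (or procedure subtype,
    e.g. ``SLT``) qualifies.
    """

    time_period: Optional[tuple[int, int]] = None
    eye_rule: Optional[str] = None
    risk_factors: Optional[frozenset[str]] = None
    diagnoses: Optional[frozenset[str]] = None
    va_min: Optional[float] = None
    md_groups: Optional[frozenset[int]] = None
    treatments: Optional[frozenset[str]] = None
    age_groups: Optional[frozenset[int]] = None
    iop_groups: Optional[frozenset[int]] = None

    def validate(self) -> None:
        if self.eye_rule is not None and self.eye_rule not in EYE_RULES:
            raise ConfigurationError(f"eye_rule must be one of {EYE_RULES}")
        if self.diagnoses is not None:
            unknown = set(self.diagnoses) - set(DIAGNOSES)
            if unknown:
                raise ConfigurationError(f"unknown diagnosis code(s): {sorted(unknown)}")
        for name in ("risk_factors", "diagnoses", "md_groups", "treatments",
                     "age_groups", "iop_groups"):
            value = getattr(self, name)
            if value is not None and len(value) == 0:
                raise ConfigurationError(f"filter clause {name} must be non-empty")


def _patient_treatments(patient: PatientRecord) -> set[str]:
    treatments: set[str] = set()
    if any(v.medications for _, v in patient.all_visits()):
        treatments.add("medication")
    for proc in patient.procedures:
        treatments.add(proc.kind)
        if proc.subtype:
            treatments.add(proc.subtype.lower())
    return treatments


def _baseline_va(patient: PatientRecord, eye: str, onset_year: Optional[int]):
    series = patient.eye(eye)
    if series is None:
        return None
    visits = series.visits
    if onset_year is not None:
        in_year = [v for v in visits if v.visit_date.year == onset_year]
        visits = in_year or visits
    return visits[0].va_raw


def _va_numeric(va) -> Optional[float]:
    """Snellen decimal equivalent; low-vision categories count as 0.01."""
    if va is None:
        return None
    if isinstance(va, str):
        return 0.01
    return float(va)


def apply_filter(
    cohort: Cohort,
    results: Sequence[ProgressionResult],
    flt: BenchmarkFilter,
) -> list[ProgressionResult]:
    """Return the per-eye results satisfying every filter clause."""
    flt.validate()
    patients = {p.patient_id: p for p in cohort.patients}
    out: list[ProgressionResult] = []
    if flt.time_period is not None and cohort.onset_year is not None:
        lo, hi = flt.time_period
        if not lo <= cohort.onset_year <= hi:
            return []
    for r in results:
        patient = patients.get(r.patient_id)
        if patient is None:
            continue
        if flt.eye_rule in ("better", "worse") and r.designation != flt.eye_rule:
            continue
        if flt.eye_rule in ("right", "left") and r.eye != flt.eye_rule:
            continue
        if flt.risk_factors is not None and not flt.risk_factors <= patient.risk_factors:
            continue
        if flt.diagnoses is not None and patient.diagnosis not in flt.diagnoses:
            continue
        if flt.va_min is not None:
            va = _va_numeric(_baseline_va(patient, r.eye, cohort.onset_year))
            if va is None or va < flt.va_min:
                continue
        if flt.md_groups is not None and r.severity_group not in flt.md_groups:
            continue
        if flt.age_groups is not None and r.age_group not in flt.age_groups:
            continue
        if flt.iop_groups is not None and r.iop_group not in flt.iop_groups:
            continue
        if flt.treatments is not None:
            have = {t.lower() for t in _patient_treatments(patient)}
            want = {t.lower() for t in flt.treatments}
            if not want & have:
                continue
        out.append(r)
    return out


def _distribution(name: str, labels: Sequence[str], counts: Mapping[str, int],
                  n: int) -> Section:
    cells = []
    for label in labels:
        count = int(counts.get(label, 0))
        pct = round(100.0 * count / n, 1) if n > 0 else None
        cells.append(Cell(label=label, count=count, pct=pct))
    return Section(name=name, n=n, cells=cells, recorded=n > 0)


def _not_recorded(name: str, labels: Sequence[str]) -> Section:
    cells = [Cell(label=label, count=None, pct=None) for label in labels]
    return Section(name=name, n=0, cells=cells, recorded=False)


def _tally(values: Iterable) -> dict:
    counts: dict = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return counts


def build_report(
    results: Sequence[ProgressionResult],
    cohort: Cohort,
    *,
    metadata: Optional[Mapping] = None,
    cost_per_patient_year: Optional[float] = None,
    clinical_progression_counts: Optional[Mapping[str, int]] = None,
) -> BenchmarkReport:
    """Aggregate per-eye progression results into the master-protocol report.

    Distributions a site does not record (here: clinical progression labels
    unless supplied, quality of life) are emitted as not-recorded sections,
    mirroring the "NR" convention of cross-study summary tables.
    """
    patients = {p.patient_id: p for p in cohort.patients}
    by_patient: dict[str, list[ProgressionResult]] = {}
    for r in results:
        by_patient.setdefault(r.patient_id, []).append(r)
    n_eyes = len(results)
    n_patients = len(by_patient)
    total = len(cohort.patients)

    meta = dict(metadata or {})
    meta.setdefault("site", cohort.provenance or "unspecified")
    meta.setdefault("onset_year", cohort.onset_year)
    meta["counts"] = {
        "total_patients": total,
        "fulfilling_criteria": n_patients,
        "proportion_pct": round(100.0 * n_patients / total, 1) if total else None,
        "eyes_analysed": n_eyes,
    }
    meta["cost_per_patient_year"] = (
        round(float(cost_per_patient_year), 1)
        if cost_per_patient_year is not None else "NR")

    sections: dict[str, Section] = {}

    def add(section: Section) -> None:
        sections[section.name] = section

    first_result = {pid: rs[0] for pid, rs in by_patient.items()}
    age_counts = _tally(AGE_LABELS[r.age_group - 1]
                        for r in first_result.values() if r.age_group)
    add(_distribution("age_groups", AGE_LABELS, age_counts,
                      sum(age_counts.values())))

    sex_counts = _tally(patients[pid].sex for pid in by_patient)
    add(_distribution("sex", SEX_LABELS, sex_counts, n_patients))

    dx_counts = _tally(patients[pid].diagnosis for pid in by_patient)
    add(_distribution("diagnosis", DIAGNOSES, dx_counts, n_patients))

    # Acuity bands on the better-seeing eye (higher Snellen equivalent).
    va_counts: dict[str, int] = {}
    n_va = 0
    for pid in by_patient:
        patient = patients[pid]
        values = [
            _va_numeric(_baseline_va(patient, s.eye, cohort.onset_year))
            for s in patient.eyes
        ]
        values = [v for v in values if v is not None]
        if not values:
            continue
        best = max(values)
        band = "<0.3" if best < 0.3 else ("0.3-0.5" if best <= 0.5 else ">0.5")
        va_counts[band] = va_counts.get(band, 0) + 1
        n_va += 1
    add(_distribution("va_bands", VA_LABELS, va_counts, n_va))

    iop_counts = _tally(IOP_LABELS[r.iop_group - 1] for r in results if r.iop_group)
    add(_distribution("iop_groups", IOP_LABELS, iop_counts,
                      sum(iop_counts.values())))

    sev_counts = _tally(SEVERITY_LABELS[r.severity_group - 1] for r in results)
    add(_distribution("md_severity", SEVERITY_LABELS, sev_counts, n_eyes))

    rate_all = _tally(r.rate_category for r in results)
    add(_distribution("rate_pooled", RATE_LABELS, rate_all, n_eyes))
    for designation in ("better", "worse"):
        sub = [r for r in results if r.designation == designation]
        add(_distribution(f"rate_{designation}", RATE_LABELS,
                          _tally(r.rate_category for r in sub), len(sub)))

    if clinical_progression_counts is not None:
        add(_distribution("clinical_progression", PROGRESSION_LABELS,
                          dict(clinical_progression_counts),
                          sum(clinical_progression_counts.values())))
    else:
        add(_not_recorded("clinical_progression", PROGRESSION_LABELS))

    # Mutually exclusive treatment intensity so the distribution sums to 100.
    treatment_counts: dict[str, int] = {}
    for pid in by_patient:
        have = _patient_treatments(patients[pid])
        if "surgery" in have:
            label = "surgery"
        elif "laser" in have:
            label = "laser"
        elif "medication" in have:
            label = "medication"
        else:
            label = "none"
        treatment_counts[label] = treatment_counts.get(label, 0) + 1
    add(_distribution("treatment", TREATMENT_LABELS, treatment_counts, n_patients))

    # Schema reserves quality-of-life fields; no instrument is computed.
    add(_not_recorded("quality_of_life", QOL_LABELS))

    return BenchmarkReport(metadata=meta, sections=sections)


def suppress_small_cells(report: BenchmarkReport, min_cell: int = 5) -> BenchmarkReport:
    """Mask cells whose underlying count is in (0, min_cell).

    Returns a new report; totals and unsuppressed cells are unchanged and
    the operation is idempotent (already-masked cells carry no count).
    """
    masked = copy.deepcopy(report)
    for section in masked.sections.values():
        for cell in section.cells:
            if cell.count is not None and 0 < cell.count < min_cell:
                cell.count = None
                cell.pct = None
                cell.suppressed = True
    return masked


def compare_reports(a: BenchmarkReport, b: BenchmarkReport) -> dict:
    """Side-by-side comparison document with signed percentage differences.

    Sections recorded in only one report are flagged ``NR``; swapping the
    arguments negates every signed difference.
    """
    if a.schema_version != b.schema_version:
        raise SchemaVersionError(
            f"schema mismatch: {a.schema_version} vs {b.schema_version}")
    comparison: dict = {
        "schema_version": a.schema_version,
        "metadata": {"a": a.metadata, "b": b.metadata},
        "sections": {},
    }
    names = list(a.sections) + [n for n in b.sections if n not in a.sections]
    for name in names:
        sa = a.sections.get(name)
        sb = b.sections.get(name)
        recorded_a = sa is not None and sa.recorded
        recorded_b = sb is not None and sb.recorded
        if not (recorded_a and recorded_b):
            status = "NR" if not (recorded_a or recorded_b) else (
                "only_a" if recorded_a else "only_b")
            comparison["sections"][name] = {"status": status, "cells": []}
            continue
        cells = []
        labels_b = {c.label: c for c in sb.cells}
        for ca in sa.cells:
            cb = labels_b.get(ca.label)
            pct_a = ca.pct if not ca.suppressed else None
            pct_b = cb.pct if (cb is not None and not cb.suppressed) else None
            diff = (round(pct_a - pct_b, 1)
                    if pct_a is not None and pct_b is not None else None)
            cells.append({
                "label": ca.label,
                "pct_a": pct_a,
                "pct_b": pct_b,
                "diff": diff,
                "abs_diff": abs(diff) if diff is not None else None,
            })
        comparison["sections"][name] = {"status": "shared", "cells": cells}
    return comparison


# --------------------------------------------------------------------------
# Serialization

def report_to_json(report: BenchmarkReport) -> str:
    payload = {
        "schema_version": report.schema_version,
        "metadata": report.metadata,
        "sections": {
            name: {
                "n": section.n,
                "recorded": section.recorded,
                "cells": [
                    {"label": c.label, "count": c.count, "pct": c.pct,
                     "suppressed": c.suppressed}
                    for c in section.cells
                ],
            }
            for name, section in report.sections.items()
        },
    }
    return json.dumps(payload, indent=2, ensure_ascii=False, sort_keys=False)


def report_from_json(text: str) -> BenchmarkReport:
    payload = json.loads(text)
    sections = {
        name: Section(
            name=name,
            n=raw["n"],
            recorded=raw["recorded"],
            cells=[Cell(label=c["label"], count=c["count"], pct=c["pct"],
                        suppressed=c["suppressed"]) for c in raw["cells"]],
        )
        for name, raw in payload["sections"].items()
    }
    return BenchmarkReport(metadata=payload["metadata"], sections=sections,
                           schema_version=payload["schema_version"])


def report_to_table(report: BenchmarkReport, *, delimiter: str = ",") -> str:
    """Human-readable delimited rendering, integer percentages."""
    lines = [delimiter.join(("section", "label", "count", "pct"))]
    for name, section in report.sections.items():
        for cell in section.cells:
            if not section.recorded:
                count = pct = "NR"
            elif cell.suppressed:
                count = pct = "<suppressed>"
            else:
                count = str(cell.count) if cell.count is not None else ""
                pct = str(round_half_away(cell.pct)) if cell.pct is not None else ""
            lines.append(delimiter.join((name, cell.label, count, pct)))
    return "\n".join(lines) + "\n"


def serialize_report(report: BenchmarkReport) -> tuple[str, str]:
    """Return loss-free JSON and a delimited table rendering."""
    return report_to_json(report), report_to_table(report)
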