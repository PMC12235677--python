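"""Domain model for longitudinal glaucoma follow-up records.

The in-memory containers mirror how glaucoma clinics record routine care: a
patient carries demographics, a diagnosis, procedure events, and one
time-ordered series of visits per eye.  Each visit holds the Humphrey
visual-field mean deviation (MD, dB; more negative = worse), the perimetric
false-positive reliability index, intraocular pressure (IOP, mmHg), visual
acuity (Snellen decimal or a low-vision category), and the medication count.

Tabular I/O uses a documented one-row-per-eye-visit delimited dialect
(UTF-8, header row mandatory, comma by default); patient-level fields are
repeated on every row of that patient.  Canonical column names::

    patient_id, eye, visit_date, md_db, fp_pct, iop_mmhg, va_snellen,
    va_category, n_meds, sex, birth_date, age_at_onset, diagnosis,
    risk_factors, procedures, death_date, moved_date

``risk_factors`` is a ``;``-joined flag list; ``procedures`` is a
``;``-joined list of ``date:kind`` or ``date:kind:subtype`` tokens.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from ._util import round_half_away
from .errors import CohortValidationError, ConfigurationError, RowError

__all__ = [
    "MD_MIN", "MD_MAX", "EYES", "SEXES", "DIAGNOSES", "VA_CATEGORY_LETTERS",
    "snellen_to_etdrs", "EyeVisit", "EyeSeries", "Procedure",
    "PatientRecord", "Cohort", "read_cohort", "write_cohort",
]

#: Plausibility window for MD after validation (instrument-scale bound).
MD_MIN = -35.0
MD_MAX = 5.0

EYES = ("right", "left")
SEXES = ("female", "male", "other")

#: Diagnosis vocabulary (clinic categories; ``other`` covers other/missing).
DIAGNOSES = (
    "oht_suspect",   # ocular hypertension or glaucoma suspect
    "poag",          # primary open-angle glaucoma
    "ntg",           # normal tension glaucoma
    "pex",           # pseudoexfoliation glaucoma
    "secondary",
    "pigmentary",
    "pacg",          # primary angle-closure glaucoma
    "mixed",         # mixed diagnosis between eyes
    "other",
)

#: ETDRS letter scores recorded for off-chart low-vision categories.
VA_CATEGORY_LETTERS = {
    "finger-counting": 3,
    "hand-movement": 2,
    "light-perception": 1,
}

DAYS_PER_YEAR = 365.25


def snellen_to_etdrs(va: Union[float, str]) -> int:
    """Convert visual acuity to an ETDRS letter score in [0, 100].

    Decimal Snellen fractions use ``letters = 85 + 50*log10(fraction)``
    (the logMAR-chart relation), rounded half away from zero and clipped to
    the chart range.  Off-chart categories map to fixed scores:
    finger-counting 3, hand-movement 2, light-perception 1.

    Raises
    ------
    ValueError
        If the fraction is not positive or the category is unknown.
    """
    if isinstance(va, str):
        try:
            return VA_CATEGORY_LETTERS[va]
        except KeyError:
            raise ValueError(f"unknown acuity category: {va!r}") from None
    fraction = float(va)
    if fraction <= 0:
        raise ValueError("Snellen fraction must be positive")
    letters = 85.0 + 50.0 * math.log10(fraction)
    return max(0, min(100, round_half_away(letters)))


@dataclass(frozen=True)
class Procedure:
    """One glaucoma-related procedure event."""

    date: date
    kind: str                      # "laser" or "surgery"
    subtype: Optional[str] = None  # e.g. "SLT", "trabeculectomy"

    def validate(self) -> None:
        if self.kind not in ("laser", "surgery"):
            raise ValueError(f"procedure kind must be laser/surgery, got {self.kind!r}")


@dataclass(frozen=True)
class EyeVisit:
    """One clinical encounter measurement for one eye."""

    visit_date: date
    md: float
    false_positive_rate: float
    iop: Optional[float] = None
    va_raw: Union[float, str, None] = None
    va_etdrs: Optional[int] = None
    medications: Optional[int] = None

    def validate(self) -> None:
        if not (MD_MIN <= self.md <= MD_MAX):
            raise ValueError(f"MD {self.md} dB outside [{MD_MIN}, {MD_MAX}]")
        if not (0.0 <= self.false_positive_rate <= 100.0):
            raise ValueError(f"false-positive rate {self.false_positive_rate} outside [0, 100]")
        if self.iop is not None and self.iop < 0:
            raise ValueError(f"negative IOP {self.iop}")
        if self.medications is not None and self.medications < 0:
            raise ValueError(f"negative medication count {self.medications}")
        if isinstance(self.va_raw, str) and self.va_raw not in VA_CATEGORY_LETTERS:
            raise ValueError(f"unknown acuity category {self.va_raw!r}")
        if isinstance(self.va_raw, (int, float)) and not 0 < float(self.va_raw) <= 2:
            raise ValueError(f"Snellen fraction {self.va_raw} outside (0, 2]")
        if self.va_etdrs is not None:
            if not (0 <= self.va_etdrs <= 100):
                raise ValueError(f"ETDRS letters {self.va_etdrs} outside [0, 100]")
            if self.va_raw is not None and self.va_etdrs != snellen_to_etdrs(self.va_raw):
                raise ValueError(
                    f"ETDRS letters {self.va_etdrs} inconsistent with acuity {self.va_raw!r}"
                )


@dataclass
class EyeSeries:
    """Time-ordered visit series for one eye (dates strictly increasing)."""

    eye: str
    visits: list[EyeVisit]

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}, got {self.eye!r}")
        if not self.visits:
            raise ValueError("eye series needs at least one visit")
        for prev, nxt in zip(self.visits, self.visits[1:]):
            if nxt.visit_date <= prev.visit_date:
                raise ValueError(
                    f"{self.eye} eye visits not strictly increasing at {nxt.visit_date}"
                )

    def validate(self) -> None:
        for v in self.visits:
            v.validate()

    def visits_in_year(self, year: int) -> list[EyeVisit]:
        return [v for v in self.visits if v.visit_date.year == year]


@dataclass
class PatientRecord:
    """Demographics, diagnosis, procedures, and up to two eye series."""

    patient_id: str
    sex: str = "other"
    diagnosis: str = "other"
    birth_date: Optional[date] = None
    age_at_onset: Optional[float] = None
    risk_factors: frozenset[str] = frozenset()
    eyes: list[EyeSeries] = field(default_factory=list)
    procedures: list[Procedure] = field(default_factory=list)
    death_date: Optional[date] = None
    moved_date: Optional[date] = None

    def eye(self, laterality: str) -> Optional[EyeSeries]:
        for series in self.eyes:
            if series.eye == laterality:
                return series
        return None

    def all_visits(self) -> Iterator[tuple[str, EyeVisit]]:
        for series in self.eyes:
            for visit in series.visits:
                yield series.eye, visit

    def age_on(self, when: date, onset_year: Optional[int] = None) -> Optional[float]:
        """Age in fractional years on ``when``; None if unknowable."""
        if self.birth_date is not None:
            return (when - self.birth_date).days / DAYS_PER_YEAR
        if self.age_at_onset is not None and onset_year is not None:
            return self.age_at_onset + (when.year - onset_year)
        return None

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        lateralities = [s.eye for s in self.eyes]
        if len(lateralities) != len(set(lateralities)):
            raise ValueError(f"patient {self.patient_id}: duplicate eye series")
        for series in self.eyes:
            series.validate()
            if self.birth_date is not None:
                for v in series.visits:
                    if v.visit_date < self.birth_date:
                        raise ValueError(
                            f"patient {self.patient_id}: visit {v.visit_date} before birth"
                        )
        for p in self.procedures:
            p.validate()


@dataclass
class Cohort:
    """A set of patients observed from a common onset year."""

    patients: list[PatientRecord]
    onset_year: Optional[int] = None
    provenance: str = ""
    rejected: list[RowError] = field(default_factory=list, compare=False, repr=False)

    def validate(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate patient ids in cohort")
        for p in self.patients:
            p.validate()

    def n_visits(self) -> int:
        return sum(len(s.visits) for p in self.patients for s in p.eyes)


# --------------------------------------------------------------------------
# Tabular I/O

COLUMNS = (
    "patient_id", "eye", "visit_date", "md_db", "fp_pct", "iop_mmhg",
    "va_snellen", "va_category", "n_meds", "sex", "birth_date",
    "age_at_onset", "diagnosis", "risk_factors", "procedures",
    "death_date", "moved_date",
)
REQUIRED_COLUMNS = ("patient_id", "eye", "visit_date", "md_db", "fp_pct")


def _load_format_config(format_config) -> tuple[dict, str]:
    """Return (source->canonical column map, delimiter)."""
    if format_config is None:
        return {}, ","
    if isinstance(format_config, (str, Path)):
        text = Path(format_config).read_text(encoding="utf-8")
        format_config = yaml.safe_load(text) or {}
    if not isinstance(format_config, Mapping):
        raise ConfigurationError("format_config must be a mapping or a YAML/JSON path")
    columns = dict(format_config.get("columns", {}))
    for canonical in columns.values():
        if canonical not in COLUMNS:
            raise ConfigurationError(f"unknown canonical column {canonical!r}")
    return columns, format_config.get("delimiter", ",")


def _parse_date(text: str, what: str) -> Optional[date]:
    if text == "":
        return None
    try:
        return date.fromisoformat(text)
    except ValueError:
        raise ValueError(f"unparseable {what} {text!r}") from None


def _parse_float(text: str, what: str) -> Optional[float]:
    if text == "":
        return None
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"unparseable {what} {text!r}") from None


def _parse_procedures(text: str) -> list[Procedure]:
    procedures = []
    for token in filter(None, text.split(";")):
        parts = token.split(":")
        if len(parts) not in (2, 3):
            raise ValueError(f"unparseable procedure token {token!r}")
        when = _parse_date(parts[0], "procedure date")
        subtype = parts[2] if len(parts) == 3 else None
        procedures.append(Procedure(date=when, kind=parts[1], subtype=subtype))
    return procedures


def read_cohort(
    path,
    format_config=None,
    *,
    strict: bool = True,
    onset_year: Optional[int] = None,
) -> Cohort:
    """Read a cohort from the one-row-per-eye-visit delimited dialect.

    ``format_config`` may be a mapping (or YAML/JSON file path) with keys
    ``columns`` (source name -> canonical name) and ``delimiter``.

    Rows failing validation are collected with their 0-based data-row index;
    with ``strict=True`` (default) a :class:`CohortValidationError` listing
    them is raised, otherwise the offending rows are skipped and reported on
    the returned cohort's ``rejected`` attribute.  Input values are never
    mutated.
    """
    column_map, delimiter = _load_format_config(format_config)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                     encoding="utf-8")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {', '.join(missing)}")

    def cell(row, name: str) -> str:
        return str(getattr(row, name)).strip() if name in df.columns else ""

    errors: list[RowError] = []
    patient_rows: dict[str, dict] = {}
    # (patient_id, eye) -> list of (row index, EyeVisit)
    series_rows: dict[tuple[str, str], list[tuple[int, EyeVisit]]] = {}

    for i, row in enumerate(df.itertuples(index=False)):
        try:
            pid = cell(row, "patient_id")
            if not pid:
                raise ValueError("empty patient_id")
            eye = cell(row, "eye")
            if eye not in EYES:
                raise ValueError(f"eye must be one of {EYES}, got {eye!r}")
            visit_date = _parse_date(cell(row, "visit_date"), "visit_date")
            if visit_date is None:
                raise ValueError("missing visit_date")
            md = _parse_float(cell(row, "md_db"), "md_db")
            if md is None:
                raise ValueError("missing md_db")
            fp = _parse_float(cell(row, "fp_pct"), "fp_pct")
            if fp is None:
                raise ValueError("missing fp_pct")
            va_raw: Union[float, str, None] = _parse_float(cell(row, "va_snellen"), "va_snellen")
            if va_raw is None and cell(row, "va_category"):
                va_raw = cell(row, "va_category")
            n_meds_text = cell(row, "n_meds")
            visit = EyeVisit(
                visit_date=visit_date,
                md=md,
                false_positive_rate=fp,
                iop=_parse_float(cell(row, "iop_mmhg"), "iop_mmhg"),
                va_raw=va_raw,
                va_etdrs=snellen_to_etdrs(va_raw) if va_raw is not None else None,
                medications=int(n_meds_text) if n_meds_text else None,
            )
            visit.validate()

            if pid not in patient_rows:
                patient_rows[pid] = {
                    "sex": cell(row, "sex") or "other",
                    "diagnosis": cell(row, "diagnosis") or "other",
                    "birth_date": _parse_date(cell(row, "birth_date"), "birth_date"),
                    "age_at_onset": _parse_float(cell(row, "age_at_onset"), "age_at_onset"),
                    "risk_factors": frozenset(filter(None, cell(row, "risk_factors").split(";"))),
                    "procedures": _parse_procedures(cell(row, "procedures")),
                    "death_date": _parse_date(cell(row, "death_date"), "death_date"),
                    "moved_date": _parse_date(cell(row, "moved_date"), "moved_date"),
                }
            birth = patient_rows[pid]["birth_date"]
            if birth is not None and visit_date < birth:
                raise ValueError(f"visit {visit_date} before birth {birth}")
            series_rows.setdefault((pid, eye), []).append((i, visit))
        except ValueError as exc:
            errors.append(RowError(row=i, message=str(exc)))

    # Assemble, flagging duplicate visit dates within an eye.
    patients: list[PatientRecord] = []
    for pid, info in patient_rows.items():
        eyes: list[EyeSeries] = []
        for laterality in EYES:
            entries = series_rows.get((pid, laterality))
            if not entries:
                continue
            entries.sort(key=lambda e: e[1].visit_date)
            kept: list[tuple[int, EyeVisit]] = []
            for idx, visit in entries:
                if kept and visit.visit_date == kept[-1][1].visit_date:
                    errors.append(RowError(row=idx, message=(
                        f"duplicate visit date {visit.visit_date} for patient "
                        f"{pid!r} {laterality} eye")))
                    continue
                kept.append((idx, visit))
            if kept:
                eyes.append(EyeSeries(eye=laterality, visits=[v for _, v in kept]))
        if not eyes:
            continue
        patients.append(PatientRecord(
            patient_id=pid,
            sex=info["sex"],
            diagnosis=info["diagnosis"],
            birth_date=info["birth_date"],
            age_at_onset=info["age_at_onset"],
            risk_factors=info["risk_factors"],
            eyes=eyes,
            procedures=info["procedures"],
            death_date=info["death_date"],
            moved_date=info["moved_date"],
        ))

    if errors and strict:
        raise CohortValidationError(errors)

    if onset_year is None:
        years = [v.visit_date.year for p in patients for _, v in p.all_visits()]
        onset_year = min(years) if years else None
    cohort = Cohort(patients=patients, onset_year=onset_year,
                    provenance=str(path), rejected=errors)
    cohort.validate()
    return cohort


def _format_number(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def write_cohort(cohort: Cohort, path, *, delimiter: str = ",") -> None:
    """Write a cohort in the documented dialect; :func:`read_cohort` inverts it."""
    cohort.validate()
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(COLUMNS)
        for patient in cohort.patients:
            procedures = ";".join(
                ":".join(filter(None, (p.date.isoformat(), p.kind, p.subtype)))
                for p in sorted(patient.procedures, key=lambda p: p.date)
            )
            risk_factors = ";".join(sorted(patient.risk_factors))
            for series in patient.eyes:
                for visit in series.visits:
                    snellen = visit.va_raw if isinstance(visit.va_raw, (int, float)) else None
                    category = visit.va_raw if isinstance(visit.va_raw, str) else None
                    writer.writerow([
                        patient.patient_id,
                        series.eye,
                        visit.visit_date.isoformat(),
                        _format_number(visit.md),
                        _format_number(visit.false_positive_rate),
                        _format_number(visit.iop),
                        _format_number(snellen),
                        category or "",
                        _format_number(visit.medications),
                        patient.sex,
                        patient.birth_date.isoformat() if patient.birth_date else "",
                        _format_number(patient.age_at_onset),
                        patient.diagnosis,
                        risk_factors,
                        procedures,
                        patient.death_date.isoformat() if patient.death_date else "",
                        patient.moved_date.isoformat() if patient.moved_date else "",
                    ])
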