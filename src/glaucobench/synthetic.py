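"""Synthetic longitudinal glaucoma cohorts with known ground truth.

The generator emulates the structure of a routine-care university-clinic
cohort followed from a fixed onset year: ages near 68 (SD 11), about two
thirds female, the clinic's diagnosis mix, two per-patient correlated
baseline MDs drawn from a severity mixture, linear true MD trajectories
with a slow/medium/fast rate mixture, Gaussian test-retest noise, an
instrument floor that truncates measurements in advanced loss, a 2-yearly
visit schedule plus the final-year visit, and yearly attrition from death
and unexplained no-shows.

Attrition probabilities are interpreted as per-year fractions of the onset
cohort (period accounting, the way clinic-level registries count prevalent
patients), not as hazards among survivors; ``generate_cohort`` therefore
reproduces the familiar "rate x years" headline fractions.  Ground truth
(true slopes, true rate/severity classes, exit year and cause) is returned
alongside the cohort for parameter-recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .cohort import (Cohort, EyeSeries, EyeVisit, PatientRecord, Procedure,
                     snellen_to_etdrs)
from .errors import ConfigurationError
from .progression import classify_rate, classify_severity

__all__ = [
    "SyntheticConfig", "TrueEye", "PatientFate", "GroundTruth",
    "generate_cohort", "summarize_truth", "attrition_fractions",
]

EYE_ORDER = ("right", "left")   # right eye is examined (and written) first

#: Clinic diagnosis mix (percent, normalized on use).
DIAGNOSIS_WEIGHTS = {
    "oht_suspect": 9.2,
    "poag": 43.0,
    "ntg": 18.0,
    "pex": 12.0,
    "secondary": 2.4,
    "other": 7.8,
    "pigmentary": 1.4,
    "pacg": 4.4,
    "mixed": 2.9,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate the reference clinic cohort."""

    n_patients: int = 200
    seed: int = 0
    onset_year: int = 2012
    followup_years: int = 5
    visit_years: tuple[int, ...] = (0, 2, 4, 5)   # 2-yearly recall + final year

    age_mean: float = 68.0
    age_sd: float = 11.0
    age_range: tuple[float, float] = (18.0, 99.0)
    female_frac: float = 0.64

    # Baseline MD mixture: per-severity-group weights and (lo, hi] supports,
    # calibrated so the overall median sits near -3 dB.
    severity_weights: tuple[float, ...] = (0.40, 0.33, 0.17, 0.07, 0.03)
    severity_intervals: tuple[tuple[float, float], ...] = (
        (-2.0, 2.0), (-6.0, -2.0), (-12.0, -6.0), (-18.0, -12.0), (-28.0, -18.0))
    inter_eye_md_corr: float = 0.5

    # Worsening-rate mixture (slow, medium, fast) in dB/year.
    rate_weights: tuple[float, float, float] = (0.77, 0.17, 0.06)
    age_slope_coeff: float = 0.0   # extra dB/year of worsening per decade over 68
    slope_floor: float = -0.3      # eyes do not systematically improve past this

    md_noise_sd: float = 1.0       # dB per test (SITA test-retest scale)
    md_floor: float = -30.0        # instrument floor applied to measurements

    iop_mean: float = 15.5
    iop_sd: float = 3.0

    annual_death_prob: float = 0.04
    annual_noshow_prob: float = 0.02
    single_eye_prob: float = 0.003

    laser_prob: float = 0.10
    surgery_prob: float = 0.08

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be non-negative")
        for name in ("female_frac", "inter_eye_md_corr", "annual_death_prob",
                     "annual_noshow_prob", "single_eye_prob", "laser_prob",
                     "surgery_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.md_noise_sd < 0:
            raise ConfigurationError("md_noise_sd must be >= 0")
        if abs(sum(self.severity_weights) - 1.0) > 1e-9:
            raise ConfigurationError("severity_weights must sum to 1")
        if abs(sum(self.rate_weights) - 1.0) > 1e-9:
            raise ConfigurationError("rate_weights must sum to 1")
        if len(self.severity_weights) != len(self.severity_intervals):
            raise ConfigurationError("severity weights/intervals length mismatch")
        horizon = self.followup_years + 1
        if horizon * (self.annual_death_prob + self.annual_noshow_prob) > 1.0:
            raise ConfigurationError(
                "attrition probabilities exceed 1 over the follow-up horizon")
        if self.followup_years not in self.visit_years:
            raise ConfigurationError("visit schedule must include the final year")
        if 0 not in self.visit_years:
            raise ConfigurationError("visit schedule must include the onset year")


@dataclass(frozen=True)
class TrueEye:
    patient_id: str
    eye: str
    true_slope: float          # dB/year of worsening (positive = loss)
    true_rate_class: str
    true_severity_group: int


@dataclass(frozen=True)
class PatientFate:
    death_year: Optional[int] = None     # years after onset, 1-based
    dropout_year: Optional[int] = None


@dataclass
class GroundTruth:
    eyes: list[TrueEye]
    fates: dict[str, PatientFate]
    horizon_years: int


def _mixture_ppf(u: float, weights: Sequence[float],
                 intervals: Sequence[tuple[float, float]]) -> float:
    """Inverse CDF of the severity mixture; u=0 maps to the best MD."""
    acc = 0.0
    last = len(weights) - 1
    for k, (w, (lo, hi)) in enumerate(zip(weights, intervals)):
        if u <= acc + w or k == last:
            frac = (u - acc) / w if w > 0 else 0.0
            return hi - min(max(frac, 0.0), 1.0) * (hi - lo)
        acc += w
    raise AssertionError("unreachable")


def _draw_rate(rng: np.random.Generator, cls: str, cfg: SyntheticConfig) -> float:
    if cls == "slow":
        return float(np.clip(rng.normal(0.1, 0.15), cfg.slope_floor, 0.45))
    if cls == "medium":
        return float(rng.uniform(0.5, 1.5))
    return float(1.5 + rng.exponential(0.5))


def _draw_exit(rng: np.random.Generator, cfg: SyntheticConfig) -> PatientFate:
    """Exit year and cause under period accounting of annual probabilities."""
    horizon = cfg.followup_years + 1
    step = cfg.annual_death_prob + cfg.annual_noshow_prob
    u = rng.random()
    if step == 0 or u >= horizon * step:
        return PatientFate()
    year = int(u // step) + 1
    if u - (year - 1) * step < cfg.annual_death_prob:
        return PatientFate(death_year=year)
    return PatientFate(dropout_year=year)


def _visit_day(rng: np.random.Generator, year: int) -> date:
    return date(year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort and its ground truth; deterministic under the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    dx_names = list(DIAGNOSIS_WEIGHTS)
    dx_probs = np.array([DIAGNOSIS_WEIGHTS[n] for n in dx_names])
    dx_probs = dx_probs / dx_probs.sum()
    rate_classes = ("slow", "medium", "fast")
    rho = config.inter_eye_md_corr

    patients: list[PatientRecord] = []
    true_eyes: list[TrueEye] = []
    fates: dict[str, PatientFate] = {}

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        # Truncated-normal age at onset.
        while True:
            age = rng.normal(config.age_mean, config.age_sd)
            if config.age_range[0] <= age <= config.age_range[1]:
                break
        sex = "female" if rng.random() < config.female_frac else "male"
        diagnosis = str(rng.choice(dx_names, p=dx_probs))
        birth = date(config.onset_year - int(age), 1, 1)

        risk = set()
        if diagnosis == "pex" or rng.random() < 0.05:
            risk.add("exfoliation")
        if rng.random() < 0.15:
            risk.add("family_history")

        fate = _draw_exit(rng, config)
        fates[pid] = fate
        exit_year = fate.death_year or fate.dropout_year

        lateralities = list(EYE_ORDER)
        if rng.random() < config.single_eye_prob:
            lateralities = [lateralities[int(rng.integers(0, 2))]]

        # Shared patient-level component induces inter-eye MD correlation.
        z_patient = rng.normal()
        visit_dates = {
            y: _visit_day(rng, config.onset_year + y)
            for y in sorted(config.visit_years)
            if exit_year is None or y < exit_year
        }
        onset_date = visit_dates.get(0, date(config.onset_year, 6, 15))

        n_meds = int(min(rng.poisson(1.3), 6))
        eyes: list[EyeSeries] = []
        for laterality in lateralities:
            z_eye = math.sqrt(rho) * z_patient + math.sqrt(1 - rho) * rng.normal()
            u = float(norm.cdf(z_eye))
            baseline = _mixture_ppf(u, config.severity_weights,
                                    config.severity_intervals)
            cls = str(rng.choice(rate_classes, p=np.asarray(config.rate_weights)))
            slope = _draw_rate(rng, cls, config)
            slope += config.age_slope_coeff * (age - 68.0) / 10.0
            slope = max(slope, config.slope_floor)
            true_eyes.append(TrueEye(
                patient_id=pid, eye=laterality, true_slope=slope,
                true_rate_class=classify_rate(slope),
                true_severity_group=classify_severity(baseline),
            ))

            letters = float(np.clip(rng.normal(76, 14), 1, 100))
            if rng.random() < 0.005:
                va_raw = str(rng.choice(
                    ["finger-counting", "hand-movement", "light-perception"]))
            else:
                va_raw = round(max(0.01, min(2.0, 10 ** ((letters - 85) / 50))), 2)

            visits = []
            for y, when in visit_dates.items():
                t = (when - onset_date).days / 365.25
                md = baseline - slope * t
                if config.md_noise_sd > 0:
                    md += rng.normal(0, config.md_noise_sd)
                md = float(np.clip(md, config.md_floor, 5.0))
                fp = (float(rng.uniform(15, 30)) if rng.random() < 0.05
                      else float(rng.uniform(0, 12)))
                iop = float(max(5.0, rng.normal(config.iop_mean, config.iop_sd)))
                visits.append(EyeVisit(
                    visit_date=when, md=md,
                    false_positive_rate=round(fp, 1),
                    iop=round(iop, 1), va_raw=va_raw,
                    va_etdrs=snellen_to_etdrs(va_raw),
                    medications=n_meds,
                ))
            if visits:
                eyes.append(EyeSeries(eye=laterality, visits=visits))

        procedures: list[Procedure] = []
        last_seen = max(visit_dates) if visit_dates else 0
        if rng.random() < config.laser_prob:
            subtype = "SLT" if rng.random() < 0.7 else "iridotomy"
            procedures.append(Procedure(
                date=_visit_day(rng, config.onset_year + int(rng.integers(0, last_seen + 1))),
                kind="laser", subtype=subtype))
        if rng.random() < config.surgery_prob:
            subtype = "trabeculectomy" if rng.random() < 0.7 else "tube"
            procedures.append(Procedure(
                date=_visit_day(rng, config.onset_year + int(rng.integers(0, last_seen + 1))),
                kind="surgery", subtype=subtype))

        death_date = (date(config.onset_year + fate.death_year, 6, 30)
                      if fate.death_year is not None else None)
        if eyes:
            patients.append(PatientRecord(
                patient_id=pid, sex=sex, diagnosis=diagnosis,
                birth_date=birth, risk_factors=frozenset(risk),
                eyes=eyes, procedures=procedures, death_date=death_date,
            ))

    cohort = Cohort(patients=patients, onset_year=config.onset_year,
                    provenance=f"synthetic(seed={config.seed}, n={config.n_patients})")
    cohort.validate()
    truth = GroundTruth(eyes=true_eyes, fates=fates,
                        horizon_years=config.followup_years + 1)
    return cohort, truth


def summarize_truth(truth: GroundTruth) -> dict:
    """Tallies of true classes in the report's bin structure."""
    rate = {"slow": 0, "medium": 0, "fast": 0}
    severity = {g: 0 for g in range(1, 6)}
    for eye in truth.eyes:
        rate[eye.true_rate_class] += 1
        severity[eye.true_severity_group] += 1
    return {"n_eyes": len(truth.eyes), "rate": rate, "severity": severity}


def attrition_fractions(truth: GroundTruth) -> dict:
    """Percent of the onset cohort that died or was lost within the horizon."""
    n = len(truth.fates)
    deceased = sum(1 for f in truth.fates.values() if f.death_year is not None)
    lost = sum(1 for f in truth.fates.values() if f.dropout_year is not None)
    return {
        "deceased_pct": 100.0 * deceased / n if n else 0.0,
        "lost_pct": 100.0 * lost / n if n else 0.0,
    }
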