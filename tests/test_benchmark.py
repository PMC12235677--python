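"""Report aggregation, filtering, suppression, comparison, serialization."""

from __future__ import annotations

from collections import Counter
from datetime import date

import pytest

from glaucobench.benchmark import (
    BenchmarkFilter, apply_filter, build_report, compare_reports,
    report_from_json, report_to_json, report_to_table, serialize_report,
    suppress_small_cells,
)
from glaucobench.cohort import Cohort, Procedure
from glaucobench.eligibility import EligibilityConfig, apply_exclusions, select_followup
from glaucobench.errors import ConfigurationError, SchemaVersionError
from glaucobench.progression import ProgressionConfig, run_progression
from glaucobench.synthetic import SyntheticConfig, generate_cohort

from conftest import make_patient

ELIG = EligibilityConfig(onset_year=2012)


def pipeline(n=150, seed=8, **cfg):
    cohort, _ = generate_cohort(SyntheticConfig(n_patients=n, seed=seed, **cfg))
    filtered, _ = apply_exclusions(cohort, ELIG)
    selected = select_followup(filtered, ELIG)
    results, _ = run_progression(selected, ProgressionConfig(rng_seed=seed))
    return selected, results


@pytest.fixture(scope="module")
def selected_results():
    return pipeline()


class TestApplyFilter:
    def test_empty_filter_is_identity(self, selected_results):
        cohort, results = selected_results
        assert apply_filter(cohort, results, BenchmarkFilter()) == results

    def test_unknown_diagnosis_rejected(self, selected_results):
        cohort, results = selected_results
        flt = BenchmarkFilter(diagnoses=frozenset({"glaucoma-helsinki"}))
        with pytest.raises(ConfigurationError, match="unknown diagnosis"):
            apply_filter(cohort, results, flt)

    def test_empty_clause_rejected(self, selected_results):
        cohort, results = selected_results
        with pytest.raises(ConfigurationError, match="non-empty"):
            apply_filter(cohort, results, BenchmarkFilter(treatments=frozenset()))

    def test_matches_brute_force_predicate(self):
        """Worse eyes of exfoliation patients with SLT, vs an independent scan."""
        cohort, results = pipeline(n=300, seed=21, laser_prob=0.5)
        flt = BenchmarkFilter(eye_rule="worse",
                              risk_factors=frozenset({"exfoliation"}),
                              treatments=frozenset({"SLT"}))
        out = apply_filter(cohort, results, flt)

        patients = {p.patient_id: p for p in cohort.patients}
        expected = []
        for r in results:
            p = patients[r.patient_id]
            if r.designation != "worse":
                continue
            if "exfoliation" not in p.risk_factors:
                continue
            if not any(proc.subtype == "SLT" for proc in p.procedures):
                continue
            expected.append(r)
        assert out == expected
        assert len(out) > 0

    def test_severity_and_va_clauses(self, selected_results):
        cohort, results = selected_results
        flt = BenchmarkFilter(md_groups=frozenset({1, 2}), va_min=0.5)
        out = apply_filter(cohort, results, flt)
        assert all(r.severity_group in (1, 2) for r in out)
        patients = {p.patient_id: p for p in cohort.patients}
        for r in out:
            series = patients[r.patient_id].eye(r.eye)
            baseline = [v for v in series.visits
                        if v.visit_date.year == 2012][0]
            assert isinstance(baseline.va_raw, float) and baseline.va_raw >= 0.5


class TestBuildReport:
    def test_hand_tally_on_small_cohort(self):
        cohort, results = pipeline(n=20, seed=13)
        report = build_report(results, cohort)

        sev = Counter(r.severity_group for r in results)
        section = report.sections["md_severity"]
        assert section.n == len(results)
        for group, cell in enumerate(section.cells, start=1):
            assert cell.count == sev.get(group, 0)
            assert cell.pct == pytest.approx(100 * sev.get(group, 0) / len(results),
                                             abs=0.051)

        sexes = Counter()
        patients = {p.patient_id: p for p in cohort.patients}
        for pid in {r.patient_id for r in results}:
            sexes[patients[pid].sex] += 1
        got = {c.label: c.count for c in report.sections["sex"].cells}
        assert got["female"] == sexes["female"]
        assert got["male"] == sexes["male"]

    def test_single_patient_distributions_concentrate(self):
        patient = make_patient("P1", right_mds=[-1.0, -1.4], years=[2012, 2017])
        cohort = Cohort(patients=[patient], onset_year=2012)
        results, _ = run_progression(cohort, ProgressionConfig())
        report = build_report(results, cohort)
        for name in ("age_groups", "sex", "diagnosis", "md_severity",
                     "rate_pooled", "va_bands", "iop_groups", "treatment"):
            section = report.sections[name]
            assert section.recorded
            assert sorted(c.pct for c in section.cells)[-1] == 100.0

    def test_rate_bins_consistent_with_classification(self, selected_results):
        cohort, results = selected_results
        report = build_report(results, cohort)
        rates = Counter(r.rate_category for r in results)
        got = {c.label: c.count for c in report.sections["rate_pooled"].cells}
        assert got == {"slow": rates.get("slow", 0), "medium": rates.get("medium", 0),
                       "fast": rates.get("fast", 0)}
        better = Counter(r.rate_category for r in results if r.designation == "better")
        got_b = {c.label: c.count for c in report.sections["rate_better"].cells}
        assert got_b == {k: better.get(k, 0) for k in ("slow", "medium", "fast")}

    def test_distributions_sum_to_100(self, selected_results):
        cohort, results = selected_results
        report = build_report(results, cohort)
        for section in report.sections.values():
            if not section.recorded:
                continue
            total = sum(c.pct for c in section.cells)
            assert total == pytest.approx(100.0, abs=1.0)

    def test_every_percentage_reconstructible(self, selected_results):
        cohort, results = selected_results
        report = build_report(results, cohort)
        for section in report.sections.values():
            if not section.recorded:
                continue
            for cell in section.cells:
                assert cell.pct == pytest.approx(100 * cell.count / section.n,
                                                 abs=0.051)

    def test_unrecorded_sections_marked(self, selected_results):
        cohort, results = selected_results
        report = build_report(results, cohort)
        assert not report.sections["clinical_progression"].recorded
        assert not report.sections["quality_of_life"].recorded
        assert report.metadata["cost_per_patient_year"] == "NR"


class TestSuppression:
    def test_small_cell_masked(self, selected_results):
        cohort, results = selected_results
        report = build_report(results, cohort)
        masked = suppress_small_cells(report, min_cell=5)
        for name, section in masked.sections.items():
            original = report.sections[name]
            assert section.n == original.n           # totals unchanged
            for cell, orig in zip(section.cells, original.cells):
                if orig.count is not None and 0 < orig.count < 5:
                    assert cell.suppressed and cell.count is None and cell.pct is None
                else:
                    assert (cell.count, cell.pct, cell.suppressed) == (
                        orig.count, orig.pct, orig.suppressed)

    def test_min_cell_zero_identity(self, selected_results):
        cohort, results = selected_results
        report = build_report(results, cohort)
        assert suppress_small_cells(report, min_cell=0) == report

    def test_idempotent(self, selected_results):
        cohort, results = selected_results
        report = build_report(results, cohort)
        once = suppress_small_cells(report, min_cell=5)
        assert suppress_small_cells(once, min_cell=5) == once


class TestCompare:
    def test_self_comparison_all_zero(self, selected_results):
        cohort, results = selected_results
        report = build_report(results, cohort)
        comparison = compare_reports(report, report)
        for section in comparison["sections"].values():
            for cell in section["cells"]:
                assert cell["diff"] in (0.0, None)

    def test_antisymmetric(self):
        cohort_a, results_a = pipeline(n=80, seed=31)
        cohort_b, results_b = pipeline(n=80, seed=32)
        a = build_report(results_a, cohort_a)
        b = build_report(results_b, cohort_b)
        ab = compare_reports(a, b)
        ba = compare_reports(b, a)
        for name in ab["sections"]:
            cells_ab = {c["label"]: c for c in ab["sections"][name]["cells"]}
            cells_ba = {c["label"]: c for c in ba["sections"][name]["cells"]}
            for label, cell in cells_ab.items():
                if cell["diff"] is not None:
                    assert cells_ba[label]["diff"] == pytest.approx(-cell["diff"])

    def test_hand_computed_shift(self):
        patient_a = make_patient("A", right_mds=[-1.0, -1.2], years=[2012, 2017])
        patient_b = make_patient("B", right_mds=[-7.0, -7.2], years=[2012, 2017])
        cohort_a = Cohort(patients=[patient_a], onset_year=2012)
        cohort_b = Cohort(patients=[patient_a, patient_b], onset_year=2012)
        ra, _ = run_progression(cohort_a, ProgressionConfig())
        rb, _ = run_progression(cohort_b, ProgressionConfig())
        comparison = compare_reports(build_report(ra, cohort_a),
                                     build_report(rb, cohort_b))
        sev = {c["label"]: c for c in comparison["sections"]["md_severity"]["cells"]}
        assert sev[">-2"]["pct_a"] == 100.0 and sev[">-2"]["pct_b"] == 50.0
        assert sev[">-2"]["diff"] == 50.0
        assert sev["-6..-12"]["diff"] == -50.0

    def test_sections_missing_on_one_side_flagged(self, selected_results):
        cohort, results = selected_results
        a = build_report(results, cohort)
        b = build_report(results, cohort,
                         clinical_progression_counts={"yes": 10, "no": 80,
                                                      "cannot-be-assessed": 5,
                                                      "no-prior-tests": 5})
        comparison = compare_reports(a, b)
        assert comparison["sections"]["clinical_progression"]["status"] == "only_b"
        assert comparison["sections"]["quality_of_life"]["status"] == "NR"

    def test_schema_mismatch_rejected(self, selected_results):
        cohort, results = selected_results
        a = build_report(results, cohort)
        b = build_report(results, cohort)
        b.schema_version = "aces-rwm-proto-2"
        with pytest.raises(SchemaVersionError):
            compare_reports(a, b)


class TestSerialization:
    def test_json_round_trip_identical(self, selected_results):
        cohort, results = selected_results
        report = build_report(results, cohort, cost_per_patient_year=312.4)
        back = report_from_json(report_to_json(report))
        assert back == report

    def test_empty_report_schema_skeleton(self):
        report = build_report([], Cohort(patients=[], onset_year=2012))
        js, table = serialize_report(report)
        back = report_from_json(js)
        assert back == report
        assert report.metadata["counts"]["fulfilling_criteria"] == 0
        assert "md_severity" in table

    def test_table_rendering_golden(self):
        patient = make_patient("P1", right_mds=[-1.0, -1.4], years=[2012, 2017])
        cohort = Cohort(patients=[patient], onset_year=2012)
        results, _ = run_progression(cohort, ProgressionConfig())
        table = report_to_table(build_report(results, cohort))
        lines = table.splitlines()
        assert lines[0] == "section,label,count,pct"
        assert "age_groups,60-69,1,100" in lines
        assert "md_severity,>-2,1,100" in lines
        assert "rate_pooled,slow,1,100" in lines
        assert "clinical_progression,yes,NR,NR" in lines
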