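"""Tests for value comparison, series matching and exam checking."""

from __future__ import annotations

import copy

import numpy as np
import pytest

from protoqc import fixtures as fx
from protoqc.checker import (
    ABSENT,
    FAIL,
    NOT_PERFORMED,
    PASS,
    check_exam,
    compare_value,
    match_series,
    render_report,
)
from protoqc.dicom_io import ExamBundle, GenericAttributes, SeriesBundle, read_exam
from protoqc.master import Exact, MasterFile, Range, SeriesSpec, generate_master

from conftest import brute_force_assignment, make_instance


class TestCompareValue:
    @pytest.mark.parametrize(
        "found,expected,result",
        [
            (6240, Range(6000, 6500), True),
            (6000, Range(6000, 6500), True),   # inclusive endpoints
            (6500, Range(6000, 6500), True),
            (6501, Range(6000, 6500), False),
            ([4.77, 2.39], Exact([2.39, 4.77]), True),  # sort-then-compare
            ([4.77], Exact([2.39, 4.77]), False),
            (7, Exact(5), False),
            (5.0000000001, Exact(5), True),    # DS round-trip tolerance
            ("  Axial ", Exact("axial"), True),
            ("MR", Exact("CT"), False),
            (ABSENT, Exact(5), False),
            (ABSENT, Range(0, 10), False),
            ("oblique", Range(0, 10), False),  # type mismatch never passes
            (5, Exact([5]), False),            # scalar vs list shape mismatch
        ],
    )
    def test_cases(self, found, expected, result):
        assert compare_value(found, expected) is result

    def test_exact_equals_degenerate_range_for_numbers(self):
        rng = np.random.default_rng(1)
        for v in rng.uniform(-1e4, 1e4, size=50):
            assert compare_value(v, Exact(float(v))) == compare_value(v, Range(v, v))


def _series(number, seq, desc, params=None):
    inst = make_instance(sn=number, desc=desc)
    bundle = SeriesBundle(
        series_number=number,
        acquisition_number=None,
        instances=[inst],
        sequence_id=seq,
        series_description=desc,
        params=params or {},
    )
    return bundle


def _exam(series, exam_id="ex"):
    return ExamBundle(exam_id=exam_id, generic=GenericAttributes(modality="MR"), series=series)


def _spec(seq, desc, params=None, role=None, required=True):
    return SeriesSpec(
        sequence_id=seq, series_description=desc,
        params={k: Exact(v) for k, v in (params or {}).items()},
        role=role, required=required,
    )


class TestMatchSeries:
    def test_partial_description_match(self):
        exam = _exam([_series(9, "*tse2d1", "T2W SAG SPINE repeat")])
        master = MasterFile(series_specs=[_spec("*tse2d1", "t2w sag spine")])
        match = match_series(exam, master)
        assert match.assignments == {0: 0}
        assert match.missing_specs == []

    def test_missing_required_spec(self):
        exam = _exam([_series(1, "*ep_b50", "DWI b50")])
        master = MasterFile(
            series_specs=[_spec("*ep_b50", "DWI b50"), _spec("*fl3d2", "T1W DIXON FAT")]
        )
        match = match_series(exam, master)
        assert [s.series_description for s in match.missing_specs] == ["T1W DIXON FAT"]

    def test_unexpected_series_reported(self):
        exam = _exam([_series(1, "*ep_b50", "DWI b50"), _series(99, "*fl2d1", "localizer")])
        master = MasterFile(series_specs=[_spec("*ep_b50", "DWI b50")])
        match = match_series(exam, master)
        assert [b.series_description for b in match.unexpected_series] == ["localizer"]

    def test_optional_spec_not_missing(self):
        exam = _exam([_series(1, "*ep_b50", "DWI b50")])
        master = MasterFile(
            series_specs=[
                _spec("*ep_b50", "DWI b50"),
                _spec("*", "ADC", required=False),
            ]
        )
        match = match_series(exam, master)
        assert match.missing_specs == []
        assert [s.series_description for s in match.unmatched_optional] == ["ADC"]

    def test_conservation(self):
        exam = _exam(
            [_series(i, "EP", f"DWI b{b}") for i, b in enumerate([50, 600, 900])]
            + [_series(9, "SE", "extra")]
        )
        master = MasterFile(
            series_specs=[
                _spec("EP", "DWI b50"), _spec("EP", "DWI b600"),
                _spec("EP", "DWI b900"), _spec("GR", "T1W DIXON FAT"),
            ]
        )
        match = match_series(exam, master)
        n_required = sum(1 for s in master.series_specs if s.required)
        assert len(match.assignments) + len(match.missing_specs) == n_required
        assert len(match.assignments) + len(match.unexpected_series) == len(exam.series)

    def test_ambiguous_assignment_matches_exhaustive_oracle(self):
        """On small random instances, the one-to-one assignment achieves
        the same total parameter agreement as brute-force enumeration."""
        rng = np.random.default_rng(202)
        for _ in range(150):
            n_specs = int(rng.integers(1, 5))
            n_series = int(rng.integers(1, 5))
            # All share one sequence id and compatible descriptions, so
            # stage 3 alone must resolve the ambiguity.
            series = []
            for ri in range(n_series):
                params = {f"P{k}": int(rng.integers(0, 3)) for k in range(3)}
                series.append(_series(ri + 1, "EP", "dwi", params))
            specs = []
            for si in range(n_specs):
                params = {f"P{k}": int(rng.integers(0, 3)) for k in range(3)}
                specs.append(
                    SeriesSpec(
                        sequence_id="EP", series_description="dwi " + "x" * si,
                        params={k: Exact(v) for k, v in params.items()},
                    )
                )
            exam = _exam(series)
            master = MasterFile(series_specs=specs)
            match = match_series(exam, master)
            agree = {
                (si, ri): sum(
                    1 for name, e in specs[si].params.items()
                    if compare_value(series[ri].params.get(name, ABSENT), e)
                )
                for si in range(n_specs)
                for ri in range(n_series)
            }
            achieved = sum(agree[(si, ri)] for si, ri in match.assignments.items())
            assert achieved == brute_force_assignment(agree, n_specs, n_series)

    def test_deterministic_tie_break_by_series_number(self):
        # Two identical series: the spec takes the lower series number.
        exam = _exam([_series(7, "EP", "dwi"), _series(3, "EP", "dwi")])
        master = MasterFile(series_specs=[_spec("EP", "dwi")])
        match = match_series(exam, master)
        assert exam.series[match.assignments[0]].series_number == 3


class TestCheckExam:
    def test_compliant_round_trip(self, siemens_exam, tier2_attrs):
        exam = read_exam(siemens_exam, tier2_attrs)
        master = generate_master(exam, tier2_attrs)
        result = check_exam(exam, master)
        assert result.fully_compliant
        assert all(v == PASS for v in result.statuses.values())

    def test_slice_thickness_deviation_reported(self, tmp_path, templates, tier1_attrs):
        d = fx.make_exam(templates["site01"], "st7", str(tmp_path), seed=21)
        fx.inject(d, fx.DeviationInjection(0, "dixon_slice_thickness", "set_param",
                                           fx.DIXON_FAMILY, "SliceThickness", 7))
        exam = read_exam(d, tier1_attrs)
        result = check_exam(exam, fx.myrads_tier1_master())
        st_devs = [dv for dv in result.deviations if dv.param == "SliceThickness"]
        assert len(st_devs) == 2  # fat and water series
        assert all(dv.found == 7 for dv in st_devs)
        assert not result.fully_compliant

    def test_dropped_series_goes_not_performed(self, tmp_path, templates, tier1_attrs):
        d = fx.make_exam(templates["site01"], "nodwi", str(tmp_path), seed=22)
        fx.inject(d, fx.DeviationInjection(0, "all_series", "drop_series", fx.DWI_FAMILY))
        exam = read_exam(d, tier1_attrs)
        result = check_exam(exam, fx.myrads_tier1_master())
        assert set(result.missing_roles) == set(fx.DWI_FAMILY)
        for role in fx.DWI_FAMILY:
            assert result.param_status[(role, "SliceThickness")] == NOT_PERFORMED
        assert not result.fully_compliant

    def test_absent_tag_is_a_deviation(self, tmp_path, templates, tier2_attrs):
        """An anonymization-stripped parameter tag surfaces as an explicit
        deviation with an ABSENT found value, never a silent skip."""
        d = fx.make_exam(templates["site01"], "stripped", str(tmp_path), seed=23)
        exam = read_exam(d, tier2_attrs)
        master = generate_master(exam, tier2_attrs)
        fx.inject(d, fx.DeviationInjection(0, "dwi_ti", "remove_tag",
                                           fx.DWI_FAMILY, "InversionTime"))
        result = check_exam(read_exam(d, tier2_attrs), master)
        ti_devs = [dv for dv in result.deviations if dv.param == "InversionTime"]
        assert len(ti_devs) == 3
        assert all(dv.found is ABSENT for dv in ti_devs)

    def test_wrong_scanner_does_not_abort_series_checks(self, tmp_path, templates, tier2_attrs):
        d = fx.make_exam(templates["site01"], "wrongscanner", str(tmp_path), seed=24)
        exam = read_exam(d, tier2_attrs)
        master = generate_master(exam, tier2_attrs)
        fx.inject(d, fx.DeviationInjection(0, "correct_scanner", "set_generic",
                                           (), "ManufacturerModelName", "Symphony"))
        result = check_exam(read_exam(d, tier2_attrs), master)
        assert [dv.param for dv in result.generic_deviations] == ["ManufacturerModelName"]
        assert result.deviations == []  # series params still checked, all pass
        assert len(result.matched_roles) == 7
        assert not result.fully_compliant

    def test_error_exam_structured_result(self, tmp_path, tier1_attrs):
        exam = read_exam(str(tmp_path), tier1_attrs)
        result = check_exam(exam, fx.myrads_tier1_master())
        assert result.error == "no DICOM instances"
        assert not result.fully_compliant

    def test_monotonicity_under_injection(self, tmp_path, templates, tier1_attrs):
        """Each added deviation injection never decreases the deviation
        count; dropping a series converts fails to not-performed."""
        master = fx.myrads_tier1_master()
        d = fx.make_exam(templates["site01"], "mono", str(tmp_path), seed=25)
        counts = []
        for inj in (
            fx.DeviationInjection(0, "dwi_slice_thickness", "set_param",
                                  fx.DWI_FAMILY, "SliceThickness", 7),
            fx.DeviationInjection(0, "t1w_slice_thickness", "set_param",
                                  ("t1w_spine",), "SliceThickness", 3),
        ):
            fx.inject(d, inj)
            result = check_exam(read_exam(d, tier1_attrs), master)
            counts.append(len(result.deviations))
        assert counts == sorted(counts) and counts[0] >= 1
        before = check_exam(read_exam(d, tier1_attrs), master)
        fx.inject(d, fx.DeviationInjection(0, "all_series", "drop_series", fx.DWI_FAMILY))
        after = check_exam(read_exam(d, tier1_attrs), master)
        for role in fx.DWI_FAMILY:
            assert before.param_status[(role, "SliceThickness")] == FAIL
            assert after.param_status[(role, "SliceThickness")] == NOT_PERFORMED


class TestRenderReport:
    def test_compliant_report(self, siemens_exam, tier2_attrs):
        exam = read_exam(siemens_exam, tier2_attrs)
        master = generate_master(exam, tier2_attrs)
        text, structured = render_report(check_exam(exam, master))
        assert "No deviations found" in text
        assert structured["deviations"] == []
        assert structured["fully_compliant"] is True

    def test_deviation_rows_conserved(self, tmp_path, templates, tier1_attrs):
        d = fx.make_exam(templates["site01"], "tworows", str(tmp_path), seed=26)
        fx.inject(d, fx.DeviationInjection(0, "x", "set_param",
                                           fx.DIXON_FAMILY, "SliceThickness", 7))
        result = check_exam(read_exam(d, tier1_attrs), fx.myrads_tier1_master())
        text, structured = render_report(result)
        assert len(structured["deviations"]) == 2
        assert text.count("SliceThickness") == 2
        assert "dixon_fat" in text and "dixon_water" in text

    def test_byte_identical_across_runs(self, siemens_exam, tier2_attrs):
        exam = read_exam(siemens_exam, tier2_attrs)
        master = generate_master(exam, tier2_attrs)
        first = render_report(check_exam(exam, master))
        second = render_report(check_exam(read_exam(siemens_exam, tier2_attrs), master))
        assert first[0] == second[0]
        assert first[1] == second[1]
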