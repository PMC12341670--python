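"""Tests for cohort aggregation and the Mann-Whitney U machinery."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
import scipy.stats

from protoqc import audit as au
from protoqc.audit import (
    CheckMatrix,
    QualityScore,
    build_matrix,
    correlate_compliance_quality,
    mann_whitney_u,
    round_percent,
    simulate_quality_scores,
    summarize,
)
from protoqc.checker import ExamCheckResult, FAIL, NOT_PERFORMED, PASS


def _result(exam_id, matched=(), missing=(), param_fail=(), generic_fail=False):
    r = ExamCheckResult(exam_id=exam_id)
    r.matched_roles = list(matched)
    r.missing_roles = list(missing)
    for role in matched:
        params = ["SliceThickness", "Orientation"]
        if role.startswith("dwi"):
            params.append("DiffusionBValue")
        for param in params:
            r.param_status[(role, param)] = PASS
    for role, param in param_fail:
        r.param_status[(role, param)] = FAIL
    for role in missing:
        for param in ("SliceThickness", "Orientation"):
            r.param_status[(role, param)] = NOT_PERFORMED
    if generic_fail:
        from protoqc.checker import ParamDeviation
        from protoqc.master import Exact

        r.generic_deviations = [ParamDeviation("generic", "ManufacturerModelName", Exact("Aera"), "X")]
    r.fully_compliant = not (missing or param_fail or generic_fail)
    return r


ALL = au.ALL_ROLES


class TestBuildMatrix:
    def test_all_compliant(self):
        results = [_result(f"e{i}", matched=ALL) for i in range(3)]
        matrix = build_matrix(results, au.TIER1)
        assert all(v == PASS for v in matrix.cells.values())

    def test_missing_family_not_performed(self):
        r = _result("e0", matched=[x for x in ALL if not x.startswith("dwi")],
                    missing=[x for x in ALL if x.startswith("dwi")])
        matrix = build_matrix([r], au.TIER1)
        row = matrix.row("e0")
        assert row["all_series"] == FAIL
        assert row["dwi_slice_thickness"] == NOT_PERFORMED
        assert row["dwi_b900"] == NOT_PERFORMED
        assert row["dixon_slice_thickness"] == PASS

    def test_duplicate_exam_ids_rejected(self):
        results = [_result("same", matched=ALL), _result("same", matched=ALL)]
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix(results, au.TIER1)

    def test_rows_grouped_by_site(self):
        results = [_result(e, matched=ALL) for e in ("b", "a", "c")]
        matrix = build_matrix(results, au.TIER1, {"a": "s2", "b": "s1", "c": "s1"})
        assert matrix.exam_ids == ["b", "c", "a"]

    def test_status_count_conservation(self):
        results = [
            _result("e0", matched=ALL),
            _result("e1", matched=[x for x in ALL if x != "dixon_fat"],
                    missing=["dixon_fat"]),
            _result("e2", matched=ALL, param_fail=[("t1w_spine", "SliceThickness")]),
        ]
        matrix = build_matrix(results, au.TIER1)
        total = sum(
            1 for e in matrix.exam_ids for c in matrix.check_names
            if matrix.cells[(e, c)] in (PASS, FAIL, NOT_PERFORMED)
        )
        assert total == len(matrix.exam_ids) * len(matrix.check_names)


class TestSummarize:
    def test_half_up_rounding(self):
        assert round_percent(1, 400) == 0.3       # 0.25 rounds up, not to even
        assert round_percent(153, 174) == 87.9
        assert round_percent(127, 169) == 75.1
        assert round_percent(167, 174) == 96.0

    def test_not_performed_excluded_from_denominator(self):
        results = [_result(f"p{i}", matched=ALL) for i in range(7)] + [
            _result("m", matched=[x for x in ALL if not x.startswith("dwi")],
                    missing=[x for x in ALL if x.startswith("dwi")]),
            _result("f", matched=ALL, param_fail=[("dwi_b50", "SliceThickness")]),
        ]
        summary = summarize(build_matrix(results, au.TIER1))
        n, applicable, pct = summary.per_check["dwi_slice_thickness"]
        assert (n, applicable) == (7, 8)
        assert pct == 87.5
        # full compliance over all exams, missing counts as non-compliant
        assert summary.full_tier_compliance == (7, 9, 77.8)

    def test_all_pass_is_100(self):
        summary = summarize(build_matrix([_result("e", matched=ALL)], au.TIER1))
        assert all(p == 100.0 for _, _, p in summary.per_check.values())


class TestMannWhitney:
    def test_fully_separated_small_groups_exact(self):
        # All C(6,3)=20 rank splits: the two extreme U values give p=0.1.
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.method == "exact"
        assert res.p == pytest.approx(0.1)
        res2 = mann_whitney_u([4, 5, 6], [1, 2, 3])
        assert res2.U == 9
        assert res2.p == pytest.approx(0.1)

    def test_identical_groups_midpoint(self):
        res = mann_whitney_u([2, 2, 3], [2, 2, 3])
        assert res.U == 4.5  # n1*n2/2 by symmetry

    def test_swap_symmetry_and_shift_invariance(self):
        rng = np.random.default_rng(5)
        g1 = list(rng.integers(1, 5, size=20))
        g2 = list(rng.integers(1, 5, size=30))
        a = mann_whitney_u(g1, g2)
        b = mann_whitney_u(g2, g1)
        assert a.U + b.U == pytest.approx(len(g1) * len(g2))
        assert a.p == pytest.approx(b.p)
        shifted = mann_whitney_u([x + 7 for x in g1], [x + 7 for x in g2])
        assert shifted.U == pytest.approx(a.U)
        assert shifted.p == pytest.approx(a.p)

    def test_u_bounds(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            g1 = list(rng.integers(1, 5, size=rng.integers(2, 15)))
            g2 = list(rng.integers(1, 5, size=rng.integers(2, 15)))
            res = mann_whitney_u(g1, g2)
            assert 0 <= res.U <= len(g1) * len(g2)

    def test_all_tied_degenerate(self):
        res = mann_whitney_u([3, 3, 3], [3, 3, 3, 3])
        assert res.p == 1.0
        assert not res.significant

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1, 2])

    def test_normal_approximation_close_to_exact(self):
        """For N <= 12 untied samples the continuity-corrected normal
        p stays within 0.02 of full enumeration."""
        from protoqc.audit import _exact_p, _u_statistic
        from scipy.stats import norm as normal

        rng = np.random.default_rng(7)
        for _ in range(60):
            vals = rng.permutation(np.arange(12, dtype=float))
            g1, g2 = list(vals[:6]), list(vals[6:])
            u = _u_statistic(g1, g2)
            exact = _exact_p(g1, g2, u)
            mu, var = 18.0, 6 * 6 * 13 / 12.0
            z = max(0.0, (abs(u - mu) - 0.5) / np.sqrt(var))
            approx = min(1.0, 2 * float(normal.sf(z)))
            assert abs(approx - exact) <= 0.02

    def test_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            g1 = list(rng.integers(1, 5, size=int(rng.integers(10, 60))))
            g2 = list(rng.integers(1, 5, size=int(rng.integers(10, 60))))
            ours = mann_whitney_u(g1, g2)
            ref = scipy.stats.mannwhitneyu(
                g1, g2, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            assert ours.U == pytest.approx(float(ref.statistic))
            assert ours.p == pytest.approx(float(ref.pvalue), abs=1e-10)


def _flag_matrix(flags: dict[str, bool]) -> CheckMatrix:
    """A one-column matrix encoding a compliance flag per exam."""
    cells = {(e, "dwi_check"): (PASS if ok else FAIL) for e, ok in flags.items()}
    ids = sorted(flags)
    return CheckMatrix(exam_ids=ids, site_of={e: "" for e in ids},
                       check_names=["dwi_check"], cells=cells)


class TestCorrelateComplianceQuality:
    def test_shifted_scores_detected(self):
        """A one-point Likert shift in non-compliant exams is detected at
        n=121 across repeated simulations."""
        flags = {f"e{i:03d}": i % 3 != 0 for i in range(121)}
        matrix = _flag_matrix(flags)
        hits = 0
        for seed in range(20):
            scores = simulate_quality_scores(flags, seed=seed, effect=1)
            res = correlate_compliance_quality(matrix, scores, grouping="dwi",
                                               score_channel="dwi")
            hits += res.significant
        assert hits == 20

    def test_null_type_one_error_rate(self):
        """Scores independent of compliance: the test rejects at about the
        nominal 5% rate over 2000 seeded replicates."""
        flags = {f"e{i:03d}": i >= 72 for i in range(121)}  # 49 compliant / 72 not
        matrix = _flag_matrix(flags)
        rejections = 0
        for seed in range(2000):
            scores = simulate_quality_scores(flags, seed=seed, effect=0)
            res = correlate_compliance_quality(matrix, scores, grouping="dwi",
                                               score_channel="dwi")
            rejections += res.significant
        rate = rejections / 2000
        assert abs(rate - 0.05) <= 0.02

    def test_zero_member_group_flagged(self):
        flags = {f"e{i}": True for i in range(10)}
        matrix = _flag_matrix(flags)
        scores = simulate_quality_scores(flags, seed=0)
        res = correlate_compliance_quality(matrix, scores, grouping="dwi")
        assert res.error is not None
        assert not res.significant

    def test_unscored_and_unknown_exams_ignored(self):
        flags = {f"e{i}": i % 2 == 0 for i in range(40)}
        matrix = _flag_matrix(flags)
        scores = simulate_quality_scores(flags, seed=1)[:30]
        scores.append(QualityScore(exam_id="stranger", overall=4, dwi=4, dixon=4))
        res = correlate_compliance_quality(matrix, scores, grouping="dwi")
        assert res.n1 + res.n2 == 30

    def test_likert_words_parse(self, tmp_path):
        path = tmp_path / "scores.csv"
        path.write_text(
            "exam_id,overall,dwi,dixon\n"
            "e0,Excellent,Good,Suboptimal\n"
            "e1,4,3,1\n"
        )
        scores = au.read_scores_csv(str(path))
        assert scores[0].overall == 4 and scores[0].dixon == 2
        assert scores[1].dixon == 1
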