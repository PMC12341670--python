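"""Compare an examination against a master file.

The check mirrors how a physicist audits a session by hand: match each
acquired series to an entry in the expected protocol, flag series that are
missing or unexpected, then compare every agreed parameter of each matched
series against its expectation.  Matching goes by the sequence-identifier
tag first (scanners report it reliably), disambiguated by a *partial*
series-description match because operators edit descriptions freely
(suffixes like "repeat", truncation).  Remaining ambiguity — several
series sharing a sequence id and compatible descriptions — is resolved by
the one-to-one assignment that maximizes parameter agreement.

A missing parameter tag counts as a deviation rather than a silent skip:
anonymization pipelines sometimes strip acquisition tags, and that damage
should surface in the report, not hide in it.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field

from .dicom_io import ExamBundle, SeriesBundle
from .master import Exact, ExpectedValue, MasterFile, Range, SeriesSpec, master_to_dict

log = logging.getLogger(__name__)

__all__ = [
    "ABSENT",
    "compare_value",
    "match_series",
    "check_exam",
    "render_report",
    "MatchResult",
    "ParamDeviation",
    "ExamCheckResult",
    "PASS",
    "FAIL",
    "NOT_PERFORMED",
]

# Check statuses (Figure-3-style): pass, fail, or check not performed
# (owning series missing, so there was nothing to compare).
PASS = "pass"
FAIL = "fail"
NOT_PERFORMED = "not_performed"

REL_TOL = 1e-6
ABS_TOL = 1e-9


class _Absent:
    """Sentinel for a parameter tag absent from the acquired data."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ABSENT"


ABSENT = _Absent()


def _num_eq(a: float, b: float) -> bool:
    return math.isclose(float(a), float(b), rel_tol=REL_TOL, abs_tol=ABS_TOL)


def _is_number(v) -> bool:
    return isinstance(v, (int, float)) and not isinstance(v, bool)


def compare_value(found, expected: ExpectedValue) -> bool:
    """Does an acquired value satisfy an expectation?

    Exact numbers compare within a relative tolerance of 1e-6 (absolute
    1e-9 near zero) to absorb DICOM decimal-string round-tripping; exact
    strings compare case-insensitively after whitespace trimming; exact
    lists compare element-wise after ascending sort (dual-echo TE order
    varies by vendor); ranges are inclusive.  An absent value never
    satisfies an expectation.
    """
    if found is ABSENT or found is None:
        return False
    if isinstance(expected, Range):
        if not _is_number(found):
            log.warning("type mismatch: range expectation vs non-numeric %r", found)
            return False
        return expected.low <= float(found) <= expected.high
    assert isinstance(expected, Exact)
    want = expected.value
    if isinstance(want, tuple):
        want = list(want)
    if isinstance(want, list) or isinstance(found, list):
        if not isinstance(want, list) or not isinstance(found, list):
            return False
        if len(want) != len(found):
            return False
        try:
            want_sorted = sorted(want)
            found_sorted = sorted(found)
        except TypeError:
            return False
        for w, f in zip(want_sorted, found_sorted):
            if _is_number(w) and _is_number(f):
                if not _num_eq(w, f):
                    return False
            elif str(w).strip().casefold() != str(f).strip().casefold():
                return False
        return True
    if _is_number(want) and _is_number(found):
        return _num_eq(want, found)
    if isinstance(want, str) or isinstance(found, str):
        return str(want).strip().casefold() == str(found).strip().casefold()
    return want == found


def _norm_desc(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip().casefold())


def _desc_partial_match(spec_desc: str, series_desc: str) -> bool:
    """Bidirectional substring match, case/whitespace-insensitive.

    An empty master description matches anything (sequence id alone
    identifies the series)."""
    a, b = _norm_desc(spec_desc), _norm_desc(series_desc)
    if not a:
        return True
    if not b:
        return False
    return a in b or b in a


def _seq_match(spec: SeriesSpec, series: SeriesBundle) -> bool:
    if spec.sequence_id == "*":
        return True
    return spec.sequence_id.strip().casefold() == series.sequence_id.strip().casefold()


def _agreement(spec: SeriesSpec, series: SeriesBundle) -> int:
    return sum(
        1
        for name, expected in spec.params.items()
        if compare_value(series.params.get(name, ABSENT), expected)
    )


@dataclass
class MatchResult:
    """Outcome of matching acquired series against the expected protocol."""

    assignments: dict[int, int]  # spec index -> series index
    missing_specs: list[SeriesSpec]
    unexpected_series: list[SeriesBundle]
    unmatched_optional: list[SeriesSpec]


def _assign_component(
    spec_idxs: list[int],
    series_idxs: list[int],
    agree: dict[tuple[int, int], int],
    series_number: dict[int, int],
) -> dict[int, int]:
    """Exhaustive optimal one-to-one assignment inside one ambiguity
    component: maximize total parameter agreement; break ties by spec
    order, then ascending series number.  Components are tiny in practice
    (series sharing a sequence id); beyond 8 specs fall back to greedy.
    """
    if len(spec_idxs) > 8:
        pairs = sorted(
            agree,
            key=lambda p: (-agree[p], spec_idxs.index(p[0]), series_number[p[1]], p[1]),
        )
        out: dict[int, int] = {}
        used: set[int] = set()
        for si, ri in pairs:
            if si in out or ri in used:
                continue
            out[si] = ri
            used.add(ri)
        return out

    best_total = -1
    best_key: tuple | None = None
    best: dict[int, int] = {}

    candidates_of = {
        si: sorted(
            (ri for ri in series_idxs if (si, ri) in agree),
            key=lambda ri: (series_number[ri], ri),
        )
        for si in spec_idxs
    }

    def search(i: int, used: frozenset, chosen: dict[int, int], total: int) -> None:
        nonlocal best_total, best_key, best
        if i == len(spec_idxs):
            # Tie-break key: for each spec in order, the series number it
            # received (unmatched sorts last).
            key = tuple(
                (series_number[chosen[si]], chosen[si]) if si in chosen else (math.inf, math.inf)
                for si in spec_idxs
            )
            if total > best_total or (total == best_total and (best_key is None or key < best_key)):
                best_total, best_key, best = total, key, dict(chosen)
            return
        si = spec_idxs[i]
        for ri in candidates_of[si]:
            if ri in used:
                continue
            chosen[si] = ri
            search(i + 1, used | {ri}, chosen, total + agree[(si, ri)])
            del chosen[si]
        search(i + 1, used, chosen, total)  # leave this spec unmatched

    search(0, frozenset(), {}, 0)
    return best


def match_series(exam: ExamBundle, master: MasterFile) -> MatchResult:
    """Match acquired series to master entries (total function).

    Stage 1: candidate pairs share a sequence id (exact, case-insensitive;
    a master id of ``"*"`` matches any).  Stage 2: candidates must also
    pass the partial description match.  Stage 3: ambiguity is resolved
    one-to-one by best parameter agreement with deterministic tie-breaks.
    Leftover required specs are missing; leftover series are unexpected.
    """
    specs = master.series_specs
    series = exam.series
    agree: dict[tuple[int, int], int] = {}
    for si, spec in enumerate(specs):
        for ri, bundle in enumerate(series):
            if _seq_match(spec, bundle) and _desc_partial_match(
                spec.series_description, bundle.series_description
            ):
                agree[(si, ri)] = _agreement(spec, bundle)

    # Connected components of the candidacy graph.
    parent: dict[tuple[str, int], tuple[str, int]] = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent[find(a)] = find(b)

    for si, ri in agree:
        union(("s", si), ("r", ri))

    comps: dict[tuple[str, int], tuple[list[int], list[int]]] = {}
    for si, ri in agree:
        root = find(("s", si))
        comp = comps.setdefault(root, ([], []))
        if si not in comp[0]:
            comp[0].append(si)
        if ri not in comp[1]:
            comp[1].append(ri)

    series_number = {ri: b.series_number for ri, b in enumerate(series)}
    assignments: dict[int, int] = {}
    for spec_idxs, series_idxs in comps.values():
        spec_idxs.sort()
        series_idxs.sort()
        sub = {p: a for p, a in agree.items() if p[0] in spec_idxs}
        assignments.update(_assign_component(spec_idxs, series_idxs, sub, series_number))

    missing = [
        spec for si, spec in enumerate(specs) if si not in assignments and spec.required
    ]
    unmatched_optional = [
        spec for si, spec in enumerate(specs) if si not in assignments and not spec.required
    ]
    assigned_series = set(assignments.values())
    unexpected = [b for ri, b in enumerate(series) if ri not in assigned_series]
    return MatchResult(
        assignments=assignments,
        missing_specs=missing,
        unexpected_series=unexpected,
        unmatched_optional=unmatched_optional,
    )


@dataclass
class ParamDeviation:
    series_label: str
    param: str
    expected: ExpectedValue
    found: object  # value or ABSENT

    def found_repr(self) -> str:
        if self.found is ABSENT:
            return "ABSENT"
        v = self.found
        return json.dumps(list(v) if isinstance(v, tuple) else v)

    def expected_repr(self) -> str:
        return json.dumps(self.expected.to_json())


@dataclass
class ExamCheckResult:
    """Everything the checker concluded about one examination."""

    exam_id: str
    generic_deviations: list[ParamDeviation] = field(default_factory=list)
    match: MatchResult | None = None
    deviations: list[ParamDeviation] = field(default_factory=list)
    statuses: dict[str, str] = field(default_factory=dict)
    param_status: dict[tuple[str, str], str] = field(default_factory=dict)
    missing_roles: list[str] = field(default_factory=list)
    matched_roles: list[str] = field(default_factory=list)
    fully_compliant: bool = False
    error: str | None = None

    @property
    def missing_labels(self) -> list[str]:
        return [] if self.match is None else [s.label for s in self.match.missing_specs]

    @property
    def unexpected_labels(self) -> list[str]:
        return [] if self.match is None else [s.label for s in self.match.unexpected_series]


def check_exam(exam: ExamBundle, master: MasterFile) -> ExamCheckResult:
    """Run the full protocol check for one examination.

    Generic attributes are compared first (a wrong scanner is recorded but
    never aborts the series checks); each matched series is then compared
    parameter by parameter.  The result is fully deterministic.  An exam
    in an error state (unreadable) yields a structured non-compliant
    result, never an exception.
    """
    if exam.error:
        return ExamCheckResult(
            exam_id=exam.exam_id, fully_compliant=False, error=exam.error
        )

    result = ExamCheckResult(exam_id=exam.exam_id)

    generic_found = exam.generic.as_dict()
    for name, expected in master.generic.items():
        found = generic_found.get(name, ABSENT)
        ok = compare_value(found, expected)
        result.statuses[f"generic::{name}"] = PASS if ok else FAIL
        if not ok:
            result.generic_deviations.append(
                ParamDeviation("generic", name, expected, found)
            )

    match = match_series(exam, master)
    result.match = match

    for si, spec in enumerate(master.series_specs):
        label = spec.label
        role = spec.role or label
        if si in match.assignments:
            bundle = exam.series[match.assignments[si]]
            result.matched_roles.append(role)
            for name, expected in spec.params.items():
                found = bundle.params.get(name, ABSENT)
                ok = compare_value(found, expected)
                status = PASS if ok else FAIL
                result.statuses[f"{label}::{name}"] = status
                result.param_status[(role, name)] = status
                if not ok:
                    result.deviations.append(ParamDeviation(label, name, expected, found))
        elif spec.required:
            result.missing_roles.append(role)
            for name in spec.params:
                result.statuses[f"{label}::{name}"] = NOT_PERFORMED
                result.param_status[(role, name)] = NOT_PERFORMED

    result.fully_compliant = (
        not match.missing_specs
        and not result.deviations
        and not result.generic_deviations
    )
    return result


def result_to_dict(result: ExamCheckResult) -> dict:
    """Structured (JSON-serializable) form of a check result."""
    return {
        "schema_version": "1.0",
        "exam_id": result.exam_id,
        "error": result.error,
        "fully_compliant": result.fully_compliant,
        "generic_deviations": [
            {"param": d.param, "expected": d.expected.to_json(), "found": None if d.found is ABSENT else d.found}
            for d in result.generic_deviations
        ],
        "missing_series": result.missing_labels,
        "unexpected_series": result.unexpected_labels,
        "deviations": [
            {
                "series": d.series_label,
                "param": d.param,
                "expected": d.expected.to_json(),
                "found": None if d.found is ABSENT else (list(d.found) if isinstance(d.found, tuple) else d.found),
            }
            for d in result.deviations
        ],
        "statuses": dict(sorted(result.statuses.items())),
    }


def render_report(result: ExamCheckResult) -> tuple[str, dict]:
    """Render the text report and the structured report.

    The text report lists the exam id, generic deviations, missing and
    unexpected series, and a per-series parameter deviation table.  Output
    is byte-identical for identical inputs.
    """
    lines: list[str] = []
    lines.append(f"Protocol check report: {result.exam_id}")
    lines.append("=" * len(lines[0]))
    if result.error:
        lines.append(f"ERROR: {result.error}")
        lines.append("")
        return "\n".join(lines) + "\n", result_to_dict(result)

    if result.generic_deviations:
        lines.append("Generic attribute deviations:")
        for d in result.generic_deviations:
            lines.append(f"  {d.param}: expected {d.expected_repr()}, found {d.found_repr()}")
    else:
        lines.append("Generic attributes: OK")

    lines.append(
        "Missing series: " + (", ".join(result.missing_labels) if result.missing_labels else "none")
    )
    lines.append(
        "Unexpected series: "
        + (", ".join(result.unexpected_labels) if result.unexpected_labels else "none")
    )

    if result.deviations:
        lines.append("Parameter deviations:")
        lines.append(f"  {'series':<24} {'parameter':<22} {'expected':<24} found")
        for d in result.deviations:
            lines.append(
                f"  {d.series_label:<24} {d.param:<22} {d.expected_repr():<24} {d.found_repr()}"
            )
    if result.fully_compliant:
        lines.append("No deviations found")
    lines.append("")
    return "\n".join(lines) + "\n", result_to_dict(result)
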