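"""Cohort-level compliance audits and the compliance/quality association.

Per-exam check results are aggregated into an exams x checks status matrix
(pass / fail / not-performed), from which compliance summaries are
computed: per-check compliance over the *applicable* exams (an exam whose
series is missing contributes no information about that series' parameters
and is excluded from the denominator), and full-protocol compliance over
all exams.  Percentages are rounded half-up to one decimal place.

The association between protocol compliance and radiological image
quality (4-point Likert scores) is tested with a two-sided Mann-Whitney U
test implemented here: midrank U statistic, tie-corrected normal
approximation with continuity correction, and exact enumeration of rank
assignments for small untied samples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy.stats import norm

from .checker import ExamCheckResult, FAIL, NOT_PERFORMED, PASS

__all__ = [
    "CheckDef",
    "TierDefinition",
    "TIER1",
    "TIER2",
    "CheckMatrix",
    "ComplianceSummary",
    "QualityScore",
    "MWUResult",
    "build_matrix",
    "summarize",
    "mann_whitney_u",
    "correlate_compliance_quality",
    "simulate_quality_scores",
    "read_scores_csv",
    "round_percent",
    "matrix_to_frame",
    "plot_matrix",
]

# Series-family roles (see master.infer_role).
DWI_ROLES = ("dwi_b50", "dwi_b600", "dwi_b900")
DIXON_ROLES = ("dixon_fat", "dixon_water")
T1W_ROLES = ("t1w_spine",)
T2W_ROLES = ("t2w_spine",)
ALL_ROLES = DWI_ROLES + DIXON_ROLES + T1W_ROLES + T2W_ROLES


@dataclass(frozen=True)
class CheckDef:
    """One audit column: a named check over a family of series roles.

    kind:
      * ``param``     — a parameter compared on every family member that
                        defines it; any failing member fails the check.
      * ``presence``  — one member series expected; not-performed when the
                        whole family is absent.
      * ``all_series``— all listed roles must be present.
      * ``scanner``   — the generic-attribute (qualified scanner) check.
    """

    name: str
    kind: str
    roles: tuple[str, ...] = ()
    param: str | None = None


@dataclass(frozen=True)
class TierDefinition:
    name: str
    checks: tuple[CheckDef, ...]

    def check_names(self) -> list[str]:
        return [c.name for c in self.checks]


TIER1 = TierDefinition(
    name="tier1",
    checks=(
        CheckDef("all_series", "all_series", ALL_ROLES),
        CheckDef("dwi_slice_thickness", "param", DWI_ROLES, "SliceThickness"),
        CheckDef("dwi_orientation", "param", DWI_ROLES, "Orientation"),
        CheckDef("dwi_b50", "param", ("dwi_b50",), "DiffusionBValue"),
        CheckDef("dwi_b600", "param", ("dwi_b600",), "DiffusionBValue"),
        CheckDef("dwi_b900", "param", ("dwi_b900",), "DiffusionBValue"),
        CheckDef("dixon_slice_thickness", "param", DIXON_ROLES, "SliceThickness"),
        CheckDef("dixon_orientation", "param", DIXON_ROLES, "Orientation"),
        CheckDef("dixon_fat", "presence", DIXON_ROLES, "dixon_fat"),
        CheckDef("dixon_water", "presence", DIXON_ROLES, "dixon_water"),
        CheckDef("t1w_slice_thickness", "param", T1W_ROLES, "SliceThickness"),
        CheckDef("t1w_orientation", "param", T1W_ROLES, "Orientation"),
        CheckDef("t2w_slice_thickness", "param", T2W_ROLES, "SliceThickness"),
        CheckDef("t2w_orientation", "param", T2W_ROLES, "Orientation"),
    ),
)

TIER2 = TierDefinition(
    name="tier2",
    checks=(
        CheckDef("correct_scanner", "scanner"),
        CheckDef("all_series", "all_series", ALL_ROLES),
        CheckDef("dwi_b50", "param", ("dwi_b50",), "DiffusionBValue"),
        CheckDef("dwi_b600", "param", ("dwi_b600",), "DiffusionBValue"),
        CheckDef("dwi_b900", "param", ("dwi_b900",), "DiffusionBValue"),
        CheckDef("dwi_averages", "param", DWI_ROLES, "NumberOfAverages"),
        CheckDef("dwi_tr", "param", DWI_ROLES, "RepetitionTime"),
        CheckDef("dwi_te", "param", DWI_ROLES, "EchoTime"),
        CheckDef("dwi_ti", "param", DWI_ROLES, "InversionTime"),
        CheckDef("dwi_fa", "param", DWI_ROLES, "FlipAngle"),
        CheckDef("dwi_bw", "param", DWI_ROLES, "PixelBandwidth"),
        CheckDef("dwi_resolution", "param", DWI_ROLES, "PixelSpacing"),
        CheckDef("dixon_tr", "param", DIXON_ROLES, "RepetitionTime"),
        CheckDef("dixon_te", "param", DIXON_ROLES, "EchoTime"),
        CheckDef("dixon_fa", "param", DIXON_ROLES, "FlipAngle"),
        CheckDef("dixon_bw", "param", DIXON_ROLES, "PixelBandwidth"),
        CheckDef("dixon_resolution", "param", DIXON_ROLES, "PixelSpacing"),
    ),
)


def _status_for(result: ExamCheckResult, check: CheckDef) -> str:
    missing = set(result.missing_roles)
    matched = set(result.matched_roles)
    if check.kind == "scanner":
        return FAIL if result.generic_deviations else PASS
    if check.kind == "all_series":
        return FAIL if any(r in missing for r in check.roles) else PASS
    if check.kind == "presence":
        family_present = any(r in matched for r in check.roles)
        if not family_present:
            return NOT_PERFORMED
        return PASS if check.param in matched else FAIL
    # param check over the family
    statuses = [
        result.param_status[(role, check.param)]
        for role in check.roles
        if (role, check.param) in result.param_status
    ]
    if any(s == FAIL for s in statuses):
        return FAIL
    if any(s == PASS for s in statuses):
        return PASS
    return NOT_PERFORMED


@dataclass
class CheckMatrix:
    """Exams x checks status matrix (rows grouped by site)."""

    exam_ids: list[str]
    site_of: dict[str, str]
    check_names: list[str]
    cells: dict[tuple[str, str], str]

    def row(self, exam_id: str) -> dict[str, str]:
        return {c: self.cells[(exam_id, c)] for c in self.check_names}

    def row_fully_compliant(self, exam_id: str) -> bool:
        return all(v != FAIL for v in self.row(exam_id).values())


def build_matrix(
    results: list[ExamCheckResult],
    tier: TierDefinition,
    site_of: dict[str, str] | None = None,
) -> CheckMatrix:
    """One row per exam, one column per tier check; rows ordered by
    (site, exam id).  Duplicate exam ids are an error.  Exams in an error
    state fail every column (they could not be audited)."""
    if not results:
        raise ValueError("no results to aggregate")
    ids = [r.exam_id for r in results]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate exam ids: {dupes}")
    site_of = dict(site_of or {})
    for r in results:
        site_of.setdefault(r.exam_id, "")
    ordered = sorted(results, key=lambda r: (site_of[r.exam_id], r.exam_id))
    cells: dict[tuple[str, str], str] = {}
    for r in ordered:
        for check in tier.checks:
            if r.error:
                cells[(r.exam_id, check.name)] = FAIL
            else:
                cells[(r.exam_id, check.name)] = _status_for(r, check)
    return CheckMatrix(
        exam_ids=[r.exam_id for r in ordered],
        site_of=site_of,
        check_names=tier.check_names(),
        cells=cells,
    )


def round_percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal place."""
    if denominator == 0:
        return float("nan")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ComplianceSummary:
    per_check: dict[str, tuple[int, int, float]]  # check -> (n_compliant, n_applicable, %)
    full_tier_compliance: tuple[int, int, float]
    per_site_full_compliance: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"check": name, "n_compliant": n, "n_applicable": d, "percent": p}
            for name, (n, d, p) in self.per_check.items()
        ]
        n, d, p = self.full_tier_compliance
        rows.append(
            {"check": "full_compliance", "n_compliant": n, "n_applicable": d, "percent": p}
        )
        return pd.DataFrame(rows)


def summarize(matrix: CheckMatrix) -> ComplianceSummary:
    """Per-check and full-protocol compliance.

    A not-performed cell is excluded from that check's denominator; the
    full-compliance denominator is all exams (an exam with a missing
    series cannot be fully compliant)."""
    if not matrix.exam_ids:
        raise ValueError("empty matrix")
    per_check: dict[str, tuple[int, int, float]] = {}
    for check in matrix.check_names:
        n_pass = sum(1 for e in matrix.exam_ids if matrix.cells[(e, check)] == PASS)
        n_fail = sum(1 for e in matrix.exam_ids if matrix.cells[(e, check)] == FAIL)
        applicable = n_pass + n_fail
        per_check[check] = (n_pass, applicable, round_percent(n_pass, applicable))
    n_full = sum(1 for e in matrix.exam_ids if matrix.row_fully_compliant(e))
    total = len(matrix.exam_ids)
    per_site: dict[str, float] = {}
    for site in sorted(set(matrix.site_of[e] for e in matrix.exam_ids)):
        members = [e for e in matrix.exam_ids if matrix.site_of[e] == site]
        n = sum(1 for e in members if matrix.row_fully_compliant(e))
        per_site[site] = round_percent(n, len(members))
    return ComplianceSummary(
        per_check=per_check,
        full_tier_compliance=(n_full, total, round_percent(n_full, total)),
        per_site_full_compliance=per_site,
    )


def matrix_to_frame(matrix: CheckMatrix) -> pd.DataFrame:
    """P/F/N matrix as a DataFrame (rows = exams, columns = checks)."""
    code = {PASS: "P", FAIL: "F", NOT_PERFORMED: "N"}
    data = {
        check: [code[matrix.cells[(e, check)]] for e in matrix.exam_ids]
        for check in matrix.check_names
    }
    frame = pd.DataFrame(data, index=pd.Index(matrix.exam_ids, name="exam_id"))
    frame.insert(0, "site", [matrix.site_of[e] for e in matrix.exam_ids])
    return frame


def plot_matrix(matrix: CheckMatrix, path: str) -> None:
    """Heatmap of the status matrix (white pass, dark fail, light
    not-performed), rows grouped by site."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    code = {PASS: 0, NOT_PERFORMED: 1, FAIL: 2}
    grid = np.array(
        [[code[matrix.cells[(e, c)]] for c in matrix.check_names] for e in matrix.exam_ids]
    )
    fig, ax = plt.subplots(figsize=(0.5 * len(matrix.check_names) + 2, 6))
    cmap = ListedColormap(["#ffffff", "#a6cee3", "#1f4e79"])
    ax.imshow(grid, aspect="auto", cmap=cmap, vmin=0, vmax=2, interpolation="nearest")
    ax.set_xticks(range(len(matrix.check_names)))
    ax.set_xticklabels(matrix.check_names, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel("examinations (grouped by site)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Quality scores and the Mann-Whitney U test
# ---------------------------------------------------------------------------

LIKERT = {"non-diagnostic": 1, "suboptimal": 2, "good": 3, "excellent": 4}


@dataclass(frozen=True)
class QualityScore:
    """Radiological quality ratings for one exam on the 4-point Likert
    scale (Non-diagnostic=1, Suboptimal=2, Good=3, Excellent=4)."""

    exam_id: str
    overall: int
    dwi: int
    dixon: int

    def __post_init__(self) -> None:
        for channel in (self.overall, self.dwi, self.dixon):
            if channel not in (1, 2, 3, 4):
                raise ValueError(f"Likert score must be in 1..4, got {channel}")

    def channel(self, name: str) -> int:
        return {"overall": self.overall, "dwi": self.dwi, "dixon": self.dixon}[name]


def _parse_likert(value) -> int:
    if isinstance(value, str):
        key = value.strip().casefold()
        if key in LIKERT:
            return LIKERT[key]
        value = int(key)
    return int(value)


def read_scores_csv(path: str) -> list[QualityScore]:
    """Read an ``exam_id,overall,dwi,dixon`` CSV (Likert words or 1-4)."""
    frame = pd.read_csv(path)
    required = {"exam_id", "overall", "dwi", "dixon"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"scores CSV missing columns: {sorted(missing)}")
    return [
        QualityScore(
            exam_id=str(row.exam_id),
            overall=_parse_likert(row.overall),
            dwi=_parse_likert(row.dwi),
            dixon=_parse_likert(row.dixon),
        )
        for row in frame.itertuples()
    ]


@dataclass
class MWUResult:
    U: float
    n1: int
    n2: int
    z: float
    p: float
    significant: bool
    alpha: float = 0.05
    method: str = "normal"
    error: str | None = None


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _u_statistic(group1, group2) -> float:
    combined = np.concatenate([np.asarray(group1, float), np.asarray(group2, float)])
    ranks = _midranks(combined)
    n1 = len(group1)
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def _exact_p(group1, group2, u_obs: float) -> float:
    """Two-sided p by full enumeration of rank assignments (no ties)."""
    n1, n2 = len(group1), len(group2)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    ranks = range(1, n + 1)
    base = n1 * (n1 + 1) / 2.0
    for combo in itertools.combinations(ranks, n1):
        u = sum(combo) - base
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            count += 1
    return count / total


def mann_whitney_u(group1, group2, alpha: float = 0.05) -> MWUResult:
    """Two-sided Mann-Whitney U test (U reported for group 1).

    Midrank U; tie-corrected variance
    ``Var = (n1 n2 / 12) * [(N+1) - sum(t^3 - t) / (N (N-1))]``; z with a
    0.5 continuity correction; two-sided p from the normal distribution.
    For N <= 12 with no ties the exact p is computed by enumerating all
    rank assignments instead.  All-tied data (zero variance) yields p = 1.
    """
    g1 = np.asarray(list(group1), dtype=float)
    g2 = np.asarray(list(group2), dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = int(g1.size), int(g2.size)
    n = n1 + n2
    u1 = _u_statistic(g1, g2)
    mu = n1 * n2 / 2.0

    combined = np.concatenate([g1, g2])
    _, counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    var = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))

    no_ties = bool(np.all(counts == 1))
    if n <= 12 and no_ties:
        p = _exact_p(g1, g2, u1)
        z = float("nan") if var <= 0 else (u1 - mu) / math.sqrt(var)
        return MWUResult(
            U=u1, n1=n1, n2=n2, z=z, p=p,
            significant=p < alpha, alpha=alpha, method="exact",
        )

    if var <= 0:
        return MWUResult(
            U=u1, n1=n1, n2=n2, z=0.0, p=1.0,
            significant=False, alpha=alpha, method="degenerate",
        )
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(norm.sf(z)))
    return MWUResult(
        U=u1, n1=n1, n2=n2, z=z, p=p,
        significant=p < alpha, alpha=alpha, method="normal",
    )


# Grouping predicates for the compliance/quality association (Figure-4
# style): full tier compliance, or compliance of the DWI / Dixon portion
# of the protocol alone.
GROUPINGS = {
    "full": None,
    "dwi": ("dwi_",),
    "dixon": ("dixon_",),
}


def _compliant_flag(matrix: CheckMatrix, exam_id: str, grouping: str) -> bool | None:
    prefixes = GROUPINGS[grouping]
    if prefixes is None:
        return matrix.row_fully_compliant(exam_id)
    row = matrix.row(exam_id)
    relevant = {c: s for c, s in row.items() if c.startswith(prefixes)}
    if not relevant:
        return None
    if all(s == NOT_PERFORMED for s in relevant.values()):
        return None  # series absent: cannot grade this portion of the protocol
    return all(s != FAIL for s in relevant.values())


def correlate_compliance_quality(
    matrix: CheckMatrix,
    scores: list[QualityScore],
    grouping: str = "full",
    score_channel: str = "overall",
    alpha: float = 0.05,
) -> MWUResult:
    """Mann-Whitney U comparison of quality scores between compliant and
    non-compliant exams.

    Only scored exams present in the matrix are used.  ``grouping``
    selects the compliance predicate: ``full`` (every check), ``dwi`` or
    ``dixon`` (that family's checks only; exams without the family are
    excluded).  A grouping with an empty compliant or non-compliant group
    is flagged as an error state in the result.
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}")
    in_matrix = set(matrix.exam_ids)
    compliant_scores: list[int] = []
    noncompliant_scores: list[int] = []
    for score in scores:
        if score.exam_id not in in_matrix:
            continue
        flag = _compliant_flag(matrix, score.exam_id, grouping)
        if flag is None:
            continue
        (compliant_scores if flag else noncompliant_scores).append(
            score.channel(score_channel)
        )
    if not compliant_scores or not noncompliant_scores:
        return MWUResult(
            U=float("nan"), n1=len(compliant_scores), n2=len(noncompliant_scores),
            z=float("nan"), p=float("nan"), significant=False, alpha=alpha,
            method="none", error="a compliance group has zero members",
        )
    return mann_whitney_u(compliant_scores, noncompliant_scores, alpha=alpha)


# Likert base distribution for score simulation: mostly good/excellent,
# mirroring a study population with generally diagnostic image quality.
_SCORE_P = np.array([0.05, 0.15, 0.40, 0.40])


def simulate_quality_scores(
    compliant: dict[str, bool],
    seed: int,
    effect: int = 0,
) -> list[QualityScore]:
    """Draw synthetic Likert scores for a set of exams.

    Compliant exams draw from a fixed 4-point distribution; non-compliant
    exams draw from the same distribution shifted down by ``effect``
    Likert points (clipped at 1).  ``effect=0`` gives the null scenario
    (scores independent of compliance)."""
    rng = np.random.default_rng(seed)
    out: list[QualityScore] = []
    for exam_id in sorted(compliant):
        draws = rng.choice([1, 2, 3, 4], size=3, p=_SCORE_P)
        if not compliant[exam_id] and effect:
            draws = np.maximum(1, draws - effect)
        out.append(
            QualityScore(
                exam_id=exam_id, overall=int(draws[0]), dwi=int(draws[1]), dixon=int(draws[2])
            )
        )
    return out
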