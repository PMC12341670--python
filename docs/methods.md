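# Methods

`protoqc` checks MRI examinations against an expected acquisition
protocol using DICOM header metadata only. This note records the
procedure, its assumptions, the tunable parameters, the design of the
synthetic cohort, and the known limitations.

## Reading examinations

An examination is a directory tree of DICOM Part-10 files. Files are
read with pydicom; non-DICOM clutter, hidden files and unreadable or
truncated files are skipped with a logged warning. Instances are grouped
into series by the pair (SeriesNumber `(0020,0011)`, AcquisitionNumber
`(0020,0012)`); within a group, instances are ordered by SliceLocation
`(0020,1041)` then TemporalPositionIdentifier `(0020,0100)`, absent
values last, with the source path as a final deterministic tie-break.
Instances without a SeriesNumber cannot be assigned and are kept in an
`unclassified` bucket — reported, never fatal. Reading the same
directory twice yields identical bundles, order included.

The sequence identifier of a series comes from the first present tag in
the chain SequenceName `(0018,0024)` → PulseSequenceName `(0018,9005)` →
ScanningSequence `(0018,0020)`, with the sentinel `UNKNOWN_SEQUENCE` when
all are absent. Parameter values are taken from the **first instance**
of the (ordered) series; intra-series parameter variation is out of
scope.

Two attribute names get dedicated handling:

* **Orientation** — the slice normal is the cross product of the row and
  column direction cosines of ImageOrientationPatient `(0020,0037)`; the
  stack is labelled by the patient axis carrying the largest |normal|
  component (x → sagittal, y → coronal, z → axial) when that component
  is ≥ 0.9, else `oblique`. The 0.9 obliquity threshold tolerates minor
  angulation (up to ≈ 25°) while rejecting genuinely oblique stacks.
  Malformed cosines in a damaged file are treated as an absent value.
* **DiffusionBValue** — resolved through a vendor-ordered tag chain
  selected by a case-insensitive Manufacturer prefix: Siemens private
  `(0019,100c)` / Philips private `(2001,1003)` / GE private
  `(0043,1039)` first (the GE value may carry a 10⁹ offset, which is
  stripped), then the standard `(0018,9087)`, then the remaining
  dialects. Private tags vary across vendor software versions; one
  documented variant per vendor is supported.

## The master file

The master file is a versioned JSON document (`schema_version` "1.0",
top-level keys `generic`, `series`, `attributes`) produced from an
exemplar examination: one series spec per acquired series with an exact
expectation for every attribute present, plus expected generic
attributes (Modality, MagneticFieldStrength, Manufacturer,
ManufacturerModelName). Validation on read collects **all** violations
(low > high, malformed expectation shapes, empty lists) rather than
stopping at the first. Expectations are either exact (scalar, string or
list) or inclusive `{"high": H, "low": L}` ranges; `Exact(v)` and
`Range(v, v)` are behaviourally identical. Values are stored exactly as
DICOM reports them (TR in ms); no unit conversion is performed. Every
spec carries `required: true` by default so that derived series such as
ADC maps can be marked optional, and a `role` label (`dwi_b50`,
`dixon_fat`, …) inferred from the series description, used to group
series into families for cohort audits. A master sequence id of `"*"`
matches any acquired sequence id; the shipped guideline-tier master uses
this because sequence naming is vendor-specific while series
descriptions are study-standardized.

## Checking

Matching is three-staged: (1) candidate pairs must share a sequence id
(exact, case-insensitive, or wildcard); (2) candidates must pass a
*partial* description match — bidirectional substring after lowercasing
and whitespace collapsing, because operators append suffixes ("repeat")
and sites truncate; (3) remaining ambiguity is resolved one-to-one by
maximizing total parameter agreement. Stage 3 enumerates assignments
exhaustively inside each connected ambiguity component (components are
tiny in practice — the series sharing one sequence id), with
deterministic tie-breaks: spec order, then ascending series number; a
greedy fallback covers pathological components beyond 8 specs. The
exhaustive rule was chosen over pure greedy because greedy provably
fails optimality on adversarial agreement matrices, and the audit's
correctness argument rests on the matcher recovering the intended
assignment.

Value comparison: exact numbers within a relative tolerance of 1e-6
(absolute 1e-9 near zero) to absorb DICOM decimal-string round-tripping;
strings case-insensitively after trimming; lists element-wise after
ascending sort, because dual-echo (Dixon) echo-time order varies by
vendor; ranges inclusive at both ends. An **absent** tag where a value
is expected counts as an explicit deviation, never a silent skip —
anonymization pipelines strip acquisition tags, and that damage should
surface in the report. A generic-attribute mismatch (wrong scanner) is
recorded but does not abort the series checks.

Every check carries one of three statuses: *pass*, *fail*, or *not
performed* (the owning series is missing, so there was nothing to
compare). An exam is fully compliant iff it has no missing required
series, no parameter deviation and no generic deviation; unexpected
extra series are reported but do not break compliance, since severity
grading of deviations is out of scope.

## Cohort audits

`build_matrix` lays per-exam results out as an exams × checks status
matrix (rows grouped by site); a *family* check (e.g. DWI repetition
time) fails if any member series fails, passes if at least one member
was compared and none failed, and is not-performed when the family is
absent. `summarize` computes per-check compliance over the *applicable*
exams — not-performed cells are excluded from the denominator, so
series-level checks are fractions of the exams that acquired that series
— while full-protocol compliance is over all exams, since an exam
missing a required series cannot be compliant. Percentages are rounded
half-up to one decimal place. Two tier definitions are shipped: the
guideline tier (series presence, slice thickness, orientation, b-value
ranges) and the site-protocol tier (exact b-values, averages, TR, TE,
TI, FA, bandwidth, resolution, plus the qualified-scanner check). The
Dixon series defines no inversion time (it is a spoiled gradient-echo
acquisition), so no Dixon TI check exists.

## Mann–Whitney U test

Image-quality scores are 4-point Likert ratings (Non-diagnostic = 1 …
Excellent = 4). Compliant and non-compliant exams are compared with a
two-sided Mann–Whitney U test implemented in the package: midrank U
statistic (reported for group 1), tie-corrected variance
`Var(U) = (n₁n₂/12)·[(N+1) − Σ(tⱼ³−tⱼ)/(N(N−1))]` over tie-group sizes
tⱼ, z with a 0.5 continuity correction, and a two-sided normal p-value.
For N ≤ 12 with no ties the exact p is computed by full enumeration of
rank assignments instead. Degenerate all-tied data yields p = 1. The
default α is 0.05, configurable. For the family-restricted groupings
(DWI-only, Dixon-only compliance) exams lacking the family are excluded
rather than counted as non-compliant, since that portion of the protocol
cannot be graded for them. The continuity-corrected normal approximation
agrees with exact enumeration to within 0.02 for untied samples at group
sizes around 5–7 (verified exhaustively; the bound does not hold for
groups smaller than 5, where the exact path is used anyway).

## The synthetic cohort

The generator emulates a ten-site whole-body MRI myeloma study. All
sites share one study protocol — axial DWI at b = 50/600/900 s·mm⁻²
(slice thickness 5 mm, TR 6240 ms, TE 73 ms, TI 180 ms at 1.5 T /
260 ms at 3 T, flip 90°, bandwidth 1964 Hz/px, 1.6 × 1.6 mm², averages
3/6/6), axial T1w Dixon fat + water (5 mm, TR 7.6 ms, TE 2.39/4.77 ms,
flip 16°, bandwidth 400, 0.8 × 0.8 mm²), and sagittal T1w/T2w spine
(4 mm) — while the vendor metadata dialect varies per site hardware
(eight Siemens sites at 1.5 T/3 T, one Philips, one GE). Exams carry two
8 × 8-pixel instances per series, the smallest payload that exercises
instance sorting; UIDs, dates and pixel content are deterministic
functions of the seed.

The 174-exam audit cohort distributes patients over the ten sites
(26/22/6/8/9/27/3/38/33/2) and injects deviations deterministically so
that the per-check compliant counts, the applicable-exam denominators
*and* the joint full-compliance counts (153/174 at the guideline tier,
70/174 at the site tier) hold simultaneously — the published-style
table gives only marginals, so the joint layout is this package's
construction, validated by assertion when the plan is built: five exams
at one site lack DWI and Dixon entirely; seven exams use an unqualified
scanner model; one site acquired all its Dixon (and DWI) imaging at
7 mm; one exam has an out-of-range b-value (650 s·mm⁻²); and 92 exams
carry site-protocol parameter deviations drawn from realistic deviant
values (TR 14.5 s / 4.2 ms, TE 83 / 1.8–4.9 ms, TI 160 ms, flip 22°,
bandwidth 1032 Hz/px, 3.4 × 3.4 and 1.3 × 1.3 mm², 2 averages). Two
sites are left fully clean at both tiers, four at the guideline tier.
The injected truth is written to a manifest, and the end-to-end oracle
of the test suite is exact truth recovery: the failing audit cells must
equal the injected plan, with no false positives and no misses.

What the generator does **not** emulate: realistic pixel content (checks
are header-only by design), per-site protocol differences beyond the
vendor dialect, intra-series parameter variation, partial anonymization
profiles beyond single-tag removal, and PACS/repository transfer. A
green suite therefore demonstrates metadata-path correctness, not
robustness to every real-world header layout — vendor private tags in
particular vary by software version.

Quality-score simulation draws Likert ratings from a fixed distribution
(P(1..4) = 0.05/0.15/0.40/0.40, a generally diagnostic population);
non-compliant exams are shifted down by a configurable number of Likert
points (0 = null scenario). The association test's type-I error under
the null and its power under a one-point shift are both exercised in the
test suite at the scored-subset size of 121 exams.

## Problem sizes and numerical choices

The audit cohort is desk-scale by construction: 174 exams × 14 tiny
files generate and check in well under a minute on one CPU, and the
whole test suite (including a 200-case fuzz suite and 2000 null
replicates of the association test) runs in about half a minute.
Deterministic tie-breaks appear wherever an ordering is not forced by
the data: file order within slices, series order by number, assignment
ties by spec order then series number, report field order fixed.
Reports are byte-identical across runs for identical inputs.

## Limitations

Only what the DICOM header records can be checked — RF coil
configuration or contrast timing cannot be monitored. Generating master
files from scanner protocol files, image-content-based series
classification, severity grading of deviations and repository (XNAT)
deployment are outside this package; the CLI's exit-code contract and
the documented `/input`–`/output` entry point are the integration
surface.
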