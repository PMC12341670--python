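"""Synthetic multicentre WB-MRI examinations for desk-scale testing.

This module writes minimal but valid DICOM Part-10 examinations emulating
a ten-site whole-body MRI myeloma study: axial DWI at three b-values,
axial T1w Dixon fat/water, and sagittal T1w/T2w spine imaging, across the
three vendor metadata dialects (Siemens sequence names and the
(0019,100c) private b-value tag; Philips pulse-sequence names and the
(2001,1003) private tag; GE scanning-sequence codes and the (0043,1039)
private tag with its 1e9-offset convention).  Every exam is deterministic
given its seed: two 8x8-pixel instances per series, the smallest payload
that still exercises instance sorting.

On top of single exams sit controlled *deviation injections* (alter a
parameter, drop a series, swap the scanner model, delete a tag) and a
deterministic 174-exam cohort plan whose injected deviations reproduce a
published-style compliance table exactly: per-check compliant counts,
applicable-exam denominators, and the joint full-compliance counts for
both checking tiers are all satisfied simultaneously.  The plan is
validated by assertion at construction, and the injected truth is written
to a manifest so audits can be verified against it with no false
positives or misses.
"""

from __future__ import annotations

import json
import logging
import os
import shutil
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

from .dicom_io import TagRef
from .master import (
    AttributeFile,
    Exact,
    MasterFile,
    Range,
    SeriesSpec,
    infer_role,
)

log = logging.getLogger(__name__)

__all__ = [
    "SeriesTemplate",
    "SiteProtocolTemplate",
    "DeviationInjection",
    "CohortSpec",
    "site_templates",
    "make_exam",
    "inject",
    "table3_cohort_spec",
    "make_cohort",
    "tier1_attributes",
    "tier2_attributes",
    "myrads_tier1_master",
    "DWI_FAMILY",
    "DIXON_FAMILY",
]

DWI_FAMILY = ("dwi_b50", "dwi_b600", "dwi_b900")
DIXON_FAMILY = ("dixon_fat", "dixon_water")

_IOP = {
    "axial": [1.0, 0.0, 0.0, 0.0, 1.0, 0.0],
    "sagittal": [0.0, 1.0, 0.0, 0.0, 0.0, -1.0],
    "coronal": [1.0, 0.0, 0.0, 0.0, 0.0, -1.0],
}


# ---------------------------------------------------------------------------
# Protocol templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeriesTemplate:
    """One series of the site protocol, with its acquisition parameters."""

    role: str
    series_number: int
    description: str
    orientation: str
    slice_thickness: float
    repetition_time: float
    echo_time: object  # scalar or [e1, e2] for dual-echo Dixon
    flip_angle: float
    pixel_bandwidth: float
    pixel_spacing: tuple[float, float]
    averages: float | None = None
    inversion_time: float | None = None
    b_value: int | None = None


@dataclass(frozen=True)
class SiteProtocolTemplate:
    """A site's qualified scanner plus its full series protocol."""

    site_id: str
    vendor: str  # "siemens" | "philips" | "ge"
    manufacturer: str
    model: str
    field_strength: float
    series: tuple[SeriesTemplate, ...]


def _protocol_series(field_strength: float) -> tuple[SeriesTemplate, ...]:
    """The shared study protocol (inversion time is field-strength
    dependent: 180 ms at 1.5 T, 260 ms at 3 T)."""
    ti = 180.0 if field_strength < 2.0 else 260.0
    dwi_common = dict(
        orientation="axial",
        slice_thickness=5.0,
        repetition_time=6240.0,
        echo_time=73.0,
        flip_angle=90.0,
        pixel_bandwidth=1964.0,
        pixel_spacing=(1.6, 1.6),
        inversion_time=ti,
    )
    dixon_common = dict(
        orientation="axial",
        slice_thickness=5.0,
        repetition_time=7.6,
        echo_time=[2.39, 4.77],
        flip_angle=16.0,
        pixel_bandwidth=400.0,
        pixel_spacing=(0.8, 0.8),
        averages=1.0,
    )
    spine_common = dict(
        orientation="sagittal",
        slice_thickness=4.0,
        flip_angle=150.0,
        pixel_bandwidth=200.0,
        pixel_spacing=(1.0, 1.0),
        averages=2.0,
    )
    return (
        SeriesTemplate(role="dwi_b50", series_number=1, description="DWI b50",
                       averages=3.0, b_value=50, **dwi_common),
        SeriesTemplate(role="dwi_b600", series_number=2, description="DWI b600",
                       averages=6.0, b_value=600, **dwi_common),
        SeriesTemplate(role="dwi_b900", series_number=3, description="DWI b900",
                       averages=6.0, b_value=900, **dwi_common),
        SeriesTemplate(role="dixon_fat", series_number=4, description="T1W DIXON FAT",
                       **dixon_common),
        SeriesTemplate(role="dixon_water", series_number=5, description="T1W DIXON WATER",
                       **dixon_common),
        SeriesTemplate(role="t1w_spine", series_number=6, description="T1W SAG SPINE",
                       repetition_time=600.0, echo_time=10.0, **spine_common),
        SeriesTemplate(role="t2w_spine", series_number=7, description="T2W SAG SPINE",
                       repetition_time=4500.0, echo_time=90.0, **spine_common),
    )


_SITE_HARDWARE = [
    # (site, vendor, manufacturer string, model, field strength, n patients)
    ("site01", "siemens", "Siemens Healthcare", "Aera", 1.5, 26),
    ("site02", "siemens", "Siemens Healthcare", "Aera", 1.5, 22),
    ("site03", "siemens", "Siemens Healthcare", "Avanto", 1.5, 6),
    ("site04", "philips", "Philips Medical Systems", "Ingenia", 1.5, 8),
    ("site05", "siemens", "Siemens Healthcare", "Skyra", 3.0, 9),
    ("site06", "siemens", "Siemens Healthcare", "Aera", 1.5, 27),
    ("site07", "siemens", "Siemens Healthcare", "Aera", 1.5, 3),
    ("site08", "siemens", "Siemens Healthcare", "Aera", 1.5, 38),
    ("site09", "siemens", "Siemens Healthcare", "Aera", 1.5, 33),
    ("site10", "ge", "GE MEDICAL SYSTEMS", "Discovery MR750w", 3.0, 2),
]

SITE_PATIENTS = {row[0]: row[5] for row in _SITE_HARDWARE}
N_EXAMS = sum(SITE_PATIENTS.values())  # 174


def site_templates() -> dict[str, SiteProtocolTemplate]:
    """The ten site templates (vendor dialect varies, protocol shared)."""
    out = {}
    for site, vendor, manufacturer, model, fs, _n in _SITE_HARDWARE:
        out[site] = SiteProtocolTemplate(
            site_id=site,
            vendor=vendor,
            manufacturer=manufacturer,
            model=model,
            field_strength=fs,
            series=_protocol_series(fs),
        )
    return out


# ---------------------------------------------------------------------------
# Attribute files and the guideline-level (tier-1) master
# ---------------------------------------------------------------------------


def tier1_attributes() -> AttributeFile:
    """Guideline-level attributes: geometry and diffusion weighting."""
    return AttributeFile((
        TagRef(0x0018, 0x0050, "SliceThickness"),
        TagRef(0x0020, 0x0037, "Orientation"),
        TagRef(0x0018, 0x9087, "DiffusionBValue"),
    ))


def tier2_attributes() -> AttributeFile:
    """Site-protocol attributes: the detailed parameter set."""
    return AttributeFile((
        TagRef(0x0018, 0x9087, "DiffusionBValue"),
        TagRef(0x0018, 0x0083, "NumberOfAverages"),
        TagRef(0x0018, 0x0080, "RepetitionTime"),
        TagRef(0x0018, 0x0081, "EchoTime"),
        TagRef(0x0018, 0x0082, "InversionTime"),
        TagRef(0x0018, 0x1314, "FlipAngle"),
        TagRef(0x0018, 0x0095, "PixelBandwidth"),
        TagRef(0x0028, 0x0030, "PixelSpacing"),
    ))


def myrads_tier1_master() -> MasterFile:
    """The guideline-level expected protocol, shared by every site.

    Sequence ids are wildcards (vendors name sequences differently);
    series are discriminated by description.  Slice thickness is exact
    5 mm for DWI/Dixon and an inclusive 4-5 mm range for spine imaging;
    b-values are the guideline ranges 50-100 / 500-600 / 800-900.
    """
    st5 = Exact(5)
    st45 = Range(4, 5)
    axial = Exact("axial")
    sagittal = Exact("sagittal")

    def spec(role, desc, params):
        return SeriesSpec(sequence_id="*", series_description=desc, params=params, role=role)

    return MasterFile(
        generic={"Modality": Exact("MR")},
        series_specs=[
            spec("dwi_b50", "DWI b50",
                 {"SliceThickness": st5, "Orientation": axial, "DiffusionBValue": Range(50, 100)}),
            spec("dwi_b600", "DWI b600",
                 {"SliceThickness": st5, "Orientation": axial, "DiffusionBValue": Range(500, 600)}),
            spec("dwi_b900", "DWI b900",
                 {"SliceThickness": st5, "Orientation": axial, "DiffusionBValue": Range(800, 900)}),
            spec("dixon_fat", "T1W DIXON FAT", {"SliceThickness": st5, "Orientation": axial}),
            spec("dixon_water", "T1W DIXON WATER", {"SliceThickness": st5, "Orientation": axial}),
            spec("t1w_spine", "T1W SAG SPINE", {"SliceThickness": st45, "Orientation": sagittal}),
            spec("t2w_spine", "T2W SAG SPINE", {"SliceThickness": st45, "Orientation": sagittal}),
        ],
        attribute_names=tier1_attributes().names,
    )


# ---------------------------------------------------------------------------
# DICOM writing
# ---------------------------------------------------------------------------


def _uid(*parts) -> str:
    return generate_uid(entropy_srcs=[str(p) for p in parts])


def _set_sequence_tags(ds: Dataset, vendor: str, series: SeriesTemplate) -> None:
    kind = "dwi" if series.role.startswith("dwi") else (
        "dixon" if series.role.startswith("dixon") else "spine"
    )
    if vendor == "siemens":
        ds.ScanningSequence = {"dwi": "EP", "dixon": "GR", "spine": "SE"}[kind]
        if kind == "dwi":
            ds.SequenceName = f"*ep_b{series.b_value}"
        elif kind == "dixon":
            ds.SequenceName = "*fl3d2"
        else:
            ds.SequenceName = "*tse2d1"
    elif vendor == "philips":
        ds.ScanningSequence = {"dwi": "EP", "dixon": "GR", "spine": "SE"}[kind]
        ds.PulseSequenceName = {"dwi": "DwiSE", "dixon": "T1FFE", "spine": "TSE"}[kind]
    else:  # ge: only the generic scanning-sequence code
        ds.ScanningSequence = {"dwi": "EP", "dixon": "GR", "spine": "SE"}[kind]


def _set_bvalue(ds: Dataset, vendor: str, b_value: int) -> None:
    if vendor == "siemens":
        block = ds.private_block(0x0019, "SIEMENS MR HEADER", create=True)
        block.add_new(0x0C, "IS", str(b_value))
    elif vendor == "philips":
        block = ds.private_block(0x2001, "Philips Imaging DD 001", create=True)
        block.add_new(0x03, "FL", float(b_value))
    else:  # ge, with the 1e9 offset convention
        block = ds.private_block(0x0043, "GEMS_PARM_01", create=True)
        block.add_new(0x39, "IS", [str(1000000000 + b_value), "8", "0", "0"])


_PIXELS = (np.arange(64, dtype=np.uint16) % 32).reshape(8, 8)


def _build_instance(
    template: SiteProtocolTemplate,
    series: SeriesTemplate,
    exam_id: str,
    study_uid: str,
    series_uid: str,
    instance_index: int,
    seed: int,
) -> Dataset:
    ds = Dataset()
    ds.file_meta = FileMetaDataset()
    ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds.file_meta.MediaStorageSOPClassUID = MRImageStorage
    sop_uid = _uid(seed, exam_id, series.series_number, instance_index, "sop")
    ds.file_meta.MediaStorageSOPInstanceUID = sop_uid

    ds.SOPClassUID = MRImageStorage
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "MR"
    ds.Manufacturer = template.manufacturer
    ds.ManufacturerModelName = template.model
    ds.MagneticFieldStrength = template.field_strength
    ds.PatientName = exam_id
    ds.PatientID = exam_id
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.StudyDate = "20240101"
    ds.SeriesDate = "20240101"
    ds.StudyTime = "120000"
    ds.StudyID = "1"
    ds.SeriesNumber = series.series_number
    ds.AcquisitionNumber = 1
    ds.InstanceNumber = instance_index + 1
    ds.SeriesDescription = series.description

    ds.SliceThickness = series.slice_thickness
    ds.SliceLocation = instance_index * series.slice_thickness
    ds.ImageOrientationPatient = list(_IOP[series.orientation])
    ds.ImagePositionPatient = [0.0, 0.0, instance_index * series.slice_thickness]
    ds.RepetitionTime = series.repetition_time
    ds.EchoTime = series.echo_time
    ds.FlipAngle = series.flip_angle
    ds.PixelBandwidth = series.pixel_bandwidth
    ds.PixelSpacing = list(series.pixel_spacing)
    if series.averages is not None:
        ds.NumberOfAverages = series.averages
    if series.inversion_time is not None and series.role.startswith("dwi"):
        ds.InversionTime = series.inversion_time

    _set_sequence_tags(ds, template.vendor, series)
    if series.b_value is not None:
        _set_bvalue(ds, template.vendor, series.b_value)

    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = 8
    ds.Columns = 8
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = _PIXELS.tobytes()
    return ds


def make_exam(
    template: SiteProtocolTemplate,
    exam_id: str,
    out_dir: str,
    seed: int = 0,
) -> str:
    """Write one examination (two instances per series) under
    ``out_dir/exam_id``; byte-identical for identical seed and inputs."""
    exam_dir = os.path.join(out_dir, exam_id)
    os.makedirs(exam_dir, exist_ok=True)
    study_uid = _uid(seed, exam_id, "study")
    for series in template.series:
        series_uid = _uid(seed, exam_id, series.series_number, "series")
        for i in range(2):
            ds = _build_instance(template, series, exam_id, study_uid, series_uid, i, seed)
            fname = f"s{series.series_number:02d}_i{i}.dcm"
            ds.save_as(os.path.join(exam_dir, fname), enforce_file_format=True)
    return exam_dir


# ---------------------------------------------------------------------------
# Deviation injection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeviationInjection:
    """One planned protocol deviation for one exam.

    ``check_name`` names the audit column the deviation breaks (the
    manifest truth); ``target`` is the tuple of series roles affected
    (empty for generic-attribute actions)."""

    exam_index: int
    check_name: str
    action: str  # set_param | drop_series | set_generic | remove_tag
    target: tuple[str, ...] = ()
    param: str | None = None
    value: object = None


_ORIENTATION_LABELS = set(_IOP)


def _apply_param(ds: Dataset, param: str, value) -> None:
    if param == "DiffusionBValue":
        vendor = str(ds.get("Manufacturer", "")).casefold()
        vendor = ("siemens" if vendor.startswith("siemens")
                  else "philips" if vendor.startswith("philips")
                  else "ge" if vendor.startswith("ge") else "siemens")
        _set_bvalue(ds, vendor, int(value))
    elif param == "Orientation":
        label = str(value)
        if label not in _ORIENTATION_LABELS:
            raise ValueError(f"unknown orientation label {label!r}")
        ds.ImageOrientationPatient = list(_IOP[label])
    else:
        setattr(ds, param, value)


def inject(exam_dir: str, deviation: DeviationInjection) -> str:
    """Apply one deviation to an already-written exam directory.

    Only the targeted tags/series change; every other decoded value is
    untouched.  Dropping an absent series or naming an unknown action is
    an error."""
    files_by_role: dict[str, list[str]] = {}
    datasets: dict[str, pydicom.Dataset] = {}
    for fname in sorted(os.listdir(exam_dir)):
        if fname.startswith("."):
            continue
        path = os.path.join(exam_dir, fname)
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue
        role = infer_role(str(ds.get("SeriesDescription", "")))
        files_by_role.setdefault(role or "", []).append(path)
        datasets[path] = ds

    if deviation.action == "drop_series":
        for role in deviation.target:
            paths = files_by_role.get(role)
            if not paths:
                raise ValueError(f"cannot drop absent series {role!r} in {exam_dir}")
            for path in paths:
                os.remove(path)
        return exam_dir

    if deviation.action == "set_generic":
        for path, ds in datasets.items():
            setattr(ds, deviation.param, deviation.value)
            ds.save_as(path, enforce_file_format=True)
        return exam_dir

    if deviation.action in ("set_param", "remove_tag"):
        touched = False
        for role in deviation.target:
            for path in files_by_role.get(role, []):
                ds = datasets[path]
                if deviation.action == "set_param":
                    _apply_param(ds, deviation.param, deviation.value)
                elif hasattr(ds, deviation.param):
                    delattr(ds, deviation.param)
                ds.save_as(path, enforce_file_format=True)
                touched = True
        if not touched:
            raise ValueError(
                f"injection target {deviation.target} not found in {exam_dir}"
            )
        return exam_dir

    raise ValueError(f"unknown injection action {deviation.action!r}")


# ---------------------------------------------------------------------------
# The published-table cohort plan
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Deterministic plan for a synthetic cohort: site assignment plus the
    full deviation-injection list, all derived from one seed."""

    n_exams: int
    site_assignment: list[str]  # exam index -> site id
    injections: list[DeviationInjection]
    seed: int
    expected: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def exam_id(self, index: int) -> str:
        return f"exam{index:03d}"


def _site_assignment() -> list[str]:
    out: list[str] = []
    for site, _v, _m, _mod, _fs, n in _SITE_HARDWARE:
        out.extend([site] * n)
    return out


# Audit-column membership of each injectable check, per tier.
_TIER1_CHECKS = {
    "all_series", "dwi_slice_thickness", "dixon_slice_thickness",
    "t1w_slice_thickness", "t2w_slice_thickness",
    "dwi_b50", "dwi_b600", "dwi_b900",
}
_TIER2_CHECKS = {
    "correct_scanner", "all_series",
    "dwi_b50", "dwi_b600", "dwi_b900",
    "dwi_averages", "dwi_tr", "dwi_te", "dwi_ti", "dwi_fa", "dwi_bw",
    "dwi_resolution", "dixon_tr", "dixon_te", "dixon_fa", "dixon_bw",
    "dixon_resolution",
}


def _tier2_slot_exam(slot: int) -> int:
    """Map the 92 tier-2 deviation slots onto exam indices: sites 1-5
    (exams 0-70), then site 8 (101-120), then one GE exam (172)."""
    if slot <= 70:
        return slot
    if slot <= 90:
        return 101 + (slot - 71)
    return 172


def table3_cohort_spec(seed: int = 0) -> CohortSpec:
    """The deterministic 174-exam cohort whose injected deviations
    reproduce the study compliance table.

    Layout: 5 exams (one site) lack DWI and Dixon entirely; 7 exams were
    acquired on an unqualified scanner model; one site acquired all its
    Dixon imaging at 7 mm slice thickness; parameter deviations are packed
    over 92 exams so that every per-check compliant count, both
    full-compliance counts (153 of 174 at the guideline tier, 70 of 174 at
    the site-protocol tier), and the clean-site counts hold at once.
    Internal consistency is asserted at construction.
    """
    inj: list[DeviationInjection] = []

    def add(idx, check, action, target=(), param=None, value=None):
        inj.append(DeviationInjection(idx, check, action, tuple(target), param, value))

    # --- series presence: 5 exams without DWI or Dixon -------------------
    missing = list(range(139, 144))
    for i in missing:
        add(i, "all_series", "drop_series", DWI_FAMILY)
        add(i, "all_series", "drop_series", DIXON_FAMILY)

    # --- guideline-tier slice-thickness deviations -----------------------
    dwi_st = list(range(54, 62)) + list(range(101, 105))          # 12 exams
    dixon_st = list(range(54, 62)) + list(range(101, 106))        # 13 exams
    for i in dwi_st:
        add(i, "dwi_slice_thickness", "set_param", DWI_FAMILY, "SliceThickness", 7)
    for i in dixon_st:
        add(i, "dixon_slice_thickness", "set_param", DIXON_FAMILY, "SliceThickness", 7)
    for i in (0, 62, 139):                                        # 3 exams
        add(i, "t1w_slice_thickness", "set_param", ("t1w_spine",), "SliceThickness", 3)
    add(26, "t2w_slice_thickness", "set_param", ("t2w_spine",), "SliceThickness", 3)
    # One exam with an out-of-range diffusion weighting (fails both tiers).
    add(26, "dwi_b600", "set_param", ("dwi_b600",), "DiffusionBValue", 650)

    # --- unqualified scanner model on 7 exams ----------------------------
    for i in range(144, 151):
        add(i, "correct_scanner", "set_generic", (), "ManufacturerModelName", "Avanto")

    # --- site-protocol parameter deviations over 92 slots ----------------
    def slots(lo, hi):
        return [_tier2_slot_exam(s) for s in range(lo, hi + 1)]

    for i in slots(0, 41):
        add(i, "dixon_tr", "set_param", DIXON_FAMILY, "RepetitionTime", 4.2)
    for i in slots(42, 72):
        add(i, "dwi_tr", "set_param", DWI_FAMILY, "RepetitionTime", 14500)
    for i in slots(73, 91) + slots(0, 5):
        add(i, "dwi_averages", "set_param", ("dwi_b600",), "NumberOfAverages", 2)
    for i in slots(6, 24):
        add(i, "dixon_fa", "set_param", DIXON_FAMILY, "FlipAngle", 22)
    for i in slots(25, 39):
        add(i, "dixon_bw", "set_param", DIXON_FAMILY, "PixelBandwidth", 1032)
    for i in slots(40, 52):
        add(i, "dwi_resolution", "set_param", DWI_FAMILY, "PixelSpacing", [3.4, 3.4])
    for i in slots(53, 62):
        add(i, "dixon_te", "set_param", DIXON_FAMILY, "EchoTime", [1.8, 4.9])
    for i in slots(63, 71):
        add(i, "dwi_te", "set_param", DWI_FAMILY, "EchoTime", 83)
    for i in slots(72, 80):
        add(i, "dixon_resolution", "set_param", DIXON_FAMILY, "PixelSpacing", [1.3, 1.3])
    for i in slots(81, 81):
        add(i, "dwi_ti", "set_param", DWI_FAMILY, "InversionTime", 160)

    spec = CohortSpec(
        n_exams=N_EXAMS,
        site_assignment=_site_assignment(),
        injections=inj,
        seed=seed,
    )
    spec.expected = _validate_plan(spec)
    return spec


def _validate_plan(spec: CohortSpec) -> dict[str, dict[str, tuple[int, int]]]:
    """Check the plan's marginal and joint counts; returns the expected
    (n_compliant, n_applicable) per audit column for both tiers."""
    n = spec.n_exams
    assert n == 174 and len(spec.site_assignment) == n

    missing = {d.exam_index for d in spec.injections if d.action == "drop_series"}
    deviants: dict[str, set[int]] = {}
    seen: set[tuple[int, str, str | None]] = set()
    for d in spec.injections:
        if d.action in ("set_param", "set_generic"):
            deviants.setdefault(d.check_name, set()).add(d.exam_index)
            for role in d.target or ("",):
                key = (d.exam_index, role, d.param)
                assert key not in seen, f"conflicting injections on {key}"
                seen.add(key)
            assert d.exam_index not in missing or d.target == ("t1w_spine",) or not set(
                d.target
            ) & set(DWI_FAMILY + DIXON_FAMILY), (
                f"injection {d.check_name} targets a dropped series on exam {d.exam_index}"
            )

    n_present = n - len(missing)  # exams with DWI and Dixon acquired

    def expect(check: str, n_deviant: int, denom: int) -> tuple[int, int]:
        got = len(deviants.get(check, set()))
        assert got == n_deviant, f"{check}: planned {got} deviants, expected {n_deviant}"
        return (denom - n_deviant, denom)

    tier1 = {
        "all_series": (n_present, n),
        "dwi_slice_thickness": expect("dwi_slice_thickness", 12, n_present),
        "dwi_orientation": (n_present, n_present),
        "dwi_b50": (n_present, n_present),
        "dwi_b600": expect("dwi_b600", 1, n_present),
        "dwi_b900": (n_present, n_present),
        "dixon_slice_thickness": expect("dixon_slice_thickness", 13, n_present),
        "dixon_orientation": (n_present, n_present),
        "dixon_fat": (n_present, n_present),
        "dixon_water": (n_present, n_present),
        "t1w_slice_thickness": expect("t1w_slice_thickness", 3, n),
        "t1w_orientation": (n, n),
        "t2w_slice_thickness": expect("t2w_slice_thickness", 1, n),
        "t2w_orientation": (n, n),
    }
    tier1_bad = missing | set().union(
        *(deviants.get(c, set()) for c in _TIER1_CHECKS)
    )
    tier1["full_compliance"] = (n - len(tier1_bad), n)
    assert tier1["full_compliance"] == (153, 174), tier1["full_compliance"]

    tier2 = {
        "correct_scanner": expect("correct_scanner", 7, n),
        "all_series": (n_present, n),
        "dwi_b50": (n_present, n_present),
        "dwi_b600": (n_present - 1, n_present),
        "dwi_b900": (n_present, n_present),
        "dwi_averages": expect("dwi_averages", 25, n_present),
        "dwi_tr": expect("dwi_tr", 31, n_present),
        "dwi_te": expect("dwi_te", 9, n_present),
        "dwi_ti": expect("dwi_ti", 1, n_present),
        "dwi_fa": (n_present, n_present),
        "dwi_bw": (n_present, n_present),
        "dwi_resolution": expect("dwi_resolution", 13, n_present),
        "dixon_tr": expect("dixon_tr", 42, n_present),
        "dixon_te": expect("dixon_te", 10, n_present),
        "dixon_fa": expect("dixon_fa", 19, n_present),
        "dixon_bw": expect("dixon_bw", 15, n_present),
        "dixon_resolution": expect("dixon_resolution", 9, n_present),
    }
    tier2_bad = missing | set().union(
        *(deviants.get(c, set()) for c in _TIER2_CHECKS)
    )
    tier2["full_compliance"] = (n - len(tier2_bad), n)
    assert tier2["full_compliance"] == (70, 174), tier2["full_compliance"]

    assert len(missing) == 5
    return {"tier1": tier1, "tier2": tier2}


def cohort_spec_to_json(spec: CohortSpec, path: str) -> None:
    data = {
        "n_exams": spec.n_exams,
        "site_assignment": list(spec.site_assignment),
        "seed": spec.seed,
        "injections": [
            {
                "exam_index": d.exam_index,
                "check_name": d.check_name,
                "action": d.action,
                "target": list(d.target),
                "param": d.param,
                "value": d.value,
            }
            for d in spec.injections
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


def cohort_spec_from_json(path: str, seed: int | None = None) -> CohortSpec:
    """Load a custom cohort plan; basic consistency is validated (an
    infeasible plan raises)."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    injections = [
        DeviationInjection(
            exam_index=int(d["exam_index"]),
            check_name=str(d["check_name"]),
            action=str(d["action"]),
            target=tuple(d.get("target") or ()),
            param=d.get("param"),
            value=d.get("value"),
        )
        for d in data.get("injections", [])
    ]
    spec = CohortSpec(
        n_exams=int(data["n_exams"]),
        site_assignment=[str(s) for s in data["site_assignment"]],
        injections=injections,
        seed=int(data["seed"] if seed is None else seed),
    )
    if len(spec.site_assignment) != spec.n_exams:
        raise ValueError("site_assignment length must equal n_exams")
    known = set(site_templates())
    unknown = sorted(set(spec.site_assignment) - known)
    if unknown:
        raise ValueError(f"unknown sites in assignment: {unknown}")
    for d in injections:
        if not (0 <= d.exam_index < spec.n_exams):
            raise ValueError(f"injection exam index {d.exam_index} out of range")
    return spec


def make_cohort(spec: CohortSpec, out_dir: str) -> str:
    """Generate every exam of the cohort plan plus its truth manifest.

    Writes one subdirectory per exam, ``manifest.csv`` (exam -> site) and
    ``injections.csv`` (the injected truth, for oracle comparison).
    Deterministic given ``spec.seed``; partial output is removed on
    failure."""
    import pandas as pd

    templates = site_templates()
    os.makedirs(out_dir, exist_ok=True)
    by_exam: dict[int, list[DeviationInjection]] = {}
    for d in spec.injections:
        by_exam.setdefault(d.exam_index, []).append(d)

    try:
        for i in range(spec.n_exams):
            exam_id = spec.exam_id(i)
            template = templates[spec.site_assignment[i]]
            exam_seed = (spec.seed * 100003 + i) % (2**31)
            exam_dir = make_exam(template, exam_id, out_dir, seed=exam_seed)
            # Drops must run last so parameter injections still find their
            # target series files.
            devs = sorted(
                by_exam.get(i, []), key=lambda d: (d.action == "drop_series",)
            )
            for dev in devs:
                if dev.action != "drop_series" and set(dev.target) & set(
                    DWI_FAMILY + DIXON_FAMILY
                ) and any(x.action == "drop_series" for x in by_exam.get(i, [])):
                    continue  # series planned for removal anyway
                inject(exam_dir, dev)
    except Exception:
        shutil.rmtree(out_dir, ignore_errors=True)
        raise

    manifest = pd.DataFrame(
        {
            "exam_id": [spec.exam_id(i) for i in range(spec.n_exams)],
            "site": list(spec.site_assignment),
        }
    )
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)

    truth = pd.DataFrame(
        [
            {
                "exam_id": spec.exam_id(d.exam_index),
                "site": spec.site_assignment[d.exam_index],
                "check_name": d.check_name,
                "action": d.action,
                "target": "|".join(d.target),
                "param": d.param or "",
                "value": json.dumps(d.value),
            }
            for d in spec.injections
        ]
    )
    truth.to_csv(os.path.join(out_dir, "injections.csv"), index=False)
    return out_dir
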