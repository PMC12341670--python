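"""Read DICOM examination trees into lightweight metadata bundles.

An *examination* is a directory tree of DICOM Part-10 files.  This module
reads every file it can, groups instances into series by their
SeriesNumber/AcquisitionNumber tags, extracts the sequence identifier and
the acquisition parameters a study cares about, and classifies the slice
orientation from the image direction cosines.  Pixel data are never
interpreted; the whole pipeline works from the DICOM header only.

The reader is deliberately resilient: malformed or non-DICOM files are
skipped with a logged warning, instances that cannot be assigned to a
series land in an ``unclassified`` bucket, and an empty directory yields a
structured error state rather than an exception.  Compliance audits over
hundreds of exams must never abort on a single corrupt file.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pydicom
from pydicom.errors import InvalidDicomError

log = logging.getLogger(__name__)

__all__ = [
    "TagRef",
    "InstanceRecord",
    "SeriesBundle",
    "GenericAttributes",
    "ExamBundle",
    "read_exam",
    "read_instance",
    "sort_into_series",
    "extract_sequence_id",
    "extract_params",
    "extract_generic",
    "classify_orientation",
    "vendor_of",
    "UNKNOWN_SEQUENCE",
]

UNKNOWN_SEQUENCE = "UNKNOWN_SEQUENCE"

_TAG_PATTERN = re.compile(r"^\(\s*([0-9a-fA-F]{4})\s*,\s*([0-9a-fA-F]{4})\s*\)$")


@dataclass(frozen=True, eq=False)
class TagRef:
    """A DICOM attribute reference: (group, element) plus a human label.

    Equality and hashing use the (group, element) pair only, so two
    references to the same tag under different labels collide rather than
    silently duplicating entries in a tag map.
    """

    group: int
    element: int
    name: str

    def __post_init__(self) -> None:
        for part in (self.group, self.element):
            if not (0x0000 <= part <= 0xFFFF):
                raise ValueError(f"tag component {part:#x} outside [0x0000, 0xFFFF]")
        if not self.name:
            raise ValueError("TagRef name must be non-empty")

    def __str__(self) -> str:
        return f"({self.group:04x},{self.element:04x})"

    def __repr__(self) -> str:
        return f"TagRef({self}, {self.name!r})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TagRef):
            return NotImplemented
        return (self.group, self.element) == (other.group, other.element)

    def __hash__(self) -> int:
        return hash((self.group, self.element))

    @classmethod
    def parse(cls, text: str, name: str) -> "TagRef":
        """Parse a ``(gggg,eeee)`` rendering back into a TagRef (lossless)."""
        m = _TAG_PATTERN.match(text.strip())
        if m is None:
            raise ValueError(f"not a (gggg,eeee) tag rendering: {text!r}")
        return cls(int(m.group(1), 16), int(m.group(2), 16), name)


# Tags used for series identity, ordering and generic attributes.
SERIES_NUMBER = TagRef(0x0020, 0x0011, "SeriesNumber")
ACQUISITION_NUMBER = TagRef(0x0020, 0x0012, "AcquisitionNumber")
SLICE_LOCATION = TagRef(0x0020, 0x1041, "SliceLocation")
TEMPORAL_POSITION = TagRef(0x0020, 0x0100, "TemporalPositionIdentifier")
SERIES_DESCRIPTION = TagRef(0x0008, 0x103E, "SeriesDescription")
SEQUENCE_NAME = TagRef(0x0018, 0x0024, "SequenceName")
PULSE_SEQUENCE_NAME = TagRef(0x0018, 0x9005, "PulseSequenceName")
SCANNING_SEQUENCE = TagRef(0x0018, 0x0020, "ScanningSequence")
MODALITY = TagRef(0x0008, 0x0060, "Modality")
FIELD_STRENGTH = TagRef(0x0018, 0x0087, "MagneticFieldStrength")
MANUFACTURER = TagRef(0x0008, 0x0070, "Manufacturer")
MODEL_NAME = TagRef(0x0008, 0x1090, "ManufacturerModelName")
IMAGE_ORIENTATION = TagRef(0x0020, 0x0037, "ImageOrientationPatient")

# Diffusion b-value: the standard tag plus the three vendor private dialects.
BVALUE_STANDARD = TagRef(0x0018, 0x9087, "DiffusionBValue")
BVALUE_SIEMENS = TagRef(0x0019, 0x100C, "DiffusionBValueSiemens")
BVALUE_PHILIPS = TagRef(0x2001, 0x1003, "DiffusionBValuePhilips")
BVALUE_GE = TagRef(0x0043, 0x1039, "DiffusionBValueGE")

PRIVATE_CREATORS = {
    BVALUE_SIEMENS: "SIEMENS MR HEADER",
    BVALUE_PHILIPS: "Philips Imaging DD 001",
    BVALUE_GE: "GEMS_PARM_01",
}

# Vendor-ordered fallback chains for the b-value (vendor private tag first,
# then the standard tag, then the remaining dialects as a last resort).
_BVALUE_CHAINS = {
    "siemens": [BVALUE_SIEMENS, BVALUE_STANDARD, BVALUE_PHILIPS, BVALUE_GE],
    "philips": [BVALUE_PHILIPS, BVALUE_STANDARD, BVALUE_SIEMENS, BVALUE_GE],
    "ge": [BVALUE_GE, BVALUE_STANDARD, BVALUE_SIEMENS, BVALUE_PHILIPS],
    "": [BVALUE_STANDARD, BVALUE_SIEMENS, BVALUE_PHILIPS, BVALUE_GE],
}

_CORE_TAGS = [
    SERIES_NUMBER,
    ACQUISITION_NUMBER,
    SLICE_LOCATION,
    TEMPORAL_POSITION,
    SERIES_DESCRIPTION,
    SEQUENCE_NAME,
    PULSE_SEQUENCE_NAME,
    SCANNING_SEQUENCE,
    MODALITY,
    FIELD_STRENGTH,
    MANUFACTURER,
    MODEL_NAME,
    IMAGE_ORIENTATION,
    BVALUE_STANDARD,
    BVALUE_SIEMENS,
    BVALUE_PHILIPS,
    BVALUE_GE,
]


@dataclass
class InstanceRecord:
    """One DICOM instance, reduced to the tag values a check can use."""

    source_path: str
    tags: dict[TagRef, object]
    has_pixel_data: bool = False

    def get(self, tag: TagRef, default=None):
        return self.tags.get(tag, default)


@dataclass
class SeriesBundle:
    """A group of instances acquired as one sequence run."""

    series_number: int
    acquisition_number: int | None
    instances: list[InstanceRecord]
    sequence_id: str = UNKNOWN_SEQUENCE
    series_description: str = ""
    params: dict[str, object] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.series_description or f"series {self.series_number}"


@dataclass
class GenericAttributes:
    """Acquisition-level attributes shared by every series of an exam.

    Each field may independently be absent (``None``), e.g. after
    aggressive anonymization.
    """

    modality: str | None = None
    field_strength: float | None = None
    manufacturer: str | None = None
    model: str | None = None

    def as_dict(self) -> dict[str, object]:
        out: dict[str, object] = {}
        if self.modality is not None:
            out["Modality"] = self.modality
        if self.field_strength is not None:
            out["MagneticFieldStrength"] = self.field_strength
        if self.manufacturer is not None:
            out["Manufacturer"] = self.manufacturer
        if self.model is not None:
            out["ManufacturerModelName"] = self.model
        return out


@dataclass
class ExamBundle:
    """One examination: generic attributes plus its sorted series."""

    exam_id: str
    generic: GenericAttributes
    series: list[SeriesBundle]
    unclassified: list[InstanceRecord] = field(default_factory=list)
    error: str | None = None

    @property
    def n_instances(self) -> int:
        return sum(len(s.instances) for s in self.series) + len(self.unclassified)


def _plain(value):
    """Convert a pydicom element value to a plain python scalar/str/list."""
    from pydicom.multival import MultiValue
    from pydicom.valuerep import DSfloat, DSdecimal, IS, PersonName

    if isinstance(value, (MultiValue, list, tuple)):
        return [_plain(v) for v in value]
    if isinstance(value, (DSfloat, DSdecimal)):
        return float(value)
    if isinstance(value, IS):
        return int(value)
    if isinstance(value, PersonName):
        return str(value)
    if isinstance(value, bytes):
        try:
            return value.decode("ascii", "replace").strip()
        except Exception:
            return repr(value)
    if isinstance(value, float) or isinstance(value, int):
        return value
    if isinstance(value, str):
        text = value.strip()
        # DICOM DS/IS arrive as str when read without VR context; try numeric.
        try:
            return int(text)
        except ValueError:
            pass
        try:
            return float(text)
        except ValueError:
            return text
    return value


def _read_private(ds: pydicom.Dataset, tag: TagRef):
    """Resolve a private tag through its creator block, falling back to the
    nominal (gggg,10ee) slot when the creator is not declared."""
    creator = PRIVATE_CREATORS.get(tag)
    low = tag.element & 0x00FF
    if creator is not None:
        try:
            block = ds.private_block(tag.group, creator)
            elem = block[low]
            return _plain(elem.value)
        except KeyError:
            pass
    try:
        elem = ds[(tag.group, tag.element)]
    except KeyError:
        return None
    return _plain(elem.value)


def read_instance(path: str, extra_tags: list[TagRef] | None = None) -> InstanceRecord:
    """Read one DICOM file into an :class:`InstanceRecord`.

    Raises on unreadable files; :func:`read_exam` catches and skips.
    """
    ds = pydicom.dcmread(path)
    wanted = list(_CORE_TAGS)
    if extra_tags:
        wanted.extend(extra_tags)
    tags: dict[TagRef, object] = {}
    for tag in wanted:
        if tag in tags:
            continue
        if (tag.group & 0x0001) and tag in PRIVATE_CREATORS:
            value = _read_private(ds, tag)
        else:
            try:
                value = _plain(ds[(tag.group, tag.element)].value)
            except KeyError:
                value = None
        if value is None or value == "":
            continue
        tags[tag] = value
    has_pixels = (0x7FE0, 0x0010) in ds
    return InstanceRecord(source_path=path, tags=tags, has_pixel_data=has_pixels)


def _sort_key_absent_last(value):
    return (value is None, value if value is not None else 0)


def sort_into_series(
    instances: list[InstanceRecord],
) -> tuple[list[SeriesBundle], list[InstanceRecord]]:
    """Group instances into series.

    Group identity is (SeriesNumber, AcquisitionNumber); SliceLocation and
    TemporalPositionIdentifier order instances *within* a group, with
    absent values sorted last.  Instances without a SeriesNumber cannot be
    assigned and are returned separately.
    """
    groups: dict[tuple, list[InstanceRecord]] = {}
    unclassified: list[InstanceRecord] = []
    for inst in instances:
        sn = inst.get(SERIES_NUMBER)
        if sn is None or not isinstance(sn, (int, float)):
            unclassified.append(inst)
            continue
        an = inst.get(ACQUISITION_NUMBER)
        an = int(an) if isinstance(an, (int, float)) else None
        groups.setdefault((int(sn), an), []).append(inst)

    bundles: list[SeriesBundle] = []
    for (sn, an) in sorted(groups, key=lambda k: (k[0], k[1] is None, k[1] or 0)):
        members = sorted(
            groups[(sn, an)],
            key=lambda i: (
                _sort_key_absent_last(i.get(SLICE_LOCATION)),
                _sort_key_absent_last(i.get(TEMPORAL_POSITION)),
                i.source_path,
            ),
        )
        first = members[0]
        desc = first.get(SERIES_DESCRIPTION)
        bundle = SeriesBundle(
            series_number=sn,
            acquisition_number=an,
            instances=members,
            series_description=str(desc) if desc is not None else "",
        )
        bundle.sequence_id = extract_sequence_id(bundle)
        bundles.append(bundle)
    return bundles, unclassified


def extract_sequence_id(bundle: SeriesBundle, vendor: str = "") -> str:
    """Sequence identifier via the ordered fallback chain
    SequenceName -> PulseSequenceName -> ScanningSequence (first instance).

    Returns ``UNKNOWN_SEQUENCE`` when none of the three tags is present.
    The ``vendor`` argument is accepted for interface symmetry; the chain
    itself is vendor-independent.
    """
    if not bundle.instances:
        raise ValueError("cannot extract a sequence id from an empty series")
    first = bundle.instances[0]
    for tag in (SEQUENCE_NAME, PULSE_SEQUENCE_NAME, SCANNING_SEQUENCE):
        value = first.get(tag)
        if value is None:
            continue
        if isinstance(value, list):
            value = "\\".join(str(v) for v in value)
        text = str(value).strip()
        if text:
            return text
    return UNKNOWN_SEQUENCE


def classify_orientation(iop) -> str:
    """Classify a slice stack as axial/sagittal/coronal/oblique from the
    ImageOrientationPatient direction cosines.

    The slice normal is the cross product of the row and column cosines;
    the stack is labelled by the patient axis carrying the largest normal
    component (x -> sagittal, y -> coronal, z -> axial) provided that
    component dominates (|n| >= 0.9), else ``oblique``.  An absent IOP
    yields ``unknown``.
    """
    if iop is None:
        return "unknown"
    arr = np.asarray(iop, dtype=float)
    if arr.shape != (6,) or not np.all(np.isfinite(arr)):
        raise ValueError("ImageOrientationPatient must be 6 finite numbers")
    normal = np.cross(arr[:3], arr[3:])
    idx = int(np.argmax(np.abs(normal)))
    if abs(normal[idx]) < 0.9:
        return "oblique"
    return ("sagittal", "coronal", "axial")[idx]


def vendor_of(manufacturer: str | None) -> str:
    """Map a Manufacturer string to a vendor key (case-insensitive prefix)."""
    if not manufacturer:
        return ""
    text = manufacturer.strip().casefold()
    for key in ("siemens", "philips", "ge"):
        if text.startswith(key):
            return key
    return ""


def _resolve_bvalue(inst: InstanceRecord, vendor: str):
    for tag in _BVALUE_CHAINS.get(vendor, _BVALUE_CHAINS[""]):
        value = inst.get(tag)
        if value is None:
            continue
        if isinstance(value, list):
            value = value[0] if value else None
            if value is None:
                continue
        if isinstance(value, str):
            try:
                value = float(value)
            except ValueError:
                continue
        # GE stores the b-value with a 1e9 offset convention in some
        # software versions; strip any large fixed offset.
        if isinstance(value, (int, float)) and value >= 100000:
            value = value % 100000
        return int(value) if float(value).is_integer() else float(value)
    return None


def extract_params(bundle: SeriesBundle, attribute_file, vendor: str = "") -> dict[str, object]:
    """Extract the requested acquisition parameters from a series.

    Values come from the first instance (after intra-series ordering).
    Two attribute names receive dedicated handling: ``DiffusionBValue``
    resolves through the vendor-specific private-tag chain, and
    ``Orientation`` is the classified label of the direction cosines.
    Absent tags are omitted from the returned map.
    """
    if not bundle.instances:
        return {}
    first = bundle.instances[0]
    params: dict[str, object] = {}
    for entry in attribute_file.entries:
        name = entry.name
        if name == "DiffusionBValue":
            value = _resolve_bvalue(first, vendor)
        elif name == "Orientation":
            iop = first.get(IMAGE_ORIENTATION)
            try:
                value = classify_orientation(iop) if iop is not None else None
            except (ValueError, TypeError):
                # malformed direction cosines (e.g. a truncated file):
                # treat as absent rather than aborting the exam read
                log.warning("malformed ImageOrientationPatient in %s", first.source_path)
                value = None
        else:
            value = first.get(entry)
        if value is not None:
            params[name] = value
    return params


def extract_generic(instances: list[InstanceRecord]) -> GenericAttributes:
    """Generic acquisition attributes from the first instance carrying them."""
    generic = GenericAttributes()
    for inst in instances:
        if generic.modality is None and inst.get(MODALITY) is not None:
            generic.modality = str(inst.get(MODALITY))
        if generic.field_strength is None and inst.get(FIELD_STRENGTH) is not None:
            fs = inst.get(FIELD_STRENGTH)
            if isinstance(fs, (int, float)) and fs > 0:
                generic.field_strength = float(fs)
        if generic.manufacturer is None and inst.get(MANUFACTURER) is not None:
            generic.manufacturer = str(inst.get(MANUFACTURER))
        if generic.model is None and inst.get(MODEL_NAME) is not None:
            generic.model = str(inst.get(MODEL_NAME))
        if None not in (
            generic.modality,
            generic.field_strength,
            generic.manufacturer,
            generic.model,
        ):
            break
    return generic


def read_exam(root_dir: str, attribute_file) -> ExamBundle:
    """Read a directory tree of DICOM files into an :class:`ExamBundle`.

    Non-DICOM and malformed files are skipped with a warning; hidden files
    are ignored; instances missing a SeriesNumber land in
    ``unclassified``.  An empty or DICOM-free directory returns a bundle
    whose ``error`` field is set — never an exception.
    """
    exam_id = os.path.basename(os.path.normpath(root_dir))
    extra = [e for e in attribute_file.entries if e.name not in ("DiffusionBValue", "Orientation")]
    instances: list[InstanceRecord] = []
    for dirpath, dirnames, filenames in os.walk(root_dir):
        dirnames[:] = sorted(d for d in dirnames if not d.startswith("."))
        for fname in sorted(filenames):
            if fname.startswith("."):
                continue
            path = os.path.join(dirpath, fname)
            try:
                instances.append(read_instance(path, extra))
            except (InvalidDicomError, Exception) as exc:  # noqa: BLE001 - resilience contract
                log.warning("skipping unreadable file %s: %s", path, exc)

    if not instances:
        return ExamBundle(
            exam_id=exam_id,
            generic=GenericAttributes(),
            series=[],
            unclassified=[],
            error="no DICOM instances",
        )

    bundles, unclassified = sort_into_series(instances)
    generic = extract_generic(instances)
    vendor = vendor_of(generic.manufacturer)
    for bundle in bundles:
        bundle.sequence_id = extract_sequence_id(bundle, vendor)
        bundle.params = extract_params(bundle, attribute_file, vendor)
    return ExamBundle(
        exam_id=exam_id, generic=generic, series=bundles, unclassified=unclassified
    )
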