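"""The master file: a JSON document encoding the expected imaging protocol.

A master file is generated from an exemplar examination known to have been
acquired correctly (typically during site qualification).  It records the
expected generic attributes (scanner identity, field strength, modality)
and one entry per expected series, each carrying the parameter values the
study has agreed on.  A parameter expectation is either an exact value
(scalar, string or list) or an inclusive ``{"high": H, "low": L}`` range —
e.g. a repetition time expected between 6.0 s and 6.5 s is written
``"RepetitionTime": {"high": 6500, "low": 6000}``.

After generation the file is reviewed by the study team, who may widen
exact values into ranges (:func:`edit_to_range`) or mark derived series
such as ADC maps optional.
"""

from __future__ import annotations

import copy
import json
import math
import re
from dataclasses import dataclass, field

from .dicom_io import ExamBundle, TagRef

__all__ = [
    "AttributeFile",
    "ExpectedValue",
    "Exact",
    "Range",
    "SeriesSpec",
    "MasterFile",
    "MasterValidationError",
    "generate_master",
    "read_master",
    "write_master",
    "edit_to_range",
    "parse_attribute_file",
    "write_attribute_file",
    "infer_role",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = "1.0"


class MasterValidationError(ValueError):
    """Raised on malformed master files; carries *all* violations found."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class AttributeFile:
    """Ordered list of the DICOM attributes a study cares about.

    The on-disk form is plain text, one ``Name,(gggg,eeee)`` entry per
    line; ``#`` comments and blank lines are ignored.
    """

    entries: tuple[TagRef, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("attribute file must contain at least one entry")
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]


def attributes_from_names(names: list[str]) -> AttributeFile:
    """Rebuild an AttributeFile from attribute names alone, resolving
    standard DICOM keywords through the data dictionary.  ``Orientation``
    and ``DiffusionBValue`` are study conventions with dedicated handling
    (direction-cosine classification; vendor b-value tag chain)."""
    from pydicom.datadict import tag_for_keyword

    special = {
        "Orientation": (0x0020, 0x0037),
        "DiffusionBValue": (0x0018, 0x9087),
    }
    entries: list[TagRef] = []
    for name in names:
        if name in special:
            g, e = special[name]
        else:
            tag = tag_for_keyword(name)
            if tag is None:
                raise ValueError(f"unknown attribute name {name!r}; supply an attribute file")
            g, e = tag >> 16, tag & 0xFFFF
        entries.append(TagRef(g, e, name))
    return AttributeFile(tuple(entries))


def parse_attribute_file(path: str) -> AttributeFile:
    entries: list[TagRef] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            name, sep, tagtext = line.partition(",")
            if not sep:
                raise ValueError(f"line {lineno}: expected 'Name,(gggg,eeee)': {line!r}")
            entries.append(TagRef.parse(tagtext, name.strip()))
    return AttributeFile(tuple(entries))


def write_attribute_file(attrs: AttributeFile, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# attribute file: Name,(gggg,eeee) per line\n")
        for entry in attrs.entries:
            fh.write(f"{entry.name},{entry}\n")


class ExpectedValue:
    """Base class for a parameter expectation."""

    def to_json(self):
        raise NotImplementedError


@dataclass(frozen=True)
class Exact(ExpectedValue):
    value: object

    def __post_init__(self) -> None:
        if isinstance(self.value, list):
            if not self.value:
                raise ValueError("Exact list expectation must be non-empty")
            object.__setattr__(self, "value", tuple(self.value))

    def to_json(self):
        v = self.value
        return list(v) if isinstance(v, tuple) else v

    def __repr__(self) -> str:
        return f"Exact({self.to_json()!r})"


@dataclass(frozen=True)
class Range(ExpectedValue):
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError("range endpoints must be finite")
        if self.low > self.high:
            raise ValueError("low exceeds high")

    def to_json(self):
        return {"high": self.high, "low": self.low}

    def __repr__(self) -> str:
        return f"Range({self.low}, {self.high})"


@dataclass
class SeriesSpec:
    """The expectation for one series of the protocol.

    ``params`` may be empty — a presence-only expectation, as used for
    derived series like ADC maps.  ``role`` is a stable label
    (``dwi_b50``, ``dixon_fat``, ...) used to group series into families
    for cohort audits; it is inferred from the series description when a
    master is generated.
    """

    sequence_id: str
    series_description: str
    params: dict[str, ExpectedValue] = field(default_factory=dict)
    required: bool = True
    role: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence_id:
            raise ValueError("sequence_id must be non-empty")

    @property
    def label(self) -> str:
        return self.role or self.series_description or self.sequence_id


@dataclass
class MasterFile:
    schema_version: str = SCHEMA_VERSION
    generic: dict[str, ExpectedValue] = field(default_factory=dict)
    series_specs: list[SeriesSpec] = field(default_factory=list)
    attribute_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for spec in self.series_specs:
            key = (spec.sequence_id.casefold(), spec.series_description.casefold())
            if key in seen:
                raise ValueError(f"duplicate series spec {key}")
            seen.add(key)

    def spec_by_role(self, role: str) -> SeriesSpec | None:
        for spec in self.series_specs:
            if spec.role == role:
                return spec
        return None


_ROLE_RULES: list[tuple[str, tuple[str, ...]]] = [
    ("dixon_fat", ("dixon", "fat")),
    ("dixon_water", ("dixon", "water")),
    ("dwi_b50", ("b50",)),
    ("dwi_b600", ("b600",)),
    ("dwi_b900", ("b900",)),
    ("adc", ("adc",)),
    ("t1w_spine", ("t1w", "spine")),
    ("t2w_spine", ("t2w", "spine")),
]


def infer_role(series_description: str) -> str | None:
    """Infer a series family role from the (normalized) series description."""
    text = re.sub(r"\s+", " ", series_description.casefold())
    for role, keywords in _ROLE_RULES:
        if all(k in text for k in keywords):
            return role
    return None


def generate_master(exam: ExamBundle, attribute_file: AttributeFile) -> MasterFile:
    """Build a master file from an exemplar exam: one spec per series, with
    an exact expectation for every requested attribute the series carries.

    Deterministic given the exam.  An exam with zero series is an error.
    """
    if exam.error:
        raise ValueError(f"cannot generate master from exam in error state: {exam.error}")
    if not exam.series:
        raise ValueError("cannot generate master from an exam with zero series")
    specs: list[SeriesSpec] = []
    for bundle in exam.series:
        params = {name: Exact(value) for name, value in bundle.params.items()}
        specs.append(
            SeriesSpec(
                sequence_id=bundle.sequence_id,
                series_description=bundle.series_description,
                params=params,
                role=infer_role(bundle.series_description),
            )
        )
    generic = {name: Exact(value) for name, value in exam.generic.as_dict().items()}
    return MasterFile(
        schema_version=SCHEMA_VERSION,
        generic=generic,
        series_specs=specs,
        attribute_names=list(attribute_file.names),
    )


def _expected_to_json(value: ExpectedValue):
    return value.to_json()


def _expected_from_json(obj, context: str, violations: list[str]) -> ExpectedValue | None:
    if isinstance(obj, dict):
        keys = set(obj)
        if keys != {"high", "low"}:
            violations.append(f"{context}: unknown expectation shape with keys {sorted(keys)}")
            return None
        low, high = obj["low"], obj["high"]
        if not all(isinstance(v, (int, float)) and math.isfinite(v) for v in (low, high)):
            violations.append(f"{context}: range endpoints must be finite numbers")
            return None
        if low > high:
            violations.append(f"{context}: low exceeds high")
            return None
        return Range(float(low), float(high))
    if isinstance(obj, list):
        if not obj:
            violations.append(f"{context}: exact list expectation is empty")
            return None
        return Exact(list(obj))
    if isinstance(obj, (int, float, str)):
        return Exact(obj)
    violations.append(f"{context}: unsupported expectation type {type(obj).__name__}")
    return None


def master_to_dict(master: MasterFile) -> dict:
    return {
        "schema_version": master.schema_version,
        "attributes": list(master.attribute_names),
        "generic": {k: _expected_to_json(v) for k, v in master.generic.items()},
        "series": [
            {
                "sequence_id": spec.sequence_id,
                "series_description": spec.series_description,
                "role": spec.role,
                "required": spec.required,
                "params": {k: _expected_to_json(v) for k, v in spec.params.items()},
            }
            for spec in master.series_specs
        ],
    }


def write_master(master: MasterFile, path: str) -> None:
    """Serialize to JSON (UTF-8, 2-space indent, sorted keys).

    Series order is preserved; ranges are emitted exactly as
    ``{"high": H, "low": L}``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(master_to_dict(master), fh, indent=2, sort_keys=True)
        fh.write("\n")


def master_from_dict(data: dict) -> MasterFile:
    violations: list[str] = []
    if not isinstance(data, dict):
        raise MasterValidationError(["master file root must be a JSON object"])
    version = data.get("schema_version")
    if not isinstance(version, str):
        violations.append("missing or non-string schema_version")
        version = SCHEMA_VERSION
    generic: dict[str, ExpectedValue] = {}
    raw_generic = data.get("generic", {})
    if not isinstance(raw_generic, dict):
        violations.append("'generic' must be an object")
        raw_generic = {}
    for name, raw in raw_generic.items():
        parsed = _expected_from_json(raw, f"generic.{name}", violations)
        if parsed is not None:
            generic[name] = parsed
    specs: list[SeriesSpec] = []
    raw_series = data.get("series", [])
    if not isinstance(raw_series, list):
        violations.append("'series' must be a list")
        raw_series = []
    for i, raw_spec in enumerate(raw_series):
        ctx = f"series[{i}]"
        if not isinstance(raw_spec, dict):
            violations.append(f"{ctx}: must be an object")
            continue
        seq = raw_spec.get("sequence_id")
        if not isinstance(seq, str) or not seq:
            violations.append(f"{ctx}: sequence_id must be a non-empty string")
            continue
        params: dict[str, ExpectedValue] = {}
        for name, raw in (raw_spec.get("params") or {}).items():
            parsed = _expected_from_json(raw, f"{ctx}.params.{name}", violations)
            if parsed is not None:
                params[name] = parsed
        specs.append(
            SeriesSpec(
                sequence_id=seq,
                series_description=str(raw_spec.get("series_description", "")),
                params=params,
                required=bool(raw_spec.get("required", True)),
                role=raw_spec.get("role"),
            )
        )
    if violations:
        raise MasterValidationError(violations)
    attrs = data.get("attributes", [])
    return MasterFile(
        schema_version=version,
        generic=generic,
        series_specs=specs,
        attribute_names=[str(a) for a in attrs],
    )


def read_master(path: str) -> MasterFile:
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise MasterValidationError([f"malformed JSON: {exc}"]) from exc
    return master_from_dict(data)


def edit_to_range(
    master: MasterFile, series_selector: str, param: str, low: float, high: float
) -> MasterFile:
    """Return a copy of ``master`` with one exact expectation widened to an
    inclusive range.  ``series_selector`` matches a spec's role exactly or
    its description as a case-insensitive substring, and must resolve to
    exactly one spec containing ``param``.
    """
    sel = series_selector.casefold()
    matches = [
        s
        for s in master.series_specs
        if (s.role is not None and s.role.casefold() == sel)
        or sel in s.series_description.casefold()
    ]
    matches = [s for s in matches if param in s.params]
    if not matches:
        raise KeyError(f"no series spec matching {series_selector!r} with param {param!r}")
    if len(matches) > 1:
        raise ValueError(
            f"selector {series_selector!r} is ambiguous: "
            f"{[s.label for s in matches]}"
        )
    out = copy.deepcopy(master)
    target = out.series_specs[master.series_specs.index(matches[0])]
    target.params[param] = Range(float(low), float(high))
    return out
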