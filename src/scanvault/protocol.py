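"""Acquisition-protocol definitions and compliance-gated image extraction.

A project defines, per image type (T1, T2, ...), the acquisition parameters a
series must satisfy: numeric closed intervals (echo time in ms, repetition
time in ms, slice thickness in mm, field strength in T), exact strings, or
allowed sets.  Extraction of image assets from a DICOM archive is gated on
compliance — by default non-compliant series are rejected, producing a
rejection record rather than an asset.

Numeric ranges are closed intervals with no additional epsilon: a protocol
that needs tolerance encodes it in the range itself.  A parameter that is
constrained but missing from the series record is a violation (strict-missing
policy) — silence about TE is not evidence of a good TE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .archive import (
    ArchiveDescriptor,
    DicomSeriesRecord,
    extract_series,
    series_content_key,
)
from .errors import CollisionError, ConfigurationError, NotFoundError
from .identifiers import derive_id

#: Series-record attributes a constraint may address.
CONSTRAINABLE_FIELDS = (
    "modality",
    "description",
    "echo_time",
    "repetition_time",
    "slice_thickness",
    "manufacturer",
    "scanner_serial",
    "software_version",
    "field_strength",
)

Constraint = Mapping[str, object]


@dataclass
class ProtocolDefinition:
    """Named per-project parameter constraints for one image type.

    ``constraints`` maps a parameter name to one of
    ``{"min": lo, "max": hi}`` (closed numeric interval),
    ``{"equals": value}`` (exact match) or
    ``{"allowed": [v1, v2, ...]}`` (membership).
    A protocol starts inactive; a successful test search is the occasion for
    the user to activate it, enabling automatic extraction.
    """

    name: str
    project: str
    image_type_label: str
    constraints: dict[str, Constraint]
    active: bool = False

    def __post_init__(self) -> None:
        if not self.constraints:
            raise ConfigurationError("a protocol needs at least one constraint")
        for param, con in self.constraints.items():
            if param not in CONSTRAINABLE_FIELDS:
                raise ConfigurationError(f"unknown protocol parameter: {param!r}")
            _check_constraint(param, con)

    def to_json(self, path: Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "name": self.name,
                    "project": self.project,
                    "image_type_label": self.image_type_label,
                    "constraints": self.constraints,
                    "active": self.active,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: Path) -> "ProtocolDefinition":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def _check_constraint(param: str, con: Constraint) -> None:
    if not isinstance(con, Mapping) or not con:
        raise ConfigurationError(f"malformed constraint for {param!r}: {con!r}")
    keys = set(con)
    if keys <= {"min", "max"} and ("min" in keys or "max" in keys):
        lo, hi = con.get("min"), con.get("max")
        if lo is not None and hi is not None and float(lo) > float(hi):
            raise ConfigurationError(f"empty range for {param!r}: [{lo}, {hi}]")
        return
    if keys == {"equals"}:
        return
    if keys == {"allowed"}:
        if not isinstance(con["allowed"], (list, tuple)) or not con["allowed"]:
            raise ConfigurationError(f"allowed-set for {param!r} must be a non-empty list")
        return
    raise ConfigurationError(f"malformed constraint for {param!r}: {con!r}")


@dataclass
class Violation:
    parameter: str
    observed: object
    constraint: Constraint


@dataclass
class ValidationResult:
    series_uid: str
    compliant: bool
    violations: list[Violation] = field(default_factory=list)


def _satisfies(value, con: Constraint) -> bool:
    if value is None:
        return False  # strict-missing policy
    if "equals" in con:
        return str(value).strip().lower() == str(con["equals"]).strip().lower()
    if "allowed" in con:
        allowed = {str(v).strip().lower() for v in con["allowed"]}
        return str(value).strip().lower() in allowed
    try:
        v = float(value)
    except (TypeError, ValueError):
        return False
    lo, hi = con.get("min"), con.get("max")
    if lo is not None and v < float(lo):
        return False
    if hi is not None and v > float(hi):
        return False
    return True


def validate_series(series: DicomSeriesRecord, protocol: ProtocolDefinition) -> ValidationResult:
    """Evaluate every constraint of ``protocol`` against one series record."""
    violations = [
        Violation(param, getattr(series, param, None), con)
        for param, con in protocol.constraints.items()
        if not _satisfies(getattr(series, param, None), con)
    ]
    return ValidationResult(series.series_uid, compliant=not violations, violations=violations)


@dataclass
class Rejection:
    series_uid: str
    violations: list[Violation]


@dataclass
class ExtractionResult:
    assets: list  # registry.Asset
    rejections: list[Rejection]


def extract_images(
    descriptor: ArchiveDescriptor,
    archive_path: Path,
    protocol: ProtocolDefinition,
    registry,
    target: Path,
) -> ExtractionResult:
    """Extract one image asset per protocol-compliant series of an archive.

    Image identifiers are derived from series byte content (sorted member
    md5s), so extracting the same series twice — from this archive or from any
    other archive carrying byte-identical files — is a collision and the whole
    call fails before anything is written.  Non-compliant series yield
    rejection records, never assets.  Extracted assets inherit the archive's
    project/individual/timepoint.
    """
    from .registry import Asset, AssetFile  # late import to avoid a cycle

    archive_asset = registry.get_asset(descriptor.archive_id)
    if archive_asset.project != protocol.project:
        raise ConfigurationError(
            f"archive {descriptor.archive_id} belongs to project "
            f"{archive_asset.project!r}, protocol to {protocol.project!r}"
        )

    compliant: list[DicomSeriesRecord] = []
    rejections: list[Rejection] = []
    for series in descriptor.series:
        result = validate_series(series, protocol)
        if result.compliant:
            compliant.append(series)
        else:
            rejections.append(Rejection(series.series_uid, result.violations))

    # all-or-nothing: check every derived id before the first write
    planned = []
    for series in compliant:
        md5s = [f.md5 for f in descriptor.files if f.series_uid == series.series_uid]
        image_id = derive_id(series_content_key(md5s))
        if registry.has_asset(image_id.render()):
            raise CollisionError(
                f"image {image_id.render()} (series {series.series_uid}) "
                "already extracted — identical content exists in the registry"
            )
        planned.append((series, image_id, md5s))

    target = Path(target)
    assets = []
    for series, image_id, md5s in planned:
        dest = target / image_id.render()
        paths = extract_series(archive_path, series.series_uid, dest)
        files = [
            AssetFile(location=str(p), format="DICOM", md5=_md5_of(p)) for p in sorted(paths)
        ]
        asset = Asset(
            id=image_id.render(),
            kind="image",
            project=archive_asset.project,
            individual=archive_asset.individual,
            timepoint=archive_asset.timepoint,
            md5=_combined_md5(md5s),
            provenance={
                "type": "derived",
                "activity": {
                    "name": "image-extraction",
                    "version": "1",
                    "parameters": protocol.name,
                },
                "inputs": [descriptor.archive_id],
                "series_uid": series.series_uid,
                "image_type": protocol.image_type_label,
            },
            files=files,
        )
        registry.register_asset(asset)
        assets.append(asset)
    return ExtractionResult(assets=assets, rejections=rejections)


def _md5_of(path: Path) -> str:
    import hashlib

    return hashlib.md5(Path(path).read_bytes()).hexdigest()


def _combined_md5(md5s: Sequence[str]) -> str:
    import hashlib

    return hashlib.md5("".join(sorted(md5s)).encode()).hexdigest()
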