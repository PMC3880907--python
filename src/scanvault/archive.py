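"""Immutable single-file DICOM archives with a three-domain descriptor.

A scanning session's folder of DICOM files is packaged into one losslessly
compressed ``<uuid>.tar.gz`` container plus a ``<uuid>.json`` sidecar
descriptor.  The descriptor documents three domains:

1. the archive itself (identifier, container checksum, format version),
2. each series it contains (acquisition parameters and scanner provenance),
3. every single file (member path, SOP instance UID, per-file md5).

The archive identifier is derived from the sorted list of per-file md5s, so
identity follows byte content, not folder layout or scan order: re-archiving
identical bytes yields the identical identifier, and archives migrate between
stores without re-identification.  Once created an archive is immutable —
series are extracted by reading members, never by rewriting the container.
"""

from __future__ import annotations

import gzip
import hashlib
import io
import json
import tarfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import pydicom
from pydicom.errors import InvalidDicomError
from pydantic import BaseModel, Field, field_validator

from .errors import (
    CollisionError,
    ConfigurationError,
    IntegrityError,
    NotFoundError,
    ImportError_,
)
from .identifiers import AssetKey, DUuid, derive_id

FORMAT_VERSION = "1.0"

#: Header attributes whose non-empty presence blocks project assignment until
#: a human confirms anonymization. PatientID and PatientBirthDate are retained
#: deliberately: demographic search filters rely on birth year.
DEFAULT_PHI_WATCHLIST = (
    "PatientName",
    "OtherPatientIDs",
    "InstitutionAddress",
    "ReferringPhysicianName",
)


def _md5(data: bytes) -> str:
    return hashlib.md5(data).hexdigest()


def _md5_file(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _da_to_iso(value: str | None) -> Optional[str]:
    """DICOM DA (YYYYMMDD) -> ISO-8601, or None when absent/blank."""
    if not value:
        return None
    v = str(value).strip()
    if len(v) == 8 and v.isdigit():
        return f"{v[:4]}-{v[4:6]}-{v[6:8]}"
    return v


def _number(value) -> Optional[float]:
    if value in (None, ""):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


class DicomFileRecord(BaseModel):
    member_path: str
    sop_instance_uid: str
    instance_number: Optional[int] = None
    md5: str = Field(pattern=r"^[0-9a-f]{32}$")
    series_uid: str


class DicomSeriesRecord(BaseModel):
    series_uid: str
    modality: Optional[str] = None
    description: Optional[str] = None
    echo_time: Optional[float] = None          # ms
    repetition_time: Optional[float] = None    # ms
    slice_thickness: Optional[float] = None    # mm
    manufacturer: Optional[str] = None
    scanner_serial: Optional[str] = None
    software_version: Optional[str] = None
    field_strength: Optional[float] = None     # tesla
    acquisition_date: Optional[str] = None     # ISO date
    patient_id: Optional[str] = None
    patient_birth_date: Optional[str] = None   # ISO date
    file_count: int = 0


class Assignment(BaseModel):
    """Project/individual/timepoint carried by a batch-created descriptor."""

    project: str
    individual: str
    timepoint: str


class ArchiveDescriptor(BaseModel):
    archive_id: str
    archive_md5: Optional[str] = None
    format_version: str = FORMAT_VERSION
    created: Optional[str] = None
    anonymized_confirmed: bool = False
    series: list[DicomSeriesRecord] = Field(default_factory=list)
    files: list[DicomFileRecord] = Field(default_factory=list)
    assignment: Optional[Assignment] = None

    @field_validator("format_version")
    @classmethod
    def _known_version(cls, v: str) -> str:
        if v != FORMAT_VERSION:
            raise ValueError(f"unsupported descriptor format version: {v!r}")
        return v

    @property
    def id(self) -> DUuid:
        return DUuid.parse(self.archive_id)

    def series_for(self, series_uid: str) -> DicomSeriesRecord:
        for rec in self.series:
            if rec.series_uid == series_uid:
                return rec
        raise NotFoundError(f"series not in descriptor: {series_uid}")

    def check_conservation(self) -> None:
        total = sum(s.file_count for s in self.series)
        if total != len(self.files):
            raise IntegrityError(
                f"descriptor inconsistent: series counts sum to {total}, "
                f"{len(self.files)} file records"
            )

    def write(self, path: Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")

    @classmethod
    def read(cls, path: Path) -> "ArchiveDescriptor":
        try:
            return cls.model_validate_json(Path(path).read_text())
        except FileNotFoundError:
            raise NotFoundError(f"descriptor not found: {path}")


def archive_content_key(file_md5s: Iterable[str]) -> AssetKey:
    """Content key of an archive: the sorted per-file md5 list."""
    return AssetKey("dicomArchive", sorted(file_md5s))


def series_content_key(file_md5s: Iterable[str]) -> AssetKey:
    """Content key of an image asset extracted from one series."""
    return AssetKey("image", sorted(file_md5s))


def _iter_dicom_files(folder: Path, strict: bool):
    paths = sorted(p for p in Path(folder).rglob("*") if p.is_file())
    for path in paths:
        try:
            ds = pydicom.dcmread(path, stop_before_pixels=True)
        except (InvalidDicomError, ValueError, AttributeError, EOFError) as exc:
            if strict:
                raise ImportError_(f"not a parseable DICOM file: {path}") from exc
            continue
        yield path, ds


def build_descriptor(folder: Path, *, strict: bool = True) -> ArchiveDescriptor:
    """Extract the three metadata domains from a folder of DICOM files.

    Every parseable file lands in exactly one series record; per-file md5s are
    computed from the bytes on disk; the archive identifier is derived from
    the content key. ``anonymized_confirmed`` starts false — confirmation is a
    human act recorded later.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise NotFoundError(f"no such folder: {folder}")

    series: dict[str, DicomSeriesRecord] = {}
    files: list[DicomFileRecord] = []
    used_members: set[str] = set()
    for path, ds in _iter_dicom_files(folder, strict):
        uid = str(getattr(ds, "SeriesInstanceUID", "")) or "UNKNOWN"
        if uid not in series:
            series[uid] = DicomSeriesRecord(
                series_uid=uid,
                modality=str(getattr(ds, "Modality", "")) or None,
                description=str(getattr(ds, "SeriesDescription", "")) or None,
                echo_time=_number(getattr(ds, "EchoTime", None)),
                repetition_time=_number(getattr(ds, "RepetitionTime", None)),
                slice_thickness=_number(getattr(ds, "SliceThickness", None)),
                manufacturer=str(getattr(ds, "Manufacturer", "")) or None,
                scanner_serial=str(getattr(ds, "DeviceSerialNumber", "")) or None,
                software_version=str(getattr(ds, "SoftwareVersions", "")) or None,
                field_strength=_number(getattr(ds, "MagneticFieldStrength", None)),
                acquisition_date=_da_to_iso(getattr(ds, "AcquisitionDate", None)
                                            or getattr(ds, "StudyDate", None)),
                patient_id=str(getattr(ds, "PatientID", "")) or None,
                patient_birth_date=_da_to_iso(getattr(ds, "PatientBirthDate", None)),
            )
        member = f"series/{uid}/{path.name}"
        if member in used_members:  # same filename twice within a series
            stem, dot, ext = path.name.partition(".")
            k = 1
            while member in used_members:
                member = f"series/{uid}/{stem}.{k}{dot}{ext}"
                k += 1
        used_members.add(member)
        files.append(
            DicomFileRecord(
                member_path=member,
                sop_instance_uid=str(getattr(ds, "SOPInstanceUID", "")),
                instance_number=int(ds.InstanceNumber) if getattr(ds, "InstanceNumber", None) is not None else None,
                md5=_md5_file(path),
                series_uid=uid,
            )
        )

    if not files:
        raise ImportError_(f"no parseable DICOM files in {folder}")
    for uid in series:
        series[uid].file_count = sum(1 for f in files if f.series_uid == uid)

    archive_id = derive_id(archive_content_key(f.md5 for f in files))
    desc = ArchiveDescriptor(
        archive_id=archive_id.render(),
        created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        series=sorted(series.values(), key=lambda s: s.series_uid),
        files=files,
    )
    desc.check_conservation()
    return desc


def _deterministic_targz(
    members: Sequence[tuple[str, bytes]], out_path: Path, level: int = 6
) -> None:
    """Write a byte-deterministic tar.gz: fixed mtimes, owners, order."""
    buf = io.BytesIO()
    with tarfile.open(fileobj=buf, mode="w", format=tarfile.USTAR_FORMAT) as tar:
        for name, data in sorted(members):
            info = tarfile.TarInfo(name=name)
            info.size = len(data)
            info.mtime = 0
            info.uid = info.gid = 0
            info.uname = info.gname = ""
            info.mode = 0o644
            tar.addfile(info, io.BytesIO(data))
    with open(out_path, "wb") as fh:
        with gzip.GzipFile(fileobj=fh, mode="wb", compresslevel=level, mtime=0) as gz:
            gz.write(buf.getvalue())


def create_archive(
    folder: Path,
    target: Path,
    *,
    strict: bool = True,
    compresslevel: int = 6,
    assignment: Optional[Assignment] = None,
) -> tuple[Path, Path]:
    """Package ``folder`` into ``<target>/<uuid>.tar.gz`` + ``<uuid>.json``.

    Returns (archive path, descriptor path). Creating from byte-identical
    content twice yields the identical identifier, so a pre-existing archive
    with that identifier in ``target`` is a collision, not an overwrite.
    """
    folder, target = Path(folder), Path(target)
    desc = build_descriptor(folder, strict=strict)
    if assignment is not None:
        desc.assignment = assignment
    target.mkdir(parents=True, exist_ok=True)
    archive_path = target / f"{desc.archive_id}.tar.gz"
    desc_path = target / f"{desc.archive_id}.json"
    if archive_path.exists():
        raise CollisionError(
            f"archive {desc.archive_id} already exists in {target}"
        )

    # re-walk in the same order build_descriptor used so member names agree
    members: list[tuple[str, bytes]] = []
    seen: set[str] = set()
    for path, ds in _iter_dicom_files(folder, strict):
        uid = str(getattr(ds, "SeriesInstanceUID", "")) or "UNKNOWN"
        member = f"series/{uid}/{path.name}"
        if member in seen:
            stem, dot, ext = path.name.partition(".")
            k = 1
            while member in seen:
                member = f"series/{uid}/{stem}.{k}{dot}{ext}"
                k += 1
        seen.add(member)
        members.append((member, path.read_bytes()))

    _deterministic_targz(members, archive_path, level=compresslevel)
    desc.archive_md5 = _md5_file(archive_path)
    desc.write(desc_path)
    return archive_path, desc_path


def descriptor_path_for(archive_path: Path) -> Path:
    p = Path(archive_path)
    name = p.name
    if name.endswith(".tar.gz"):
        name = name[: -len(".tar.gz")]
    return p.with_name(name + ".json")


def read_descriptor(archive_path: Path) -> ArchiveDescriptor:
    return ArchiveDescriptor.read(descriptor_path_for(archive_path))


def extract_series(archive_path: Path, series_uid: str, target: Path) -> list[Path]:
    """Extract exactly one series' members to ``target``, bytes untouched."""
    archive_path = Path(archive_path)
    desc = read_descriptor(archive_path)
    desc.series_for(series_uid)  # raises NotFoundError if absent
    target = Path(target)
    target.mkdir(parents=True, exist_ok=True)
    wanted = {f.member_path: f for f in desc.files if f.series_uid == series_uid}
    out: list[Path] = []
    with tarfile.open(archive_path, "r:gz") as tar:
        for member in tar.getmembers():
            if member.name in wanted:
                data = tar.extractfile(member).read()
                dest = target / Path(member.name).name
                dest.write_bytes(data)
                out.append(dest)
    if len(out) != len(wanted):
        raise IntegrityError(
            f"archive is missing {len(wanted) - len(out)} member(s) of series {series_uid}"
        )
    return out


@dataclass
class VerificationReport:
    archive_path: str
    archive_ok: bool
    file_results: list[tuple[str, bool]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.archive_ok and all(ok for _, ok in self.file_results)

    @property
    def failed_members(self) -> list[str]:
        return [name for name, ok in self.file_results if not ok]


def verify_archive(archive_path: Path) -> VerificationReport:
    """Check the container md5 and every member's md5 against the descriptor."""
    archive_path = Path(archive_path)
    if not archive_path.exists():
        raise NotFoundError(f"no such archive: {archive_path}")
    desc = read_descriptor(archive_path)
    archive_ok = desc.archive_md5 is not None and _md5_file(archive_path) == desc.archive_md5
    results: list[tuple[str, bool]] = []
    with tarfile.open(archive_path, "r:gz") as tar:
        present = {m.name: m for m in tar.getmembers()}
        for rec in desc.files:
            m = present.get(rec.member_path)
            ok = m is not None and _md5(tar.extractfile(m).read()) == rec.md5
            results.append((rec.member_path, ok))
    return VerificationReport(str(archive_path), archive_ok, results)


MANIFEST_COLUMNS = ("Project", "Individual", "TimePoint", "SourceLocation", "TargetLocation")


@dataclass(frozen=True)
class ArchiveJob:
    """One archive-creation job derived from a manifest row."""

    project: str
    individual: str
    timepoint: str
    source: Path
    target: Path


@dataclass
class BatchResult:
    jobs: list[ArchiveJob]
    created: list[tuple[ArchiveJob, Path, Path]] = field(default_factory=list)
    failures: list[tuple[ArchiveJob, str]] = field(default_factory=list)


def batch_from_manifest(manifest: Path) -> list[ArchiveJob]:
    """Parse a batch manifest CSV into archive-creation job specs.

    The manifest mirrors the bulk-ingest convention for large downloads:
    columns Project, Individual, TimePoint, SourceLocation, TargetLocation,
    one row per session folder. Parsing needs no registry connection.
    """
    df = pd.read_csv(manifest, dtype=str).fillna("")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ImportError_(f"manifest missing column(s): {', '.join(missing)}")
    return [
        ArchiveJob(
            project=row["Project"],
            individual=row["Individual"],
            timepoint=row["TimePoint"],
            source=Path(row["SourceLocation"]),
            target=Path(row["TargetLocation"]),
        )
        for _, row in df.iterrows()
    ]


def run_batch(jobs: Sequence[ArchiveJob], *, strict: bool = True) -> BatchResult:
    """Execute archive-creation jobs; per-row failures do not stop the batch."""
    result = BatchResult(jobs=list(jobs))
    for job in jobs:
        try:
            if not job.source.is_dir():
                raise NotFoundError(f"source folder missing: {job.source}")
            archive, desc = create_archive(
                job.source,
                job.target,
                strict=strict,
                assignment=Assignment(
                    project=job.project,
                    individual=job.individual,
                    timepoint=job.timepoint,
                ),
            )
            result.created.append((job, archive, desc))
        except Exception as exc:  # collected, batch continues
            result.failures.append((job, str(exc)))
    return result


@dataclass
class PhiFinding:
    series_uid: str
    tag: str
    value: str


@dataclass
class PhiReport:
    findings: list[PhiFinding] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.findings

    def tags_found(self) -> set[str]:
        return {f.tag for f in self.findings}


def phi_scan(
    source: Union[Path, str],
    watchlist: Sequence[str] = DEFAULT_PHI_WATCHLIST,
) -> PhiReport:
    """Report watchlisted header attributes found non-empty, per series.

    ``source`` may be a folder of DICOM files or an archive ``.tar.gz``; the
    report supports — never replaces — the human anonymization confirmation.
    """
    if not watchlist:
        raise ConfigurationError("PHI watchlist must not be empty")
    source = Path(source)
    report = PhiReport()

    def scan_dataset(ds, series_uid: str) -> None:
        for tag in watchlist:
            value = getattr(ds, tag, None)
            if value not in (None, ""):
                text = str(value).strip()
                if text:
                    report.findings.append(PhiFinding(series_uid, tag, text))

    if source.is_dir():
        for _, ds in _iter_dicom_files(source, strict=False):
            scan_dataset(ds, str(getattr(ds, "SeriesInstanceUID", "")) or "UNKNOWN")
    elif source.name.endswith(".tar.gz"):
        desc = read_descriptor(source)
        by_member = {f.member_path: f.series_uid for f in desc.files}
        with tarfile.open(source, "r:gz") as tar:
            for member in tar.getmembers():
                if member.name in by_member:
                    ds = pydicom.dcmread(
                        io.BytesIO(tar.extractfile(member).read()),
                        stop_before_pixels=True,
                    )
                    scan_dataset(ds, by_member[member.name])
    else:
        raise NotFoundError(f"not a folder or archive: {source}")

    # deduplicate identical findings within a series
    seen: set[tuple[str, str, str]] = set()
    unique: list[PhiFinding] = []
    for f in report.findings:
        key = (f.series_uid, f.tag, f.value)
        if key not in seen:
            seen.add(key)
            unique.append(f)
    report.findings = unique
    return report
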