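"""Seedable generator of small, valid DICOM studies with a truth table.

Real multi-centre MRI studies arrive as folders of Part-10 files whose headers
carry the acquisition parameters (TE, TR, slice thickness), scanner provenance
(manufacturer, serial, software version, field strength) and subject
demographics that every other subsystem here keys on.  This module emulates
such studies at desk scale: tiny 16x16 pixel payloads, fully controllable
headers, and *byte determinism* — the same seed always produces the same
files, so checksums can be frozen into tests.

Alongside the files a machine-readable :class:`TruthTable` is produced with
one row per series (every templated header value, the file count, the
intended protocol-compliance flag) and one row per file (path, SOP instance
UID, md5).  The truth table is the oracle that archive, protocol, search and
query tests consult; they never re-read headers ad hoc.

UIDs are minted deterministically under the ``2.25`` (UUID-derived) root from
the study seed, so synthetic series can never collide with real studies.
"""

from __future__ import annotations

import hashlib
import uuid as _uuid
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage

from .errors import ConfigurationError

_UID_NAMESPACE = _uuid.UUID("9b0e4f3c-6d21-5a78-8c45-1f2e3d4c5b6a")


def _det_uid(*parts: object) -> str:
    """Deterministic DICOM UID under the 2.25 (UUID-in-decimal) root."""
    name = "/".join(str(p) for p in parts)
    return "2.25." + str(_uuid.uuid5(_UID_NAMESPACE, name).int)


def _seed32(*parts: object) -> int:
    name = "/".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(name).digest()[:4], "big")


@dataclass(frozen=True)
class SeriesTemplate:
    """Header template for one acquisition series."""

    description: str = "MPRAGE"
    modality: str = "MR"
    echo_time: float = 3.2            # ms
    repetition_time: float = 7.1      # ms
    slice_thickness: float = 1.2      # mm
    manufacturer: str = "GE MEDICAL SYSTEMS"
    scanner_serial: str = "SN-0001"
    software_version: str = "24.0"
    field_strength: float = 1.5       # tesla
    n_slices: int = 3


#: Two-series session emulating a structural MRI visit: a T1 volume and a
#: T2 fast spin echo. Values are in the range typical for 1.5 T scanners.
DEFAULT_TEMPLATES: tuple[SeriesTemplate, ...] = (
    SeriesTemplate(),
    SeriesTemplate(
        description="T2-FSE",
        echo_time=96.0,
        repetition_time=4200.0,
        slice_thickness=3.0,
        n_slices=3,
    ),
)


@dataclass(frozen=True)
class StudySpec:
    """Declarative description of a synthetic multi-individual study.

    ``protocol`` is an optional constraint map (see :mod:`scanvault.protocol`)
    used only to stamp the intended compliance flag into the truth table.
    ``manufacturer_cycle`` overrides the template manufacturer per individual,
    round-robin, so search fixtures can plant a mixed scanner fleet.
    """

    project: str = "demo"
    n_individuals: int = 4
    timepoints: tuple[str, ...] = ("M00", "M12")
    templates: tuple[SeriesTemplate, ...] = DEFAULT_TEMPLATES
    birth_year_span: tuple[int, int] = (1935, 1975)
    acquisition_span: tuple[str, str] = ("2005-01-01", "2009-12-31")
    seed: int = 7
    protocol: Optional[Mapping[str, Mapping[str, object]]] = None
    manufacturer_cycle: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if not self.timepoints:
            raise ConfigurationError("at least one timepoint label is required")
        if not self.templates:
            raise ConfigurationError("at least one series template is required")
        if any(t.n_slices < 1 for t in self.templates):
            raise ConfigurationError("every template needs n_slices >= 1")
        if self.birth_year_span[0] > self.birth_year_span[1]:
            raise ConfigurationError("birth_year_span is empty")
        if self.acquisition_span[0] > self.acquisition_span[1]:
            raise ConfigurationError("acquisition_span is empty")


@dataclass
class TruthTable:
    """Expected values for everything the generator wrote to disk."""

    series: pd.DataFrame
    files: pd.DataFrame

    def write(self, directory: Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.series.to_csv(directory / "truth.series.csv", index=False)
        self.files.to_csv(directory / "truth.files.csv", index=False)


def _pixel_array(seed: int, instance: int) -> np.ndarray:
    """16x16 16-bit gradient plus low-amplitude seeded noise.

    Tiny and highly compressible, which exercises the lossless-compression
    path, while the noise keeps per-file checksums distinct.
    """
    grad = np.add.outer(np.arange(16), np.arange(16)).astype(np.uint16) * 32
    rng = np.random.default_rng(_seed32(seed, "pixels", instance))
    noise = rng.integers(0, 16, size=(16, 16), dtype=np.uint16)
    return grad + noise + np.uint16(instance)


def _build_dataset(
    template: SeriesTemplate,
    *,
    patient_id: str,
    patient_name: str,
    birth_date: str,
    acquisition_date: str,
    study_uid: str,
    series_uid: str,
    sop_uid: str,
    instance_number: int,
    seed: int,
) -> pydicom.FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = MRImageStorage
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = _det_uid("implementation")
    meta.ImplementationVersionName = "SCANVAULT_1"

    ds = pydicom.FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = MRImageStorage
    ds.SOPInstanceUID = sop_uid
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.Modality = template.modality
    ds.SeriesDescription = template.description
    ds.PatientID = patient_id
    ds.PatientName = patient_name
    ds.PatientBirthDate = birth_date.replace("-", "")
    ds.StudyDate = acquisition_date.replace("-", "")
    ds.SeriesDate = ds.StudyDate
    ds.AcquisitionDate = ds.StudyDate
    ds.StudyTime = "090000"
    ds.Manufacturer = template.manufacturer
    ds.DeviceSerialNumber = template.scanner_serial
    ds.SoftwareVersions = template.software_version
    ds.MagneticFieldStrength = str(template.field_strength)
    ds.EchoTime = str(template.echo_time)
    ds.RepetitionTime = str(template.repetition_time)
    ds.SliceThickness = str(template.slice_thickness)
    ds.InstanceNumber = instance_number
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows = 16
    ds.Columns = 16
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = _pixel_array(seed, instance_number).tobytes()
    return ds


def generate_series(
    template: SeriesTemplate,
    out_dir: Path,
    *,
    seed: int,
    patient_id: str = "S001",
    patient_name: str = "",
    birth_date: str = "1950-06-15",
    acquisition_date: str = "2006-03-15",
    study_uid: Optional[str] = None,
) -> tuple[str, list[Path]]:
    """Write one series of Part-10 files; returns (series UID, file paths).

    Fully deterministic in ``seed`` and the header arguments: calling twice
    with identical arguments produces byte-identical folders.
    """
    if template.n_slices < 1:
        raise ConfigurationError("n_slices must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study_uid = study_uid or _det_uid(seed, "study", patient_id, acquisition_date)
    series_uid = _det_uid(seed, "series", patient_id, acquisition_date, template.description)
    paths: list[Path] = []
    for i in range(1, template.n_slices + 1):
        sop_uid = _det_uid(seed, "sop", series_uid, i)
        ds = _build_dataset(
            template,
            patient_id=patient_id,
            patient_name=patient_name,
            birth_date=birth_date,
            acquisition_date=acquisition_date,
            study_uid=study_uid,
            series_uid=series_uid,
            sop_uid=sop_uid,
            instance_number=i,
            seed=_seed32(seed, series_uid),
        )
        path = out_dir / f"MR.{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return series_uid, paths


def _compliance(template: SeriesTemplate, protocol) -> Optional[bool]:
    if protocol is None:
        return None
    # local import: protocol module depends on archive record types
    from .archive import DicomSeriesRecord
    from .protocol import ProtocolDefinition, validate_series

    record = DicomSeriesRecord(
        series_uid="-",
        modality=template.modality,
        description=template.description,
        echo_time=template.echo_time,
        repetition_time=template.repetition_time,
        slice_thickness=template.slice_thickness,
        manufacturer=template.manufacturer,
        scanner_serial=template.scanner_serial,
        software_version=template.software_version,
        field_strength=template.field_strength,
        acquisition_date="2000-01-01",
        patient_id="-",
        file_count=template.n_slices,
    )
    proto = (
        protocol
        if isinstance(protocol, ProtocolDefinition)
        else ProtocolDefinition(name="embedded", project="-", image_type_label="-",
                                constraints=dict(protocol))
    )
    return validate_series(record, proto).compliant


def generate_study(spec: StudySpec, out_dir: Path) -> TruthTable:
    """Generate a folder-per-session study and its truth table.

    Layout: ``<out>/<individual>/<timepoint>/<series description>/*.dcm``.
    Birth dates and acquisition dates are drawn deterministically from the
    spec's spans; acquisition dates advance with the timepoint index so
    longitudinal ordering is respected.
    """
    spec.validate()
    out_dir = Path(out_dir)
    series_rows: list[dict] = []
    file_rows: list[dict] = []
    start = pd.Timestamp(spec.acquisition_span[0])
    stop = pd.Timestamp(spec.acquisition_span[1])
    span_days = max(int((stop - start).days), 1)

    for idx in range(spec.n_individuals):
        individual = f"{spec.project.upper()}{idx + 1:03d}"
        rng = np.random.default_rng(_seed32(spec.seed, "demographics", individual))
        birth_year = int(rng.integers(spec.birth_year_span[0], spec.birth_year_span[1] + 1))
        birth = f"{birth_year:04d}-{int(rng.integers(1, 13)):02d}-{int(rng.integers(1, 29)):02d}"
        base_offset = int(rng.integers(0, span_days + 1))
        for t_idx, timepoint in enumerate(spec.timepoints):
            # later visits never precede earlier ones
            acq = start + pd.Timedelta(days=min(base_offset + 366 * t_idx, span_days + 366 * t_idx))
            acq_date = acq.strftime("%Y-%m-%d")
            study_uid = _det_uid(spec.seed, "study", individual, timepoint)
            for template in spec.templates:
                if spec.manufacturer_cycle:
                    manu = spec.manufacturer_cycle[idx % len(spec.manufacturer_cycle)]
                    template = SeriesTemplate(**{**template.__dict__, "manufacturer": manu})
                folder = out_dir / individual / timepoint / template.description
                series_uid, paths = generate_series(
                    template,
                    folder,
                    seed=_seed32(spec.seed, individual, timepoint),
                    patient_id=individual,
                    birth_date=birth,
                    acquisition_date=acq_date,
                    study_uid=study_uid,
                )
                series_rows.append(
                    {
                        "project": spec.project,
                        "individual": individual,
                        "timepoint": timepoint,
                        "series_uid": series_uid,
                        "modality": template.modality,
                        "description": template.description,
                        "echo_time": template.echo_time,
                        "repetition_time": template.repetition_time,
                        "slice_thickness": template.slice_thickness,
                        "manufacturer": template.manufacturer,
                        "scanner_serial": template.scanner_serial,
                        "software_version": template.software_version,
                        "field_strength": template.field_strength,
                        "acquisition_date": acq_date,
                        "patient_birth_date": birth,
                        "file_count": template.n_slices,
                        "session_folder": str(out_dir / individual / timepoint),
                        "compliant": _compliance(template, spec.protocol),
                    }
                )
                for i, path in enumerate(paths, start=1):
                    file_rows.append(
                        {
                            "series_uid": series_uid,
                            "path": str(path),
                            "instance_number": i,
                            "sop_instance_uid": pydicom.dcmread(path, stop_before_pixels=True).SOPInstanceUID,
                            "md5": hashlib.md5(path.read_bytes()).hexdigest(),
                        }
                    )
    return TruthTable(series=pd.DataFrame(series_rows), files=pd.DataFrame(file_rows))


def session_folders(truth: TruthTable) -> list[Path]:
    """Distinct session folders of a generated study, in generation order."""
    seen: dict[str, None] = {}
    for folder in truth.series["session_folder"]:
        seen.setdefault(folder, None)
    return [Path(f) for f in seen]
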