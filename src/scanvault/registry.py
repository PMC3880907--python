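"""Transactional registry of projects, individuals, timepoints, assets, ratings.

A single-file sqlite store plays the role a relational server plays at
production scale: atomic inserts, store-wide identifier uniqueness, and
referential integrity between projects, individuals, timepoint labels and
assets.  The registry also keeps the per-series acquisition metadata of
assigned archives so that searches can filter on scanner provenance
(manufacturer, serial, field strength) and demographics (birth date) without
touching the archives on disk.

Access control is collapsed to a single-user model with a session-level set
of *active* projects: searches and queries only ever see assets of projects
the session has activated, mirroring the ability to switch off projects one
is authorized for but not currently working on.
"""

from __future__ import annotations

import json
import re
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .archive import ArchiveDescriptor
from .errors import (
    AnonymizationError,
    CollisionError,
    ConfigurationError,
    NotFoundError,
    ImportError_,
)
from .identifiers import DUuid

_SCHEMA = """
CREATE TABLE IF NOT EXISTS projects (
    name TEXT PRIMARY KEY,
    timepoint_labels TEXT NOT NULL,
    default_formats TEXT NOT NULL DEFAULT '["DICOM"]'
);
CREATE TABLE IF NOT EXISTS individuals (
    project TEXT NOT NULL REFERENCES projects(name),
    site_id TEXT NOT NULL,
    gender TEXT,
    date_of_birth TEXT,
    PRIMARY KEY (project, site_id)
);
CREATE TABLE IF NOT EXISTS assets (
    id TEXT PRIMARY KEY,
    kind TEXT NOT NULL,
    project TEXT NOT NULL,
    individual TEXT NOT NULL,
    timepoint TEXT NOT NULL,
    md5 TEXT,
    provenance TEXT NOT NULL,
    created TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS asset_files (
    asset_id TEXT NOT NULL REFERENCES assets(id),
    location TEXT NOT NULL,
    format TEXT NOT NULL,
    md5 TEXT
);
CREATE TABLE IF NOT EXISTS archive_series (
    asset_id TEXT NOT NULL REFERENCES assets(id),
    series_uid TEXT NOT NULL,
    modality TEXT, description TEXT,
    echo_time REAL, repetition_time REAL, slice_thickness REAL,
    manufacturer TEXT, scanner_serial TEXT, software_version TEXT,
    field_strength REAL,
    acquisition_date TEXT, patient_id TEXT, patient_birth_date TEXT,
    file_count INTEGER
);
CREATE TABLE IF NOT EXISTS ratings (
    rowid_ INTEGER PRIMARY KEY AUTOINCREMENT,
    asset_id TEXT NOT NULL REFERENCES assets(id),
    rater TEXT NOT NULL,
    score INTEGER NOT NULL,
    note TEXT DEFAULT '',
    timestamp TEXT NOT NULL,
    current INTEGER NOT NULL DEFAULT 1
);
"""

SEARCH_FIELDS = {
    "project", "kind", "timepoint", "individual",
    "dob", "acq_date", "manufacturer", "scanner_serial",
    "field_strength", "rating",
}

_OPS = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
}


@dataclass
class AssetFile:
    location: str
    format: str
    md5: Optional[str] = None


@dataclass
class Asset:
    id: str
    kind: str
    project: str
    individual: str
    timepoint: str
    md5: Optional[str] = None
    provenance: dict = field(default_factory=lambda: {"type": "upload"})
    files: list[AssetFile] = field(default_factory=list)
    created: Optional[str] = None


@dataclass
class Rating:
    asset: str
    rater: str
    score: int
    note: str
    timestamp: str
    current: bool


@dataclass
class ImportReport:
    new: int = 0
    existing: int = 0
    errors: list[str] = field(default_factory=list)


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


class Registry:
    """Single-file transactional store with a session active-project set."""

    def __init__(self, path: Union[str, Path] = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.row_factory = sqlite3.Row
        self.conn.executescript(_SCHEMA)
        self.active_projects: set[str] = set()

    def close(self) -> None:
        self.conn.close()

    # -- projects -----------------------------------------------------------

    def create_project(
        self,
        name: str,
        timepoint_labels: Sequence[str],
        default_formats: Sequence[str] = ("DICOM",),
    ) -> None:
        labels = list(timepoint_labels)
        if len(set(labels)) != len(labels):
            raise ConfigurationError("timepoint labels must be unique within a project")
        try:
            with self.conn:
                self.conn.execute(
                    "INSERT INTO projects (name, timepoint_labels, default_formats) VALUES (?,?,?)",
                    (name, json.dumps(labels), json.dumps(list(default_formats))),
                )
        except sqlite3.IntegrityError as exc:
            raise CollisionError(f"project already exists: {name}") from exc

    def project_timepoints(self, name: str) -> list[str]:
        row = self.conn.execute(
            "SELECT timepoint_labels FROM projects WHERE name = ?", (name,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no such project: {name}")
        return json.loads(row["timepoint_labels"])

    def activate(self, *projects: str) -> None:
        for p in projects:
            self.project_timepoints(p)  # existence check
            self.active_projects.add(p)

    def deactivate(self, *projects: str) -> None:
        self.active_projects -= set(projects)

    # -- individuals --------------------------------------------------------

    def register_individuals(
        self,
        table: Union[Path, str, pd.DataFrame],
        project: Optional[str] = None,
    ) -> ImportReport:
        """Upsert individuals from a CSV with columns Project/SiteId[+Gender,DateOfBirth].

        A file named ``<project>.individuals.list.csv`` routes to that project
        automatically when no explicit project or Project column is given.
        Idempotent on (project, site_id): re-uploading the same list adds
        nothing.
        """
        if isinstance(table, pd.DataFrame):
            df = table.copy()
        else:
            path = Path(table)
            if project is None:
                m = re.match(r"^(?P<project>[^.]+)\.individuals\.list\.csv$", path.name)
                if m:
                    project = m.group("project")
            df = pd.read_csv(path, dtype=str)
        df.columns = [c.strip() for c in df.columns]
        cols = {c.lower(): c for c in df.columns}
        if "siteid" not in cols:
            raise ImportError_("individual list needs a SiteId column")
        if "project" not in cols and project is None:
            raise ImportError_("no Project column and no project could be inferred")

        report = ImportReport()
        for i, row in df.iterrows():
            proj = str(row[cols["project"]]).strip() if "project" in cols else ""
            proj = proj if proj and proj.lower() != "nan" else (project or "")
            site = str(row[cols["siteid"]]).strip() if pd.notna(row[cols["siteid"]]) else ""
            if not site or site.lower() == "nan":
                report.errors.append(f"row {i}: missing SiteId")
                continue
            if not proj:
                report.errors.append(f"row {i}: missing Project")
                continue
            self.project_timepoints(proj)  # project must exist
            gender = None
            dob = None
            if "gender" in cols and pd.notna(row[cols["gender"]]):
                gender = str(row[cols["gender"]]).strip() or None
            if "dateofbirth" in cols and pd.notna(row[cols["dateofbirth"]]):
                dob = str(row[cols["dateofbirth"]]).strip() or None
            exists = self.conn.execute(
                "SELECT 1 FROM individuals WHERE project=? AND site_id=?", (proj, site)
            ).fetchone()
            with self.conn:
                if exists:
                    self.conn.execute(
                        "UPDATE individuals SET gender=COALESCE(?,gender), "
                        "date_of_birth=COALESCE(?,date_of_birth) WHERE project=? AND site_id=?",
                        (gender, dob, proj, site),
                    )
                    report.existing += 1
                else:
                    self.conn.execute(
                        "INSERT INTO individuals (project, site_id, gender, date_of_birth) "
                        "VALUES (?,?,?,?)",
                        (proj, site, gender, dob),
                    )
                    report.new += 1
        return report

    def has_individual(self, project: str, site_id: str) -> bool:
        return (
            self.conn.execute(
                "SELECT 1 FROM individuals WHERE project=? AND site_id=?",
                (project, site_id),
            ).fetchone()
            is not None
        )

    def individuals(self, project: str) -> pd.DataFrame:
        return pd.read_sql_query(
            "SELECT * FROM individuals WHERE project=? ORDER BY site_id",
            self.conn,
            params=(project,),
        )

    # -- assets -------------------------------------------------------------

    def has_asset(self, asset_id: str) -> bool:
        return (
            self.conn.execute("SELECT 1 FROM assets WHERE id=?", (asset_id,)).fetchone()
            is not None
        )

    def register_asset(self, asset: Asset) -> DUuid:
        """Atomic insert; a duplicate identifier is a collision, never an overwrite."""
        did = DUuid.parse(asset.id)  # validates canonical form
        try:
            with self.conn:
                self.conn.execute(
                    "INSERT INTO assets (id, kind, project, individual, timepoint, md5, "
                    "provenance, created) VALUES (?,?,?,?,?,?,?,?)",
                    (
                        asset.id,
                        asset.kind,
                        asset.project,
                        asset.individual,
                        asset.timepoint,
                        asset.md5,
                        json.dumps(asset.provenance),
                        asset.created or _now(),
                    ),
                )
                self.conn.executemany(
                    "INSERT INTO asset_files (asset_id, location, format, md5) VALUES (?,?,?,?)",
                    [(asset.id, f.location, f.format, f.md5) for f in asset.files],
                )
        except sqlite3.IntegrityError as exc:
            raise CollisionError(f"asset id already registered: {asset.id}") from exc
        return did

    def get_asset(self, asset_id: str) -> Asset:
        row = self.conn.execute("SELECT * FROM assets WHERE id=?", (asset_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"no such asset: {asset_id}")
        files = [
            AssetFile(r["location"], r["format"], r["md5"])
            for r in self.conn.execute(
                "SELECT * FROM asset_files WHERE asset_id=?", (asset_id,)
            )
        ]
        return Asset(
            id=row["id"],
            kind=row["kind"],
            project=row["project"],
            individual=row["individual"],
            timepoint=row["timepoint"],
            md5=row["md5"],
            provenance=json.loads(row["provenance"]),
            files=files,
            created=row["created"],
        )

    def assets_of(self, project: str, kind: Optional[str] = None) -> list[Asset]:
        q = "SELECT id FROM assets WHERE project=?"
        params: list = [project]
        if kind:
            q += " AND kind=?"
            params.append(kind)
        return [self.get_asset(r["id"]) for r in self.conn.execute(q + " ORDER BY created, id", params)]

    def assign_archive(
        self,
        descriptor: ArchiveDescriptor,
        project: str,
        individual: str,
        timepoint: str,
        location: Optional[str] = None,
    ) -> Asset:
        """Register a DICOM archive as a project asset.

        Refused unless the descriptor has been confirmed anonymized and the
        (individual, timepoint) pair exists in the project.
        """
        if not descriptor.anonymized_confirmed:
            raise AnonymizationError(
                f"archive {descriptor.archive_id} has not been confirmed anonymized"
            )
        if timepoint not in self.project_timepoints(project):
            raise NotFoundError(f"timepoint {timepoint!r} not registered in project {project!r}")
        if not self.has_individual(project, individual):
            raise NotFoundError(f"individual {individual!r} not registered in project {project!r}")
        files = []
        if location:
            files.append(AssetFile(location=location, format="tar.gz", md5=descriptor.archive_md5))
        asset = Asset(
            id=descriptor.archive_id,
            kind="dicomArchive",
            project=project,
            individual=individual,
            timepoint=timepoint,
            md5=descriptor.archive_md5,
            provenance={"type": "upload", "assigned": _now()},
            files=files,
        )
        self.register_asset(asset)
        with self.conn:
            self.conn.executemany(
                "INSERT INTO archive_series (asset_id, series_uid, modality, description, "
                "echo_time, repetition_time, slice_thickness, manufacturer, scanner_serial, "
                "software_version, field_strength, acquisition_date, patient_id, "
                "patient_birth_date, file_count) VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                [
                    (
                        descriptor.archive_id, s.series_uid, s.modality, s.description,
                        s.echo_time, s.repetition_time, s.slice_thickness, s.manufacturer,
                        s.scanner_serial, s.software_version, s.field_strength,
                        s.acquisition_date, s.patient_id, s.patient_birth_date, s.file_count,
                    )
                    for s in descriptor.series
                ],
            )
        return asset

    # -- search -------------------------------------------------------------

    def search_assets(self, criteria: Sequence[tuple[str, str, object]] = ()) -> list[Asset]:
        """Conjunctive search over session-active projects.

        ``criteria`` is a list of ``(field, op, value)`` triples; ops are
        eq/ne/lt/le/gt/ge.  Asset-level fields (project, kind, timepoint,
        individual, rating) apply directly; acquisition fields (acq_date,
        manufacturer, scanner_serial, field_strength) must hold together on at
        least one series of the asset; ``dob`` is the registered (or header)
        birth date of the individual.  Date comparisons are lexicographic on
        ISO dates; manufacturer matching is case-insensitive.
        """
        for f, op, _ in criteria:
            if f not in SEARCH_FIELDS:
                raise ConfigurationError(f"unknown search field: {f!r}")
            if op not in _OPS:
                raise ConfigurationError(f"unknown search operator: {op!r}")
        out = []
        rows = self.conn.execute("SELECT id FROM assets ORDER BY created, id").fetchall()
        for row in rows:
            asset = self.get_asset(row["id"])
            if asset.project not in self.active_projects:
                continue
            if self._matches(asset, criteria):
                out.append(asset)
        return out

    def _matches(self, asset: Asset, criteria) -> bool:
        asset_level = {"project": asset.project, "kind": asset.kind,
                       "timepoint": asset.timepoint, "individual": asset.individual}
        series_rows = self.conn.execute(
            "SELECT * FROM archive_series WHERE asset_id=?", (asset.id,)
        ).fetchall()
        series_crit = []
        for fieldname, op, value in criteria:
            cmp = _OPS[op]
            if fieldname in asset_level:
                if not cmp(asset_level[fieldname], value):
                    return False
            elif fieldname == "rating":
                row = self.conn.execute(
                    "SELECT MAX(score) AS s FROM ratings WHERE asset_id=? AND current=1",
                    (asset.id,),
                ).fetchone()
                if row["s"] is None or not cmp(row["s"], value):
                    return False
            elif fieldname == "dob":
                dob = self.conn.execute(
                    "SELECT date_of_birth FROM individuals WHERE project=? AND site_id=?",
                    (asset.project, asset.individual),
                ).fetchone()
                dob_value = dob["date_of_birth"] if dob else None
                if dob_value is None and series_rows:
                    dob_value = series_rows[0]["patient_birth_date"]
                if dob_value is None or not cmp(str(dob_value), str(value)):
                    return False
            else:
                series_crit.append((fieldname, cmp, value))
        if series_crit:
            col = {"acq_date": "acquisition_date", "manufacturer": "manufacturer",
                   "scanner_serial": "scanner_serial", "field_strength": "field_strength"}
            def series_ok(s) -> bool:
                for fieldname, cmp, value in series_crit:
                    observed = s[col[fieldname]]
                    if observed is None:
                        return False
                    if fieldname == "manufacturer":
                        observed, value = str(observed).lower(), str(value).lower()
                    elif fieldname == "acq_date":
                        observed, value = str(observed), str(value)
                    if not cmp(observed, value):
                        return False
                return True
            if not any(series_ok(s) for s in series_rows):
                return False
        return True

    # -- download naming ----------------------------------------------------

    def render_download_name(
        self,
        asset: Union[Asset, str],
        preference: str = "plain",
        template: Optional[str] = None,
        extension: str = "tar",
    ) -> str:
        """Deterministic download filename embedding the canonical identifier.

        ``plain``     -> ``<uuid>.<ext>``
        ``typed``     -> ``<kind>.<uuid>.<ext>``
        ``enriched``  -> template tokens (``<AcquisitionDate>``, ``<PatientID>``,
        ...) resolved from the asset's series metadata, then ``.<uuid>.<ext>``.
        """
        if isinstance(asset, str):
            asset = self.get_asset(asset)
        if preference == "plain":
            return f"{asset.id}.{extension}"
        if preference == "typed":
            return f"{asset.kind}.{asset.id}.{extension}"
        if preference == "enriched":
            if not template:
                raise ConfigurationError("enriched naming requires a template")
            resolved = self._resolve_tokens(asset, template)
            return f"{resolved}.{asset.id}.{extension}"
        raise ConfigurationError(f"unknown naming preference: {preference!r}")

    def _resolve_tokens(self, asset: Asset, template: str) -> str:
        series = self.conn.execute(
            "SELECT * FROM archive_series WHERE asset_id=? ORDER BY series_uid LIMIT 1",
            (asset.id,),
        ).fetchone()
        tokens = {
            "PatientID": series["patient_id"] if series else None,
            "AcquisitionDate": series["acquisition_date"].replace("-", "")
            if series and series["acquisition_date"] else None,
            "Manufacturer": series["manufacturer"] if series else None,
            "Individual": asset.individual,
            "TimePoint": asset.timepoint,
            "Project": asset.project,
        }

        def sub(match: re.Match) -> str:
            token = match.group(1)
            if token not in tokens:
                raise ConfigurationError(f"unknown naming token: <{token}>")
            value = tokens[token]
            if value in (None, ""):
                raise NotFoundError(f"token <{token}> unavailable for asset {asset.id}")
            return str(value)

        return re.sub(r"<([A-Za-z]+)>", sub, template)

    # -- ratings ------------------------------------------------------------

    def record_rating(self, asset_id: str, rater: str, score: int, note: str = "") -> Rating:
        """Append a 1-5 quality rating; each rater's history is preserved."""
        if not isinstance(score, int) or not 1 <= score <= 5:
            raise ConfigurationError(f"rating score must be an integer 1-5, got {score!r}")
        self.get_asset(asset_id)  # must exist
        ts = _now()
        with self.conn:
            self.conn.execute(
                "UPDATE ratings SET current=0 WHERE asset_id=? AND rater=?",
                (asset_id, rater),
            )
            self.conn.execute(
                "INSERT INTO ratings (asset_id, rater, score, note, timestamp, current) "
                "VALUES (?,?,?,?,?,1)",
                (asset_id, rater, score, note, ts),
            )
        return Rating(asset_id, rater, score, note, ts, True)

    def ratings(self, asset_id: str, current_only: bool = True) -> list[Rating]:
        q = "SELECT * FROM ratings WHERE asset_id=?"
        if current_only:
            q += " AND current=1"
        return [
            Rating(r["asset_id"], r["rater"], r["score"], r["note"], r["timestamp"], bool(r["current"]))
            for r in self.conn.execute(q + " ORDER BY rowid_", (asset_id,))
        ]
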