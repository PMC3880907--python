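"""Versioned activity instances, job lifecycle, provenance and accounting.

Processing is modelled as *activity instances*: an immutable (name, version,
parameters) triple bound to a registered compute resource and authorized for
specific projects.  Requesting work creates one job per input asset whose
identity IS its future output identifier, computed up front from the activity
triple and the sorted input identifiers.  The job stages its inputs into
``<input_path>/<output_id>/``; completion follows the external-upload
convention — a file named ``<output_id>.tar.gz`` appearing in the resource's
output path marks the job complete and registers the output collection under
the precomputed identifier, inheriting project/individual/timepoint from its
inputs.

Because versions enter the identifier, reprocessing with a new tool release
mints new output identifiers, while re-requesting an identical invocation
collides — previous results must be removed first.  Every derived asset is
therefore traceable back through (name, version, parameters) links to the
original upload, and the job ledger doubles as the accounting source.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tarfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import (
    CollisionError,
    ConfigurationError,
    NotFoundError,
    StateError,
)
from .identifiers import DUuid, derive_output_id
from .registry import Asset, AssetFile, Registry

JOB_STATES = ("pending", "staged", "running", "completed", "failed")
_TRANSITIONS = {
    "pending": {"staged"},
    "staged": {"running", "completed", "failed"},
    "running": {"completed", "failed"},
    "completed": set(),
    "failed": set(),
}

_SCHEMA = """
CREATE TABLE IF NOT EXISTS resources (
    name TEXT PRIMARY KEY,
    host TEXT NOT NULL,
    purpose TEXT NOT NULL,
    input_path TEXT,
    output_path TEXT,
    owner TEXT
);
CREATE TABLE IF NOT EXISTS instances (
    label TEXT PRIMARY KEY,
    activity_name TEXT NOT NULL,
    version TEXT NOT NULL,
    parameters TEXT NOT NULL DEFAULT '',
    resource TEXT NOT NULL REFERENCES resources(name),
    authorized_projects TEXT NOT NULL,
    stats_member TEXT,
    UNIQUE (activity_name, version, parameters, resource)
);
CREATE TABLE IF NOT EXISTS jobs (
    output_id TEXT PRIMARY KEY,
    instance_label TEXT NOT NULL REFERENCES instances(label),
    project TEXT NOT NULL,
    individual TEXT NOT NULL,
    timepoint TEXT NOT NULL,
    input_ids TEXT NOT NULL,
    state TEXT NOT NULL,
    timestamps TEXT NOT NULL,
    accounting TEXT NOT NULL DEFAULT '{}'
);
"""


def _now() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass(frozen=True)
class Resource:
    name: str
    host: str
    purpose: str  # processing | project-server | dropbox
    input_path: Optional[str] = None
    output_path: Optional[str] = None
    owner: Optional[str] = None

    def __post_init__(self) -> None:
        if self.purpose not in ("processing", "project-server", "dropbox"):
            raise ConfigurationError(f"unknown resource purpose: {self.purpose!r}")
        if self.purpose == "processing" and not (self.input_path and self.output_path):
            raise ConfigurationError("processing resources need input and output paths")


@dataclass(frozen=True)
class ActivityInstance:
    """Immutable invocation definition: (name, version, parameters) on a resource."""

    label: str
    activity_name: str
    version: str
    parameters: str
    resource: str
    authorized_projects: frozenset[str]
    stats_member: Optional[str] = None


@dataclass
class Job:
    output_id: str
    instance: ActivityInstance
    project: str
    individual: str
    timepoint: str
    input_ids: list[str]
    state: str
    timestamps: dict[str, str]
    accounting: dict


class ActivitySystem:
    """Job ledger, staging/completion conventions, provenance and accounting."""

    def __init__(self, registry: Registry):
        self.registry = registry
        self.conn = registry.conn
        self.conn.executescript(_SCHEMA)

    # -- resources & instances ---------------------------------------------

    def add_resource(self, resource: Resource) -> None:
        with self.conn:
            self.conn.execute(
                "INSERT INTO resources (name, host, purpose, input_path, output_path, owner) "
                "VALUES (?,?,?,?,?,?)",
                (resource.name, resource.host, resource.purpose,
                 resource.input_path, resource.output_path, resource.owner),
            )

    def get_resource(self, name: str) -> Resource:
        row = self.conn.execute("SELECT * FROM resources WHERE name=?", (name,)).fetchone()
        if row is None:
            raise NotFoundError(f"no such resource: {name}")
        return Resource(row["name"], row["host"], row["purpose"],
                        row["input_path"], row["output_path"], row["owner"])

    def create_instance(
        self,
        label: str,
        activity_name: str,
        version: str,
        parameters: str,
        resource: str,
        authorized_projects: Sequence[str],
        stats_member: Optional[str] = None,
    ) -> ActivityInstance:
        if not activity_name.strip() or not version.strip():
            raise ConfigurationError("activity name and version must be non-empty")
        self.get_resource(resource)
        with self.conn:
            self.conn.execute(
                "INSERT INTO instances (label, activity_name, version, parameters, resource, "
                "authorized_projects, stats_member) VALUES (?,?,?,?,?,?,?)",
                (label, activity_name, version, parameters, resource,
                 json.dumps(sorted(authorized_projects)), stats_member),
            )
        return self.get_instance(label)

    def get_instance(self, label: str) -> ActivityInstance:
        row = self.conn.execute("SELECT * FROM instances WHERE label=?", (label,)).fetchone()
        if row is None:
            raise NotFoundError(f"no such activity instance: {label}")
        return ActivityInstance(
            label=row["label"],
            activity_name=row["activity_name"],
            version=row["version"],
            parameters=row["parameters"],
            resource=row["resource"],
            authorized_projects=frozenset(json.loads(row["authorized_projects"])),
            stats_member=row["stats_member"],
        )

    # -- jobs ---------------------------------------------------------------

    def get_job(self, output_id: str) -> Job:
        row = self.conn.execute("SELECT * FROM jobs WHERE output_id=?", (output_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"no such job: {output_id}")
        return Job(
            output_id=row["output_id"],
            instance=self.get_instance(row["instance_label"]),
            project=row["project"],
            individual=row["individual"],
            timepoint=row["timepoint"],
            input_ids=json.loads(row["input_ids"]),
            state=row["state"],
            timestamps=json.loads(row["timestamps"]),
            accounting=json.loads(row["accounting"]),
        )

    def _set_state(self, job: Job, new_state: str, **accounting) -> None:
        if new_state not in _TRANSITIONS[job.state]:
            raise StateError(f"illegal transition {job.state} -> {new_state} for {job.output_id}")
        job.timestamps[new_state] = _now()
        job.state = new_state
        job.accounting.update(accounting)
        with self.conn:
            self.conn.execute(
                "UPDATE jobs SET state=?, timestamps=?, accounting=? WHERE output_id=?",
                (job.state, json.dumps(job.timestamps), json.dumps(job.accounting),
                 job.output_id),
            )

    def request_jobs(
        self,
        instance: ActivityInstance | str,
        asset_ids: Sequence[str],
        group: str = "per-asset",
    ) -> list[Job]:
        """Create and stage one job per asset (or one for the whole group).

        The output identifier is computed NOW, from (name, version,
        parameters, sorted inputs); staging copies every input asset file into
        ``<input_path>/<output_id>/``.  An identifier already present in the
        job ledger or the asset registry is a collision: reprocessing without
        removing previous results always fails.
        """
        if isinstance(instance, str):
            instance = self.get_instance(instance)
        if group not in ("per-asset", "all"):
            raise ConfigurationError(f"unknown grouping: {group!r}")
        if not asset_ids:
            raise ConfigurationError("at least one input asset is required")
        assets = [self.registry.get_asset(a) for a in asset_ids]
        for asset in assets:
            if asset.project not in instance.authorized_projects:
                raise ConfigurationError(
                    f"project {asset.project!r} is not authorized for instance {instance.label!r}"
                )
        groups = [[a] for a in assets] if group == "per-asset" else [assets]
        resource = self.get_resource(instance.resource)

        planned: list[tuple[list[Asset], DUuid]] = []
        for members in groups:
            output_id = derive_output_id(
                instance.activity_name,
                instance.version,
                instance.parameters,
                [DUuid.parse(a.id) for a in members],
            )
            if self.registry.has_asset(output_id.render()) or self._job_exists(output_id.render()):
                raise CollisionError(
                    f"output {output_id.render()} already exists — remove previous "
                    f"results of {instance.activity_name} {instance.version} first"
                )
            planned.append((members, output_id))

        jobs = []
        for members, output_id in planned:
            staging = Path(resource.input_path) / output_id.render()
            staging.mkdir(parents=True, exist_ok=True)
            for asset in members:
                for f in asset.files:
                    src = Path(f.location)
                    if src.is_file():
                        shutil.copy2(src, staging / src.name)
            first = members[0]
            job = Job(
                output_id=output_id.render(),
                instance=instance,
                project=first.project,
                individual=first.individual,
                timepoint=first.timepoint,
                input_ids=[a.id for a in members],
                state="staged",
                timestamps={"pending": _now(), "staged": _now()},
                accounting={},
            )
            with self.conn:
                self.conn.execute(
                    "INSERT INTO jobs (output_id, instance_label, project, individual, "
                    "timepoint, input_ids, state, timestamps, accounting) "
                    "VALUES (?,?,?,?,?,?,?,?,?)",
                    (job.output_id, instance.label, job.project, job.individual,
                     job.timepoint, json.dumps(job.input_ids), job.state,
                     json.dumps(job.timestamps), json.dumps(job.accounting)),
                )
            jobs.append(job)
        return jobs

    def _job_exists(self, output_id: str) -> bool:
        return (
            self.conn.execute("SELECT 1 FROM jobs WHERE output_id=?", (output_id,)).fetchone()
            is not None
        )

    # -- completion ---------------------------------------------------------

    def scan_completions(self, instance: ActivityInstance | str) -> tuple[list[Asset], list[str]]:
        """Apply the external-completion convention to a resource's output path.

        Files named ``<output_id>.tar.gz`` matching a staged/running job
        complete that job; anything else is rejected and reported.  Returns
        (registered output collections, rejected file names).
        """
        if isinstance(instance, str):
            instance = self.get_instance(instance)
        resource = self.get_resource(instance.resource)
        out_dir = Path(resource.output_path)
        registered: list[Asset] = []
        rejected: list[str] = []
        for path in sorted(out_dir.glob("*.tar.gz")):
            name = path.name[: -len(".tar.gz")]
            try:
                job = self.get_job(name)
            except NotFoundError:
                rejected.append(path.name)
                continue
            if job.state in ("staged", "running"):
                registered.append(self.complete_job(job, path))
            else:
                rejected.append(path.name)
        return registered, rejected

    def complete_job(self, job: Job | str, collection_file: Path) -> Asset:
        """Mark a job complete and register its output collection asset.

        The collection inherits project/individual/timepoint from the job's
        inputs and is registered under the identifier computed at request
        time; completing an already-completed job is a state error.
        """
        if isinstance(job, str):
            job = self.get_job(job)
        collection_file = Path(collection_file)
        expected = f"{job.output_id}.tar.gz"
        if collection_file.name != expected:
            raise ConfigurationError(
                f"output file {collection_file.name!r} does not follow the "
                f"naming convention ({expected!r})"
            )
        if job.state not in ("staged", "running"):
            raise StateError(f"job {job.output_id} is {job.state}, cannot complete")
        with tarfile.open(collection_file, "r:gz") as tar:
            members = [m.name for m in tar.getmembers() if m.isfile()]
        if not members:
            raise ConfigurationError("an output collection must contain at least one item")
        import hashlib

        md5 = hashlib.md5(collection_file.read_bytes()).hexdigest()
        asset = Asset(
            id=job.output_id,
            kind="outputCollection",
            project=job.project,
            individual=job.individual,
            timepoint=job.timepoint,
            md5=md5,
            provenance={
                "type": "job",
                "activity": {
                    "name": job.instance.activity_name,
                    "version": job.instance.version,
                    "parameters": job.instance.parameters,
                },
                "inputs": job.input_ids,
                "members": members,
            },
            files=[AssetFile(location=str(collection_file), format="tar.gz", md5=md5)],
        )
        self.registry.register_asset(asset)
        self._set_state(job, "completed", members=len(members))
        if job.instance.stats_member:
            self._ingest_stats(job, collection_file)
        return asset

    def _ingest_stats(self, job: Job, collection_file: Path) -> None:
        """Parse a declared key/value stats member into an asset-level collection.

        The collection is named ``<activity>-<version>`` and keyed by the
        output collection's identifier, so derived scalar measures join back
        to imaging and clinical data through the normal query path.  The stats
        dialect is one ``name<TAB or =>value`` pair per line.
        """
        from .scalar import ScalarStore

        with tarfile.open(collection_file, "r:gz") as tar:
            member = next(
                (m for m in tar.getmembers() if Path(m.name).name == job.instance.stats_member),
                None,
            )
            if member is None:
                return
            text = tar.extractfile(member).read().decode()
        values: dict[str, str] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line:
                k, _, v = line.partition("=")
            else:
                parts = line.split(None, 1)
                if len(parts) != 2:
                    continue
                k, v = parts
            values[k.strip()] = v.strip()
        if not values:
            return
        frame = pd.DataFrame([{"UUID": job.output_id, **values}])
        name = f"{job.instance.activity_name}-{job.instance.version}"
        ScalarStore(self.registry).import_table(frame, name)

    def extract_members(self, collection_id: str, patterns: Sequence[str], target: Path) -> list[Path]:
        """Copy declared members out of a stored collection; the archive stays intact."""
        asset = self.registry.get_asset(collection_id)
        if asset.kind != "outputCollection":
            raise ConfigurationError(f"{collection_id} is not an output collection")
        source = Path(asset.files[0].location)
        target = Path(target)
        target.mkdir(parents=True, exist_ok=True)
        out = []
        with tarfile.open(source, "r:gz") as tar:
            for m in tar.getmembers():
                if m.isfile() and any(Path(m.name).match(p) for p in patterns):
                    dest = target / Path(m.name).name
                    dest.write_bytes(tar.extractfile(m).read())
                    out.append(dest)
        return out

    # -- local execution ----------------------------------------------------

    def run_local(self, job: Job | str, command_template: str) -> Job:
        """Run a staged job with a local subprocess (desk-scale executor).

        The template may reference ``{input_dir}``, ``{work_dir}`` and
        ``{parameters}``.  On success the work directory is packaged as the
        properly named collection into the resource's output path and routed
        through :meth:`complete_job`; a nonzero exit leaves the job failed
        with the exit code and output captured in accounting.
        """
        if isinstance(job, str):
            job = self.get_job(job)
        if job.state != "staged":
            raise StateError(f"job {job.output_id} is {job.state}, expected staged")
        resource = self.get_resource(job.instance.resource)
        input_dir = Path(resource.input_path) / job.output_id
        work_dir = Path(resource.output_path) / f"work-{job.output_id}"
        work_dir.mkdir(parents=True, exist_ok=True)
        command = command_template.format(
            input_dir=input_dir, work_dir=work_dir, parameters=job.instance.parameters
        )
        self._set_state(job, "running", command=command)
        proc = subprocess.run(
            command, shell=True, capture_output=True, text=True, cwd=work_dir
        )
        if proc.returncode != 0:
            self._set_state(
                job, "failed", exit_code=proc.returncode,
                log=(proc.stderr or proc.stdout)[-2000:],
            )
            return job
        produced = [p for p in sorted(work_dir.rglob("*")) if p.is_file()]
        if not produced:
            marker = work_dir / "DONE.txt"
            marker.write_text("completed with no declared outputs\n")
            produced = [marker]
        collection = Path(resource.output_path) / f"{job.output_id}.tar.gz"
        with tarfile.open(collection, "w:gz") as tar:
            for p in produced:
                tar.add(p, arcname=str(p.relative_to(work_dir)))
        job.accounting["exit_code"] = 0
        self.complete_job(job, collection)
        return self.get_job(job.output_id)

    # -- provenance ---------------------------------------------------------

    def trace(self, asset_id: str) -> list[dict]:
        """Provenance chain from an asset back to its original upload.

        Each link is ``{"asset": id, "kind": ..., "via": provenance-type,
        "activity": triple-or-None}``; the chain follows the first input of
        derived assets (all inputs are recorded on the link) and is guarded
        against cycles.
        """
        chain: list[dict] = []
        seen: set[str] = set()
        current: Optional[str] = asset_id
        while current is not None:
            if current in seen:
                raise StateError(f"provenance cycle detected at {current}")
            seen.add(current)
            asset = self.registry.get_asset(current)
            prov = asset.provenance
            chain.append(
                {
                    "asset": asset.id,
                    "kind": asset.kind,
                    "via": prov.get("type", "upload"),
                    "activity": prov.get("activity"),
                    "inputs": prov.get("inputs", []),
                }
            )
            inputs = prov.get("inputs", [])
            current = inputs[0] if inputs else None
        return chain

    # -- accounting ---------------------------------------------------------

    def accounting_summary(
        self,
        project: Optional[str] = None,
        instance: Optional[str] = None,
    ) -> dict:
        """Counts per state (and mean wall time of completed jobs) over the ledger."""
        rows = self.conn.execute("SELECT * FROM jobs ORDER BY rowid").fetchall()
        counts = {state: 0 for state in JOB_STATES}
        durations: list[float] = []
        total = 0
        for row in rows:
            if project and row["project"] != project:
                continue
            if instance and row["instance_label"] != instance:
                continue
            total += 1
            counts[row["state"]] += 1
            ts = json.loads(row["timestamps"])
            if row["state"] == "completed" and "staged" in ts and "completed" in ts:
                t0 = datetime.fromisoformat(ts["staged"])
                t1 = datetime.fromisoformat(ts["completed"])
                durations.append((t1 - t0).total_seconds())
        return {
            "total": total,
            "by_state": counts,
            "mean_completed_seconds": (sum(durations) / len(durations)) if durations else None,
        }

    def ledger(self) -> pd.DataFrame:
        """The job ledger as a flat table (exportable as CSV)."""
        return pd.read_sql_query("SELECT * FROM jobs ORDER BY rowid", self.conn)
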