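"""Convention-based tabular import and cross-level wide-table querying.

Clinical, cognitive and derived scalar variables arrive as spreadsheets and
attach at one of three levels, inferred from the key columns of the file:

1. individual level — columns ``Project, Individual`` (e.g. gender, APOE);
2. timepoint level  — columns ``Project, Individual, TimePoint`` (e.g. MMSE);
3. asset level      — a single ``UUID`` (or ``AssetID``) key column: because
   an asset already belongs to a project, individual and timepoint, the
   identifier alone places the value.

Variables are grouped into named *variable collections* whose field names are
the header row; importing into an existing collection appends to it, which is
what makes a collection (say MMSE, always imported with the same field names)
queryable across projects.  The query side produces one wide table with one
row per (individual, timepoint): individual-level variables repeat across an
individual's rows, asset-level variables join through the asset's assignment,
and missing cells stay empty — never fabricated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import ConfigurationError, ImportError_, NotFoundError
from .registry import Registry

LEVELS = ("individual", "timepoint", "asset")

_SCHEMA = """
CREATE TABLE IF NOT EXISTS collections (
    name TEXT PRIMARY KEY,
    level TEXT NOT NULL,
    fields TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS scalar_records (
    collection TEXT NOT NULL REFERENCES collections(name),
    project TEXT,
    individual TEXT,
    timepoint TEXT,
    asset_id TEXT,
    field TEXT NOT NULL,
    value TEXT,
    UNIQUE (collection, project, individual, timepoint, asset_id, field)
);
"""

_KEY_ALIASES = {
    "project": "project",
    "individual": "individual",
    "siteid": "individual",
    "timepoint": "timepoint",
    "uuid": "asset_id",
    "assetid": "asset_id",
}


@dataclass
class VariableCollection:
    name: str
    level: str
    field_names: list[str]


@dataclass
class ScalarImportReport:
    new: int = 0
    updated: int = 0
    unchanged: int = 0
    failed: int = 0
    errors: list[str] = field(default_factory=list)


def _typed(value: str):
    """Keep values as typed scalars: numeric when parseable, else string."""
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() == "nan":
        return None
    try:
        f = float(s)
        return int(f) if f.is_integer() and "." not in s and "e" not in s.lower() else f
    except ValueError:
        return s


class ScalarStore:
    """Variable collections and records, stored beside the registry tables."""

    def __init__(self, registry: Registry):
        self.registry = registry
        self.conn = registry.conn
        self.conn.executescript(_SCHEMA)

    # -- import -------------------------------------------------------------

    def _infer_level(self, columns: list[str]) -> tuple[str, dict[str, str]]:
        keymap: dict[str, str] = {}
        for c in columns:
            alias = _KEY_ALIASES.get(c.strip().lower())
            if alias:
                keymap[alias] = c
        has_asset = "asset_id" in keymap
        has_tp = "timepoint" in keymap
        has_ind = "project" in keymap and "individual" in keymap
        if has_asset and (has_tp or has_ind):
            raise ImportError_(
                "ambiguous key columns: provide either a UUID column or "
                "Project/Individual[/TimePoint], not both"
            )
        if has_asset:
            return "asset", keymap
        if has_ind and has_tp:
            return "timepoint", keymap
        if has_ind:
            return "individual", keymap
        raise ImportError_(
            "cannot infer attachment level: need Project+Individual, "
            "Project+Individual+TimePoint, or a UUID column"
        )

    def get_collection(self, name: str) -> VariableCollection:
        row = self.conn.execute("SELECT * FROM collections WHERE name=?", (name,)).fetchone()
        if row is None:
            raise NotFoundError(f"no such variable collection: {name}")
        return VariableCollection(row["name"], row["level"], json.loads(row["fields"]))

    def import_table(
        self,
        table: Union[Path, str, pd.DataFrame],
        collection_name: Optional[str] = None,
    ) -> ScalarImportReport:
        """Import one CSV (or frame) into a variable collection.

        The collection name defaults from the ``<project>.<collection>.csv``
        naming convention.  Re-importing identical rows is a no-op; a
        conflicting value for an existing key+field is a row error, never a
        silent overwrite.
        """
        if isinstance(table, pd.DataFrame):
            df = table.copy()
            if collection_name is None:
                raise ImportError_("collection name required when importing a DataFrame")
        else:
            path = Path(table)
            if collection_name is None:
                parts = path.name.split(".")
                if len(parts) >= 3 and parts[-1] == "csv":
                    collection_name = ".".join(parts[1:-1])
                else:
                    raise ImportError_(
                        f"cannot infer collection name from {path.name!r}; pass it explicitly"
                    )
            df = pd.read_csv(path, dtype=str)
        df.columns = [c.strip() for c in df.columns]
        level, keymap = self._infer_level(list(df.columns))
        value_cols = [c for c in df.columns if c not in keymap.values()]
        if not value_cols:
            raise ImportError_("table has key columns but no variable columns")

        existing = self.conn.execute(
            "SELECT * FROM collections WHERE name=?", (collection_name,)
        ).fetchone()
        if existing is None:
            with self.conn:
                self.conn.execute(
                    "INSERT INTO collections (name, level, fields) VALUES (?,?,?)",
                    (collection_name, level, json.dumps(value_cols)),
                )
        else:
            if existing["level"] != level:
                raise ImportError_(
                    f"collection {collection_name!r} is {existing['level']}-level, "
                    f"file keys imply {level}-level"
                )
            known = json.loads(existing["fields"])
            merged = known + [c for c in value_cols if c not in known]
            if merged != known:
                with self.conn:
                    self.conn.execute(
                        "UPDATE collections SET fields=? WHERE name=?",
                        (json.dumps(merged), collection_name),
                    )

        report = ScalarImportReport()
        for i, row in df.iterrows():
            try:
                key = self._row_key(level, keymap, row, i)
            except ImportError_ as exc:
                report.failed += 1
                report.errors.append(str(exc))
                continue
            row_new = row_same = row_conflict = 0
            for col in value_cols:
                value = _typed(row[col])
                if value is None:
                    continue
                stored = self.conn.execute(
                    "SELECT value FROM scalar_records WHERE collection=? AND "
                    "project IS ? AND individual IS ? AND timepoint IS ? AND "
                    "asset_id IS ? AND field=?",
                    (collection_name, *key, col),
                ).fetchone()
                if stored is None:
                    with self.conn:
                        self.conn.execute(
                            "INSERT INTO scalar_records (collection, project, individual, "
                            "timepoint, asset_id, field, value) VALUES (?,?,?,?,?,?,?)",
                            (collection_name, *key, col, json.dumps(value)),
                        )
                    row_new += 1
                elif json.loads(stored["value"]) == value:
                    row_same += 1
                else:
                    row_conflict += 1
                    report.errors.append(
                        f"row {i}: conflicting value for {col!r} "
                        f"(stored {stored['value']}, file {value!r})"
                    )
            if row_conflict:
                report.failed += 1
            elif row_new:
                report.new += 1
            else:
                report.unchanged += 1
        return report

    def _row_key(self, level: str, keymap, row, i: int):
        """(project, individual, timepoint, asset_id) with None padding."""
        if level == "asset":
            asset_id = str(row[keymap["asset_id"]]).strip()
            if not self.registry.has_asset(asset_id):
                raise ImportError_(f"row {i}: unknown asset UUID {asset_id}")
            a = self.registry.get_asset(asset_id)
            return (a.project, a.individual, a.timepoint, asset_id)
        project = str(row[keymap["project"]]).strip()
        individual = str(row[keymap["individual"]]).strip()
        if not project or not individual or project.lower() == "nan":
            raise ImportError_(f"row {i}: missing Project/Individual key")
        if level == "timepoint":
            tp = str(row[keymap["timepoint"]]).strip()
            if not tp or tp.lower() == "nan":
                raise ImportError_(f"row {i}: missing TimePoint key")
            return (project, individual, tp, None)
        return (project, individual, None, None)

    # -- query --------------------------------------------------------------

    def query(
        self,
        projects: Sequence[str],
        variables: Sequence[str],
        timepoints: Optional[Sequence[str]] = None,
        asset_mode: str = "strict",
    ) -> pd.DataFrame:
        """Cross-level wide table: one row per (individual, timepoint) in scope.

        ``variables`` are ``collection.field`` names.  Individual-level values
        repeat across the individual's rows; asset-level values join through
        the asset's project/individual/timepoint assignment.  With several
        asset-level records per cell, ``strict`` errors and ``expand`` emits
        one row per asset.
        """
        if not variables:
            raise ConfigurationError("at least one variable must be requested")
        if asset_mode not in ("strict", "expand"):
            raise ConfigurationError(f"unknown asset_mode: {asset_mode!r}")
        inactive = [p for p in projects if p not in self.registry.active_projects]
        if inactive:
            raise ConfigurationError(
                f"project(s) not active in session: {', '.join(inactive)}"
            )
        parsed: list[tuple[str, str, str]] = []  # (collection, field, level)
        for var in variables:
            if "." not in var:
                raise NotFoundError(f"variables are collection.field names, got {var!r}")
            # collection names may themselves contain dots (freesurfer-5.1),
            # so the field is whatever follows the LAST dot
            cname, fieldname = var.rsplit(".", 1)
            coll = self.get_collection(cname)
            if fieldname not in coll.field_names:
                raise NotFoundError(f"no field {fieldname!r} in collection {cname!r}")
            parsed.append((cname, fieldname, coll.level))

        rows: list[dict] = []
        for project in projects:
            labels = self.registry.project_timepoints(project)
            scope = [t for t in labels if timepoints is None or t in timepoints]
            inds = self.registry.individuals(project)
            for site_id in inds["site_id"]:
                for tp in scope:
                    base = {"project": project, "individual": site_id, "timepoint": tp}
                    cells: dict[str, object] = {}
                    expansions: list[dict[str, object]] = []
                    for cname, fieldname, level in parsed:
                        colname = f"{cname}.{fieldname}"
                        if level == "individual":
                            cells[colname] = self._lookup(cname, fieldname, project, site_id, None, None)
                        elif level == "timepoint":
                            cells[colname] = self._lookup(cname, fieldname, project, site_id, tp, None)
                        else:
                            hits = self.conn.execute(
                                "SELECT asset_id, value FROM scalar_records WHERE collection=? "
                                "AND field=? AND project=? AND individual=? AND timepoint=? "
                                "ORDER BY asset_id",
                                (cname, fieldname, project, site_id, tp),
                            ).fetchall()
                            if len(hits) > 1 and asset_mode == "strict":
                                raise ImportError_(
                                    f"{len(hits)} assets carry {colname!r} at "
                                    f"({project}, {site_id}, {tp}); use expand mode"
                                )
                            if len(hits) <= 1:
                                cells[colname] = json.loads(hits[0]["value"]) if hits else None
                            else:
                                expansions = [
                                    {colname: json.loads(h["value"]), "asset": h["asset_id"]}
                                    for h in hits
                                ]
                    if expansions:
                        for ex in expansions:
                            rows.append({**base, **cells, **ex})
                    else:
                        rows.append({**base, **cells})
        columns = ["project", "individual", "timepoint"] + [f"{c}.{f}" for c, f, _ in parsed]
        df = pd.DataFrame(rows)
        for col in columns:
            if col not in df.columns:
                df[col] = None
        ordered = columns + [c for c in df.columns if c not in columns]
        return df[ordered]

    def _lookup(self, collection, fieldname, project, individual, timepoint, asset_id):
        row = self.conn.execute(
            "SELECT value FROM scalar_records WHERE collection=? AND field=? AND "
            "project IS ? AND individual IS ? AND timepoint IS ? AND asset_id IS ?",
            (collection, fieldname, project, individual, timepoint, asset_id),
        ).fetchone()
        return json.loads(row["value"]) if row else None
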