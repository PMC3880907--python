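# Methods

## Identifier derivation

Identifiers are RFC-4122 name-based version-5 UUIDs: the SHA-1 digest of a
fixed namespace UUID concatenated with a canonical key string, truncated to
128 bits with version/variant bits forced. The canonical key string joins
the asset kind and its components with the ASCII unit separator (0x1F);
backslashes and separators occurring *inside* a component are escaped first,
so no two distinct component lists can produce the same key string
(`["x\x1fy"]` and `["x","y"]` differ). Kinds must be registered before use
so a typo cannot silently mint a parallel identifier space.

Design choices that were genuinely open:

- **One fixed, deployment-independent namespace.** Mixing a per-deployment
  value into the namespace would make archives re-identify on migration
  between stores; content identity should be portable, so the namespace is a
  package constant.
- **Activity parameters are part of output keys.** Output identifiers hash
  (name, version, parameters, sorted input ids). Excluding parameters would
  collide two instances of the same tool version run with different
  command-line arguments on the same inputs — e.g. a 1.5 T and a 3 T
  parameterization — which are distinct scientific results. An empty
  parameter string is replaced by a fixed placeholder so the key shape stays
  unambiguous.
- **Input ids are sorted before keying**, making the request order of inputs
  irrelevant to the output identity.

## Archive format

A session folder becomes one `tar.gz` container plus a `<uuid>.json`
sidecar descriptor (JSON Schema shipped in `scanvault/schemas/`). Members
are stored under `series/<SeriesInstanceUID>/<filename>`. The tar stream is
byte-deterministic — members sorted, mtimes zeroed, owners cleared, gzip
timestamp zeroed — so byte-identical input folders produce byte-identical
archives, which in turn makes the container md5 reproducible. The archive
identifier hashes the sorted per-file md5s: identity is carried by the DICOM
bytes alone, not by folder layout, scan order or compression settings.
gzip (DEFLATE) was chosen as the codec because it is universal and the
codec is deliberately *not* identity-bearing; the level is configurable.

The descriptor documents three domains — archive (id, container md5, format
version), series (TE/TR/slice thickness in ms/ms/mm, manufacturer, scanner
serial, software version, field strength in tesla, dates, patient id) and
files (member path, SOP instance UID, per-file md5). DICOM `DA` dates are
normalized to ISO-8601 at build time; missing numeric headers are stored as
absent, never as zero. The invariant Σ series.file_count == file records is
checked at build and at verification. `created` is a wall-clock timestamp
excluded from identity. Unknown descriptor format versions are rejected
rather than guessed. Archives are immutable: extraction reads members,
verification reads members, nothing rewrites the container.

The PHI scan reports watchlisted header attributes found non-empty
(default watchlist: PatientName, OtherPatientIDs, InstitutionAddress,
ReferringPhysicianName). PatientID and PatientBirthDate are deliberately
retained — demographic search filters need the birth date — and the scan
supports, but never replaces, the human anonymization confirmation that
gates project assignment.

## Protocol gating

Constraints are closed numeric intervals (after unit normalization to ms,
mm, T), exact strings (case-insensitive) or allowed sets. No epsilon is
added beyond the interval itself: a protocol that needs tolerance encodes it
in the range. A constrained parameter missing from a series record is a
violation (strict-missing policy). Extraction is all-or-nothing per archive:
every compliant series' image identifier is checked against the registry
*before* the first write, so a collision leaves no partial state. Image
identifiers hash the series' member md5s, which is what makes re-extraction
— from the same archive or from any other archive carrying byte-identical
series — collide mechanically.

## Registry and search

The backing store is a single-file sqlite database (stdlib `sqlite3`) with
the same uniqueness contracts a relational server would provide at
production scale: atomic asset inserts with primary-key uniqueness, and
referential checks of project/individual/timepoint on assignment. Access
control is collapsed to a single-user session with an active-project set;
searches only see assets of activated projects.

Search criteria are conjunctive `(field, op, value)` triples. Asset-level
predicates (project, kind, timepoint, individual, rating) apply directly;
acquisition predicates (acquisition date, manufacturer, scanner serial,
field strength) must hold *together on at least one series* of the asset;
birth-date predicates consult the registered individual first and fall back
to the archived header. Boundary conventions are declared, not inferred:
"born before 1963" means date_of_birth < 1963-01-01 and "after January
2006" means acquisition_date ≥ 2006-02-01 (strictly after the named month);
manufacturer matching is case-insensitive. Dates compare lexicographically
as ISO strings.

Ratings are a fixed 1–5 ordinal with free text. Every rater's history is
preserved; the latest rating per (asset, rater) is flagged current.

## Scalar data

Attachment level is inferred from key columns — Project+Individual
(individual level), +TimePoint (timepoint level), or a single UUID/AssetID
column (asset level); a layout carrying both TimePoint and UUID is rejected
rather than guessed. Values are kept as typed scalars (numeric when
parseable). Re-importing identical rows is a no-op; a conflicting value for
an existing key+field is a row error, never an overwrite. The wide-table
query emits one row per (individual, timepoint) in scope regardless of which
variables are selected; when several assets carry an asset-level variable at
one cell, strict mode errors and expand mode emits one row per asset (the
duplicate-resolution policy was an open design point; making it an explicit
mode keeps the default row-count law intact). Collection names may contain
dots, so `collection.field` variable references split on the *last* dot.

## Activity system

Remote execution (ssh, grid schedulers, cloud VMs) is replaced by two
mechanisms that preserve every observable contract at desk scale: the
external-completion convention (a file named `<output id>.tar.gz` appearing
in the resource's output path completes the job and registers the
collection) and a local subprocess executor for tests and small runs. Jobs
follow pending → staged → running → {completed, failed}; any other
transition raises. The output collection must contain at least one item; on
completion it inherits project/individual/timepoint from the job's first
input and its registry identifier equals the identifier computed at request
time. Instances may declare a stats member name; on completion a simple
`key=value`-per-line stats file inside the collection is parsed into an
asset-level variable collection named `<activity>-<version>`, keyed by the
collection's UUID. How multi-input activities group assets is
instance-configurable (one job per asset, or one job over all requested
assets); no single grouping fits every pipeline.

Provenance chains walk `inputs` links from any asset back to an upload
event, recording the activity triple on each derived link, with cycle
detection as a guard. Accounting aggregates the job ledger (counts per
state, mean staged→completed wall time).

## Synthetic data generator

The generator emulates multi-individual, multi-timepoint structural MRI
studies: valid Part-10 files with controllable headers and 16×16 16-bit
pixel payloads (a gradient plus seeded low-amplitude noise — tiny,
deterministic, and compressible enough to exercise the lossless-compression
path). All UIDs are minted deterministically under the `2.25` UUID-derived
root, so synthetic series can never collide with real studies, and the whole
output is byte-deterministic in the seed. The default study is 4 individuals
× 2 timepoints × 2 series (a T1 MPRAGE-like template, TE 3.2 ms / TR 7.1 ms
/ 1.2 mm, and a T2 FSE-like template, TE 96 ms / TR 4200 ms / 3 mm, both
3 slices at 1.5 T) with birth years spanning 1935–1975 and acquisitions
spanning 2005–2009 — values chosen once as typical for the longitudinal
dementia-imaging studies this kind of system manages. Demographic search
fixtures use 10 individuals, birth years 1950–1975, acquisitions mid-2004 to
mid-2008 and a SIEMENS/GE/Philips fleet cycle so the standard demographic
filter selects a proper, non-empty subset.

Every generated study comes with a truth table (per-series header values,
file counts, per-file md5s, and the intended compliance flag against a
protocol embedded in the spec). Archive, protocol, search and query tests
consult only this table, never ad-hoc header re-reads.

What the generator does *not* emulate: realistic anatomy or k-space,
vendor private tags, multi-frame or compressed transfer syntaxes, missing
or malformed headers beyond what individual tests construct, and
scanner-export folder idiosyncrasies. Passing tests therefore demonstrate
the bookkeeping contracts (identity, integrity, gating, lineage, joins) —
not robustness to the full variability of clinical DICOM exports.

## Problem sizes and numerics

The test suite and the acceptance script run on deliberately small corpora:
a 16-series study (48 files) for round trips, 10,000-key corpora for
collision properties, 10 single-series archives for search, a 3×2 grid for
the join. These sizes were chosen so that every property is exercised
end-to-end in seconds while remaining a faithful miniature of the archival
workflow. md5 is used for content checksums throughout (integrity, not
security); SHA-1 appears only inside the UUID-v5 recipe. Floating-point
acquisition parameters are compared exactly after float conversion —
protocol ranges, not epsilons, express tolerance.

## Known limitations

- Not wire-compatible with any production system's identifier space: the
  hash recipe and the header fields feeding it are this package's own
  documented reconstruction.
- Single-user model; authentication, transport encryption and multi-store
  federation are out of scope.
- No image-format conversion (NIfTI/minc) and no DICOM network services;
  the archive is the unit of storage and exchange.
- The stats-ingestion dialect is a deliberately simple key/value format;
  real pipeline stats files need a parser of their own.
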