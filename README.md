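# scanvault

Desk-scale management of neuroimaging study data: deterministic
content-derived identifiers, immutable checksummed DICOM archives,
acquisition-protocol-gated image extraction, a transactional asset registry
with multi-level scalar data import and cross-level querying, and a versioned
activity/job subsystem with full provenance — plus a seedable synthetic DICOM
generator so everything is testable without any real patient data.

It is aimed at imaging labs and data managers who curate multi-individual,
multi-timepoint MRI studies (raw DICOM sessions, clinical spreadsheets,
pipeline outputs) and need the bookkeeping — identity, integrity, lineage —
to survive data leaving and re-entering the managed store.

## The core idea: deterministic identifiers

Every managed asset (a DICOM archive, an extracted image, a processing
output) carries a 128-bit deterministic UUID computed from what the asset
*is*, not drawn at random:

- **content assets** — an RFC-4122 name-based (v5) UUID over a fixed
  namespace `N` and the canonical key string; for a DICOM archive the key is
  the *sorted list of per-file md5s*, so identity follows bytes, not folder
  layout:

  `id = uuid5(N, "dicomArchive" ⊕ sorted(md5₁ … md5ₙ))`

- **derived assets** — the key is the generating process:

  `id = uuid5(N, "outputCollection" ⊕ name ⊕ version ⊕ parameters ⊕ sorted(input ids))`

Identical content or identical invocations always map to the identical
identifier, on any platform. Accidental re-archival, re-extraction of a
series already extracted, or re-processing with the same tool version
therefore surfaces as an immediate *identifier collision* instead of silent
duplication — and bumping the tool version (5.1 → 5.3) automatically mints
new output identifiers, keeping results of both versions side by side.

Around that core: archives are single `tar.gz` files with a JSON descriptor
documenting three domains (archive, series, files) with md5s at every level;
image extraction is gated on per-project acquisition protocols (closed
numeric ranges for TE/TR/slice thickness/field strength, exact or set-valued
string constraints); scalar spreadsheets import at individual, timepoint or
asset level inferred from their key columns; and every derived asset traces
back through (activity, version, parameters) links to its original upload.

## Worked example

```python
from pathlib import Path
from scanvault import StudySpec, generate_study, create_archive, verify_archive
from scanvault.archive import read_descriptor
from scanvault.synthdicom import session_folders

spec = StudySpec(project="demo", n_individuals=2, timepoints=("M00",), seed=13)
truth = generate_study(spec, Path("data"))
print(len(truth.series), len(truth.files))      # 4 12

session = session_folders(truth)[0]             # one individual's visit
archive, descriptor = create_archive(session, Path("archives"))
print(archive.name)   # 908ac001-08b8-50ab-9aba-078cbc9a813c.tar.gz
desc = read_descriptor(archive)
print([s.description for s in desc.series])     # ['MPRAGE', 'T2-FSE']
print(desc.series[0].echo_time)                 # 3.2
print(verify_archive(archive).passed)           # True
```

The study generator wrote 4 series (2 individuals x 1 visit x 2 series) as
12 Part-10 DICOM files; packaging one session produced an archive whose
filename *is* its content-derived identifier; the descriptor documents both
series with their acquisition parameters (the T1 template's echo time is
3.2 ms), and verification re-checks every member md5 plus the container md5
— `True` means the archive is byte-perfect.

The same operations are available from the shell via the `scanvault`
command (`scanvault archive create|verify|extract|scan|batch`,
`scanvault protocol ...`, `scanvault jobs ...`, `scanvault query ...`;
see `scanvault --help`).

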