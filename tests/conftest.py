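"""Shared fixtures: synthetic studies, archives, and a populated registry.

All fixture data is generated programmatically from seeds; the generator's
truth table is the oracle the tests consult for expected header values,
checksums and compliance flags.
"""

from __future__ import annotations

from pathlib import Path

import pytest

from scanvault.archive import Assignment, create_archive, read_descriptor
from scanvault.registry import Registry
from scanvault.synthdicom import (
    SeriesTemplate,
    StudySpec,
    generate_study,
    session_folders,
)

#: Protocol accepting the default T1 template and rejecting the T2 template.
T1_PROTOCOL_CONSTRAINTS = {
    "echo_time": {"min": 3.0, "max": 3.5},
    "repetition_time": {"min": 6.0, "max": 8.0},
    "slice_thickness": {"min": 1.0, "max": 1.5},
}

DEFAULT_SPEC = StudySpec(
    project="demo",
    n_individuals=4,
    timepoints=("M00", "M12"),
    seed=7,
    protocol=T1_PROTOCOL_CONSTRAINTS,
)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Seeded 4-individual x 2-timepoint x 2-series study with truth table."""
    root = tmp_path_factory.mktemp("study")
    truth = generate_study(DEFAULT_SPEC, root)
    return root, truth


@pytest.fixture(scope="session")
def study_archives(study, tmp_path_factory):
    """One archive + descriptor per session folder of the default study."""
    root, truth = study
    target = tmp_path_factory.mktemp("archives")
    archives = {}
    for folder in session_folders(truth):
        individual = folder.parent.name
        timepoint = folder.name
        a, d = create_archive(
            folder,
            target,
            assignment=Assignment(project="demo", individual=individual, timepoint=timepoint),
        )
        archives[(individual, timepoint)] = (a, d)
    return archives


@pytest.fixture
def registry(tmp_path):
    reg = Registry(tmp_path / "store.sqlite")
    yield reg
    reg.close()


@pytest.fixture
def demo_registry(registry, study, study_archives):
    """Registry with the demo project, its individuals and confirmed archives."""
    _, truth = study
    registry.create_project("demo", ["M00", "M12"])
    registry.activate("demo")
    import pandas as pd

    individuals = truth.series[["individual", "patient_birth_date"]].drop_duplicates()
    registry.register_individuals(
        pd.DataFrame(
            {
                "Project": "demo",
                "SiteId": individuals["individual"],
                "DateOfBirth": individuals["patient_birth_date"],
            }
        )
    )
    for (individual, timepoint), (a, d) in study_archives.items():
        desc = read_descriptor(a)
        desc.anonymized_confirmed = True
        registry.assign_archive(desc, "demo", individual, timepoint, location=str(a))
    return registry
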