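"""Activity instances, job lifecycle, local execution, provenance, accounting."""

import tarfile
from pathlib import Path

import pytest

from scanvault.activity import ActivitySystem, Resource
from scanvault.archive import read_descriptor
from scanvault.errors import (
    CollisionError,
    ConfigurationError,
    NotFoundError,
    StateError,
)
from scanvault.identifiers import DUuid, derive_output_id
from scanvault.protocol import ProtocolDefinition, extract_images
from tests.conftest import T1_PROTOCOL_CONSTRAINTS


@pytest.fixture
def system(demo_registry, study_archives, tmp_path):
    """Activity system with a processing resource and extracted T1 images."""
    sys_ = ActivitySystem(demo_registry)
    (tmp_path / "in").mkdir()
    (tmp_path / "out").mkdir()
    sys_.add_resource(
        Resource("cluster", "localhost", "processing",
                 str(tmp_path / "in"), str(tmp_path / "out"))
    )
    proto = ProtocolDefinition(
        name="t1", project="demo", image_type_label="T1",
        constraints=T1_PROTOCOL_CONSTRAINTS,
    )
    images = []
    for (ind, tp) in [("DEMO001", "M00"), ("DEMO002", "M00"), ("DEMO003", "M00")]:
        archive, _ = study_archives[(ind, tp)]
        result = extract_images(
            read_descriptor(archive), archive, proto, demo_registry, tmp_path / "img"
        )
        images.extend(result.assets)
    return sys_, images, tmp_path


def _instance(sys_, label="fs51", version="5.1", parameters="-all", **kw):
    return sys_.create_instance(
        label, "freesurfer", version, parameters, "cluster", ["demo"], **kw
    )


def _upload(sys_, job, out_dir: Path, extra: dict[str, str] | None = None):
    """Emulate the external upload of a properly named output collection."""
    path = out_dir / f"{job.output_id}.tar.gz"
    files = {"aseg.stats": "hippocampus=4321\n", **(extra or {})}
    scratch = out_dir / f"scratch-{job.output_id}"
    scratch.mkdir()
    with tarfile.open(path, "w:gz") as tar:
        for name, text in files.items():
            p = scratch / name
            p.write_text(text)
            tar.add(p, arcname=name)
    return path


class TestResourcesAndInstances:
    def test_processing_resource_needs_paths(self):
        with pytest.raises(ConfigurationError):
            Resource("bad", "localhost", "processing")
        Resource("box", "host", "dropbox")  # fine without paths

    def test_instance_triple_recorded(self, system):
        sys_, _, _ = system
        inst = _instance(sys_)
        assert (inst.activity_name, inst.version, inst.parameters) == (
            "freesurfer", "5.1", "-all")


class TestRequestJobs:
    def test_three_jobs_staged_with_inputs(self, system):
        sys_, images, tmp = system
        inst = _instance(sys_)
        jobs = sys_.request_jobs(inst, [a.id for a in images])
        assert len(jobs) == 3
        assert len({j.output_id for j in jobs}) == 3
        for job, image in zip(jobs, images):
            staging = tmp / "in" / job.output_id
            assert staging.is_dir()
            assert len(list(staging.iterdir())) == len(image.files) == 3
            assert job.state == "staged"
            expected = derive_output_id(
                "freesurfer", "5.1", "-all", [DUuid.parse(image.id)]
            ).render()
            assert job.output_id == expected

    def test_unauthorized_project_refused(self, system):
        sys_, images, _ = system
        inst = sys_.create_instance(
            "foreign", "freesurfer", "5.1", "-all", "cluster", ["elsewhere"]
        )
        with pytest.raises(ConfigurationError):
            sys_.request_jobs(inst, [images[0].id])

    def test_rerequest_after_completion_collides(self, system):
        sys_, images, tmp = system
        inst = _instance(sys_)
        [job] = sys_.request_jobs(inst, [images[0].id])
        sys_.complete_job(job, _upload(sys_, job, tmp / "out"))
        with pytest.raises(CollisionError):
            sys_.request_jobs(inst, [images[0].id])

    def test_pending_job_also_blocks_rerequest(self, system):
        sys_, images, _ = system
        inst = _instance(sys_)
        sys_.request_jobs(inst, [images[0].id])
        with pytest.raises(CollisionError):
            sys_.request_jobs(inst, [images[0].id])

    def test_group_all_makes_one_job(self, system):
        sys_, images, _ = system
        inst = _instance(sys_, label="multi", parameters="-combine")
        jobs = sys_.request_jobs(inst, [a.id for a in images], group="all")
        assert len(jobs) == 1
        assert sorted(jobs[0].input_ids) == sorted(a.id for a in images)


class TestCompletion:
    def test_named_upload_completes_and_registers(self, system):
        sys_, images, tmp = system
        inst = _instance(sys_)
        [job] = sys_.request_jobs(inst, [images[0].id])
        _upload(sys_, job, tmp / "out")
        registered, rejected = sys_.scan_completions(inst)
        assert [a.id for a in registered] == [job.output_id]
        assert rejected == []
        asset = sys_.registry.get_asset(job.output_id)
        assert asset.kind == "outputCollection"
        assert (asset.individual, asset.timepoint) == (images[0].individual, images[0].timepoint)
        assert sys_.get_job(job.output_id).state == "completed"

    def test_misnamed_upload_rejected_job_unchanged(self, system):
        sys_, images, tmp = system
        inst = _instance(sys_)
        [job] = sys_.request_jobs(inst, [images[0].id])
        stray = tmp / "out" / "results_final.tar.gz"
        with tarfile.open(stray, "w:gz") as tar:
            pass
        registered, rejected = sys_.scan_completions(inst)
        assert registered == [] and rejected == ["results_final.tar.gz"]
        assert sys_.get_job(job.output_id).state == "staged"

    def test_duplicate_completion_is_error(self, system):
        sys_, images, tmp = system
        inst = _instance(sys_)
        [job] = sys_.request_jobs(inst, [images[0].id])
        path = _upload(sys_, job, tmp / "out")
        sys_.complete_job(job, path)
        with pytest.raises(StateError):
            sys_.complete_job(job.output_id, path)

    def test_identifier_stable_through_lifecycle(self, system):
        """The registry id of the collection equals the id computed at request."""
        sys_, images, tmp = system
        inst = _instance(sys_)
        [job] = sys_.request_jobs(inst, [images[1].id])
        requested_id = job.output_id
        asset = sys_.complete_job(job, _upload(sys_, job, tmp / "out"))
        assert asset.id == requested_id

    def test_stats_member_ingested_as_asset_level_collection(self, system):
        sys_, images, tmp = system
        inst = _instance(sys_, label="fs51s", stats_member="aseg.stats")
        [job] = sys_.request_jobs(inst, [images[2].id])
        sys_.complete_job(job, _upload(sys_, job, tmp / "out"))
        from scanvault.scalar import ScalarStore

        scalar = ScalarStore(sys_.registry)
        coll = scalar.get_collection("freesurfer-5.1")
        assert coll.level == "asset"
        df = scalar.query(["demo"], ["freesurfer-5.1.hippocampus"])
        assert 4321 in set(df["freesurfer-5.1.hippocampus"].dropna())


class TestRunLocal:
    def test_happy_path_produces_collection(self, system):
        sys_, images, tmp = system
        inst = _instance(sys_)
        [job] = sys_.request_jobs(inst, [images[0].id])
        done = sys_.run_local(job, "echo volume=1234 > {work_dir}/aseg.stats")
        assert done.state == "completed"
        assert sys_.registry.has_asset(done.output_id)
        assert done.accounting.get("exit_code") == 0

    def test_failing_command_records_exit_code(self, system):
        sys_, images, _ = system
        inst = _instance(sys_)
        [job] = sys_.request_jobs(inst, [images[0].id])
        done = sys_.run_local(job, "false")
        assert done.state == "failed"
        assert done.accounting["exit_code"] == 1
        assert not sys_.registry.has_asset(done.output_id)

    def test_ledger_in_submission_order(self, system):
        sys_, images, tmp = system
        inst = _instance(sys_)
        jobs = sys_.request_jobs(inst, [images[0].id, images[1].id])
        for j in jobs:
            sys_.run_local(j, "echo ok > {work_dir}/r.txt")
        ledger = sys_.ledger()
        assert list(ledger["output_id"]) == [j.output_id for j in jobs]


class TestProvenance:
    def test_chain_collection_image_archive(self, system):
        sys_, images, tmp = system
        inst = _instance(sys_)
        [job] = sys_.request_jobs(inst, [images[0].id])
        sys_.complete_job(job, _upload(sys_, job, tmp / "out"))
        chain = sys_.trace(job.output_id)
        assert [link["kind"] for link in chain] == ["outputCollection", "image", "dicomArchive"]
        assert chain[0]["activity"] == {
            "name": "freesurfer", "version": "5.1", "parameters": "-all"}
        assert chain[-1]["via"] == "upload"

    def test_upload_chain_length_one(self, system):
        sys_, _, _ = system
        archive = sys_.registry.assets_of("demo", "dicomArchive")[0]
        chain = sys_.trace(archive.id)
        assert len(chain) == 1 and chain[0]["via"] == "upload"

    def test_two_versions_two_chains_shared_suffix(self, system):
        sys_, images, tmp = system
        v51 = _instance(sys_, label="v51", version="5.1")
        v53 = _instance(sys_, label="v53", version="5.3")
        [j51] = sys_.request_jobs(v51, [images[1].id])
        [j53] = sys_.request_jobs(v53, [images[1].id])
        assert j51.output_id != j53.output_id
        sys_.complete_job(j51, _upload(sys_, j51, tmp / "out"))
        sys_.complete_job(j53, _upload(sys_, j53, tmp / "out"))
        c51, c53 = sys_.trace(j51.output_id), sys_.trace(j53.output_id)
        assert c51[0]["asset"] != c53[0]["asset"]
        assert [l["asset"] for l in c51[1:]] == [l["asset"] for l in c53[1:]]

    def test_unknown_asset_rejected(self, system):
        sys_, _, _ = system
        with pytest.raises(NotFoundError):
            sys_.trace("00000000-0000-0000-0000-000000000000")

    def test_every_derived_asset_reaches_an_upload(self, system):
        """Traceability closure over everything registered in the fixture."""
        sys_, images, tmp = system
        inst = _instance(sys_)
        jobs = sys_.request_jobs(inst, [a.id for a in images])
        for j in jobs:
            sys_.complete_job(j, _upload(sys_, j, tmp / "out"))
        for row in sys_.registry.conn.execute("SELECT id FROM assets"):
            chain = sys_.trace(row["id"])
            assert chain[-1]["via"] == "upload"


class TestAccounting:
    def test_empty_ledger_all_zero(self, system):
        sys_, _, _ = system
        summary = sys_.accounting_summary()
        assert summary["total"] == 0
        assert all(v == 0 for v in summary["by_state"].values())

    def test_state_counts(self, system):
        sys_, images, tmp = system
        inst = _instance(sys_)
        jobs = sys_.request_jobs(inst, [a.id for a in images])
        sys_.complete_job(jobs[0], _upload(sys_, jobs[0], tmp / "out"))
        sys_.run_local(jobs[1], "false")
        summary = sys_.accounting_summary()
        assert summary["total"] == 3
        assert summary["by_state"]["completed"] == 1
        assert summary["by_state"]["failed"] == 1
        assert summary["by_state"]["staged"] == 1

    def test_filters(self, system):
        sys_, images, tmp = system
        inst = _instance(sys_)
        sys_.request_jobs(inst, [images[0].id])
        assert sys_.accounting_summary(project="demo")["total"] == 1
        assert sys_.accounting_summary(project="other")["total"] == 0
        assert sys_.accounting_summary(instance="fs51")["total"] == 1
        assert sys_.accounting_summary(instance="nope")["total"] == 0


class TestStateMachine:
    def test_no_transition_outside_graph(self, system):
        sys_, images, tmp = system
        inst = _instance(sys_)
        [job] = sys_.request_jobs(inst, [images[0].id])
        with pytest.raises(StateError):
            sys_._set_state(job, "pending")
        path = _upload(sys_, job, tmp / "out")
        sys_.complete_job(job, path)
        fresh = sys_.get_job(job.output_id)
        for target in ("running", "failed", "staged"):
            with pytest.raises(StateError):
                sys_._set_state(fresh, target)
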