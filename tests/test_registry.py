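"""Registry: projects, individuals, assets, search, naming, ratings."""

import pandas as pd
import pytest

from scanvault.archive import read_descriptor
from scanvault.errors import (
    AnonymizationError,
    CollisionError,
    ConfigurationError,
    NotFoundError,
)
from scanvault.identifiers import AssetKey, derive_id
from scanvault.registry import Asset, Registry
from scanvault.synthdicom import StudySpec, generate_study, session_folders

EXAMPLE_ID = "6d0b1c00-2a11-4aaa-a337-3ba06e9ee2ef"


def _asset(i: int, project="demo", individual="DEMO001", timepoint="M00") -> Asset:
    return Asset(
        id=derive_id(AssetKey("file", [f"reg-test-{i}"])).render(),
        kind="file",
        project=project,
        individual=individual,
        timepoint=timepoint,
    )


class TestProjectsAndIndividuals:
    def test_duplicate_project_collides(self, registry):
        registry.create_project("demo", ["M00"])
        with pytest.raises(CollisionError):
            registry.create_project("demo", ["M00"])

    def test_duplicate_timepoint_labels_rejected(self, registry):
        with pytest.raises(ConfigurationError):
            registry.create_project("p", ["M00", "M00"])

    def test_individual_list_import_and_idempotence(self, registry, tmp_path):
        registry.create_project("adni", ["M00"])
        df = pd.DataFrame(
            {
                "Project": ["adni"] * 4,
                "SiteId": ["S001", "S002", "S003", "S004"],
                "Gender": ["F", "M", "F", "M"],
                "DateOfBirth": ["1950-01-02", "1961-07-30", "1940-11-11", "1970-03-03"],
            }
        )
        path = tmp_path / "list.csv"
        df.to_csv(path, index=False)
        report = registry.register_individuals(path, "adni")
        assert report.new == 4 and not report.errors
        again = registry.register_individuals(path, "adni")
        assert again.new == 0 and again.existing == 4

    def test_filename_convention_routes_project(self, registry, tmp_path):
        registry.create_project("adni", ["M00"])
        path = tmp_path / "adni.individuals.list.csv"
        pd.DataFrame({"SiteId": ["S010", "S011"]}).to_csv(path, index=False)
        report = registry.register_individuals(path)
        assert report.new == 2
        assert registry.has_individual("adni", "S010")

    def test_missing_site_id_is_row_error(self, registry, tmp_path):
        registry.create_project("adni", ["M00"])
        path = tmp_path / "adni.individuals.list.csv"
        pd.DataFrame({"SiteId": ["S020", ""]}).to_csv(path, index=False)
        report = registry.register_individuals(path)
        assert report.new == 1 and len(report.errors) == 1


class TestAssets:
    def test_register_and_fetch(self, registry):
        registry.create_project("demo", ["M00"])
        a = _asset(1)
        registry.register_asset(a)
        assert registry.get_asset(a.id).kind == "file"

    def test_duplicate_id_collides_without_overwrite(self, registry):
        a = _asset(2)
        registry.register_asset(a)
        clone = _asset(2, timepoint="M12")
        with pytest.raises(CollisionError):
            registry.register_asset(clone)
        assert registry.get_asset(a.id).timepoint == "M00"

    def test_one_component_difference_distinct(self, registry):
        registry.register_asset(_asset(3))
        registry.register_asset(_asset(4))
        assert len(registry.assets_of("demo")) == 2

    def test_uniqueness_survives_duplicate_insert_fuzz(self, registry):
        """1,000 duplicate insert attempts never break store-wide uniqueness."""
        a = _asset(5)
        registry.register_asset(a)
        for _ in range(1000):
            with pytest.raises(CollisionError):
                registry.register_asset(a)
        rows = registry.conn.execute(
            "SELECT COUNT(*) AS n FROM assets WHERE id=?", (a.id,)
        ).fetchone()
        assert rows["n"] == 1


class TestAssignArchive:
    def test_unconfirmed_archive_refused(self, registry, study_archives):
        registry.create_project("demo", ["M00", "M12"])
        archive, _ = study_archives[("DEMO001", "M00")]
        desc = read_descriptor(archive)
        assert not desc.anonymized_confirmed
        with pytest.raises(AnonymizationError):
            registry.assign_archive(desc, "demo", "DEMO001", "M00")

    def test_confirmed_archive_listed(self, demo_registry):
        archives = demo_registry.assets_of("demo", "dicomArchive")
        assert len(archives) == 8

    def test_unknown_timepoint_refused(self, registry, study_archives):
        registry.create_project("demo", ["M00", "M12"])
        registry.register_individuals(
            pd.DataFrame({"Project": ["demo"], "SiteId": ["DEMO001"]})
        )
        archive, _ = study_archives[("DEMO001", "M00")]
        desc = read_descriptor(archive)
        desc.anonymized_confirmed = True
        with pytest.raises(NotFoundError):
            registry.assign_archive(desc, "demo", "DEMO001", "M99")


class TestSearch:
    @pytest.fixture
    def fleet_registry(self, tmp_path_factory):
        """10 one-series archives with a mixed fleet and spread demographics."""
        root = tmp_path_factory.mktemp("fleet")
        spec = StudySpec(
            project="fleet",
            n_individuals=10,
            timepoints=("M00",),
            templates=(StudySpec().templates[0],),
            birth_year_span=(1950, 1975),
            acquisition_span=("2004-06-01", "2008-06-01"),
            manufacturer_cycle=("SIEMENS", "GE MEDICAL SYSTEMS", "Philips"),
            seed=21,
        )
        truth = generate_study(spec, root / "data")
        reg = Registry(root / "store.sqlite")
        reg.create_project("fleet", ["M00"])
        reg.register_individuals(
            pd.DataFrame(
                {
                    "Project": "fleet",
                    "SiteId": truth.series["individual"].unique(),
                    "DateOfBirth": truth.series.drop_duplicates("individual")["patient_birth_date"].values,
                }
            )
        )
        from scanvault.archive import Assignment, create_archive

        for folder in session_folders(truth):
            a, d = create_archive(folder, root / "archives")
            desc = read_descriptor(a)
            desc.anonymized_confirmed = True
            reg.assign_archive(desc, "fleet", folder.parent.name, folder.name)
        reg.activate("fleet")
        return reg, truth

    FIG1 = [("dob", "lt", "1963-01-01"), ("acq_date", "ge", "2006-02-01"),
            ("manufacturer", "ne", "SIEMENS")]

    def test_demographic_scanner_filter_matches_truth_table(self, fleet_registry):
        """Born before 1963, scanned after January 2006, non-Siemens scanner."""
        reg, truth = fleet_registry
        expected = set(
            truth.series[
                (truth.series["patient_birth_date"] < "1963-01-01")
                & (truth.series["acquisition_date"] >= "2006-02-01")
                & (truth.series["manufacturer"].str.upper() != "SIEMENS")
            ]["individual"]
        )
        hits = reg.search_assets(self.FIG1)
        assert {a.individual for a in hits} == expected
        assert 0 < len(hits) < 10  # the filter is a proper, non-empty subset

    def test_manufacturer_match_case_insensitive(self, fleet_registry):
        reg, truth = fleet_registry
        lower = reg.search_assets([("manufacturer", "eq", "siemens")])
        upper = reg.search_assets([("manufacturer", "eq", "SIEMENS")])
        assert {a.id for a in lower} == {a.id for a in upper} != set()

    def test_empty_criteria_returns_all_active(self, fleet_registry):
        reg, _ = fleet_registry
        assert len(reg.search_assets([])) == 10

    def test_deactivated_project_invisible(self, fleet_registry):
        reg, _ = fleet_registry
        reg.deactivate("fleet")
        assert reg.search_assets([]) == []
        assert reg.search_assets(self.FIG1) == []

    def test_unknown_field_rejected(self, fleet_registry):
        reg, _ = fleet_registry
        with pytest.raises(ConfigurationError):
            reg.search_assets([("shoe_size", "eq", 42)])


class TestDownloadNaming:
    def test_plain_and_typed_literal_forms(self):
        reg = Registry()
        asset = Asset(id=EXAMPLE_ID, kind="dicomArchive", project="p",
                      individual="i", timepoint="t")
        assert reg.render_download_name(asset, "plain") == f"{EXAMPLE_ID}.tar"
        assert reg.render_download_name(asset, "typed") == f"dicomArchive.{EXAMPLE_ID}.tar"

    def test_enriched_template_substitution(self, demo_registry, study):
        _, truth = study
        row = truth.series.iloc[0]
        archive = demo_registry.assets_of("demo", "dicomArchive")[0]
        name = demo_registry.render_download_name(
            archive, "enriched", template="DCM.<AcquisitionDate>.<PatientID>"
        )
        series = demo_registry.conn.execute(
            "SELECT * FROM archive_series WHERE asset_id=? ORDER BY series_uid LIMIT 1",
            (archive.id,),
        ).fetchone()
        compact = series["acquisition_date"].replace("-", "")
        assert name == f"DCM.{compact}.{series['patient_id']}.{archive.id}.tar"

    def test_unavailable_token_is_error(self):
        reg = Registry()
        asset = Asset(id=EXAMPLE_ID, kind="image", project="p", individual="i", timepoint="t")
        with pytest.raises(NotFoundError):
            reg.render_download_name(asset, "enriched", template="X.<PatientID>")
        with pytest.raises(ConfigurationError):
            reg.render_download_name(asset, "enriched", template="X.<NoSuchToken>")


class TestRatings:
    def test_two_raters_two_current(self, registry):
        a = _asset(10)
        registry.register_asset(a)
        registry.record_rating(a.id, "alice", 4)
        registry.record_rating(a.id, "bob", 2, note="motion artifact")
        current = registry.ratings(a.id)
        assert {r.rater for r in current} == {"alice", "bob"}

    def test_rerating_keeps_history(self, registry):
        a = _asset(11)
        registry.register_asset(a)
        registry.record_rating(a.id, "alice", 4)
        registry.record_rating(a.id, "alice", 2)
        current = registry.ratings(a.id)
        assert len(current) == 1 and current[0].score == 2
        assert len(registry.ratings(a.id, current_only=False)) == 2

    def test_out_of_range_scores_rejected(self, registry):
        a = _asset(12)
        registry.register_asset(a)
        for bad in (0, 6, 3.5):
            with pytest.raises(ConfigurationError):
                registry.record_rating(a.id, "alice", bad)
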