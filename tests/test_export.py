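"""Export: codebook, visit tables, aggregated wide table, deterministic bundle."""

import csv
import io
import json
import zipfile
from datetime import datetime, timezone

import pytest

from edcforge import (
    DemoConfig,
    Submission,
    build_codebook,
    export_aggregated,
    export_visit_table,
    generate_demo_metadata,
    import_metadata,
    simulate_entries,
    write_bundle,
)
from edcforge.errors import UnknownVisit
from edcforge.export import export_participant_table
from edcforge.metadata import metadata_manifest, metadata_tables, write_zip

from conftest import complete_baseline

TS = datetime(2024, 6, 1, 12, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="module")
def simulated():
    cfg = DemoConfig(seed=5, n_widgets=24, n_visits=2, n_participants=15,
                     missingness=0.15)
    metadata = generate_demo_metadata(cfg)
    return metadata, simulate_entries(metadata, cfg)


class TestCodebook:
    def test_one_row_per_widget(self, small_metadata):
        codebook = build_codebook(small_metadata)
        assert len(codebook) == len(small_metadata.widgets)
        assert set(codebook["variable_id"]) == {w.variable_id
                                                for w in small_metadata.widgets}

    @pytest.mark.parametrize("seed", [0, 6, 42])
    def test_row_count_matches_generated_widget_count(self, seed):
        metadata = generate_demo_metadata(DemoConfig(seed=seed, n_widgets=33))
        assert len(build_codebook(metadata)) == 33

    def test_choices_serialization(self, small_metadata):
        codebook = build_codebook(small_metadata).set_index("variable_id")
        assert codebook.loc["sex", "choices_serialized"] == "f=Female|m=Male"
        assert codebook.loc["pregnant", "condition_serialized"] == 'sex eq "f"'
        assert codebook.loc["age", "units"] == "years"

    def test_every_data_column_resolves_to_codebook_row(self, simulated):
        metadata, result = simulated
        codebook_vars = set(build_codebook(metadata)["variable_id"])
        for visit in metadata.visits:
            table = export_visit_table(result.study.store, metadata, visit.visit_id)
            assert set(table.columns) - {"pid", "visit_instance"} <= codebook_vars


class TestVisitTables:
    def test_empty_store_gives_header_only(self, deployed_study):
        table = export_visit_table(deployed_study.store, deployed_study.metadata,
                                   "baseline")
        assert len(table) == 0
        assert list(table.columns) == ["pid", "visit_instance", "age", "sex",
                                       "pregnant", "dx"]

    def test_one_row_per_complete_baseline(self, deployed_study):
        for _ in range(10):
            pid = deployed_study.include_participant("muc", "t").pid
            deployed_study.record_submission(
                complete_baseline(deployed_study, pid), actor="t"
            )
        table = export_visit_table(deployed_study.store, deployed_study.metadata,
                                   "baseline")
        assert len(table) == 10
        assert list(table["age"].unique()) == ["34"]

    def test_unknown_visit_rejected(self, deployed_study):
        with pytest.raises(UnknownVisit):
            export_visit_table(deployed_study.store, deployed_study.metadata, "ghost")

    def test_cells_equal_store_heads(self, simulated):
        """Full-scan oracle: every exported cell is the audit head value."""
        metadata, result = simulated
        store = result.study.store
        heads = {}
        for row in store.all_rows():  # brute force head per record
            cur = heads.get(row.record_id)
            if cur is None or row.version_no > cur.version_no:
                heads[row.record_id] = row
        expected = {}
        for row in heads.values():
            if row.entity != "visit_data" or row.deleted:
                continue
            p = row.payload
            expected[(p["pid"], p["visit_id"], p["visit_instance"])] = p["values"]
        seen = set()
        for visit in metadata.visits:
            table = export_visit_table(store, metadata, visit.visit_id)
            for _, record in table.iterrows():
                key = (record["pid"], visit.visit_id, record["visit_instance"])
                seen.add(key)
                for var in table.columns[2:]:
                    assert record[var] == expected[key].get(var, "")
        assert seen == set(expected)


class TestAggregated:
    def test_column_naming_non_repeating_and_repeating(self, deployed_study):
        pid = deployed_study.include_participant("muc", "t").pid
        deployed_study.record_submission(
            complete_baseline(deployed_study, pid), actor="t")
        for instance in (1, 2):
            deployed_study.record_submission(
                Submission(pid, "followup", instance,
                           {"weight": f"7{instance}.0", "seen_at": "09:00",
                            "visit_date": "2024-03-01"}, complete_flag=True),
                actor="t")
        deployed_study.record_submission(
            Submission(pid, None, 1, {"notes": "ok"}, complete_flag=True), actor="t")
        wide = export_aggregated(deployed_study.store, deployed_study.metadata)
        assert "baseline.age" in wide.columns
        assert "followup.1.weight" in wide.columns  # repeating visit: indexed
        assert "followup.2.weight" in wide.columns
        assert "participant.notes" in wide.columns
        row = wide.iloc[0]
        assert row["followup.1.weight"] == "71.0"
        assert row["followup.2.weight"] == "72.0"
        assert row["participant.notes"] == "ok"

    def test_one_row_per_participant(self, simulated):
        metadata, result = simulated
        wide = export_aggregated(result.study.store, metadata)
        assert list(wide["pid"]) == sorted(
            p.pid for p in result.study.participants()
        )

    def test_unpivot_matches_visit_tables(self, simulated):
        """Pivot/unpivot oracle: wide cells equal the per-visit table cells."""
        metadata, result = simulated
        store = result.study.store
        wide = export_aggregated(store, metadata).set_index("pid")
        # independent chronological rank: order each participant's surviving
        # records of a repeating visit by the timestamp of their first version
        first_ts = {}
        for row in store.all_rows():
            first_ts.setdefault(row.record_id, row.timestamp)
        surviving = {
            (r.payload["pid"], r.payload["visit_id"], r.payload["visit_instance"]):
            first_ts[r.record_id]
            for r in store.query_current(entity="visit_data")
            if r.payload["visit_id"]
        }
        rank = {}
        for visit in metadata.visits:
            per_pid = {}
            for (pid, vid, instance), ts in surviving.items():
                if vid == visit.visit_id:
                    per_pid.setdefault(pid, []).append((ts, instance))
            for pid, items in per_pid.items():
                for k, (_, instance) in enumerate(sorted(items), start=1):
                    rank[(pid, visit.visit_id, instance)] = k
        for visit in metadata.visits:
            table = export_visit_table(store, metadata, visit.visit_id)
            for _, record in table.iterrows():
                pid = record["pid"]
                for var in table.columns[2:]:
                    if visit.repeating:
                        k = rank[(pid, visit.visit_id, record["visit_instance"])]
                        column = f"{visit.visit_id}.{k}.{var}"
                    else:
                        column = f"{visit.visit_id}.{var}"
                    assert wide.loc[pid, column] == record[var]


class TestBundle:
    def test_bundle_layout(self, simulated):
        metadata, result = simulated
        bundle = write_bundle(result.study.store, metadata, timestamp=TS)
        with zipfile.ZipFile(io.BytesIO(bundle)) as zf:
            names = set(zf.namelist())
        assert {"codebook.csv", "audit/audit_log.csv", "manifest.json",
                "data/participants.csv", "data/aggregated_wide.csv",
                "data/baseline.csv", "metadata/widgets.csv",
                "metadata/manifest.json"} <= names
        assert len(names) >= 6

    def test_bundle_bytes_deterministic(self, simulated):
        metadata, result = simulated
        first = write_bundle(result.study.store, metadata, timestamp=TS)
        second = write_bundle(result.study.store, metadata, timestamp=TS)
        assert first == second

    def test_manifest_row_counts_match_members(self, simulated):
        metadata, result = simulated
        bundle = write_bundle(result.study.store, metadata, timestamp=TS)
        with zipfile.ZipFile(io.BytesIO(bundle)) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            for name, count in manifest["members"].items():
                if not name.endswith(".csv"):
                    continue
                rows = list(csv.reader(io.StringIO(zf.read(name).decode("utf-8"))))
                assert len(rows) - 1 == count, name

    def test_metadata_subtree_round_trips(self, simulated):
        metadata, result = simulated
        bundle = write_bundle(result.study.store, metadata, timestamp=TS)
        with zipfile.ZipFile(io.BytesIO(bundle)) as zf:
            members = {
                name[len("metadata/"):]: zf.read(name)
                for name in zf.namelist() if name.startswith("metadata/")
            }
        assert import_metadata(write_zip(members, TS)) == metadata

    def test_audit_log_lists_every_row(self, simulated):
        metadata, result = simulated
        bundle = write_bundle(result.study.store, metadata, timestamp=TS)
        with zipfile.ZipFile(io.BytesIO(bundle)) as zf:
            log_rows = list(csv.DictReader(
                io.StringIO(zf.read("audit/audit_log.csv").decode("utf-8"))))
        assert len(log_rows) == result.study.store.row_count()
        deleted_ops = sum(1 for op in result.log if op["op"] == "delete")
        assert sum(1 for r in log_rows if r["deleted"] == "true") == deleted_ops

    def test_deleted_records_absent_from_data_tables(self, simulated):
        metadata, result = simulated
        store = result.study.store
        deleted_keys = {
            (op["pid"], op["visit"], op["instance"])
            for op in result.log if op["op"] == "delete"
        }
        assert deleted_keys  # the scenario includes deletions
        for visit in metadata.visits:
            table = export_visit_table(store, metadata, visit.visit_id)
            for _, record in table.iterrows():
                key = (record["pid"], visit.visit_id, record["visit_instance"])
                assert key not in deleted_keys

    def test_participant_table(self, simulated):
        metadata, result = simulated
        table = export_participant_table(result.study.store, metadata)
        assert list(table.columns)[0] == "pid"
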