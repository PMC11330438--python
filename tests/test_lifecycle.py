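"""Lifecycle: deployment gate, frozen visits, inclusion, documentation status."""

import random
from dataclasses import replace

import pytest

from edcforge import SimClock, Study, Submission
from edcforge.errors import (
    AlreadyDeployed,
    InvalidMetadata,
    NarrowingChange,
    NotAdmin,
    NotDeployed,
    UnknownParticipant,
    VisitFrozen,
)
from edcforge.metadata import VisitDefinition, WidgetDefinition

from conftest import complete_baseline


def _editor_study(metadata):
    return Study.create(metadata, clock=SimClock(step_ms=500), rng=random.Random(1))


class TestDeploymentGate:
    def test_activation_purges_preview_entries(self, small_metadata):
        study = _editor_study(small_metadata)
        row, report = study.record_submission(
            complete_baseline(study, "preview-1"), actor="tester"
        )
        assert report.ok and study.preview_store.row_count() == 1
        permanent_before = study.store.row_count()
        study.activate_deployment("tester")
        assert study.preview_store.row_count() == 0
        assert study.store.row_count() == permanent_before

    def test_editor_entries_never_reach_permanent_store(self, small_metadata):
        """No permanent visit_data row exists for a study never deployed."""
        rng = random.Random(2)
        study = _editor_study(small_metadata)
        for i in range(30):
            if rng.random() < 0.5:
                study.record_submission(
                    complete_baseline(study, f"p{i}", age=str(rng.randint(1, 99))),
                    actor="tester",
                )
            else:
                study.save_metadata(study.metadata, actor="tester")
        assert all(r.entity != "visit_data" for r in study.store.all_rows())

    def test_activation_requires_valid_metadata(self, small_metadata):
        broken = replace(
            small_metadata,
            widgets=small_metadata.widgets
            + (WidgetDefinition("bad", "slider", "Bad"),),
        )
        study = Study.create(small_metadata)
        study.metadata = broken
        with pytest.raises(InvalidMetadata):
            study.activate_deployment("tester")

    def test_double_activation_rejected(self, deployed_study):
        with pytest.raises(AlreadyDeployed):
            deployed_study.activate_deployment("tester")


class TestFrozenVisits:
    def test_visit_edits_after_activation_rejected(self, deployed_study):
        deployed_study.revert_to_editor("root", role="admin")
        changed = tuple(
            replace(v, title="Renamed") if v.visit_id == "baseline" else v
            for v in deployed_study.metadata.visits
        )
        with pytest.raises(VisitFrozen):
            deployed_study.save_metadata(
                replace(deployed_study.metadata, visits=changed), actor="tester"
            )

    def test_visit_removal_after_activation_rejected(self, deployed_study):
        deployed_study.revert_to_editor("root", role="admin")
        remaining = tuple(
            v for v in deployed_study.metadata.visits if v.visit_id != "followup"
        )
        with pytest.raises(VisitFrozen):
            deployed_study.save_metadata(
                replace(deployed_study.metadata, visits=remaining), actor="tester"
            )

    def test_narrowing_widget_changes_rejected(self, deployed_study):
        deployed_study.revert_to_editor("root", role="admin")
        md = deployed_study.metadata
        without_sex = replace(
            md, widgets=tuple(w for w in md.widgets if w.variable_id != "sex")
        )
        with pytest.raises(NarrowingChange):
            deployed_study.save_metadata(without_sex, actor="tester")
        narrowed = replace(
            md,
            widgets=tuple(
                replace(w, choices=(("f", "Female"),)) if w.variable_id == "sex" else w
                for w in md.widgets
            ),
        )
        with pytest.raises(NarrowingChange):
            deployed_study.save_metadata(narrowed, actor="tester")

    def test_additive_changes_allowed_and_new_visits_editable(self, deployed_study):
        deployed_study.revert_to_editor("root", role="admin")
        md = deployed_study.metadata
        extra_visit = VisitDefinition("extension", "Extension", 2)
        extra_widget = WidgetDefinition("qol", "integer", "Quality of life",
                                        visit_ids=("extension",))
        deployed_study.save_metadata(
            replace(md, visits=md.visits + (extra_visit,),
                    widgets=md.widgets + (extra_widget,)),
            actor="tester",
        )
        # the new visit is still editable before the next activation
        md2 = deployed_study.metadata
        renamed = tuple(
            replace(v, title="Ext") if v.visit_id == "extension" else v
            for v in md2.visits
        )
        deployed_study.save_metadata(replace(md2, visits=renamed), actor="tester")
        deployed_study.activate_deployment("tester")
        # ... and frozen afterwards
        assert "extension" in deployed_study.frozen_visits

    def test_frozen_set_preserved_across_excursions(self, deployed_study):
        first_frozen = set(deployed_study.frozen_visits)
        deployed_study.revert_to_editor("root", role="admin")
        deployed_study.activate_deployment("tester")
        assert first_frozen <= deployed_study.frozen_visits


class TestReversal:
    def test_admin_reversal_keeps_clinical_rows(self, deployed_study):
        deployed_study.include_participant("muc", "tester")
        deployed_study.record_submission(
            complete_baseline(deployed_study, "muc-0001"), actor="tester"
        )
        rows_before = deployed_study.store.row_count()
        deployed_study.revert_to_editor("root", role="admin")
        assert deployed_study.mode == "editor"
        assert deployed_study.store.row_count() == rows_before

    def test_non_admin_reversal_rejected(self, deployed_study):
        with pytest.raises(NotAdmin):
            deployed_study.revert_to_editor("user", role="user")
        assert deployed_study.mode == "deployment"

    def test_reversal_requires_deployment(self, small_metadata):
        study = Study.create(small_metadata)
        with pytest.raises(NotDeployed):
            study.revert_to_editor("root", role="admin")


class TestInclusion:
    def test_pid_scheme(self, deployed_study):
        assert deployed_study.include_participant("muc", "t").pid == "muc-0001"
        assert deployed_study.include_participant("muc", "t").pid == "muc-0002"
        assert deployed_study.include_participant("ber", "t").pid == "ber-0001"

    def test_mass_inclusion_yields_unique_pids(self, deployed_study):
        pids = [
            deployed_study.include_participant(f"s{i % 5}", "t").pid
            for i in range(1700)
        ]
        assert len(set(pids)) == 1700
        assert len(deployed_study.participants()) == 1700

    def test_inclusion_requires_deployment(self, small_metadata):
        study = Study.create(small_metadata)
        with pytest.raises(NotDeployed):
            study.include_participant("muc", "t")

    def test_pid_exists_contract(self, deployed_study):
        pid = deployed_study.include_participant("muc", "t").pid
        assert deployed_study.pid_exists(pid)
        assert not deployed_study.pid_exists("muc-9999")
        deployed_study.remove_participant(pid, "t")
        assert not deployed_study.pid_exists(pid)

    def test_pid_sequence_survives_reopen(self, small_metadata, tmp_path):
        path = str(tmp_path / "study.db")
        study = Study.create(small_metadata, path=path, clock=SimClock())
        study.activate_deployment("t")
        study.include_participant("muc", "t")
        study.store.close()
        reopened = Study.open(path, clock=SimClock(step_ms=99))
        assert reopened.mode == "deployment"
        assert reopened.include_participant("muc", "t").pid == "muc-0002"


class TestDocumentationStatus:
    def test_no_data_means_all_visits_empty(self, deployed_study):
        pid = deployed_study.include_participant("muc", "t").pid
        doc = deployed_study.documentation_status(pid)
        assert doc.of("baseline") == "empty" and doc.of("followup") == "empty"

    def test_complete_submission_marks_visit_complete(self, deployed_study):
        pid = deployed_study.include_participant("muc", "t").pid
        row, report = deployed_study.record_submission(
            complete_baseline(deployed_study, pid), actor="t"
        )
        assert report.ok and row is not None
        doc = deployed_study.documentation_status(pid)
        assert doc.of("baseline") == "complete" and doc.of("followup") == "empty"

    def test_partial_save_marks_visit_partial(self, deployed_study):
        pid = deployed_study.include_participant("muc", "t").pid
        sub = Submission(pid, "baseline", 1, {"age": "40"}, complete_flag=False)
        row, report = deployed_study.record_submission(sub, actor="t")
        assert report.ok
        assert deployed_study.documentation_status(pid).of("baseline") == "partial"

    def test_status_recomputed_from_stored_values(self, deployed_study):
        """Independent recount: stored non-empty values drive the status."""
        pid = deployed_study.include_participant("muc", "t").pid
        deployed_study.record_submission(
            Submission(pid, "baseline", 1, {"age": "40", "sex": "f"},
                       complete_flag=False),
            actor="t",
        )
        head = [
            r for r in deployed_study.store.query_current(entity="visit_data")
            if r.payload["pid"] == pid
        ]
        stored_nonempty = sum(1 for v in head[0].payload["values"].values() if v)
        assert stored_nonempty == 2
        assert deployed_study.documentation_status(pid).of("baseline") == "partial"

    def test_unknown_participant_rejected(self, deployed_study):
        with pytest.raises(UnknownParticipant):
            deployed_study.documentation_status("ghost-0001")

    def test_repeating_visit_instances_tracked_separately(self, deployed_study):
        pid = deployed_study.include_participant("muc", "t").pid
        for instance in (1, 2):
            deployed_study.record_submission(
                Submission(pid, "followup", instance,
                           {"weight": "70.5", "seen_at": "09:15",
                            "visit_date": "2024-02-01"},
                           complete_flag=True),
                actor="t",
            )
        doc = deployed_study.documentation_status(pid)
        assert doc.of("followup", 1) == "complete"
        assert doc.of("followup", 2) == "complete"
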