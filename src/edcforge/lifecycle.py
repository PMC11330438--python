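"""Study lifecycle: editor→deployment workflow, inclusion, documentation status.

A study lives in one of two modes. In *editor* mode the metadata is
authored, tested against a transient preview store, and versioned; nothing
recorded there survives. Activating *deployment* purges the preview store,
freezes the visit definitions that exist at that moment, and opens the
permanent audit store for clinical data — only then is clinical data
recorded permanently. Only an administrator can revert to editor mode, and
even then frozen visits cannot be changed or removed and metadata edits must
be additive (new visits, new widgets, widened choice lists) to protect the
integrity of data already captured.

Participants are included under pseudonymized IDs ``{site}-{seq:04d}``,
sequential per site — a scheme chosen for mergeability across offline
devices and human readability.

The audit store is the single source of truth; the ``Study`` object keeps
derived caches (current heads, participant registry, per-site sequence
counters) that are rebuilt from the store on open and kept in sync on every
write, so routine operations stay O(1) in store size.
"""

from __future__ import annotations

import json
import logging
import random
import re
from dataclasses import dataclass

from .errors import (
    AlreadyDeployed,
    InvalidMetadata,
    NarrowingChange,
    NotAdmin,
    NotDeployed,
    StudyNotInEditorMode,
    UnknownParticipant,
    UnknownRecord,
    UnknownVisit,
    VisitFrozen,
)
from .forms import (
    FormSpec,
    Submission,
    build_form_spec,
    clean_submission_values,
    validate_submission,
)
from .metadata import (
    StudyMetadata,
    VariableSet,
    import_variable_set,
    study_from_dict,
    study_to_dict,
    validate_study_metadata,
)
from .store import AuditStore, iso_ms, new_record_id

logger = logging.getLogger(__name__)

_PID_SEQ_RE = re.compile(r"^(?P<site>.+)-(?P<seq>[0-9]+)$")


@dataclass(frozen=True)
class Participant:
    pid: str
    site: str
    included_at: str
    record_id: str


@dataclass(frozen=True)
class DocumentationStatus:
    """Per (visit_id, visit_instance) entry status for one participant."""

    statuses: dict  # (visit_id, visit_instance) -> "empty" | "partial" | "complete"

    def of(self, visit_id: str, visit_instance: int = 1) -> str:
        return self.statuses.get((visit_id, visit_instance), "empty")

    def count(self, status: str) -> int:
        return sum(1 for s in self.statuses.values() if s == status)


def _values_nonempty(values: dict) -> bool:
    return any(v not in ("", None) for v in values.values())


def _status_of(payload: dict) -> str:
    if not _values_nonempty(payload.get("values", {})):
        return "empty"
    if payload.get("complete_flag") and payload.get("valid"):
        return "complete"
    return "partial"


class Study:
    """One study deployment: metadata + mode + audit store + participants."""

    def __init__(
        self,
        store: AuditStore,
        metadata: StudyMetadata,
        mode: str = "editor",
        rng: random.Random | None = None,
    ):
        self.store = store
        self.metadata = metadata
        self.mode = mode
        self.rng = rng
        self.deployed_at: str | None = store.get_meta("deployed_at")
        self.frozen_visits: set[str] = set(json.loads(store.get_meta("frozen_visits", "[]")))
        self.ever_deployed: bool = store.get_meta("ever_deployed", "0") == "1"
        # transient preview store: purged on deployment activation
        self.preview_store = AuditStore(
            ":memory:", origin_id=store.origin_id, clock=store.clock
        )
        self._rebuild_caches()

    # -- construction / persistence ----------------------------------------

    @classmethod
    def create(
        cls,
        metadata: StudyMetadata,
        path: str = ":memory:",
        origin_id: str = "local",
        clock=None,
        rng: random.Random | None = None,
    ) -> "Study":
        store = AuditStore(path, origin_id=origin_id, clock=clock)
        study = cls(store, metadata, mode="editor", rng=rng)
        study._persist_metadata("system")
        study._persist_state()
        return study

    @classmethod
    def open(cls, path: str, clock=None, rng: random.Random | None = None) -> "Study":
        store = AuditStore(path, clock=clock)
        return cls.attach(store, rng=rng)

    @classmethod
    def attach(cls, store: AuditStore, rng: random.Random | None = None) -> "Study":
        """Wrap an existing store (a reopened file, or an offline-merge output)."""
        raw = store.get_meta("metadata")
        if raw is None:
            raise InvalidMetadata("store holds no study metadata")
        store.origin_id = store.get_meta("origin_id", store.origin_id)
        metadata = study_from_dict(json.loads(raw))
        return cls(store, metadata, mode=store.get_meta("mode", "editor"), rng=rng)

    def _persist_state(self) -> None:
        self.store.set_meta("mode", self.mode)
        self.store.set_meta("study_id", self.metadata.study_id)
        self.store.set_meta("metadata_version", str(self.metadata.metadata_version))
        self.store.set_meta("origin_id", self.store.origin_id)
        self.store.set_meta("frozen_visits", json.dumps(sorted(self.frozen_visits)))
        self.store.set_meta("ever_deployed", "1" if self.ever_deployed else "0")
        if self.deployed_at is not None:
            self.store.set_meta("deployed_at", self.deployed_at)

    def _persist_metadata(self, actor: str) -> None:
        self.store.set_meta("metadata", json.dumps(study_to_dict(self.metadata)))
        record_id = self.store.get_meta("metadata_record_id")
        if record_id is None:
            record_id = new_record_id(self.rng)
            self.store.set_meta("metadata_record_id", record_id)
        self.store.append_version(
            record_id,
            {"metadata_version": self.metadata.metadata_version,
             "study_id": self.metadata.study_id},
            actor,
            entity="metadata_item",
        )
        self.store.set_meta("metadata_version", str(self.metadata.metadata_version))

    def _rebuild_caches(self) -> None:
        self._record_index: dict[tuple, str] = {}  # (pid, visit, instance) -> record_id
        self._visit_heads: dict[tuple, dict] = {}  # same key -> head payload
        self._pids: dict[str, str] = {}  # pid -> record_id
        self._site_seq: dict[str, int] = {}
        heads: dict[str, object] = {}
        for row in self.store.all_rows():
            prev = heads.get(row.record_id)
            if prev is None or (row.version_no, row.timestamp, row.row_seq) > (
                prev.version_no, prev.timestamp, prev.row_seq
            ):
                heads[row.record_id] = row
        for row in heads.values():
            if row.entity == "visit_data":
                p = row.payload
                key = (p.get("pid"), p.get("visit_id") or None, p.get("visit_instance", 1))
                self._record_index[key] = row.record_id
                if not row.deleted:
                    self._visit_heads[key] = p
            elif row.entity == "participant" and not row.deleted:
                pid = row.payload["pid"]
                self._pids[pid] = row.record_id
                self._bump_site_seq(pid)

    def _bump_site_seq(self, pid: str) -> None:
        m = _PID_SEQ_RE.match(pid)
        if m:
            site, seq = m.group("site"), int(m.group("seq"))
            self._site_seq[site] = max(self._site_seq.get(site, 0), seq)

    # -- metadata editing ----------------------------------------------------

    def save_metadata(self, new_metadata: StudyMetadata, actor: str) -> None:
        """Editor-mode metadata save; bumps metadata_version by one.

        After the study has ever been deployed, frozen visits must survive
        unchanged and edits must be additive (existing widgets may not be
        removed, retyped, or have their choices narrowed).
        """
        if self.mode != "editor":
            raise StudyNotInEditorMode("metadata can only be edited in editor mode")
        if self.ever_deployed:
            self._check_additive(self.metadata, new_metadata)
        report = validate_study_metadata(new_metadata)
        if not report.ok:
            raise InvalidMetadata("metadata fails validation", report=report)
        self.metadata = StudyMetadata(
            study_id=new_metadata.study_id,
            title=new_metadata.title,
            visits=new_metadata.visits,
            widgets=new_metadata.widgets,
            lookup_tables=new_metadata.lookup_tables,
            metadata_version=self.metadata.metadata_version + 1,
        )
        self._persist_metadata(actor)
        self._persist_state()

    def _check_additive(self, old: StudyMetadata, new: StudyMetadata) -> None:
        new_visits = new.visit_map()
        for visit_id in self.frozen_visits:
            old_visit = old.visit_map().get(visit_id)
            if old_visit is None:
                continue
            if visit_id not in new_visits:
                raise VisitFrozen(f"visit {visit_id!r} was frozen at deployment "
                                  "and cannot be removed")
            if new_visits[visit_id] != old_visit:
                raise VisitFrozen(f"visit {visit_id!r} was frozen at deployment "
                                  "and cannot be changed")
        new_widgets = new.widget_map()
        for widget in old.widgets:
            replacement = new_widgets.get(widget.variable_id)
            if replacement is None:
                raise NarrowingChange(
                    f"widget {widget.variable_id!r} cannot be removed after deployment")
            if replacement.input_type != widget.input_type:
                raise NarrowingChange(
                    f"widget {widget.variable_id!r} cannot change type after deployment")
            if not set(widget.choice_codes()) <= set(replacement.choice_codes()):
                raise NarrowingChange(
                    f"choices of {widget.variable_id!r} can only be widened "
                    "after deployment")

    def import_set(self, vset: VariableSet, target_visit: str, actor: str) -> None:
        """Add a library variable set to a visit (editor mode only)."""
        self.metadata = import_variable_set(
            vset, self.metadata, target_visit, mode=self.mode
        )
        report = validate_study_metadata(self.metadata)
        if not report.ok:
            raise InvalidMetadata("import produced invalid metadata", report=report)
        self._persist_metadata(actor)
        self._persist_state()

    # -- lifecycle transitions ------------------------------------------------

    def activate_deployment(self, actor: str) -> None:
        if self.mode == "deployment":
            raise AlreadyDeployed("study is already in deployment mode")
        report = validate_study_metadata(self.metadata)
        if not report.ok:
            raise InvalidMetadata("cannot deploy invalid metadata", report=report)
        # preview entries are never carried over
        self.preview_store = AuditStore(
            ":memory:", origin_id=self.store.origin_id, clock=self.store.clock
        )
        self.frozen_visits |= {v.visit_id for v in self.metadata.visits}
        self.mode = "deployment"
        self.ever_deployed = True
        self.deployed_at = iso_ms(self.store.clock())
        logger.info("study %s deployed by %s", self.metadata.study_id, actor)
        self._persist_state()

    def revert_to_editor(self, actor: str, role: str = "user") -> None:
        if role != "admin":
            raise NotAdmin("only an administrator may revert to editor mode")
        if self.mode != "deployment":
            raise NotDeployed("study is not in deployment mode")
        self.mode = "editor"
        logger.warning(
            "study %s reverted to editor mode by admin %s; "
            "deployed clinical data remains in the audit store",
            self.metadata.study_id, actor,
        )
        self._persist_state()

    # -- participants ----------------------------------------------------------

    def participants(self) -> list[Participant]:
        out = []
        for row in self.store.query_current(entity="participant"):
            p = row.payload
            out.append(Participant(p["pid"], p["site"], p["included_at"], row.record_id))
        return out

    def include_participant(self, site: str, actor: str) -> Participant:
        """Include (pseudonymize) a new participant: pid = ``{site}-{seq:04d}``."""
        if self.mode != "deployment":
            raise NotDeployed("participants can only be included in deployment mode")
        seq = self._site_seq.get(site, 0) + 1
        pid = f"{site}-{seq:04d}"
        record_id = new_record_id(self.rng)
        row = self.store.append_version(
            record_id,
            {"pid": pid, "site": site, "included_at": iso_ms(self.store.clock())},
            actor,
            entity="participant",
        )
        self._pids[pid] = record_id
        self._site_seq[site] = seq
        return Participant(pid=pid, site=site,
                           included_at=row.payload["included_at"], record_id=record_id)

    def pid_exists(self, pid: str) -> bool:
        """The whole server-side contract a mobile client needs before a form."""
        return pid in self._pids

    def remove_participant(self, pid: str, actor: str) -> None:
        record_id = self._pids.get(pid)
        if record_id is None:
            raise UnknownParticipant(f"no participant {pid!r}")
        self.store.soft_delete(record_id, actor)
        del self._pids[pid]

    # -- clinical data -----------------------------------------------------------

    def _stored_values(self, pid: str, visit_id: str | None, visit_instance: int) -> dict:
        """Union of this visit-instance's stored values and participant-centered ones."""
        if self.mode != "deployment":
            # editor previews: small transient store, scan is fine
            state: dict = {}
            for row in self.preview_store.query_current(entity="visit_data"):
                p = row.payload
                if p.get("pid") != pid:
                    continue
                row_visit = p.get("visit_id") or None
                if row_visit is None or (
                    row_visit == visit_id and p.get("visit_instance", 1) == visit_instance
                ):
                    state.update({k: v for k, v in p.get("values", {}).items() if v != ""})
            return state
        state = {}
        for key in ((pid, None, 1), (pid, visit_id, visit_instance)):
            payload = self._visit_heads.get(key)
            if payload:
                state.update({k: v for k, v in payload.get("values", {}).items() if v != ""})
        return state

    def form_for(self, pid: str, visit_id: str | None, visit_instance: int = 1) -> FormSpec:
        if self.mode == "deployment" and not self.pid_exists(pid):
            raise UnknownParticipant(f"no participant {pid!r}")
        state = self._stored_values(pid, visit_id, visit_instance)
        return build_form_spec(
            self.metadata, visit_id, state,
            participant_id=pid, visit_instance=visit_instance,
        )

    def record_submission(self, sub: Submission, actor: str):
        """Validate a submission and persist it if ok.

        Returns ``(AuditRow | None, ValidationReport)``: the row is ``None``
        when validation failed and nothing was stored. In editor mode entries
        go to the transient preview store only; clinical data reaches the
        permanent store exclusively through this path, in deployment mode.
        """
        if sub.visit_id is not None and sub.visit_id not in self.metadata.visit_map():
            raise UnknownVisit(f"visit {sub.visit_id!r} does not exist")
        instance = 1 if sub.visit_id is None else sub.visit_instance
        form = self.form_for(sub.participant_id, sub.visit_id, instance)
        report = validate_submission(self.metadata, form, sub)
        if not report.ok:
            return None, report
        values = clean_submission_values(self.metadata, form, sub)
        key = (sub.participant_id, sub.visit_id, instance)
        payload = {
            "pid": sub.participant_id,
            "visit_id": sub.visit_id or "",
            "visit_instance": instance,
            "values": values,
            "complete_flag": sub.complete_flag,
            "valid": True,
        }
        if self.mode == "deployment":
            record_id = self._record_index.get(key) or new_record_id(self.rng)
            row = self.store.append_version(record_id, payload, actor, entity="visit_data")
            self._record_index[key] = record_id
            self._visit_heads[key] = payload
        else:
            record_id = new_record_id(self.rng)
            row = self.preview_store.append_version(
                record_id, payload, actor, entity="visit_data"
            )
        return row, report

    def delete_visit_record(self, pid: str, visit_id: str | None,
                            visit_instance: int, actor: str) -> None:
        key = (pid, visit_id, visit_instance)
        record_id = self._record_index.get(key)
        if record_id is None:
            raise UnknownRecord(f"no stored data for {key}")
        self.store.soft_delete(record_id, actor)
        self._visit_heads.pop(key, None)

    # -- documentation status -------------------------------------------------

    def documentation_status(self, pid: str) -> DocumentationStatus:
        """Entry status per visit instance: empty, partial, or complete."""
        if not self.pid_exists(pid):
            raise UnknownParticipant(f"no participant {pid!r}")
        statuses: dict = {(v.visit_id, 1): "empty" for v in self.metadata.visits}
        for (head_pid, visit_id, instance), payload in self._visit_heads.items():
            if head_pid != pid or visit_id is None:
                continue
            statuses[(visit_id, instance)] = _status_of(payload)
        return DocumentationStatus(statuses)

    def documentation_statuses(self) -> dict[str, DocumentationStatus]:
        """Bulk status report for every included participant (single pass)."""
        base = {(v.visit_id, 1): "empty" for v in self.metadata.visits}
        per_pid: dict[str, dict] = {pid: dict(base) for pid in self._pids}
        for (pid, visit_id, instance), payload in self._visit_heads.items():
            if visit_id is None or pid not in per_pid:
                continue
            per_pid[pid][(visit_id, instance)] = _status_of(payload)
        return {pid: DocumentationStatus(statuses) for pid, statuses in per_pid.items()}
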