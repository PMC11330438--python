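"""Study export: per-visit tables, aggregated wide table, codebook, zip bundle.

The bundle is the downloadable study artifact:

    data/participants.csv        one row per included participant
    data/<visit_id>.csv          one row per (participant, visit instance)
    data/aggregated_wide.csv     one row per participant, all visits wide
    metadata/...                 the complete metadata bundle tables
    codebook.csv                 auto-generated data dictionary
    audit/audit_log.csv          every audit row, payload JSON-encoded
    manifest.json                member list with data-row counts

All CSV output is RFC 4180, UTF-8, LF line endings, quoted only when
necessary, and the zip is reproducible byte-for-byte given a fixed store and
an injected timestamp. Exported cells always reflect the audit store's
current heads; deleted records appear only in the audit log.
"""

from __future__ import annotations

import csv
import io
import json
from datetime import datetime, timezone

import pandas as pd

from .errors import InvalidMetadata, UnknownVisit
from .conditions import serialize_condition
from .metadata import (
    StudyMetadata,
    metadata_manifest,
    metadata_tables,
    validate_study_metadata,
    write_zip,
)
from .store import AuditRow, AuditStore, canonical_payload

CODEBOOK_COLUMNS = [
    "variable_id", "visit_ids", "label", "input_type", "required",
    "condition_serialized", "choices_serialized", "lookup_table_id",
    "units", "order_index",
]

AUDIT_COLUMNS = [
    "row_seq", "record_id", "entity", "version_no", "origin_id", "actor",
    "timestamp", "deleted", "supersedes", "payload_json",
]


def _widget_sort_key(study: StudyMetadata):
    visit_order = {v.visit_id: v.order_index for v in study.visits}

    def key(widget):
        # participant-centered widgets (no visit) sort after all visits
        first = min((visit_order[v] for v in widget.visit_ids if v in visit_order),
                    default=len(visit_order) + 1)
        return (first, widget.order_index, widget.variable_id)

    return key


def build_codebook(metadata: StudyMetadata) -> pd.DataFrame:
    """One codebook row per widget, ordered by (visit order, order_index)."""
    report = validate_study_metadata(metadata)
    if not report.ok:
        raise InvalidMetadata("metadata fails validation", report=report)
    rows = []
    for w in sorted(metadata.widgets, key=_widget_sort_key(metadata)):
        rows.append({
            "variable_id": w.variable_id,
            "visit_ids": ";".join(w.visit_ids),
            "label": w.label,
            "input_type": w.input_type,
            "required": "true" if w.required else "false",
            "condition_serialized": serialize_condition(w.condition) if w.condition else "",
            "choices_serialized": "|".join(f"{c}={l}" for c, l in w.choices),
            "lookup_table_id": w.lookup_table_id or "",
            "units": w.units or "",
            "order_index": w.order_index,
        })
    return pd.DataFrame(rows, columns=CODEBOOK_COLUMNS)


def _visit_records(store: AuditStore) -> list[AuditRow]:
    return store.query_current(entity="visit_data")


def export_visit_table(store: AuditStore, metadata: StudyMetadata, visit_id: str) -> pd.DataFrame:
    """One row per (participant, visit_instance) with current head values."""
    if visit_id not in metadata.visit_map():
        raise UnknownVisit(f"visit {visit_id!r} does not exist")
    variables = [w.variable_id for w in metadata.visit_widgets(visit_id)]
    rows = []
    for record in _visit_records(store):
        p = record.payload
        if (p.get("visit_id") or None) != visit_id:
            continue
        row = {"pid": p["pid"], "visit_instance": p.get("visit_instance", 1)}
        values = p.get("values", {})
        for var in variables:
            row[var] = values.get(var, "")
        rows.append(row)
    rows.sort(key=lambda r: (r["pid"], r["visit_instance"]))
    return pd.DataFrame(rows, columns=["pid", "visit_instance"] + variables).astype(object)


def export_participant_table(store: AuditStore, metadata: StudyMetadata) -> pd.DataFrame:
    """Participant-centered data: one row per participant."""
    variables = [w.variable_id for w in metadata.participant_widgets()]
    rows = []
    for record in _visit_records(store):
        p = record.payload
        if (p.get("visit_id") or None) is not None:
            continue
        row = {"pid": p["pid"]}
        values = p.get("values", {})
        for var in variables:
            row[var] = values.get(var, "")
        rows.append(row)
    rows.sort(key=lambda r: r["pid"])
    return pd.DataFrame(rows, columns=["pid"] + variables).astype(object)


def _first_seen(store: AuditStore) -> dict[str, str]:
    """record_id -> timestamp of its first version (chronological instance order)."""
    first: dict[str, str] = {}
    for row in store.all_rows():
        if row.record_id not in first:
            first[row.record_id] = row.timestamp
    return first


def export_aggregated(store: AuditStore, metadata: StudyMetadata) -> pd.DataFrame:
    """One row per participant, all visits side by side.

    Columns are ``<visit_id>.<variable_id>`` for non-repeating visits and
    ``<visit_id>.<k>.<variable_id>`` for the k-th instance of a repeating
    visit (k from 1, chronological by first submission). Participant-centered
    variables are prefixed ``participant.``.
    """
    participants = sorted(
        r.payload["pid"] for r in store.query_current(entity="participant")
    )
    records = _visit_records(store)
    first_seen = _first_seen(store)

    # per (pid, visit): instance records in chronological first-submission order
    by_pid_visit: dict[tuple, list[AuditRow]] = {}
    participant_values: dict[str, dict] = {}
    for record in records:
        p = record.payload
        visit_id = p.get("visit_id") or None
        if visit_id is None:
            participant_values.setdefault(p["pid"], {}).update(p.get("values", {}))
        else:
            by_pid_visit.setdefault((p["pid"], visit_id), []).append(record)
    for items in by_pid_visit.values():
        items.sort(key=lambda r: (first_seen[r.record_id], r.row_seq))

    max_instances = {
        v.visit_id: max(
            (len(items) for (pid, vid), items in by_pid_visit.items() if vid == v.visit_id),
            default=0,
        )
        for v in metadata.visits
    }

    columns = ["pid"]
    accessors = []  # (column, visit_id | None, instance_index, variable_id)
    for visit in sorted(metadata.visits, key=lambda v: v.order_index):
        variables = [w.variable_id for w in metadata.visit_widgets(visit.visit_id)]
        if visit.repeating:
            for k in range(1, max(max_instances[visit.visit_id], 1) + 1):
                for var in variables:
                    columns.append(f"{visit.visit_id}.{k}.{var}")
                    accessors.append((columns[-1], visit.visit_id, k, var))
        else:
            for var in variables:
                columns.append(f"{visit.visit_id}.{var}")
                accessors.append((columns[-1], visit.visit_id, 1, var))
    for w in metadata.participant_widgets():
        columns.append(f"participant.{w.variable_id}")
        accessors.append((columns[-1], None, 1, w.variable_id))

    rows = []
    for pid in participants:
        row = {"pid": pid}
        for column, visit_id, k, var in accessors:
            if visit_id is None:
                row[column] = participant_values.get(pid, {}).get(var, "")
            else:
                items = by_pid_visit.get((pid, visit_id), [])
                if k <= len(items):
                    row[column] = items[k - 1].payload.get("values", {}).get(var, "")
                else:
                    row[column] = ""
        rows.append(row)
    return pd.DataFrame(rows, columns=columns).astype(object)


def write_table(df: pd.DataFrame, path: str, fmt: str = "csv") -> None:
    """Write a table as CSV (canonical) or XLSX (spreadsheet convenience)."""
    if fmt == "csv":
        df.to_csv(path, index=False, lineterminator="\n")
    elif fmt == "xlsx":
        df.to_excel(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _df_csv_bytes(df: pd.DataFrame) -> bytes:
    buf = io.StringIO(newline="")
    df.to_csv(buf, index=False, lineterminator="\n")
    return buf.getvalue().encode("utf-8")


def audit_log_csv(store: AuditStore) -> bytes:
    buf = io.StringIO(newline="")
    writer = csv.writer(buf, lineterminator="\n", quoting=csv.QUOTE_MINIMAL)
    writer.writerow(AUDIT_COLUMNS)
    for row in store.all_rows():
        supersedes = f"{row.supersedes[0]}:{row.supersedes[1]}" if row.supersedes else ""
        writer.writerow([
            row.row_seq, row.record_id, row.entity, row.version_no, row.origin_id,
            row.actor, row.timestamp, "true" if row.deleted else "false",
            supersedes, canonical_payload(row.payload),
        ])
    return buf.getvalue().encode("utf-8")


def participants_csv(store: AuditStore) -> bytes:
    rows = sorted(
        (r.payload["pid"], r.payload["site"], r.payload["included_at"])
        for r in store.query_current(entity="participant")
    )
    buf = io.StringIO(newline="")
    writer = csv.writer(buf, lineterminator="\n", quoting=csv.QUOTE_MINIMAL)
    writer.writerow(["pid", "site", "included_at"])
    writer.writerows(rows)
    return buf.getvalue().encode("utf-8")


def _csv_data_rows(data: bytes) -> int:
    text = data.decode("utf-8")
    reader = csv.reader(io.StringIO(text, newline=""))
    return max(sum(1 for _ in reader) - 1, 0)


def write_bundle(
    store: AuditStore,
    metadata: StudyMetadata,
    destination: str | None = None,
    timestamp: datetime | None = None,
) -> bytes:
    """Assemble the complete export bundle; optionally write it to a file.

    Re-running with an identical store and the same injected timestamp
    produces identical bytes.
    """
    report = validate_study_metadata(metadata)
    if not report.ok:
        raise InvalidMetadata("metadata fails validation", report=report)
    if timestamp is None:
        timestamp = datetime.now(timezone.utc)

    members: dict[str, bytes] = {}
    members["data/participants.csv"] = participants_csv(store)
    for visit in metadata.visits:
        members[f"data/{visit.visit_id}.csv"] = _df_csv_bytes(
            export_visit_table(store, metadata, visit.visit_id)
        )
    members["data/aggregated_wide.csv"] = _df_csv_bytes(export_aggregated(store, metadata))
    for name, data in metadata_tables(metadata).items():
        members[f"metadata/{name}"] = data
    members["metadata/manifest.json"] = metadata_manifest(metadata, timestamp)
    members["codebook.csv"] = _df_csv_bytes(build_codebook(metadata))
    members["audit/audit_log.csv"] = audit_log_csv(store)

    manifest = {
        "study_id": metadata.study_id,
        "metadata_version": metadata.metadata_version,
        "created_utc": timestamp.astimezone(timezone.utc).isoformat(),
        "members": {
            name: (_csv_data_rows(data) if name.endswith(".csv") else None)
            for name, data in sorted(members.items())
        },
    }
    members["manifest.json"] = (
        json.dumps(manifest, indent=2, ensure_ascii=False, sort_keys=True) + "\n"
    ).encode("utf-8")

    bundle = write_zip(members, timestamp)
    if destination is not None:
        with open(destination, "wb") as fh:
            fh.write(bundle)
    return bundle
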