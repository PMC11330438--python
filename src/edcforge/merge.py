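"""Merging audit stores from independently operated offline devices.

Several machines can run the same study from an identical configuration
template, capture data offline, and be consolidated afterwards. Rows are
keyed by ``(record_id, version_no, origin_id)``: record_ids are
device-generated UUIDs, so independent devices are conflict-free by
construction and merging reduces to a union. Byte-identical duplicate keys
(e.g. re-merging an already merged store) deduplicate silently. The same
key with a differing payload digest — possible only when a seed database
was duplicated — is a *conflict*: the default ``strict`` policy aborts with
a report, ``latest_wins`` keeps the later ``(timestamp, row_seq)`` row and
records the loser.

Participants included on different devices under the same site prefix can
collide on pid. Colliding pids are remapped deterministically (each extra
origin's sequence numbers are offset by a stride of 10000) and the remap is
logged in the report.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

from .errors import MergeConflict, MetadataMismatch
from .store import AuditRow, AuditStore, canonical_payload

logger = logging.getLogger(__name__)

PID_STRIDE = 10000
_PID_RE = re.compile(r"^(?P<site>.+)-(?P<seq>[0-9]+)$")


@dataclass(frozen=True)
class Conflict:
    record_id: str
    version_no: int
    origin_ids: tuple
    digests: tuple


@dataclass
class MergeReport:
    rows_in: dict = field(default_factory=dict)  # source label -> row count
    rows_out: int = 0
    duplicates_skipped: int = 0
    conflicts: list = field(default_factory=list)
    pid_remaps: list = field(default_factory=list)  # (origin_id, old_pid, new_pid)

    def to_dict(self) -> dict:
        return {
            "rows_in": dict(self.rows_in),
            "rows_out": self.rows_out,
            "duplicates_skipped": self.duplicates_skipped,
            "conflicts": [
                {"record_id": c.record_id, "version_no": c.version_no,
                 "origin_ids": list(c.origin_ids), "digests": list(c.digests)}
                for c in self.conflicts
            ],
            "pid_remaps": [list(r) for r in self.pid_remaps],
        }


def _check_sources(sources: list[AuditStore]) -> None:
    if not sources:
        raise MetadataMismatch("no sources to merge")
    reference = (sources[0].get_meta("study_id"), sources[0].get_meta("metadata_version"))
    for src in sources[1:]:
        candidate = (src.get_meta("study_id"), src.get_meta("metadata_version"))
        if candidate != reference:
            raise MetadataMismatch(
                f"sources disagree on study identity: {reference} vs {candidate}"
            )


def _collect(sources: list[AuditStore]):
    """(key -> list of (source_index, AuditRow)) over all source rows."""
    groups: dict[tuple, list] = {}
    counts: dict[str, int] = {}
    for idx, src in enumerate(sources):
        label = f"source_{idx}:{src.origin_id}"
        rows = src.all_rows()
        counts[label] = len(rows)
        for row in rows:
            groups.setdefault(row.identity_key(), []).append((idx, row))
    return groups, counts


def detect_conflicts(sources: list[AuditStore]) -> list[Conflict]:
    """The conflicts a strict merge would raise; no mutation, dry run."""
    _check_sources(sources)
    groups, _ = _collect(sources)
    conflicts = []
    for key in sorted(groups):
        entries = groups[key]
        digests = {row.payload_digest(): (idx, row) for idx, row in entries}
        full = {row.content_key() for _, row in entries}
        if len(digests) > 1 or (len(digests) == 1 and len(full) > 1):
            record_id, version_no, _origin = key
            conflicts.append(
                Conflict(
                    record_id=record_id,
                    version_no=version_no,
                    origin_ids=tuple(sorted({row.origin_id for _, row in entries})),
                    digests=tuple(sorted({row.payload_digest() for _, row in entries})),
                )
            )
    return conflicts


def merge_stores(
    sources: list[AuditStore],
    policy: str = "strict",
    out_path: str = ":memory:",
) -> tuple[AuditStore, MergeReport]:
    """Union-merge device stores into a consolidated store.

    Strict policy: idempotent, commutative, associative (row-set-wise);
    aborts on any conflict. ``latest_wins``: conflicts resolved toward the
    later ``(timestamp, row_seq)`` row, losers recorded in the report.
    """
    if policy not in ("strict", "latest_wins"):
        raise ValueError(f"unknown merge policy {policy!r}")
    _check_sources(sources)
    groups, counts = _collect(sources)
    report = MergeReport(rows_in=counts)

    kept: list[tuple] = []  # (timestamp, source_index, original_row_seq, AuditRow)
    for key in sorted(groups):
        entries = groups[key]
        unique_content = {}
        for idx, row in entries:
            unique_content.setdefault(row.content_key(), (idx, row))
        report.duplicates_skipped += len(entries) - len(unique_content)
        if len(unique_content) == 1:
            idx, row = next(iter(unique_content.values()))
            kept.append((row.timestamp, idx, row.row_seq, row))
            continue
        record_id, version_no, _origin = key
        conflict = Conflict(
            record_id=record_id,
            version_no=version_no,
            origin_ids=tuple(sorted({row.origin_id for _, row in entries})),
            digests=tuple(sorted({row.payload_digest() for _, row in entries})),
        )
        report.conflicts.append(conflict)
        if policy == "strict":
            continue
        winner_idx, winner = max(
            unique_content.values(), key=lambda e: (e[1].timestamp, e[1].row_seq)
        )
        report.duplicates_skipped += len(unique_content) - 1
        kept.append((winner.timestamp, winner_idx, winner.row_seq, winner))

    if policy == "strict" and report.conflicts:
        raise MergeConflict(
            f"{len(report.conflicts)} conflicting row version(s)", report=report
        )

    kept.sort(key=lambda item: item[:3])
    remap = _pid_remapping([row for *_, row in kept], report)

    merged = AuditStore(out_path, origin_id="merged", clock=sources[0].clock)
    merged.conn.execute("DELETE FROM audit")  # fresh output file
    for _, _, _, row in kept:
        payload = _apply_remap(row, remap)
        merged.conn.execute(
            "INSERT INTO audit (record_id, entity, payload_json, version_no, "
            "origin_id, actor, timestamp, deleted, supersedes_record, "
            "supersedes_version) VALUES (?,?,?,?,?,?,?,?,?,?)",
            (
                row.record_id, row.entity, canonical_payload(payload), row.version_no,
                row.origin_id, row.actor, row.timestamp, int(row.deleted),
                row.supersedes[0] if row.supersedes else None,
                row.supersedes[1] if row.supersedes else None,
            ),
        )
    merged.conn.commit()
    for key in ("study_id", "metadata_version", "metadata", "mode",
                "frozen_visits", "ever_deployed", "deployed_at",
                "metadata_record_id"):
        value = sources[0].get_meta(key)
        if value is not None:
            merged.set_meta(key, value)
    merged.set_meta("origin_id", "merged")
    report.rows_out = merged.row_count()
    return merged, report


def _pid_remapping(rows: list[AuditRow], report: MergeReport) -> dict[tuple, str]:
    """(origin_id, old_pid) -> new_pid for pids duplicated across origins."""
    pid_origins: dict[str, list[str]] = {}
    for row in rows:
        if row.entity != "participant":
            continue
        pid = row.payload.get("pid")
        origin = row.origin_id
        if pid is not None and origin not in pid_origins.setdefault(pid, []):
            pid_origins[pid].append(origin)
    remap: dict[tuple, str] = {}
    for pid in sorted(pid_origins):
        origins = sorted(pid_origins[pid])
        if len(origins) < 2:
            continue
        m = _PID_RE.match(pid)
        for k, origin in enumerate(origins[1:], start=1):
            if m:
                new_pid = f"{m.group('site')}-{int(m.group('seq')) + PID_STRIDE * k:04d}"
            else:
                new_pid = f"{pid}_{origin}"
            remap[(origin, pid)] = new_pid
            report.pid_remaps.append((origin, pid, new_pid))
            logger.warning("pid %s from origin %s remapped to %s", pid, origin, new_pid)
    return remap


def _apply_remap(row: AuditRow, remap: dict[tuple, str]) -> dict:
    if not remap:
        return row.payload
    pid = row.payload.get("pid")
    new_pid = remap.get((row.origin_id, pid))
    if new_pid is None:
        return row.payload
    payload = dict(row.payload)
    payload["pid"] = new_pid
    return payload


def write_report(report: MergeReport, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
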