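"""Append-only audit store with point-in-time reconstruction.

The only persistence primitive in the system is the :class:`AuditRow`: one
immutable version of one logical record. Rows are never updated or removed;
edits append a new version, deletions append a row flagged ``deleted`` that
carries an unchanged copy of the payload it deletes. Because of this, the
state of the database can be reconstructed for any given time point
(:meth:`AuditStore.query_as_of`), and a digest over pre-existing rows is
invariant under every operation — the tamper-evidence property.

Backing store is a single-file embedded SQL database (sqlite3), or
in-memory for transient editor-mode previews. Ordering authority is
``(timestamp, row_seq)`` with ``row_seq`` as tie-breaker. Offline devices
may have skewed clocks: if a new version's timestamp would precede its
record's head, it is clamped to head + 1 ms and the event is logged, keeping
every version chain monotone without rejecting field data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sqlite3
import uuid
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone

from .errors import AlreadyDeleted, StoreReadOnly, UnknownRecord

logger = logging.getLogger(__name__)

ENTITIES = ("participant", "visit_data", "metadata_item")


def iso_ms(dt: datetime) -> str:
    """UTC ISO 8601 with millisecond precision: 2024-01-01T12:00:00.000Z"""
    dt = dt.astimezone(timezone.utc)
    return dt.strftime("%Y-%m-%dT%H:%M:%S.") + f"{dt.microsecond // 1000:03d}Z"


def parse_iso_ms(ts: str) -> datetime:
    return datetime.strptime(ts, "%Y-%m-%dT%H:%M:%S.%fZ").replace(tzinfo=timezone.utc)


class SimClock:
    """Deterministic injectable clock advancing a fixed step per call."""

    def __init__(self, start: datetime | None = None, step_ms: int = 1000):
        self.now = start or datetime(2024, 1, 1, tzinfo=timezone.utc)
        self.step = timedelta(milliseconds=step_ms)

    def __call__(self) -> datetime:
        current = self.now
        self.now = self.now + self.step
        return current


def canonical_payload(payload: dict) -> str:
    return json.dumps(payload, sort_keys=True, ensure_ascii=False, separators=(",", ":"))


def payload_digest(payload: dict) -> str:
    return hashlib.sha256(canonical_payload(payload).encode("utf-8")).hexdigest()


@dataclass(frozen=True)
class AuditRow:
    row_seq: int
    record_id: str
    entity: str
    payload: dict
    version_no: int
    origin_id: str
    actor: str
    timestamp: str  # ISO 8601 UTC with milliseconds
    deleted: bool
    supersedes: tuple | None  # (record_id, version_no)

    def payload_digest(self) -> str:
        return payload_digest(self.payload)

    def identity_key(self) -> tuple:
        return (self.record_id, self.version_no, self.origin_id)

    def content_key(self) -> tuple:
        """Everything except the store-local row_seq; used for dedup/equality."""
        return (
            self.record_id, self.entity, canonical_payload(self.payload),
            self.version_no, self.origin_id, self.actor, self.timestamp,
            self.deleted, self.supersedes,
        )


_SCHEMA = """
CREATE TABLE IF NOT EXISTS audit (
    row_seq INTEGER PRIMARY KEY AUTOINCREMENT,
    record_id TEXT NOT NULL,
    entity TEXT NOT NULL,
    payload_json TEXT NOT NULL,
    version_no INTEGER NOT NULL,
    origin_id TEXT NOT NULL,
    actor TEXT NOT NULL,
    timestamp TEXT NOT NULL,
    deleted INTEGER NOT NULL,
    supersedes_record TEXT,
    supersedes_version INTEGER,
    UNIQUE (record_id, version_no, origin_id)
);
CREATE INDEX IF NOT EXISTS idx_audit_record ON audit (record_id, version_no);
CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value TEXT NOT NULL);
"""


class AuditStore:
    """Append-only versioned row store over a sqlite3 file (or ``:memory:``)."""

    def __init__(
        self,
        path: str = ":memory:",
        origin_id: str = "local",
        clock=None,
    ):
        self.path = path
        self.origin_id = origin_id
        self.clock = clock or (lambda: datetime.now(timezone.utc))
        self.read_only = False
        self.conn = sqlite3.connect(path)
        self.conn.executescript(_SCHEMA)
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    # -- meta key-value (study_id, mode, ... — control state, not audit data)

    def get_meta(self, key: str, default=None):
        row = self.conn.execute("SELECT value FROM meta WHERE key=?", (key,)).fetchone()
        return row[0] if row else default

    def set_meta(self, key: str, value: str) -> None:
        self.conn.execute(
            "INSERT INTO meta (key, value) VALUES (?, ?) "
            "ON CONFLICT(key) DO UPDATE SET value=excluded.value",
            (key, value),
        )
        self.conn.commit()

    # -- core operations

    def _head(self, record_id: str) -> AuditRow | None:
        rows = self.conn.execute(
            "SELECT * FROM audit WHERE record_id=? "
            "ORDER BY version_no DESC, timestamp DESC, row_seq DESC LIMIT 1",
            (record_id,),
        ).fetchall()
        return self._from_sql(rows[0]) if rows else None

    @staticmethod
    def _from_sql(row) -> AuditRow:
        (row_seq, record_id, entity, payload_json, version_no, origin_id,
         actor, timestamp, deleted, sup_rec, sup_ver) = row
        return AuditRow(
            row_seq=row_seq,
            record_id=record_id,
            entity=entity,
            payload=json.loads(payload_json),
            version_no=version_no,
            origin_id=origin_id,
            actor=actor,
            timestamp=timestamp,
            deleted=bool(deleted),
            supersedes=(sup_rec, sup_ver) if sup_rec is not None else None,
        )

    def _insert(self, row_fields: dict) -> AuditRow:
        cur = self.conn.execute(
            "INSERT INTO audit (record_id, entity, payload_json, version_no, "
            "origin_id, actor, timestamp, deleted, supersedes_record, "
            "supersedes_version) VALUES (?,?,?,?,?,?,?,?,?,?)",
            (
                row_fields["record_id"], row_fields["entity"],
                canonical_payload(row_fields["payload"]), row_fields["version_no"],
                row_fields["origin_id"], row_fields["actor"], row_fields["timestamp"],
                int(row_fields["deleted"]),
                row_fields["supersedes"][0] if row_fields["supersedes"] else None,
                row_fields["supersedes"][1] if row_fields["supersedes"] else None,
            ),
        )
        self.conn.commit()
        return AuditRow(row_seq=cur.lastrowid, **row_fields)

    def append_version(
        self,
        record_id: str,
        payload: dict,
        actor: str,
        entity: str = "visit_data",
        origin_id: str | None = None,
        deleted: bool = False,
    ) -> AuditRow:
        """Append the next version of a record (version 1 if it is new)."""
        if self.read_only:
            raise StoreReadOnly("store is read-only")
        origin = origin_id or self.origin_id
        head = self._head(record_id)
        ts = iso_ms(self.clock())
        if head is not None and ts <= head.timestamp:
            clamped = iso_ms(parse_iso_ms(head.timestamp) + timedelta(milliseconds=1))
            logger.warning(
                "clock skew on record %s: %s <= head %s; clamped to %s",
                record_id, ts, head.timestamp, clamped,
            )
            ts = clamped
        return self._insert(
            dict(
                record_id=record_id,
                entity=entity if head is None else head.entity,
                payload=dict(payload),
                version_no=1 if head is None else head.version_no + 1,
                origin_id=origin,
                actor=actor,
                timestamp=ts,
                deleted=deleted,
                supersedes=None if head is None else (record_id, head.version_no),
            )
        )

    def soft_delete(self, record_id: str, actor: str, origin_id: str | None = None) -> AuditRow:
        """Mark a record deleted by appending a deletion row (payload copied)."""
        head = self._head(record_id)
        if head is None:
            raise UnknownRecord(f"record {record_id!r} does not exist")
        if head.deleted:
            raise AlreadyDeleted(f"record {record_id!r} is already deleted")
        if self.read_only:
            raise StoreReadOnly("store is read-only")
        origin = origin_id or self.origin_id
        ts = iso_ms(self.clock())
        if ts <= head.timestamp:
            ts = iso_ms(parse_iso_ms(head.timestamp) + timedelta(milliseconds=1))
            logger.warning("clock skew on delete of %s; clamped to %s", record_id, ts)
        return self._insert(
            dict(
                record_id=record_id,
                entity=head.entity,
                payload=dict(head.payload),
                version_no=head.version_no + 1,
                origin_id=origin,
                actor=actor,
                timestamp=ts,
                deleted=True,
                supersedes=(record_id, head.version_no),
            )
        )

    # -- queries

    def all_rows(self) -> list[AuditRow]:
        rows = self.conn.execute("SELECT * FROM audit ORDER BY row_seq").fetchall()
        return [self._from_sql(r) for r in rows]

    def row_count(self) -> int:
        return self.conn.execute("SELECT COUNT(*) FROM audit").fetchone()[0]

    def _heads(self, rows: list[AuditRow]) -> list[AuditRow]:
        by_record: dict[str, AuditRow] = {}
        for row in rows:
            head = by_record.get(row.record_id)
            if head is None or (row.version_no, row.timestamp, row.row_seq) > (
                head.version_no, head.timestamp, head.row_seq
            ):
                by_record[row.record_id] = row
        return [r for r in by_record.values() if not r.deleted]

    def query_current(self, entity: str | None = None) -> list[AuditRow]:
        """Head (maximum-version, non-deleted) row per record."""
        rows = self.all_rows()
        if entity is not None:
            rows = [r for r in rows if r.entity == entity]
        return sorted(self._heads(rows), key=lambda r: r.row_seq)

    def query_as_of(self, t, entity: str | None = None) -> list[AuditRow]:
        """State of the database at time ``t`` (datetime or ISO string)."""
        cutoff = iso_ms(t) if isinstance(t, datetime) else t
        rows = [r for r in self.all_rows() if r.timestamp <= cutoff]
        if entity is not None:
            rows = [r for r in rows if r.entity == entity]
        return sorted(self._heads(rows), key=lambda r: r.row_seq)

    def history(self, record_id: str) -> list[AuditRow]:
        """Complete version chain including deletion rows, in version order."""
        rows = self.conn.execute(
            "SELECT * FROM audit WHERE record_id=? "
            "ORDER BY version_no, timestamp, row_seq",
            (record_id,),
        ).fetchall()
        if not rows:
            raise UnknownRecord(f"record {record_id!r} does not exist")
        return [self._from_sql(r) for r in rows]

    def digest(self) -> str:
        """SHA-256 over all rows in row_seq order; tamper-evidence handle."""
        h = hashlib.sha256()
        for row in self.all_rows():
            h.update(repr((row.row_seq,) + row.content_key()).encode("utf-8"))
        return h.hexdigest()


def new_record_id(rng=None) -> str:
    """Device-generated UUIDv4 (optionally from a seeded RNG for fixtures)."""
    if rng is None:
        return str(uuid.uuid4())
    return str(uuid.UUID(int=rng.getrandbits(128), version=4))
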