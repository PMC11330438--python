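"""Study metadata: visits, widgets, choice lists, lookup vocabularies.

The metadata is the single source of truth the rest of the engine renders,
validates and exports from. A *widget* is one input field's complete
definition (type, label, requiredness, choices, display condition, visit
assignment); a *visit* is a data-collection occasion (baseline, follow-up,
repeated intervention); *lookup tables* hold controlled vocabularies such as
ICD-10 or SNOMED subsets behind searchable dropdowns.

Metadata serializes to a zip of RFC 4180 CSV tables plus a JSON manifest
(the *metadata bundle*), which is both the study-cloning format and the
``metadata/`` subtree of the full export bundle. Export and re-import are a
field-for-field identity (timestamps aside), and bundle bytes are
deterministic given the metadata and an injected timestamp.
"""

from __future__ import annotations

import csv
import io
import json
import re
import zipfile
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timezone

from .conditions import (
    Atom,
    ConditionExpr,
    ConditionParseError,
    NULLARY_OPERATORS,
    OPERATORS,
    ORDERING_OPERATORS,
    parse_condition,
    referenced_variables,
    rename_variables,
    serialize_condition,
)
from .errors import (
    InvalidMetadata,
    MalformedBundle,
    StudyNotInEditorMode,
    UnknownVisit,
    UnsupportedFormatVersion,
)
from .validation import ValidationReport

INPUT_TYPES = (
    "text",
    "integer",
    "float",
    "checkbox",
    "time",
    "date",
    "radio",
    "dropdown",
    "dropdown_search",
)
CHOICE_TYPES = frozenset({"radio", "dropdown"})
TOKEN_RE = re.compile(r"^[a-z][a-z0-9_]{0,63}$")
BUNDLE_FORMAT_VERSION = 1

_TIME_RE = re.compile(r"^([01][0-9]|2[0-3]):[0-5][0-9]$")


def is_token(value: str) -> bool:
    return isinstance(value, str) and bool(TOKEN_RE.match(value))


@dataclass(frozen=True)
class VisitDefinition:
    visit_id: str
    title: str
    order_index: int = 0
    repeating: bool = False
    mobile: bool = False


@dataclass(frozen=True)
class LookupTable:
    lookup_table_id: str
    name: str
    entries: tuple = ()  # ordered (code, label) pairs

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple((c, l) for c, l in self.entries))

    def codes(self) -> list[str]:
        return [c for c, _ in self.entries]


@dataclass(frozen=True)
class WidgetDefinition:
    variable_id: str
    input_type: str
    label: str
    required: bool = False
    visit_ids: tuple = ()  # empty = participant-centered
    choices: tuple = ()  # ordered (code, label) pairs for radio/dropdown
    lookup_table_id: str | None = None
    condition: ConditionExpr | None = None
    order_index: int = 0
    units: str | None = None
    help_text: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "visit_ids", tuple(self.visit_ids))
        object.__setattr__(self, "choices", tuple((c, l) for c, l in self.choices))

    def choice_codes(self) -> list[str]:
        return [c for c, _ in self.choices]


@dataclass(frozen=True)
class VariableSet:
    """A reusable, study-independent library of widget definitions."""

    name: str
    widgets: tuple = ()
    lookup_tables: tuple = ()

    def __post_init__(self):
        # library widgets carry no visit assignment by definition
        object.__setattr__(
            self, "widgets", tuple(replace(w, visit_ids=()) for w in self.widgets)
        )
        object.__setattr__(self, "lookup_tables", tuple(self.lookup_tables))


@dataclass(frozen=True)
class StudyMetadata:
    study_id: str
    title: str
    visits: tuple = ()
    widgets: tuple = ()
    lookup_tables: tuple = ()
    metadata_version: int = 1

    def __post_init__(self):
        object.__setattr__(self, "visits", tuple(self.visits))
        object.__setattr__(self, "widgets", tuple(self.widgets))
        object.__setattr__(self, "lookup_tables", tuple(self.lookup_tables))

    def widget_map(self) -> dict[str, WidgetDefinition]:
        return {w.variable_id: w for w in self.widgets}

    def visit_map(self) -> dict[str, VisitDefinition]:
        return {v.visit_id: v for v in self.visits}

    def lookup_map(self) -> dict[str, LookupTable]:
        return {t.lookup_table_id: t for t in self.lookup_tables}

    def visit_widgets(self, visit_id: str) -> list[WidgetDefinition]:
        """Widgets assigned to a visit, in order_index order (stable)."""
        ws = [w for w in self.widgets if visit_id in w.visit_ids]
        return sorted(ws, key=lambda w: w.order_index)

    def participant_widgets(self) -> list[WidgetDefinition]:
        ws = [w for w in self.widgets if not w.visit_ids]
        return sorted(ws, key=lambda w: w.order_index)


# ---------------------------------------------------------------------------
# validation


def _literal_type_ok(literal, input_type: str) -> bool:
    """Does a scalar comparison literal match a widget's value domain?"""
    if input_type == "integer":
        return isinstance(literal, int) and not isinstance(literal, bool)
    if input_type == "float":
        return isinstance(literal, (int, float)) and not isinstance(literal, bool)
    if input_type == "checkbox":
        return isinstance(literal, bool)
    if input_type == "date":
        if not isinstance(literal, str):
            return False
        try:
            date.fromisoformat(literal)
            return True
        except ValueError:
            return False
    if input_type == "time":
        return isinstance(literal, str) and bool(_TIME_RE.match(literal))
    # text / radio / dropdown / dropdown_search compare as strings (codes)
    return isinstance(literal, str)


def _check_condition(
    widget: WidgetDefinition, study: StudyMetadata, report: ValidationReport
) -> None:
    widgets = study.widget_map()
    if widget.variable_id not in widgets:
        widgets = dict(widgets, **{widget.variable_id: widget})

    def walk(expr: ConditionExpr) -> None:
        if not isinstance(expr, Atom):
            for child in expr.children:
                walk(child)
            return
        if expr.operator not in OPERATORS:
            report.add(widget.variable_id, "CONDITION_BAD_OPERATOR",
                       f"unknown operator {expr.operator!r}")
            return
        target = widgets.get(expr.variable_id)
        if target is None:
            report.add(widget.variable_id, "CONDITION_UNKNOWN_VAR",
                       f"condition references undefined variable {expr.variable_id!r}")
            return
        if expr.operator in NULLARY_OPERATORS:
            return
        if expr.operator in ORDERING_OPERATORS and target.input_type in (
            "checkbox", "radio", "dropdown", "dropdown_search",
        ):
            report.add(widget.variable_id, "CONDITION_TYPE_MISMATCH",
                       f"{expr.operator} not defined for {target.input_type} "
                       f"variable {expr.variable_id!r}")
            return
        if expr.operator == "in_set":
            values = expr.literal if isinstance(expr.literal, tuple) else None
            if not values or not all(_literal_type_ok(v, target.input_type) for v in values):
                report.add(widget.variable_id, "CONDITION_TYPE_MISMATCH",
                           f"in_set literal does not match {target.input_type} "
                           f"variable {expr.variable_id!r}")
            return
        if not _literal_type_ok(expr.literal, target.input_type):
            report.add(widget.variable_id, "CONDITION_TYPE_MISMATCH",
                       f"literal {expr.literal!r} does not match {target.input_type} "
                       f"variable {expr.variable_id!r}")

    if widget.condition is not None:
        walk(widget.condition)


def validate_widget_definition(
    widget: WidgetDefinition, study: StudyMetadata
) -> ValidationReport:
    """Check one widget against a (possibly partially built) study.

    All problems become report entries with machine-readable codes; nothing
    is raised. An empty report means the widget is admissible as defined.
    """
    report = ValidationReport()
    vid = widget.variable_id

    if not is_token(vid):
        report.add(vid, "BAD_VARIABLE_ID",
                   "variable_id must match [a-z][a-z0-9_]{0,63}")
    if widget.input_type not in INPUT_TYPES:
        report.add(vid, "UNKNOWN_INPUT_TYPE",
                   f"unsupported input type {widget.input_type!r}")
    others = [w for w in study.widgets if w.variable_id == vid and w is not widget]
    if others:
        report.add(vid, "DUPLICATE_ID", f"variable_id {vid!r} already defined")
    if not isinstance(widget.order_index, int) or widget.order_index < 0:
        report.add(vid, "BAD_ORDER_INDEX", "order_index must be an integer >= 0")

    visit_ids = set(study.visit_map())
    for v in widget.visit_ids:
        if v not in visit_ids:
            report.add(vid, "UNKNOWN_VISIT", f"widget assigned to unknown visit {v!r}")

    if widget.input_type in CHOICE_TYPES:
        if len(widget.choices) < 2:
            report.add(vid, "MISSING_CHOICES",
                       f"{widget.input_type} widgets need at least 2 choices")
        codes = widget.choice_codes()
        if len(set(codes)) != len(codes):
            report.add(vid, "DUPLICATE_CHOICE_CODE", "choice codes must be unique")
        for code in codes:
            if not is_token(code):
                report.add(vid, "BAD_CHOICE_CODE", f"choice code {code!r} is not a token")
        if widget.lookup_table_id is not None:
            report.add(vid, "UNEXPECTED_LOOKUP_REF",
                       f"{widget.input_type} widgets use inline choices, not lookup tables")
    elif widget.input_type == "dropdown_search":
        if widget.choices:
            report.add(vid, "UNEXPECTED_CHOICES",
                       "dropdown_search widgets use a lookup table, not inline choices")
        if widget.lookup_table_id is None:
            report.add(vid, "MISSING_LOOKUP_REF",
                       "dropdown_search widgets must reference a lookup table")
        elif widget.lookup_table_id not in study.lookup_map():
            report.add(vid, "BAD_LOOKUP_REF",
                       f"lookup table {widget.lookup_table_id!r} does not exist")
    else:
        if widget.choices:
            report.add(vid, "UNEXPECTED_CHOICES",
                       f"{widget.input_type} widgets take no choices")
        if widget.lookup_table_id is not None:
            report.add(vid, "UNEXPECTED_LOOKUP_REF",
                       f"{widget.input_type} widgets take no lookup table")

    _check_condition(widget, study, report)
    return report


def _condition_cycles(study: StudyMetadata) -> list[str]:
    """Variables participating in a cyclic visibility dependency (DFS)."""
    graph = {
        w.variable_id: sorted(referenced_variables(w.condition))
        if w.condition is not None
        else []
        for w in study.widgets
    }
    WHITE, GREY, BLACK = 0, 1, 2
    color = {v: WHITE for v in graph}
    in_cycle: list[str] = []

    def visit(node: str, stack: list[str]) -> None:
        color[node] = GREY
        stack.append(node)
        for dep in graph.get(node, []):
            if dep not in graph:
                continue
            if color[dep] == GREY:
                start = stack.index(dep)
                for member in stack[start:]:
                    if member not in in_cycle:
                        in_cycle.append(member)
            elif color[dep] == WHITE:
                visit(dep, stack)
        stack.pop()
        color[node] = BLACK

    for node in graph:
        if color[node] == WHITE:
            visit(node, [])
    return in_cycle


def validate_study_metadata(study: StudyMetadata) -> ValidationReport:
    """Whole-study closure of the per-widget checks plus global invariants."""
    report = ValidationReport()

    if not is_token(study.study_id):
        report.add(None, "BAD_STUDY_ID", "study_id must be a lowercase token")
    if study.metadata_version < 1:
        report.add(None, "BAD_METADATA_VERSION", "metadata_version must be >= 1")

    seen_visits: set[str] = set()
    seen_orders: set[int] = set()
    for visit in study.visits:
        if not is_token(visit.visit_id):
            report.add(None, "BAD_VISIT_ID", f"visit id {visit.visit_id!r} is not a token")
        if visit.visit_id in seen_visits:
            report.add(None, "DUPLICATE_VISIT_ID", f"visit {visit.visit_id!r} defined twice")
        seen_visits.add(visit.visit_id)
        if visit.order_index in seen_orders:
            report.add(None, "DUPLICATE_VISIT_ORDER",
                       f"visit order_index {visit.order_index} used twice")
        seen_orders.add(visit.order_index)

    for table in study.lookup_tables:
        if not is_token(table.lookup_table_id):
            report.add(None, "BAD_LOOKUP_ID",
                       f"lookup table id {table.lookup_table_id!r} is not a token")
        if not table.entries:
            report.add(None, "EMPTY_LOOKUP",
                       f"lookup table {table.lookup_table_id!r} has no entries")
        codes = table.codes()
        if len(set(codes)) != len(codes):
            report.add(None, "DUPLICATE_LOOKUP_CODE",
                       f"lookup table {table.lookup_table_id!r} has duplicate codes")

    seen_vars: set[str] = set()
    for widget in study.widgets:
        if widget.variable_id in seen_vars:
            report.add(widget.variable_id, "DUPLICATE_ID",
                       f"variable_id {widget.variable_id!r} defined twice")
        seen_vars.add(widget.variable_id)
        per_widget = validate_widget_definition(widget, study)
        # global duplicate pass above already covers DUPLICATE_ID
        per_widget.entries = [e for e in per_widget.entries if e.code != "DUPLICATE_ID"]
        report.extend(per_widget)

    for var in _condition_cycles(study):
        report.add(var, "CONDITION_CYCLE",
                   f"variable {var!r} participates in a cyclic visibility dependency")
    return report


# ---------------------------------------------------------------------------
# variable-set (library) import


def _free_identifier(base: str, taken: set[str]) -> str:
    if base not in taken:
        return base
    k = 2
    while True:
        candidate = f"{base[:60]}_{k}" if len(base) > 60 else f"{base}_{k}"
        if candidate not in taken:
            return candidate
        k += 1


def import_variable_set(
    vset: VariableSet,
    study: StudyMetadata,
    target_visit: str,
    mode: str = "editor",
) -> StudyMetadata:
    """Append a library's widgets to a visit, renaming colliding identifiers.

    Colliding variable_ids get deterministic ``_2``, ``_3``, ... suffixes (the
    library's internal condition references are rewritten accordingly), so a
    published set can always be merged. Returns a new metadata version.
    """
    if mode != "editor":
        raise StudyNotInEditorMode("variable sets can only be imported in editor mode")
    if target_visit not in study.visit_map():
        raise UnknownVisit(f"visit {target_visit!r} does not exist")

    taken = {w.variable_id for w in study.widgets}
    rename: dict[str, str] = {}
    for widget in vset.widgets:
        new_id = _free_identifier(widget.variable_id, taken)
        rename[widget.variable_id] = new_id
        taken.add(new_id)

    lookup_rename: dict[str, str] = {}
    new_tables = list(study.lookup_tables)
    existing = study.lookup_map()
    taken_tables = set(existing)
    for table in vset.lookup_tables:
        present = existing.get(table.lookup_table_id)
        if present is not None and present == table:
            lookup_rename[table.lookup_table_id] = table.lookup_table_id
            continue
        new_id = _free_identifier(table.lookup_table_id, taken_tables)
        lookup_rename[table.lookup_table_id] = new_id
        taken_tables.add(new_id)
        new_tables.append(replace(table, lookup_table_id=new_id))

    existing_orders = [w.order_index for w in study.widgets if target_visit in w.visit_ids]
    next_order = (max(existing_orders) + 1) if existing_orders else 0

    new_widgets = list(study.widgets)
    for offset, widget in enumerate(vset.widgets):
        new_widgets.append(
            replace(
                widget,
                variable_id=rename[widget.variable_id],
                visit_ids=(target_visit,),
                order_index=next_order + offset,
                lookup_table_id=lookup_rename.get(widget.lookup_table_id, widget.lookup_table_id)
                if widget.lookup_table_id
                else None,
                condition=rename_variables(widget.condition, rename)
                if widget.condition is not None
                else None,
            )
        )

    return replace(
        study,
        widgets=tuple(new_widgets),
        lookup_tables=tuple(new_tables),
        metadata_version=study.metadata_version + 1,
    )


# ---------------------------------------------------------------------------
# metadata bundle (zip of CSV tables)

WIDGET_COLUMNS = [
    "variable_id", "input_type", "label", "required", "visit_ids",
    "lookup_table_id", "order_index", "units", "help_text",
]
VISIT_COLUMNS = ["visit_id", "title", "order_index", "repeating", "mobile"]
CHOICE_COLUMNS = ["variable_id", "code", "label", "choice_order"]
CONDITION_COLUMNS = ["variable_id", "condition_serialized"]
LOOKUP_COLUMNS = ["code", "label"]


def _csv_bytes(columns: list[str], rows: list[list]) -> bytes:
    buf = io.StringIO(newline="")
    writer = csv.writer(buf, lineterminator="\n", quoting=csv.QUOTE_MINIMAL)
    writer.writerow(columns)
    writer.writerows(rows)
    return buf.getvalue().encode("utf-8")


def _bool_str(value: bool) -> str:
    return "true" if value else "false"


def metadata_tables(study: StudyMetadata) -> dict[str, bytes]:
    """The bundle's CSV members (without the manifest), name -> bytes."""
    visits = [
        [v.visit_id, v.title, v.order_index, _bool_str(v.repeating), _bool_str(v.mobile)]
        for v in study.visits
    ]
    widgets, choices, conditions = [], [], []
    for w in study.widgets:
        widgets.append([
            w.variable_id, w.input_type, w.label, _bool_str(w.required),
            ";".join(w.visit_ids), w.lookup_table_id or "", w.order_index,
            w.units or "", w.help_text or "",
        ])
        for idx, (code, label) in enumerate(w.choices):
            choices.append([w.variable_id, code, label, idx])
        if w.condition is not None:
            conditions.append([w.variable_id, serialize_condition(w.condition)])
    tables = {
        "visits.csv": _csv_bytes(VISIT_COLUMNS, visits),
        "widgets.csv": _csv_bytes(WIDGET_COLUMNS, widgets),
        "choices.csv": _csv_bytes(CHOICE_COLUMNS, choices),
        "conditions.csv": _csv_bytes(CONDITION_COLUMNS, conditions),
    }
    for table in study.lookup_tables:
        tables[f"lookup_tables/{table.lookup_table_id}.csv"] = _csv_bytes(
            LOOKUP_COLUMNS, [[c, l] for c, l in table.entries]
        )
    return tables


def metadata_manifest(study: StudyMetadata, timestamp: datetime) -> bytes:
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "study_id": study.study_id,
        "title": study.title,
        "metadata_version": study.metadata_version,
        "created_utc": timestamp.astimezone(timezone.utc).isoformat(),
        # list of [id, name] pairs: preserves study order under sorted JSON keys
        "lookup_tables": [[t.lookup_table_id, t.name] for t in study.lookup_tables],
    }
    return (json.dumps(manifest, indent=2, ensure_ascii=False, sort_keys=True) + "\n").encode(
        "utf-8"
    )


def write_zip(members: dict[str, bytes], timestamp: datetime) -> bytes:
    """Deterministic zip: sorted member names, fixed per-member mtime."""
    ts = timestamp.astimezone(timezone.utc)
    date_time = (ts.year, ts.month, ts.day, ts.hour, ts.minute, ts.second)
    buf = io.BytesIO()
    with zipfile.ZipFile(buf, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(members):
            info = zipfile.ZipInfo(name, date_time=date_time)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, members[name])
    return buf.getvalue()


def export_metadata(study: StudyMetadata, timestamp: datetime | None = None) -> bytes:
    """Serialize a study's metadata to a bundle (zip bytes).

    Byte content is deterministic given identical metadata and timestamp.
    """
    report = validate_study_metadata(study)
    if not report.ok:
        raise InvalidMetadata("metadata fails validation", report=report)
    if timestamp is None:
        timestamp = datetime.now(timezone.utc)
    members = metadata_tables(study)
    members["manifest.json"] = metadata_manifest(study, timestamp)
    return write_zip(members, timestamp)


def study_to_dict(study: StudyMetadata) -> dict:
    """JSON-safe representation (used to persist metadata in the audit store)."""
    return {
        "study_id": study.study_id,
        "title": study.title,
        "metadata_version": study.metadata_version,
        "visits": [
            {"visit_id": v.visit_id, "title": v.title, "order_index": v.order_index,
             "repeating": v.repeating, "mobile": v.mobile}
            for v in study.visits
        ],
        "widgets": [
            {"variable_id": w.variable_id, "input_type": w.input_type, "label": w.label,
             "required": w.required, "visit_ids": list(w.visit_ids),
             "choices": [list(c) for c in w.choices],
             "lookup_table_id": w.lookup_table_id,
             "condition": serialize_condition(w.condition) if w.condition else None,
             "order_index": w.order_index, "units": w.units, "help_text": w.help_text}
            for w in study.widgets
        ],
        "lookup_tables": [
            {"lookup_table_id": t.lookup_table_id, "name": t.name,
             "entries": [list(e) for e in t.entries]}
            for t in study.lookup_tables
        ],
    }


def study_from_dict(data: dict) -> StudyMetadata:
    return StudyMetadata(
        study_id=data["study_id"],
        title=data["title"],
        metadata_version=data["metadata_version"],
        visits=tuple(VisitDefinition(**v) for v in data["visits"]),
        widgets=tuple(
            WidgetDefinition(
                variable_id=w["variable_id"], input_type=w["input_type"],
                label=w["label"], required=w["required"],
                visit_ids=tuple(w["visit_ids"]),
                choices=tuple(tuple(c) for c in w["choices"]),
                lookup_table_id=w["lookup_table_id"],
                condition=parse_condition(w["condition"]) if w["condition"] else None,
                order_index=w["order_index"], units=w["units"],
                help_text=w["help_text"],
            )
            for w in data["widgets"]
        ),
        lookup_tables=tuple(
            LookupTable(t["lookup_table_id"], t["name"], tuple(tuple(e) for e in t["entries"]))
            for t in data["lookup_tables"]
        ),
    )


def _read_csv_member(zf: zipfile.ZipFile, name: str, columns: list[str]) -> list[dict]:
    try:
        raw = zf.read(name)
    except KeyError:
        raise MalformedBundle(f"bundle is missing {name}")
    reader = csv.reader(io.StringIO(raw.decode("utf-8"), newline=""))
    try:
        header = next(reader)
    except StopIteration:
        raise MalformedBundle(f"{name} is empty (missing header row)")
    if header != columns:
        raise MalformedBundle(f"{name} has unexpected header {header!r}")
    return [dict(zip(columns, row)) for row in reader]


def import_metadata(bundle: bytes) -> StudyMetadata:
    """Reconstruct a study from a metadata bundle (round-trip inverse of export)."""
    try:
        zf = zipfile.ZipFile(io.BytesIO(bundle))
    except zipfile.BadZipFile as exc:
        raise MalformedBundle(f"not a zip archive: {exc}") from exc
    with zf:
        try:
            manifest = json.loads(zf.read("manifest.json"))
        except KeyError:
            raise MalformedBundle("bundle is missing manifest.json")
        except json.JSONDecodeError as exc:
            raise MalformedBundle(f"manifest.json is not valid JSON: {exc}") from exc
        if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
            raise UnsupportedFormatVersion(
                f"format_version {manifest.get('format_version')!r} is not supported"
            )

        visits = tuple(
            VisitDefinition(
                visit_id=row["visit_id"],
                title=row["title"],
                order_index=int(row["order_index"]),
                repeating=row["repeating"] == "true",
                mobile=row["mobile"] == "true",
            )
            for row in _read_csv_member(zf, "visits.csv", VISIT_COLUMNS)
        )

        choice_rows = _read_csv_member(zf, "choices.csv", CHOICE_COLUMNS)
        choices_by_var: dict[str, list] = {}
        for row in choice_rows:
            choices_by_var.setdefault(row["variable_id"], []).append(row)
        for rows in choices_by_var.values():
            rows.sort(key=lambda r: int(r["choice_order"]))

        conditions: dict[str, ConditionExpr] = {}
        for row in _read_csv_member(zf, "conditions.csv", CONDITION_COLUMNS):
            try:
                conditions[row["variable_id"]] = parse_condition(row["condition_serialized"])
            except ConditionParseError as exc:
                raise MalformedBundle(
                    f"unparseable condition for {row['variable_id']!r}: {exc}"
                ) from exc

        widgets = tuple(
            WidgetDefinition(
                variable_id=row["variable_id"],
                input_type=row["input_type"],
                label=row["label"],
                required=row["required"] == "true",
                visit_ids=tuple(v for v in row["visit_ids"].split(";") if v),
                choices=tuple(
                    (r["code"], r["label"])
                    for r in choices_by_var.get(row["variable_id"], [])
                ),
                lookup_table_id=row["lookup_table_id"] or None,
                condition=conditions.get(row["variable_id"]),
                order_index=int(row["order_index"]),
                units=row["units"] or None,
                help_text=row["help_text"] or None,
            )
            for row in _read_csv_member(zf, "widgets.csv", WIDGET_COLUMNS)
        )

        tables = []
        for table_id, table_name in manifest.get("lookup_tables", []):
            rows = _read_csv_member(zf, f"lookup_tables/{table_id}.csv", LOOKUP_COLUMNS)
            tables.append(
                LookupTable(
                    lookup_table_id=table_id,
                    name=table_name,
                    entries=tuple((r["code"], r["label"]) for r in rows),
                )
            )

        study = StudyMetadata(
            study_id=manifest["study_id"],
            title=manifest["title"],
            visits=visits,
            widgets=widgets,
            lookup_tables=tuple(tables),
            metadata_version=int(manifest["metadata_version"]),
        )

    report = validate_study_metadata(study)
    if not report.ok:
        raise InvalidMetadata("imported metadata fails validation", report=report)
    return study
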