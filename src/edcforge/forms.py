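"""Form engine: abstract form rendering, value coercion, submission checks.

Everything here is a pure function of metadata and current values — no
store access, no clock, no hidden state. The engine decides which widgets
are visible (skip logic), coerces raw input strings into typed values, and
validates submissions (missing required fields, uncoercible values, values
for hidden widgets).

Canonical raw strings are the wire format throughout the system: dates are
ISO 8601 (``2024-03-01``), times 24 h ``HH:MM`` with minute precision,
booleans ``true``/``false``, floats use ``.`` as decimal separator, choice
widgets store the choice *code*. The empty string is the explicit missing
value. ``render_value`` is the inverse of ``coerce_value`` on the canonical
forms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date, time

from .conditions import Atom, AllOf, AnyOf, ConditionExpr
from .errors import CoercionFailure, UnknownVisit
from .metadata import StudyMetadata, WidgetDefinition
from .validation import ValidationReport

_INT_RE = re.compile(r"^[+-]?[0-9]+$")
_FLOAT_RE = re.compile(r"^[+-]?([0-9]+\.?[0-9]*|\.[0-9]+)([eE][+-]?[0-9]+)?$")
_TIME_RE = re.compile(r"^([01][0-9]|2[0-3]):([0-5][0-9])$")
_TRUE = frozenset({"true", "1"})
_FALSE = frozenset({"false", "0"})


def coerce_value(raw: str, widget: WidgetDefinition, study: StudyMetadata | None = None):
    """Coerce a raw input string to the widget's typed value.

    Returns ``None`` for the empty string (explicit missing). Raises
    :class:`CoercionFailure` when the string is not in the type's domain;
    submission validation converts that into a COERCION_ERROR report entry.
    ``study`` is needed only to resolve dropdown_search lookup tables.
    """
    if raw is None:
        return None
    if not isinstance(raw, str):
        raise CoercionFailure(widget.variable_id, widget.input_type, repr(raw))
    stripped = raw.strip()
    if stripped == "":
        return None
    t = widget.input_type
    if t == "text":
        return stripped
    if t == "integer":
        if not _INT_RE.match(stripped):
            raise CoercionFailure(widget.variable_id, t, raw)
        return int(stripped)
    if t == "float":
        if not _FLOAT_RE.match(stripped):
            raise CoercionFailure(widget.variable_id, t, raw)
        return float(stripped)
    if t == "checkbox":
        low = stripped.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise CoercionFailure(widget.variable_id, t, raw)
    if t == "date":
        try:
            return date.fromisoformat(stripped)
        except ValueError:
            raise CoercionFailure(widget.variable_id, t, raw) from None
    if t == "time":
        m = _TIME_RE.match(stripped)
        if not m:
            raise CoercionFailure(widget.variable_id, t, raw)
        return time(int(m.group(1)), int(m.group(2)))
    if t in ("radio", "dropdown"):
        if stripped not in widget.choice_codes():
            raise CoercionFailure(widget.variable_id, t, raw)
        return stripped
    if t == "dropdown_search":
        table = study.lookup_map().get(widget.lookup_table_id) if study else None
        if table is None or stripped not in table.codes():
            raise CoercionFailure(widget.variable_id, t, raw)
        return stripped
    raise CoercionFailure(widget.variable_id, t, raw)


def render_value(value, widget: WidgetDefinition) -> str:
    """Serialize a typed value back to its canonical raw string."""
    if value is None:
        return ""
    t = widget.input_type
    if t == "checkbox":
        return "true" if value else "false"
    if t == "date":
        return value.isoformat()
    if t == "time":
        return f"{value.hour:02d}:{value.minute:02d}"
    if t == "float":
        return repr(float(value))
    return str(value)


def _is_missing(value) -> bool:
    return value is None or value == ""


def evaluate_condition(expr: ConditionExpr, values: dict) -> bool:
    """Evaluate skip logic against typed values.

    Atoms referencing a missing or unanswered variable evaluate false,
    except ``is_empty`` which evaluates true. ``ALL()`` of nothing is true,
    ``ANY()`` of nothing is false. Pure function.
    """
    if isinstance(expr, AllOf):
        return all(evaluate_condition(c, values) for c in expr.children)
    if isinstance(expr, AnyOf):
        return any(evaluate_condition(c, values) for c in expr.children)
    assert isinstance(expr, Atom)
    value = values.get(expr.variable_id)
    missing = _is_missing(value)
    op = expr.operator
    if op == "is_empty":
        return missing
    if op == "not_empty":
        return not missing
    if missing:
        return False
    lit = expr.literal
    try:
        if op == "eq":
            return _compare_eq(value, lit)
        if op == "ne":
            return not _compare_eq(value, lit)
        if op == "in_set":
            members = lit if isinstance(lit, tuple) else (lit,)
            return any(_compare_eq(value, m) for m in members)
        if op == "lt":
            return _as_orderable(value) < _as_orderable(lit)
        if op == "le":
            return _as_orderable(value) <= _as_orderable(lit)
        if op == "gt":
            return _as_orderable(value) > _as_orderable(lit)
        if op == "ge":
            return _as_orderable(value) >= _as_orderable(lit)
    except TypeError:
        return False
    return False


def _as_orderable(value):
    # dates and times compare via their ISO strings, numbers numerically
    if isinstance(value, (date, time)):
        return value.isoformat()
    return value


def _compare_eq(value, literal) -> bool:
    if isinstance(value, (date, time)):
        return value.isoformat() == literal
    if isinstance(value, bool) or isinstance(literal, bool):
        return value is literal if isinstance(value, bool) and isinstance(literal, bool) else False
    if isinstance(value, (int, float)) and isinstance(literal, (int, float)):
        return float(value) == float(literal)
    return value == literal


def compute_visibility(widgets, typed: dict) -> dict:
    """Cascaded visibility: hidden widgets count as unanswered downstream.

    A widget hidden by skip logic has its value treated as missing when
    evaluating every other widget's condition, so hiding a controller hides
    (and later strips) its whole dependent chain — no contradictory
    skip-logic data can persist. The condition graph is acyclic (enforced by
    metadata validation), so the fixed point is unique and reached in at most
    ``len(widgets)`` rounds (almost always 2).
    """
    visible = {w.variable_id: True for w in widgets}
    effective = dict(typed)
    for _ in range(len(widgets) + 1):
        new_visible = {
            w.variable_id: (
                evaluate_condition(w.condition, effective)
                if w.condition is not None
                else True
            )
            for w in widgets
        }
        if new_visible == visible:
            break
        visible = new_visible
        effective = dict(typed)
        for w in widgets:
            if not visible[w.variable_id]:
                effective[w.variable_id] = None
    return visible


@dataclass(frozen=True)
class FormWidget:
    widget: WidgetDefinition
    current_value: str | None  # canonical raw string, None if never stored
    visible: bool


@dataclass(frozen=True)
class FormSpec:
    """Abstract rendering of one visit's form for one participant."""

    study_id: str
    visit_id: str | None  # None = the participant-centered form
    participant_id: str
    visit_instance: int
    widgets: tuple  # ordered FormWidget

    def widget_ids(self) -> list[str]:
        return [fw.widget.variable_id for fw in self.widgets]


@dataclass(frozen=True)
class Submission:
    """One flat key→raw-string entry for a participant/visit/instance."""

    participant_id: str
    visit_id: str | None
    visit_instance: int
    values: dict
    submitted_by: str = "user"
    complete_flag: bool = True


def _typed_state(study: StudyMetadata, raw_values: dict) -> dict:
    """Coerce a raw-string state map; uncoercible entries count as missing."""
    widgets = study.widget_map()
    typed: dict = {}
    for var, raw in raw_values.items():
        widget = widgets.get(var)
        if widget is None:
            continue
        try:
            typed[var] = coerce_value(raw, widget, study) if isinstance(raw, str) else raw
        except CoercionFailure:
            typed[var] = None
    return typed


def build_form_spec(
    study: StudyMetadata,
    visit_id: str | None,
    participant_state: dict,
    participant_id: str = "",
    visit_instance: int = 1,
    include_participant_centered: bool = False,
) -> FormSpec:
    """Assemble the ordered, visibility-annotated widget list for a form.

    ``visit_id=None`` requests the participant-centered form (widgets with no
    visit assignment). ``participant_state`` maps variable_id to the canonical
    raw string (union of this visit-instance's values and participant-centered
    values). Hidden widgets stay in the list with ``visible=False``.
    """
    if visit_id is None:
        widgets = study.participant_widgets()
    else:
        if visit_id not in study.visit_map():
            raise UnknownVisit(f"visit {visit_id!r} does not exist")
        widgets = study.visit_widgets(visit_id)
        if include_participant_centered:
            widgets = widgets + study.participant_widgets()
    typed = _typed_state(study, participant_state)
    visible = compute_visibility(widgets, typed)
    entries = []
    for widget in widgets:
        raw = participant_state.get(widget.variable_id)
        entries.append(FormWidget(widget, raw, visible[widget.variable_id]))
    return FormSpec(
        study_id=study.study_id,
        visit_id=visit_id,
        participant_id=participant_id,
        visit_instance=visit_instance,
        widgets=tuple(entries),
    )


def validate_submission(
    study: StudyMetadata, form: FormSpec, sub: Submission
) -> ValidationReport:
    """Check a submission against its form.

    Errors: MISSING_REQUIRED (visible required field empty while
    ``complete_flag`` is set — partial saves suspend only this check),
    COERCION_ERROR (uncoercible raw value; always checked), UNKNOWN_VARIABLE
    (key outside the form). Values supplied to hidden widgets are warnings
    (VALUE_FOR_HIDDEN) and are stripped before storage, never persisted.
    """
    report = ValidationReport()
    known = set(form.widget_ids())
    for key in sub.values:
        if key not in known:
            report.add(key, "UNKNOWN_VARIABLE", f"{key!r} is not on this form")

    # effective raw state = stored values overlaid with the submission
    effective: dict = {}
    for fw in form.widgets:
        var = fw.widget.variable_id
        if var in sub.values:
            effective[var] = sub.values[var]
        elif fw.current_value is not None:
            effective[var] = fw.current_value

    coerced_ok: dict = {}
    for fw in form.widgets:
        var = fw.widget.variable_id
        raw = effective.get(var, "")
        try:
            coerced_ok[var] = coerce_value(raw, fw.widget, study)
        except CoercionFailure as exc:
            coerced_ok[var] = None
            report.add(var, "COERCION_ERROR",
                       f"{exc.raw!r} is not a valid {exc.expected_type}")

    visibility = compute_visibility([fw.widget for fw in form.widgets], coerced_ok)
    for fw in form.widgets:
        var = fw.widget.variable_id
        visible = visibility[var]
        if not visible and var in sub.values and sub.values[var].strip() != "":
            report.warn(var, "VALUE_FOR_HIDDEN",
                        "value supplied for a hidden widget; it will be stripped")
        if (
            sub.complete_flag
            and visible
            and fw.widget.required
            and _is_missing(coerced_ok.get(var))
            and not any(e.variable_id == var and e.code == "COERCION_ERROR"
                        for e in report.entries)
        ):
            report.add(var, "MISSING_REQUIRED",
                       f"required field {var!r} is empty on a complete submission")
    return report


def clean_submission_values(
    study: StudyMetadata, form: FormSpec, sub: Submission
) -> dict:
    """Canonical values to persist: coerced, re-rendered, hidden stripped.

    Assumes the submission already validated ``ok``; uncoercible or unknown
    keys are dropped defensively.
    """
    effective: dict = {}
    for fw in form.widgets:
        var = fw.widget.variable_id
        if var in sub.values:
            effective[var] = sub.values[var]
        elif fw.current_value is not None:
            effective[var] = fw.current_value

    typed: dict = {}
    for fw in form.widgets:
        var = fw.widget.variable_id
        try:
            typed[var] = coerce_value(effective.get(var, ""), fw.widget, study)
        except CoercionFailure:
            typed[var] = None

    visibility = compute_visibility([fw.widget for fw in form.widgets], typed)
    out: dict = {}
    for fw in form.widgets:
        var = fw.widget.variable_id
        value = typed[var] if visibility[var] else None
        out[var] = render_value(value, fw.widget)
    return out
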