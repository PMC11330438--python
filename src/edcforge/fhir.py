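"""FHIR R4 import: Questionnaire → metadata, QuestionnaireResponse → entries.

The bridge reads FHIR R4 JSON from files or already-parsed dicts (transport
to a live server is the caller's concern; the testable contract is the
mapping). Item types map onto the engine's input types:

    string/text → text        integer → integer      decimal → float
    boolean → checkbox        date → date            time → time
    choice → radio (≤ 7 answerOptions) or dropdown (> 7)
    open-choice → dropdown_search backed by a lookup table built from the
    answerOptions

``enableWhen`` clauses become display-condition atoms (ALL over multiple
clauses; ``enableBehavior: any`` gives ANY). Group items are flattened with
their linkId as prefix. Unsupported item types (attachment, reference,
quantity, display, ...) are skipped with a reason. linkIds are sanitized
deterministically into the lowercase snake_case identifier charset.

Clinical data import is a validating pass-through: responses become ordinary
:class:`~edcforge.forms.Submission` objects and flow through the normal
validate/append path — the bridge never writes to the audit store directly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .conditions import AllOf, AnyOf, Atom, ConditionExpr
from .errors import MalformedResource, NotAQuestionnaire, NotDeployed, UnknownPid
from .forms import Submission, render_value
from .metadata import LookupTable, StudyMetadata, VariableSet, WidgetDefinition

RADIO_MAX_CHOICES = 7  # UI convention: few options render as radio buttons

_TYPE_MAP = {
    "string": "text",
    "text": "text",
    "integer": "integer",
    "decimal": "float",
    "boolean": "checkbox",
    "date": "date",
    "time": "time",
}
_ENABLE_OPS = {
    "=": "eq",
    "!=": "ne",
    "<": "lt",
    "<=": "le",
    ">": "gt",
    ">=": "ge",
}


@dataclass
class FhirImportReport:
    items_mapped: int = 0
    items_skipped: list = field(default_factory=list)  # (linkId/code, reason)
    warnings: list = field(default_factory=list)

    def skip(self, link_id: str, reason: str) -> None:
        self.items_skipped.append((link_id, reason))


def sanitize_link_id(link_id: str, taken: set[str] | None = None) -> str:
    """Deterministic mapping of a FHIR linkId into the identifier charset."""
    cleaned = re.sub(r"[^a-z0-9_]+", "_", str(link_id).lower()).strip("_")
    if not cleaned or not cleaned[0].isalpha():
        cleaned = f"q_{cleaned}" if cleaned else "q"
    cleaned = cleaned[:64]
    if taken is None:
        return cleaned
    base, k = cleaned, 2
    while cleaned in taken:
        suffix = f"_{k}"
        cleaned = base[: 64 - len(suffix)] + suffix
        k += 1
    return cleaned


def _load(resource) -> dict:
    if isinstance(resource, (str, bytes)):
        try:
            return json.loads(resource)
        except json.JSONDecodeError as exc:
            raise MalformedResource(f"not valid JSON: {exc}") from exc
    if isinstance(resource, dict):
        return resource
    raise MalformedResource(f"unsupported resource input {type(resource).__name__}")


def _answer_option_code(option: dict) -> tuple[str, str] | None:
    if "valueCoding" in option:
        coding = option["valueCoding"]
        code = coding.get("code")
        return (code, coding.get("display", code)) if code else None
    if "valueString" in option:
        return option["valueString"], option["valueString"]
    if "valueInteger" in option:
        return str(option["valueInteger"]), str(option["valueInteger"])
    return None


def _enable_when_literal(clause: dict, operator: str):
    for key in ("answerCoding", "answerString", "answerInteger", "answerDecimal",
                "answerBoolean", "answerDate", "answerTime"):
        if key in clause:
            value = clause[key]
            if key == "answerCoding":
                code = value.get("code")
                # choice codes are sanitized on import; compare like with like
                return sanitize_link_id(code) if code is not None else None
            return value
    if operator == "exists":
        return clause.get("answerBoolean", True)
    return None


def _enable_when_to_condition(
    clauses: list[dict], behavior: str, link_map: dict[str, str]
) -> ConditionExpr | None:
    atoms = []
    for clause in clauses:
        question = clause.get("question")
        var = link_map.get(question, sanitize_link_id(question or ""))
        op = clause.get("operator")
        if op == "exists":
            exists = clause.get("answerBoolean", True)
            atoms.append(Atom(var, "not_empty" if exists else "is_empty"))
            continue
        mapped = _ENABLE_OPS.get(op)
        if mapped is None:
            continue
        literal = _enable_when_literal(clause, op)
        if literal is None:
            continue
        atoms.append(Atom(var, mapped, literal))
    if not atoms:
        return None
    if len(atoms) == 1:
        return atoms[0]
    return AnyOf(tuple(atoms)) if behavior == "any" else AllOf(tuple(atoms))


def questionnaire_to_metadata(questionnaire) -> tuple[VariableSet, FhirImportReport]:
    """Map a FHIR Questionnaire to a reusable variable set.

    Returns the set plus a report of mapped and skipped items. Deterministic:
    the same resource bytes yield the same set and report.
    """
    resource = _load(questionnaire)
    if resource.get("resourceType") != "Questionnaire":
        raise NotAQuestionnaire(
            f"resourceType is {resource.get('resourceType')!r}, expected 'Questionnaire'"
        )
    items = resource.get("item")
    if not isinstance(items, list):
        raise MalformedResource("Questionnaire has no item list")

    report = FhirImportReport()
    widgets: list[WidgetDefinition] = []
    lookups: list[LookupTable] = []
    taken: set[str] = set()
    link_map: dict[str, str] = {}
    pending_conditions: list[tuple[int, list, str]] = []

    def walk(items: list, prefix: str) -> None:
        for item in items:
            link_id = item.get("linkId")
            if not link_id:
                raise MalformedResource("Questionnaire item without linkId")
            qualified = f"{prefix}.{link_id}" if prefix else str(link_id)
            item_type = item.get("type")
            if item_type == "group":
                walk(item.get("item", []), qualified)
                continue
            if item_type == "display":
                report.skip(qualified, "display items carry no data")
                continue
            var_id = sanitize_link_id(qualified, taken)
            input_type = None
            choices: tuple = ()
            lookup_id = None
            if item_type in _TYPE_MAP:
                input_type = _TYPE_MAP[item_type]
            elif item_type in ("choice", "open-choice"):
                options = [
                    o for o in (
                        _answer_option_code(opt) for opt in item.get("answerOption", [])
                    )
                    if o is not None
                ]
                options = [(sanitize_link_id(c), l) for c, l in options]
                if len(options) < 2:
                    report.skip(qualified, "fewer than 2 usable answerOptions")
                    continue
                if item_type == "open-choice":
                    input_type = "dropdown_search"
                    lookup_id = sanitize_link_id(f"{var_id}_options", taken | {var_id})
                    lookups.append(LookupTable(lookup_id, f"Options for {qualified}",
                                               tuple(options)))
                elif len(options) <= RADIO_MAX_CHOICES:
                    input_type = "radio"
                    choices = tuple(options)
                else:
                    input_type = "dropdown"
                    choices = tuple(options)
                    report.warnings.append(
                        f"{qualified}: {len(options)} options > {RADIO_MAX_CHOICES}, "
                        "mapped to dropdown instead of radio"
                    )
            else:
                report.skip(qualified, f"unsupported item type {item_type!r}")
                continue

            taken.add(var_id)
            if lookup_id:
                taken.add(lookup_id)
            link_map[str(link_id)] = var_id
            link_map[qualified] = var_id
            if item.get("enableWhen"):
                pending_conditions.append(
                    (len(widgets), item["enableWhen"], item.get("enableBehavior", "all"))
                )
            widgets.append(
                WidgetDefinition(
                    variable_id=var_id,
                    input_type=input_type,
                    label=item.get("text", qualified),
                    required=bool(item.get("required", False)),
                    choices=choices,
                    lookup_table_id=lookup_id,
                    order_index=len(widgets),
                )
            )
            report.items_mapped += 1

    walk(items, "")

    # enableWhen may reference later items; resolve after the full pass
    from dataclasses import replace

    for index, clauses, behavior in pending_conditions:
        condition = _enable_when_to_condition(clauses, behavior, link_map)
        if condition is not None:
            widgets[index] = replace(widgets[index], condition=condition)

    name = resource.get("title") or resource.get("name") or "FHIR questionnaire"
    return VariableSet(name=name, widgets=tuple(widgets),
                       lookup_tables=tuple(lookups)), report


# ---------------------------------------------------------------------------
# clinical data import


def _answer_raw(answer: dict, widget: WidgetDefinition) -> str | None:
    """Render a FHIR answer value[x] to the engine's canonical raw string."""
    if "valueCoding" in answer:
        code = answer["valueCoding"].get("code")
        return sanitize_link_id(code) if code is not None else None
    for key, convert in (
        ("valueString", str),
        ("valueInteger", str),
        ("valueDecimal", lambda v: repr(float(v))),
        ("valueBoolean", lambda v: "true" if v else "false"),
        ("valueDate", str),
        ("valueTime", lambda v: str(v)[:5]),  # minute precision
    ):
        if key in answer:
            return convert(answer[key])
    return None


def responses_to_records(
    bundle,
    study: StudyMetadata,
    visit_id: str,
    pid_mapping: dict[str, str],
    mode: str = "deployment",
    known_pids: set[str] | None = None,
) -> tuple[list[Submission], FhirImportReport]:
    """Map QuestionnaireResponses (or a Bundle of them) to Submissions.

    ``pid_mapping`` translates FHIR subject references to study pids. The
    returned submissions are meant to flow through the normal
    validate/record path; nothing is stored here.
    """
    if mode != "deployment":
        raise NotDeployed("clinical data can only be imported into a deployed study")
    resource = _load(bundle)
    if resource.get("resourceType") == "Bundle":
        responses = [
            entry.get("resource", {})
            for entry in resource.get("entry", [])
            if entry.get("resource", {}).get("resourceType") == "QuestionnaireResponse"
        ]
    elif resource.get("resourceType") == "QuestionnaireResponse":
        responses = [resource]
    elif isinstance(resource, dict) and "responses" in resource:
        responses = resource["responses"]
    else:
        raise MalformedResource("expected a QuestionnaireResponse or a Bundle of them")

    widgets = study.widget_map()
    report = FhirImportReport()
    submissions: list[Submission] = []

    def collect_items(items: list, out: dict) -> None:
        for item in items:
            link_id = item.get("linkId", "")
            if item.get("item"):
                collect_items(item["item"], out)
            answers = item.get("answer", [])
            if not answers:
                continue
            var_id = sanitize_link_id(link_id)
            widget = widgets.get(var_id)
            if widget is None:
                report.skip(link_id, "UNKNOWN_LINK_ID")
                continue
            raw = _answer_raw(answers[0], widget)
            if raw is None:
                report.skip(link_id, "UNSUPPORTED_VALUE_TYPE")
                continue
            if widget.input_type in ("radio", "dropdown") and raw not in widget.choice_codes():
                report.skip(link_id, "CODE_NOT_IN_CHOICES")
                continue
            if widget.input_type == "dropdown_search":
                table = study.lookup_map().get(widget.lookup_table_id)
                if table is None or raw not in table.codes():
                    report.skip(link_id, "CODE_NOT_IN_CHOICES")
                    continue
            out[var_id] = raw
            report.items_mapped += 1

    for response in responses:
        subject = (response.get("subject") or {}).get("reference", "")
        pid = pid_mapping.get(subject)
        if pid is None:
            raise UnknownPid(f"no pid mapping for subject {subject!r}")
        if known_pids is not None and pid not in known_pids:
            raise UnknownPid(f"pid {pid!r} is not included in the study")
        values: dict = {}
        collect_items(response.get("item", []), values)
        submissions.append(
            Submission(
                participant_id=pid,
                visit_id=visit_id,
                visit_instance=1,
                values=values,
                submitted_by="fhir_import",
                complete_flag=response.get("status") == "completed",
            )
        )
    return submissions, report
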