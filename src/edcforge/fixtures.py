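"""Synthetic studies and simulated data entry.

Real clinical datasets cannot ship with the package, so this module
generates structurally realistic studies — every input type, skip logic,
repeating visits, controlled vocabularies, multi-site inclusion — and
replays deterministic data-entry sessions against them (complete and
partial saves, later amendments, soft deletions). Scale parameters default
to a modest demo but go up to the workloads the engine is built for
(hundreds of variables per participant, >1,500 participants).

Everything is deterministic under a fixed seed: the RNG drives values,
record UUIDs, and a simulated millisecond clock; no ambient randomness.
Value generators draw from fixed plausible ranges (ages 0–120, lab-like
floats, a 25-code ICD-10-style vocabulary); structural coverage, not
clinical realism, is the goal.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import date, datetime, timezone

from .conditions import AllOf, Atom
from .errors import InvalidConfig
from .forms import Submission, evaluate_condition, render_value
from .lifecycle import Study
from .metadata import (
    INPUT_TYPES,
    LookupTable,
    StudyMetadata,
    VisitDefinition,
    WidgetDefinition,
)
from .store import SimClock

_WORDS = (
    "stable", "elevated", "mild", "moderate", "severe", "absent", "present",
    "improving", "unchanged", "recurrent",
)

_DIAGNOSES = (
    "Acute bleeding", "Anemia", "Asthma", "Atrial fibrillation", "Cholangitis",
    "Cirrhosis", "Colitis", "COPD", "Diabetes mellitus", "Dyspnea",
    "Embolism", "Gastritis", "Heart failure", "Hypertension", "Jaundice",
    "Melena", "Pancreatitis", "Peptic ulcer", "Pneumonia", "Renal failure",
    "Sepsis", "Syncope", "Thrombosis", "Ulcerative colitis", "Varices",
)


@dataclass(frozen=True)
class DemoConfig:
    """Shape of a generated demo study and its simulated entries."""

    seed: int = 0
    n_visits: int = 2
    n_widgets: int = 30
    type_mix: dict | None = None  # proportions over the 9 input types
    condition_density: float = 0.2
    n_participants: int = 20
    missingness: float = 0.1
    n_sites: int = 2
    site_prefix: str = "site"  # distinct per offline device to avoid pid collisions
    partial_fraction: float = 0.05  # submissions saved incomplete
    amendment_fraction: float = 0.1  # records later re-edited
    deletion_fraction: float = 0.02  # records later soft-deleted
    repeat_instance_fraction: float = 0.3  # participants with a 2nd repeating-visit instance

    def validate(self) -> None:
        if self.n_visits < 1 or self.n_widgets < 1 or self.n_participants < 0:
            raise InvalidConfig("n_visits, n_widgets >= 1 and n_participants >= 0 required")
        if self.n_sites < 1:
            raise InvalidConfig("n_sites must be >= 1")
        for name in ("condition_density", "missingness", "partial_fraction",
                     "amendment_fraction", "deletion_fraction",
                     "repeat_instance_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InvalidConfig(f"{name} must be in [0, 1]")
        if self.type_mix is not None:
            if set(self.type_mix) - set(INPUT_TYPES):
                raise InvalidConfig("type_mix keys must be input types")
            if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
                raise InvalidConfig("type_mix proportions must sum to 1")


def _demo_lookup() -> LookupTable:
    entries = tuple((f"dx_{i:02d}", _DIAGNOSES[i]) for i in range(len(_DIAGNOSES)))
    return LookupTable("icd10_mini", "Miniature ICD-10-style vocabulary", entries)


def _pick_condition(rng: random.Random, candidates: list[WidgetDefinition]):
    """An atom over one earlier widget of the same visit (acyclic by construction)."""

    def atom_for(target: WidgetDefinition) -> Atom:
        t = target.input_type
        if t in ("radio", "dropdown"):
            return Atom(target.variable_id, "eq", rng.choice(target.choice_codes()))
        if t == "checkbox":
            return Atom(target.variable_id, "eq", True)
        if t == "integer":
            return Atom(target.variable_id, "ge", rng.randint(10, 60))
        if t == "float":
            return Atom(target.variable_id, "le", float(rng.randint(40, 90)))
        return Atom(target.variable_id, "not_empty")

    first = atom_for(rng.choice(candidates))
    if len(candidates) >= 2 and rng.random() < 0.2:
        second = atom_for(rng.choice(candidates))
        return AllOf((first, second))
    return first


def generate_demo_metadata(cfg: DemoConfig) -> StudyMetadata:
    """A deterministic, always-valid demo study.

    At least one widget of every input type is present when ``n_widgets >= 9``;
    conditions only reference earlier-ordered widgets of the same visit, so
    the visibility graph is acyclic by construction. One bundled 25-code
    ICD-10-style lookup table backs the searchable dropdowns.
    """
    cfg.validate()
    rng = random.Random(cfg.seed)
    visit_names = ["baseline", "followup"] + [f"visit_{i}" for i in range(3, cfg.n_visits + 1)]
    visits = tuple(
        VisitDefinition(
            visit_id=visit_names[i],
            title=visit_names[i].replace("_", " ").title(),
            order_index=i,
            repeating=(cfg.n_visits >= 2 and i == cfg.n_visits - 1),
            mobile=(i == 0),
        )
        for i in range(cfg.n_visits)
    )

    mix = cfg.type_mix or {t: 1 / len(INPUT_TYPES) for t in INPUT_TYPES}
    types, weights = zip(*sorted(mix.items()))

    widgets = []
    per_visit: dict[str, list[WidgetDefinition]] = {v.visit_id: [] for v in visits}
    for i in range(cfg.n_widgets):
        input_type = INPUT_TYPES[i] if i < len(INPUT_TYPES) else rng.choices(types, weights)[0]
        visit = visits[i % len(visits)] if i < len(visits) * 2 else rng.choice(visits)
        choices: tuple = ()
        lookup_id = None
        if input_type in ("radio", "dropdown"):
            n = rng.randint(2, 5)
            choices = tuple((f"c{j}", f"Choice {j}") for j in range(1, n + 1))
        elif input_type == "dropdown_search":
            lookup_id = "icd10_mini"
        condition = None
        earlier = per_visit[visit.visit_id]
        if earlier and rng.random() < cfg.condition_density:
            condition = _pick_condition(rng, earlier)
        units = "years" if input_type == "integer" and rng.random() < 0.3 else None
        widget = WidgetDefinition(
            variable_id=f"var_{i:04d}",
            input_type=input_type,
            label=f"Variable {i} ({input_type})",
            required=rng.random() < 0.3,
            visit_ids=(visit.visit_id,),
            choices=choices,
            lookup_table_id=lookup_id,
            condition=condition,
            order_index=len(per_visit[visit.visit_id]),
            units=units,
            help_text=f"Synthetic demo field {i}" if rng.random() < 0.2 else None,
        )
        widgets.append(widget)
        per_visit[visit.visit_id].append(widget)

    return StudyMetadata(
        study_id="demo_study",
        title="Synthetic demo study",
        visits=visits,
        widgets=tuple(widgets),
        lookup_tables=(_demo_lookup(),),
        metadata_version=1,
    )


def _generate_value(rng: random.Random, widget: WidgetDefinition, lookup_codes: list[str]):
    t = widget.input_type
    if t == "text":
        return rng.choice(_WORDS)
    if t == "integer":
        return rng.randint(0, 120)
    if t == "float":
        return round(rng.uniform(0.0, 200.0), 1)
    if t == "checkbox":
        return rng.random() < 0.5
    if t == "date":
        return date.fromordinal(date(2023, 1, 1).toordinal() + rng.randint(0, 365))
    if t == "time":
        from datetime import time

        return time(rng.randint(0, 23), rng.randint(0, 59))
    if t in ("radio", "dropdown"):
        return rng.choice(widget.choice_codes())
    if t == "dropdown_search":
        return rng.choice(lookup_codes)
    raise InvalidConfig(f"no generator for input type {t!r}")


def _fill_visit(
    rng: random.Random,
    study_md: StudyMetadata,
    visit_id: str,
    missingness: float,
    drop_required: bool = False,
) -> dict:
    """Raw values for one visit form, respecting skip logic.

    Hidden widgets stay empty; missingness is injected only into visible
    non-required fields, so complete submissions validate by construction.
    When ``drop_required`` is set, one visible required field is left empty
    (to exercise partial saves).
    """
    lookup = study_md.lookup_map()
    typed: dict = {}
    raw: dict = {}
    required_filled: list[str] = []
    for widget in study_md.visit_widgets(visit_id):
        visible = (
            evaluate_condition(widget.condition, typed)
            if widget.condition is not None
            else True
        )
        if not visible:
            continue
        if not widget.required and rng.random() < missingness:
            continue
        codes = lookup[widget.lookup_table_id].codes() if widget.lookup_table_id else []
        value = _generate_value(rng, widget, codes)
        typed[widget.variable_id] = value
        raw[widget.variable_id] = render_value(value, widget)
        if widget.required:
            required_filled.append(widget.variable_id)
    if drop_required and required_filled:
        victim = rng.choice(required_filled)
        del raw[victim]
    return raw


@dataclass
class SimulationResult:
    study: Study
    log: list = field(default_factory=list)  # operation dicts, in order

    def coverage(self) -> dict:
        counters: dict[str, int] = {
            "include": 0, "submit_complete": 0, "submit_partial": 0,
            "amend": 0, "delete": 0, "repeat_instances": 0, "sites": 0,
        }
        sites = set()
        for op in self.log:
            kind = op["op"]
            if kind == "include":
                counters["include"] += 1
                sites.add(op["site"])
            elif kind == "submit":
                counters["submit_complete" if op["complete"] else "submit_partial"] += 1
                if op.get("instance", 1) > 1:
                    counters["repeat_instances"] += 1
            elif kind == "amend":
                counters["amend"] += 1
            elif kind == "delete":
                counters["delete"] += 1
        counters["sites"] = len(sites)
        return counters


def simulate_entries(
    study_md: StudyMetadata,
    cfg: DemoConfig,
    store_path: str = ":memory:",
    origin_id: str = "local",
    clock: SimClock | None = None,
) -> SimulationResult:
    """Deploy a fresh study and replay a deterministic data-entry session."""
    cfg.validate()
    rng = random.Random((cfg.seed * 1_000_003 + 17) % (2**31))
    clock = clock or SimClock(datetime(2024, 1, 1, 8, 0, tzinfo=timezone.utc), step_ms=750)
    study = Study.create(study_md, path=store_path, origin_id=origin_id,
                         clock=clock, rng=rng)
    log: list[dict] = []
    study.activate_deployment("sim")
    log.append({"op": "deploy"})

    sites = [f"{cfg.site_prefix}{j:02d}" for j in range(1, cfg.n_sites + 1)]
    pids = []
    for i in range(cfg.n_participants):
        site = sites[i % len(sites)]
        participant = study.include_participant(site, actor="sim")
        pids.append(participant.pid)
        log.append({"op": "include", "pid": participant.pid, "site": site})

    repeating = {v.visit_id for v in study_md.visits if v.repeating}
    amend_candidates = []
    for pid in pids:
        for visit in study_md.visits:
            instances = 1
            if visit.visit_id in repeating and rng.random() < cfg.repeat_instance_fraction:
                instances = 2
            for instance in range(1, instances + 1):
                partial = rng.random() < cfg.partial_fraction
                raw = _fill_visit(rng, study_md, visit.visit_id,
                                  cfg.missingness, drop_required=partial)
                sub = Submission(
                    participant_id=pid,
                    visit_id=visit.visit_id,
                    visit_instance=instance,
                    values=raw,
                    submitted_by="sim",
                    complete_flag=not partial,
                )
                row, report = study.record_submission(sub, actor="sim")
                if row is None:  # partial drop removed a field another depends on
                    raise AssertionError(f"generated submission rejected: {report}")
                log.append({
                    "op": "submit", "pid": pid, "visit": visit.visit_id,
                    "instance": instance, "complete": not partial,
                    "n_values": len(raw),
                })
                if not partial:
                    amend_candidates.append((pid, visit.visit_id, instance))

    n_amend = int(round(cfg.amendment_fraction * len(amend_candidates)))
    for pid, visit_id, instance in rng.sample(amend_candidates, n_amend):
        raw = _fill_visit(rng, study_md, visit_id, cfg.missingness)
        sub = Submission(pid, visit_id, instance, raw, "sim", complete_flag=True)
        row, report = study.record_submission(sub, actor="sim")
        if row is None:
            raise AssertionError(f"generated amendment rejected: {report}")
        log.append({"op": "amend", "pid": pid, "visit": visit_id, "instance": instance})

    n_delete = int(round(cfg.deletion_fraction * len(amend_candidates)))
    for pid, visit_id, instance in rng.sample(amend_candidates, n_delete):
        key_deleted = any(
            op["op"] == "delete" and (op["pid"], op["visit"], op["instance"])
            == (pid, visit_id, instance)
            for op in log
        )
        if key_deleted:
            continue
        study.delete_visit_record(pid, visit_id, instance, actor="sim")
        log.append({"op": "delete", "pid": pid, "visit": visit_id, "instance": instance})

    return SimulationResult(study=study, log=log)
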