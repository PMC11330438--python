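import random

import pytest

from edcforge import (
    DemoConfig,
    LookupTable,
    SimClock,
    Study,
    StudyMetadata,
    Submission,
    VisitDefinition,
    WidgetDefinition,
    generate_demo_metadata,
)
from edcforge.conditions import Atom


@pytest.fixture
def small_metadata() -> StudyMetadata:
    """A tiny hand-built study: 2 visits, skip logic, every reference kind."""
    return StudyMetadata(
        study_id="mini",
        title="Mini study",
        visits=(
            VisitDefinition("baseline", "Baseline", 0, repeating=False, mobile=True),
            VisitDefinition("followup", "Follow-up", 1, repeating=True),
        ),
        widgets=(
            WidgetDefinition("age", "integer", "Age", required=True,
                             visit_ids=("baseline",), order_index=0, units="years"),
            WidgetDefinition("sex", "radio", "Sex", required=True,
                             visit_ids=("baseline",),
                             choices=(("f", "Female"), ("m", "Male")), order_index=1),
            WidgetDefinition("pregnant", "checkbox", "Pregnant",
                             visit_ids=("baseline",),
                             condition=Atom("sex", "eq", "f"), order_index=2),
            WidgetDefinition("dx", "dropdown_search", "Diagnosis",
                             visit_ids=("baseline",), lookup_table_id="icd",
                             order_index=3),
            WidgetDefinition("weight", "float", "Weight", visit_ids=("followup",),
                             order_index=0, units="kg"),
            WidgetDefinition("seen_at", "time", "Seen at", visit_ids=("followup",),
                             order_index=1),
            WidgetDefinition("visit_date", "date", "Visit date",
                             visit_ids=("followup",), order_index=2),
            WidgetDefinition("notes", "text", "Notes", visit_ids=(), order_index=0),
        ),
        lookup_tables=(
            LookupTable("icd", "Diagnoses",
                        (("j45", "Asthma"), ("k92", "GI bleeding"), ("i26", "Embolism"))),
        ),
    )


@pytest.fixture
def deployed_study(small_metadata) -> Study:
    study = Study.create(
        small_metadata, clock=SimClock(step_ms=500), rng=random.Random(42)
    )
    study.activate_deployment("tester")
    return study


@pytest.fixture
def demo_config() -> DemoConfig:
    return DemoConfig(seed=7, n_widgets=30, n_visits=2, n_participants=12)


@pytest.fixture
def demo_metadata(demo_config) -> StudyMetadata:
    return generate_demo_metadata(demo_config)


def complete_baseline(study: Study, pid: str, **overrides) -> Submission:
    values = {"age": "34", "sex": "f", "pregnant": "false", "dx": "j45"}
    values.update(overrides)
    return Submission(participant_id=pid, visit_id="baseline", visit_instance=1,
                      values=values, submitted_by="tester", complete_flag=True)
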