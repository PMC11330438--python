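"""Metadata model: widget/study validation, library import, bundle round trip."""

import io
import zipfile
from dataclasses import replace
from datetime import datetime, timezone

import pytest

from edcforge import (
    DemoConfig,
    LookupTable,
    StudyMetadata,
    VariableSet,
    VisitDefinition,
    WidgetDefinition,
    export_metadata,
    generate_demo_metadata,
    import_metadata,
    import_variable_set,
    validate_study_metadata,
    validate_widget_definition,
)
from edcforge.conditions import Atom
from edcforge.errors import (
    InvalidMetadata,
    MalformedBundle,
    StudyNotInEditorMode,
    UnknownVisit,
    UnsupportedFormatVersion,
)

TS = datetime(2024, 6, 1, 12, 0, tzinfo=timezone.utc)


def _empty_study():
    return StudyMetadata("s", "S", visits=(VisitDefinition("v1", "V1", 0),))


class TestWidgetValidation:
    def test_minimal_valid_radio_widget(self, small_metadata):
        widget = WidgetDefinition("consent", "radio", "Consent?",
                                  visit_ids=("baseline",),
                                  choices=(("y", "Yes"), ("n", "No")))
        assert validate_widget_definition(widget, small_metadata).ok

    @pytest.mark.parametrize("input_type", [
        "text", "integer", "float", "checkbox", "time", "date",
    ])
    def test_all_simple_input_types_accepted(self, input_type):
        widget = WidgetDefinition("x", input_type, "X", visit_ids=("v1",))
        assert validate_widget_definition(widget, _empty_study()).ok

    @pytest.mark.parametrize("bad_type", ["dropdown-search", "slider", "TEXT", ""])
    def test_unknown_input_type_reported(self, bad_type):
        widget = WidgetDefinition("x", bad_type, "X")
        report = validate_widget_definition(widget, _empty_study())
        assert "UNKNOWN_INPUT_TYPE" in report.codes()

    def test_dropdown_search_requires_existing_lookup(self, small_metadata):
        widget = WidgetDefinition("dx2", "dropdown_search", "Dx",
                                  visit_ids=("baseline",), lookup_table_id="icd10")
        report = validate_widget_definition(widget, small_metadata)
        assert "BAD_LOOKUP_REF" in report.codes()

    @pytest.mark.parametrize("choices,code", [
        ((), "MISSING_CHOICES"),
        ((("y", "Yes"),), "MISSING_CHOICES"),
        ((("y", "Yes"), ("y", "Yep")), "DUPLICATE_CHOICE_CODE"),
    ])
    def test_choice_invariants(self, choices, code):
        widget = WidgetDefinition("x", "radio", "X", choices=choices)
        assert code in validate_widget_definition(widget, _empty_study()).codes()

    def test_plain_types_reject_choices_and_lookups(self):
        study = _empty_study()
        with_choices = WidgetDefinition("x", "integer", "X", choices=(("a", "A"), ("b", "B")))
        assert "UNEXPECTED_CHOICES" in validate_widget_definition(with_choices, study).codes()
        with_lookup = WidgetDefinition("y", "text", "Y", lookup_table_id="icd")
        assert "UNEXPECTED_LOOKUP_REF" in validate_widget_definition(with_lookup, study).codes()

    def test_condition_references_must_resolve_and_type_match(self, small_metadata):
        unknown = WidgetDefinition("w1", "text", "W",
                                   condition=Atom("ghost", "eq", "x"))
        assert "CONDITION_UNKNOWN_VAR" in validate_widget_definition(
            unknown, small_metadata).codes()
        mismatch = WidgetDefinition("w2", "text", "W",
                                    condition=Atom("age", "eq", "eighteen"))
        assert "CONDITION_TYPE_MISMATCH" in validate_widget_definition(
            mismatch, small_metadata).codes()
        ordering_on_radio = WidgetDefinition("w3", "text", "W",
                                             condition=Atom("sex", "lt", "f"))
        assert "CONDITION_TYPE_MISMATCH" in validate_widget_definition(
            ordering_on_radio, small_metadata).codes()


class TestStudyValidation:
    def test_duplicate_variable_ids_detected(self):
        study = StudyMetadata("s", "S", visits=(VisitDefinition("v1", "V", 0),),
                              widgets=(WidgetDefinition("age", "integer", "A"),
                                       WidgetDefinition("age", "text", "B")))
        assert "DUPLICATE_ID" in validate_study_metadata(study).codes()

    def test_condition_cycle_detected(self):
        study = StudyMetadata(
            "s", "S", visits=(VisitDefinition("v1", "V", 0),),
            widgets=(
                WidgetDefinition("a", "text", "A", condition=Atom("b", "not_empty")),
                WidgetDefinition("b", "text", "B", condition=Atom("a", "not_empty")),
            ),
        )
        assert "CONDITION_CYCLE" in validate_study_metadata(study).codes()

    def test_duplicate_visit_order_detected(self):
        study = StudyMetadata("s", "S", visits=(VisitDefinition("v1", "V", 0),
                                                VisitDefinition("v2", "W", 0)))
        assert "DUPLICATE_VISIT_ORDER" in validate_study_metadata(study).codes()

    @pytest.mark.parametrize("seed", [0, 1, 2, 11, 97])
    def test_generated_demo_metadata_is_always_valid(self, seed):
        metadata = generate_demo_metadata(DemoConfig(seed=seed, n_widgets=40, n_visits=3))
        assert validate_study_metadata(metadata).ok

    def test_small_fixture_is_valid(self, small_metadata):
        assert validate_study_metadata(small_metadata).ok


class TestVariableSetImport:
    def _set(self):
        return VariableSet(
            name="vitals",
            widgets=(
                WidgetDefinition("age", "integer", "Age"),
                WidgetDefinition("bp", "float", "Blood pressure",
                                 condition=Atom("age", "ge", 18)),
                WidgetDefinition("hr", "integer", "Heart rate"),
            ),
        )

    def test_import_into_empty_visit_keeps_order(self):
        study = _empty_study()
        merged = import_variable_set(self._set(), study, "v1")
        imported = merged.visit_widgets("v1")
        assert [w.variable_id for w in imported] == ["age", "bp", "hr"]
        assert [w.order_index for w in imported] == [0, 1, 2]
        assert merged.metadata_version == study.metadata_version + 1

    def test_collision_suffixes_and_condition_rewrite(self, small_metadata):
        merged = import_variable_set(self._set(), small_metadata, "baseline")
        ids = {w.variable_id for w in merged.widgets}
        assert "age_2" in ids  # "age" already defined by the host study
        bp = merged.widget_map()["bp"]
        assert bp.condition == Atom("age_2", "ge", 18)
        assert validate_study_metadata(merged).ok

    def test_double_import_stays_valid(self, small_metadata):
        once = import_variable_set(self._set(), small_metadata, "baseline")
        twice = import_variable_set(self._set(), once, "followup")
        assert validate_study_metadata(twice).ok
        ids = [w.variable_id for w in twice.widgets]
        assert len(ids) == len(set(ids))

    def test_mode_and_visit_preconditions(self, small_metadata):
        with pytest.raises(StudyNotInEditorMode):
            import_variable_set(self._set(), small_metadata, "baseline", mode="deployment")
        with pytest.raises(UnknownVisit):
            import_variable_set(self._set(), small_metadata, "nope")


class TestBundleRoundTrip:
    def test_round_trip_identity_small(self, small_metadata):
        assert import_metadata(export_metadata(small_metadata, TS)) == small_metadata

    @pytest.mark.parametrize("seed", [3, 14, 159])
    def test_round_trip_identity_generated(self, seed):
        metadata = generate_demo_metadata(DemoConfig(seed=seed, n_widgets=25, n_visits=2))
        assert import_metadata(export_metadata(metadata, TS)) == metadata

    def test_export_bytes_deterministic(self, small_metadata):
        assert export_metadata(small_metadata, TS) == export_metadata(small_metadata, TS)

    def test_empty_study_exports_header_only_tables(self):
        bundle = export_metadata(StudyMetadata("empty", "Empty"), TS)
        with zipfile.ZipFile(io.BytesIO(bundle)) as zf:
            widgets = zf.read("widgets.csv").decode().splitlines()
        assert len(widgets) == 1  # header row only
        assert import_metadata(bundle) == StudyMetadata("empty", "Empty")

    def test_condition_serialized_in_bundle(self, small_metadata):
        bundle = export_metadata(small_metadata, TS)
        with zipfile.ZipFile(io.BytesIO(bundle)) as zf:
            conditions = zf.read("conditions.csv").decode()
        assert 'pregnant,"sex eq ""f"""' in conditions  # RFC 4180 quoting

    def test_missing_table_is_malformed(self, small_metadata):
        bundle = export_metadata(small_metadata, TS)
        with zipfile.ZipFile(io.BytesIO(bundle)) as zf:
            members = {n: zf.read(n) for n in zf.namelist() if n != "widgets.csv"}
        from edcforge.metadata import write_zip

        with pytest.raises(MalformedBundle):
            import_metadata(write_zip(members, TS))

    def test_unsupported_format_version_rejected(self, small_metadata):
        import json

        bundle = export_metadata(small_metadata, TS)
        with zipfile.ZipFile(io.BytesIO(bundle)) as zf:
            members = {n: zf.read(n) for n in zf.namelist()}
        manifest = json.loads(members["manifest.json"])
        manifest["format_version"] = 99
        members["manifest.json"] = json.dumps(manifest).encode()
        from edcforge.metadata import write_zip

        with pytest.raises(UnsupportedFormatVersion):
            import_metadata(write_zip(members, TS))

    def test_dangling_condition_reference_fails_validation(self, small_metadata):
        bundle = export_metadata(small_metadata, TS)
        with zipfile.ZipFile(io.BytesIO(bundle)) as zf:
            members = {n: zf.read(n) for n in zf.namelist()}
        members["conditions.csv"] = (
            b"variable_id,condition_serialized\nnotes,ghost not_empty\n"
        )
        from edcforge.metadata import write_zip

        with pytest.raises(InvalidMetadata) as exc:
            import_metadata(write_zip(members, TS))
        assert "CONDITION_UNKNOWN_VAR" in exc.value.report.codes()

    def test_export_refuses_invalid_metadata(self):
        study = StudyMetadata("s", "S", widgets=(WidgetDefinition("a", "slider", "A"),))
        with pytest.raises(InvalidMetadata):
            export_metadata(study, TS)
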