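# edcforge

**Headless, metadata-driven electronic data capture (EDC) for clinical
studies.**

Small clinical research projects routinely fall back on spreadsheets and
paper forms because commercial EDC systems are costly to license and
open-source ones are costly to operate. `edcforge` is the engine such a
lightweight system needs, as a plain Python library plus a CLI — no web
stack, no identity provider, no vendor database:

- **Metadata-driven eCRFs.** A study is a set of *visits* (baseline,
  follow-up, repeatable interventions) and *widgets* — one input field's
  complete definition: type (text, integer, float, checkbox, time, date,
  radio, dropdown, searchable dropdown over an uploaded vocabulary such as
  an ICD-10 subset), label, requiredness, and a display condition
  (skip logic) written as `ALL(...)`/`ANY(...)` trees over comparison atoms
  like `age ge 18`. Forms are rendered abstractly from this metadata and
  submissions are validated against it.
- **Append-only auditable storage.** Every stored value-set is an immutable
  versioned row in a single-file SQL database; edits append versions,
  deletions append a flagged copy. The state of the database can be
  reconstructed for any time point (`query_as_of`), and a digest over
  pre-existing rows is invariant under every operation.
- **Two-phase lifecycle.** Metadata is authored and previewed in *editor*
  mode; activating *deployment* purges preview entries, freezes the existing
  visit definitions, and opens permanent capture. Participants are included
  under pseudonymized IDs (`{site}-{seq:04d}`), and a documentation-status
  report tracks each participant's visits as empty / partial / complete.
- **Export with an auto-generated codebook.** One zip bundle with per-visit
  tables, an aggregated wide table (one row per participant), the full
  metadata, the codebook, and the complete audit log — byte-reproducible
  given a fixed store and timestamp. CSV is canonical; XLSX is available for
  the aggregated table.
- **Offline-first merging.** Several machines can run the same study from an
  identical template without any network; their audit stores merge by union
  over device-generated UUID record identities, with strict conflict
  detection and deterministic pseudonym remapping.
- **FHIR R4 import.** Questionnaires map to reusable variable sets
  (enableWhen → skip logic, answerOptions → choices or lookup tables);
  QuestionnaireResponses become ordinary submissions that pass through the
  normal validation path.

## Worked example

```python
import random
from edcforge import (LookupTable, SimClock, Study, StudyMetadata, Submission,
                      VisitDefinition, WidgetDefinition, build_codebook,
                      write_bundle)
from edcforge.conditions import Atom

metadata = StudyMetadata(
    study_id="gi_bleed", title="GI bleeding registry",
    visits=(VisitDefinition("baseline", "Baseline", 0, mobile=True),
            VisitDefinition("intervention", "Intervention", 1, repeating=True)),
    widgets=(
        WidgetDefinition("age", "integer", "Age at admission", required=True,
                         visit_ids=("baseline",), order_index=0, units="years"),
        WidgetDefinition("sex", "radio", "Sex", required=True,
                         visit_ids=("baseline",),
                         choices=(("f", "Female"), ("m", "Male")), order_index=1),
        WidgetDefinition("pregnant", "checkbox", "Currently pregnant",
                         visit_ids=("baseline",),
                         condition=Atom("sex", "eq", "f"), order_index=2),
        WidgetDefinition("dx", "dropdown_search", "Primary diagnosis",
                         visit_ids=("baseline",), lookup_table_id="icd10",
                         order_index=3),
        WidgetDefinition("units_transfused", "integer", "Units transfused",
                         visit_ids=("intervention",), order_index=0),
    ),
    lookup_tables=(LookupTable("icd10", "ICD-10 subset",
                               (("k92_0", "Haematemesis"),
                                ("k92_1", "Melaena"),
                                ("k92_2", "GI haemorrhage, unspecified"))),),
)

study = Study.create(metadata, clock=SimClock(step_ms=500), rng=random.Random(1))
study.activate_deployment("alice")           # freezes visits, opens capture
pid = study.include_participant("muc", "alice").pid
print("included:", pid)

row, report = study.record_submission(
    Submission(pid, "baseline", 1,
               {"age": "63", "sex": "f", "pregnant": "false", "dx": "k92_1"}),
    actor="alice")
print("baseline stored as version", row.version_no, "| validation ok:", report.ok)

for instance in (1, 2):                      # a repeating visit
    study.record_submission(
        Submission(pid, "intervention", instance,
                   {"units_transfused": str(instance)}), actor="alice")

doc = study.documentation_status(pid)
for key in sorted(doc.statuses):
    print(f"status {key[0]}#{key[1]}:", doc.of(*key))
write_bundle(study.store, metadata, destination="gi_bleed.zip")
```

prints

```
included: muc-0001
baseline stored as version 1 | validation ok: True
status baseline#1: complete
status intervention#1: complete
status intervention#2: complete
```

`muc-0001` is the first pseudonym issued for site `muc`; the baseline
submission passed all metadata checks (required fields present, values
coercible, `pregnant` visible because `sex eq "f"`), so it was persisted as
version 1 of that record; both instances of the repeating intervention
visit are documented completely. `gi_bleed.zip` contains
`data/baseline.csv`, `data/intervention.csv`, `data/aggregated_wide.csv`
(with columns `intervention.1.units_transfused`,
`intervention.2.units_transfused`), the metadata tables, `codebook.csv` —
one row per widget, e.g.

```
variable_id  visit_ids  label               input_type  required  condition_serialized  choices_serialized
pregnant     baseline   Currently pregnant  checkbox    false     sex eq "f"
```

— and `audit/audit_log.csv` with every stored row version.

The same workflow is available from the shell:

```
edcforge init --study-id gi_bleed --db study.db
edcforge add-visit --visit-id baseline --title Baseline
edcforge add-widget --variable-id age --type integer --label "Age" \
    --visit baseline --required
edcforge deploy
edcforge include --site muc          # -> muc-0001
edcforge enter --pid muc-0001 --visit baseline --data entry.json
edcforge status --pid muc-0001
edcforge export --format bundle --out bundle.zip
edcforge merge deviceA.db deviceB.db --out merged.db --report report.json
```

`edcforge demo --seed 1` builds a fully synthetic study with simulated
entries (see `edcforge.fixtures`) to explore the export formats.

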