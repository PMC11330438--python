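# Methods

This note documents the model behind `edcforge`, the choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
show about real clinical data capture.

## Data model

A study's metadata is the single source of truth: a list of
`VisitDefinition`s (ordered occasions, optionally repeating per participant,
optionally served to a mobile client) and `WidgetDefinition`s. A widget owns
one variable: its identifier (lowercase snake_case, ≤ 64 chars — a charset
chosen so every exported table has safe column names in CSV, XLSX and SQL),
one of nine input types, label, requiredness, inline choices (radio,
dropdown) or a reference to an uploaded controlled vocabulary
(dropdown_search, e.g. ICD-10/ICHI/SNOMED subsets), an optional display
condition, ordering, units and help text. Widgets with no visit assignment
are *participant-centered*: data that changes independently of scheduled
visits (diagnoses, medications).

Requiredness is a widget-level property; a widget shared by several visits
is either required everywhere or nowhere. Splitting requiredness per visit
would complicate the codebook (one row per widget) for a need none of the
workflows modeled here had.

### Skip logic

Display conditions are trees of `ALL`/`ANY` combinators over atoms
`(variable, operator, literal)` with operators
`eq ne lt le gt ge in_set is_empty not_empty`. The canonical text form uses
JSON literals (`sex eq "f"`, `dx in_set ["k92_0", "k92_1"]`), making the
serialization unambiguous without any locale assumptions. Evaluation
semantics: an atom over an unanswered variable is false, except `is_empty`,
which is true; `ALL()` of nothing is true, `ANY()` of nothing is false.
Metadata validation enforces that references resolve, literal types match
the referenced widget's value domain, ordering operators are not applied to
categorical or boolean variables, and the reference graph is acyclic
(depth-first search).

Visibility is computed as a *cascaded* fixed point: a widget hidden by skip
logic counts as unanswered when every other condition is evaluated, so
hiding a controller hides its entire dependent chain. Because the graph is
acyclic the fixed point is unique and reached in at most `n` rounds
(almost always 2). Without the cascade, an amendment that blanks a
controller could leave a dependent widget's stale value stored while its
controller reads "hidden" — exactly the contradictory skip-logic state the
stripping rule exists to prevent.

### Values

Raw submissions are flat `variable_id → string` records. Canonical string
forms: ISO 8601 dates, 24-hour `HH:MM` times (minute precision — time-of-day
fields in bedside documentation do not need seconds), `true`/`false`
booleans, `.`-decimal floats (rendered via `repr`, so render→coerce is exact
for every float), choice *codes* for categorical widgets, and the empty
string as the explicit missing value. Normalizing locale input (e.g. `,`
decimals) is a UI concern, deliberately outside the engine.

Submission validation distinguishes errors from warnings. Errors
(`COERCION_ERROR`, `MISSING_REQUIRED`, `UNKNOWN_VARIABLE`) block
persistence. A partial save (`complete_flag=False`) suspends only the
required-field check — type checks always apply, so uncoercible data can
never be stored. Values supplied to hidden widgets are warnings
(`VALUE_FOR_HIDDEN`) and are stripped to missing before storage rather than
rejected: the user may legitimately have filled a field before flipping its
controller.

## Audit store

The only persistence primitive is the `AuditRow`: `(record_id UUID, version,
origin_id, actor, timestamp, deleted, payload)`. Rows are never updated or
removed; version chains grow by 1; a deletion appends a row flagged
`deleted=true` carrying an unchanged copy of the payload it deletes, so
every row is self-describing. `query_as_of(t)` returns, per record, the
highest version with timestamp ≤ t, excluded if that version is a deletion —
the database state at any past moment. Ordering authority is
`(timestamp, row_seq)`; when an offline device's clock runs backwards the
new version's timestamp is clamped to head + 1 ms and logged, which keeps
chains monotone without rejecting field data. The backing store is a
single-file sqlite database (or in-memory for transient editor previews);
the contract is engine-agnostic.

`record_id`s are device-generated UUIDv4, so independently operating devices
cannot collide — the precondition that makes offline merging a union.

## Lifecycle

Editor mode authors metadata (versioned by a monotone integer bumped on
every save) and previews forms against a throwaway in-memory store.
Activation requires clean validation, purges the preview store, freezes the
set of existing visit ids, and timestamps the deployment; only then do
`visit_data` rows reach the permanent store. Reversal to editor mode is
admin-only. After a study has ever been deployed, metadata edits must be
*additive*: frozen visits may not be changed or removed, widgets may not be
removed or retyped, choice lists may only widen. This operationalizes
integrity protection while still allowing protocol amendments (new visits,
new variables) without archiving the database.

Pseudonyms are `{site}-{seq:04d}`, sequential per site — human-readable,
mergeable, and free of identifying information by construction. The
`pid_exists` check is the entire server-side contract a mobile client needs
before opening a form.

Documentation status per (visit, instance): `empty` iff no stored non-empty
value exists, `complete` iff the last submission was flagged complete and
validated, else `partial`.

## Export

The bundle contains per-visit tables (one row per participant × instance,
current head values only), an aggregated wide table (one row per
participant; repeating visits contribute `visit.k.variable` columns with k
assigned chronologically by first submission among *surviving* records;
participant-centered variables prefixed `participant.`), the complete
metadata tables, a codebook with exactly one row per widget, and the full
audit log (payloads JSON-encoded). Deleted records appear only in the audit
log. All CSVs are RFC 4180/UTF-8/LF, quoted minimally; zip members are
written in sorted order with an injected timestamp, so identical store +
timestamp gives identical bytes. CSV is the canonical format (it preserves
all information); XLSX is offered for the aggregated table as a convenience.

## Offline merge

Merging unions rows keyed `(record_id, version_no, origin_id)` after
verifying the sources share study id and metadata version. Byte-identical
duplicates (re-merges) deduplicate silently; the same key with different
content — possible only when a seed database was duplicated — is a conflict.
The default `strict` policy aborts with a report and is idempotent,
commutative and associative on the row set; `latest_wins` keeps the later
`(timestamp, row_seq)` row and records the loser. Merged `row_seq` is
reassigned in `(timestamp, source order, original row_seq)` order.
Pseudonyms colliding across devices that shared a site prefix are remapped
deterministically (each later origin's sequence offset by a stride of
10,000, ordered by origin id) in both participant and clinical payloads, and
logged in the merge report.

## FHIR bridge

Questionnaire items map: string/text→text, integer→integer, decimal→float,
boolean→checkbox, date→date, time→time, choice→radio when ≤ 7 answerOptions
else dropdown (a UI convention; the override is recorded in the report so
importers can adjust per item), open-choice→dropdown_search with a lookup
table built from the options. `enableWhen` clauses become condition atoms
(`ALL` over clauses, `ANY` under `enableBehavior: any`; `exists` maps to
`not_empty`/`is_empty`). Groups flatten with prefixed ids; linkIds and codes
sanitize deterministically into the identifier charset. Unsupported types
(attachment, reference, quantity, display) are skipped with reasons.
Responses become ordinary `Submission`s (`status == "completed"` →
`complete_flag`) and flow through the normal validate/append path — the
bridge never writes to the store directly. Transport is the caller's
concern: the bridge reads files/bytes/dicts only.

## Synthetic fixtures

`generate_demo_metadata` emits deterministic, always-valid studies: at least
one widget of each input type (when ≥ 9 widgets), skip-logic conditions
referencing only earlier-ordered widgets of the same visit (acyclic by
construction), inline choice lists of 2–5 options, and a bundled 25-code
ICD-10-style vocabulary behind the searchable dropdowns.
`simulate_entries` deploys a fresh study and replays a seeded session:
multi-site inclusion, per-visit form filling that respects skip logic
(hidden widgets left empty; missingness injected only into visible
non-required fields so complete submissions validate by construction),
a configurable fraction of partial saves, later amendments, and soft
deletions. Time comes from a simulated clock (fixed start, fixed step) and
record UUIDs from the seeded RNG, so runs are bit-reproducible.

Default scales are modest (2 visits, 30 widgets, 20 participants); the
acceptance script and the workload-scale test run the configuration the
engine is sized for — 2 visits, 679 variables per participant and 1,700
participants across 4 sites, roughly the largest per-participant variable
count and the pooled participant count of the studies this class of system
serves. Values are drawn from fixed plausible ranges (ages 0–120, lab-like
floats, 2023 calendar dates); the generator aims at structural coverage
(every input type, conditional visibility, repeating visits, partial saves,
amendments, deletions, multi-site pseudonyms — asserted by coverage counters
on the operation log), not clinical realism. Passing tests therefore
demonstrate engine correctness under realistic *shape and volume*, not
robustness to messy real-world inputs such as free-text noise, concurrent
multi-user editing, or malformed third-party FHIR resources beyond the
handled cases.

## Numerical and degenerate-input choices

- Timestamps are UTC ISO 8601 with millisecond precision; string comparison
  equals chronological comparison by construction.
- `query_as_of` ties (same timestamp) break by `row_seq`; merged stores
  break by `(version, timestamp, row_seq)`.
- Condition evaluation never raises: incomparable operands (a type-mismatch
  that validation would have flagged) evaluate false.
- Empty studies export header-only tables; empty stores export empty data
  tables; `ALL()`/`ANY()` follow vacuous-truth conventions.
- Variable-id collisions on library import get `_2`, `_3`, … suffixes
  (truncated to stay within 64 chars) rather than being rejected, and the
  set's internal condition references are rewritten to the new names, so
  published variable sets always merge cleanly.

## Known limitations

- No cross-field arithmetic validation (range checks, sum constraints).
- Single-process writers; no concurrent multi-user transaction semantics.
- Roles are caller-supplied flat levels (user/admin); authentication and
  transport security belong to the deployment stack, not the engine.
- Observation-resource import is limited to code→variable lookup with
  value coercion; no terminology-server ValueSet expansion.
- R-specific serialization formats are not produced; CSV carries the
  complete information.
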