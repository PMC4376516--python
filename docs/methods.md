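# Methods

## The system being modelled

`cares` is a desk-scale, fully testable model of a *custodian-administered
research extract server*: the central component of a linked-data delivery
pipeline in a jurisdictional data-linkage setting.  A linkage branch creates
person-level links between administrative collections (hospital admissions,
emergency presentations, cancer and vital registries, the electoral roll)
using demographic fields; researchers receive de-identified service content
joined by project-scoped linkage keys.  Under the **separation principle**,
no party ever holds demographics and service content together: linkage staff
see demographics, researchers see keys plus content, and the extract server
sits strictly on the content side.

The package implements, as importable library modules:

- `synthetic_data` — populations, per-collection source tables, project
  keys, ground-truth fixtures, discrepancy injection, leak scanning;
- `crypto_ids` — one-way encrypted record identifiers and the escrowed
  decrypt bridge;
- `hub_store` — collection registration, loading of de-identified partial
  copies, the sender/recipient-only transfer partition, record retrieval;
- `governance` — the three-tier access framework, project workspaces and an
  append-only audit log;
- `extraction_engine` — the six-step extraction module procedure, in central
  ("cares") and per-collection fan-out ("classical") modes;
- `qa_standardisation` — canonical output rendering, layout (data
  dictionary) files and QA reports;
- `validation` — parallel-run extract comparison and cause classification;
- `metrics` — turnaround-time records, summaries and delay simulation.

`workflow` and `_dates` are internal wiring/utility modules; `cli` is a thin
command shell over the library.

## Record identifiers and the decrypt bridge

Every record loaded onto the hub is keyed by a **one-way encrypted record
ID**: HMAC-SHA256 of `collection_id|source_uid` under a 32-byte
per-collection secret, truncated to a fixed 32-hex-character token
(128 bits).  Determinism makes repeated loads converge on one hub row and
makes tokens stable across sessions; truncation to 128 bits keeps collision
probability negligible at any realistic scale (birthday bound ≈ 2⁻⁶⁴ even at
billions of records).

Loading *encrypts but never decrypts*: no hub or extraction API maps a token
back to a source UID.  The way back is an **escrowed forward mapping**
recorded at load time (the one moment token and clear UID coexist) and held
by the bridge authority.  Reversal requires *both* the escrow store and the
linkage-officer role, and every bridge call is audited.  Whether a real
deployment would use a reversible cipher instead is unobservable from the
stated behaviour; the escrow realisation reproduces exactly the observable
contract (ordinary users cannot backtrack, designated officers can) without
claiming any cryptanalytic property beyond HMAC's.

## Governance

Access to a collection for a task requires three tiers, evaluated in a fixed
order so deny reasons are deterministic:

1. a confidentiality agreement signed on or before the access date;
2. an unexpired custodian dataset grant — valid *through* `expires_on`
   inclusive, matching form-based administrative practice;
3. a custodian approval of the task's use of that collection (evidence may
   be informal and is stored with the task).

Default posture is deny; decisions are recomputed from the registry on every
check (revocation is immediate); multiple custodians per collection are
allowed.  The audit log is append-only with gap-free sequence numbers;
verification detects deletion or reordering.  Authentication checks a salted
hash in a local registry only — external authentication backends are out of
scope — and reports wrong-password and unknown-user identically.

## The extraction procedure

The engine executes, per collection: key file import → governed retrieval →
person-key append → optional transforms → standardised emission.  Decisions
worth recording:

- **Fail-closed multi-collection tasks.**  Governance is checked for every
  collection *before* any data is touched; a single denial refuses the whole
  task, because a partial extraction would silently change study scope.
- **The record token is dropped from researcher output** by default.  The
  researcher needs person-level links (the person key) and content; a
  durable record-level token would weaken the unlinked-at-rest posture.  A
  `keep_record_token` flag restores it for QA workflows.
- **Transforms are a closed language**, not a scripting hook: predicates use
  comparators {=, ≠, <, ≤, >, ≥, in-set, in-date-range} with typed
  comparison (dates as dates, integers as numbers, otherwise strings);
  derived fields are limited to arithmetic (`+ - * /`), date differences in
  days or whole years (`floor(days/365.25)`), and categorical recodes.
  Missing values satisfy **no** predicate, including `≠`, and propagate
  through derived expressions as missing.  Field maps rename in place
  (preserving column position) and may recode category levels.
- **Output ordering** is lexicographic on the rendered row (person key
  first, then content in layout order), giving reproducible byte-level
  diffs.  Steps may be given per collection or once for the whole task.

Classical mode produces the same record content but renders each
collection's file in its own date dialect, a collection-specific field order
and delimiter, with a simulated completion delay — the heterogeneous
baseline against which standardisation and the turnaround metrics are
demonstrated.

## Standardisation and QA

Canonical output is RFC-4180 CSV, UTF-8, LF, header row; dates `YYYYMMDD`;
canonical category labels; empty string for missing.  `standardise` parses
dates from a named dialect (supported: `DD/MM/YYYY`, `YYYYMMDD`,
`YYYY-MM-DD`) with strict calendar validation, and accepts already-canonical
input, making it idempotent — so for central-mode outputs it is a no-op,
which is precisely the sense in which central extraction removes
post-extraction standardisation.

"Correctness of content" is operationalised as structural checksums
(row/field/cell counts plus per-field non-null counts) recomputed from the
rendered file, together with type conformity — the strongest
content-agnostic check available at extraction time.  A "missing record" is
a key row whose record token matches nothing on the hub.  Conservation
identities (`matched + unmatched = rows_in`; per category field,
Σ level counts + missing = rows_out`) are asserted on every fixture.

## Parallel-run validation

`compare_extracts` matches rows on a composite key — by default the person
key plus all date fields, since researcher extracts carry no record token —
and diffs matched rows field by field with exact string equality (these are
administrative fields, not measurements; no tolerance is appropriate).
Duplicate keys within one input are an error rather than a guess.
`classify_discrepancies` maps each finding to a cause bucket: absent records
outside a supplied date window → *cut-off dates*; other absences → *missing
data*; field deltas → *script bugs*; anything uncovered by the taxonomy →
*other*.

## Turnaround metrics

Turnaround is elapsed calendar days from formal request to file return
(extraction level) or final dispatch (project level).  Summaries report n,
mean, Q1/median/Q3 and sample SD per group.  Quantiles use linear
interpolation between order statistics (the "type 7" convention, numpy's
default); the underlying operational data behind any published turnaround
table are not available, so matching printed quartiles is explicitly not an
objective — only the qualitative pattern is.  SD uses the n−1 denominator
and is reported as undefined for singleton groups.

Delay models: classical per-collection extraction is lognormal
(μ = ln 18, σ = 1 → mean ≈ 30 days, SD ≈ 39 days), reflecting queues with
competing priorities and a long right tail; central extraction is lognormal
(μ = ln 2, σ = 0.6 → mean ≈ 2.4 days, SD ≈ 1.6 days).  These defaults are of
the order observed in operational linkage settings (classical means of
roughly 9–38 days versus central means of ~3–4 days) and are configurable.
Project dispatch occurs when the last extraction returns, so one slow
external collection puts a floor under the whole project — the simulated
analogue of the external-collection bottleneck.

## What the synthetic generator does and does not emulate

The generator produces: placeholder demographics (word-list names and
addresses, uniform birth dates 1920–1985); per-collection inclusion by a
Bernoulli coverage draw; per-person record counts from a **zero-truncated
Poisson** with a stated mean (the rate is solved numerically from the mean;
a mean of 1 degenerates to a point mass, matching registry-style collections
which are additionally capped at one record per person); service dates
uniform over 1990–2014 rendered in each collection's input dialect; ~2%
missingness in non-date fields.  Demographic and service values are kept
textually disjoint by construction (birth years, name/token casing) so the
leak scan is exact rather than probabilistic.

Not emulated: realistic clinical content and coding systems, realistic
demographic distributions, probabilistic-linkage error (link creation is
upstream of the extract server), deletion propagation other than full
reload, and scheduling/queueing of update deliveries.  Passing tests
therefore demonstrate the *mechanics* — joins, governance, one-wayness,
standardisation, accounting identities — under controlled conditions, not
robustness to messy real-world content.

Determinism: every generator is a pure function of its parameters and a
single integer seed; sub-streams are derived by hashing the seed with a
stream label, so adding a collection does not perturb the others.

## Numerical and degenerate-input choices

- Date parsing is strict (`31/02/2010` rejects; width is enforced by
  round-trip).  Unparseable rows are rejected row-wise at load with a
  reasoned ledger; a `strict` flag aborts the load instead.
- Append-mode loads upsert on the record token with new values winning;
  rows identical to stored content are left untouched, so reloading the
  same update is byte-identical (including load-batch numbers).
- Derived-field division renders integral results as integers and
  non-integral results as shortest-repr floats; sort keys are the rendered
  strings, so ordering is platform-independent.
- Empty cohorts, empty key files, empty comparison inputs and empty metric
  groups all return empty results rather than erroring; a singleton metric
  group reports an undefined SD.

## Problem sizes used in the shipped checks

The randomised end-to-end batch runs 50 scenarios spanning cohort sizes
0–500, 1–6 collections and 0–4 transform steps; validation recall runs 30
injection trials of 1–10 drops plus 1–10 perturbations on a ~100-row
registry extract; identifier checks enumerate 10⁴ UIDs; the turnaround
simulation uses 200 extractions × 100 replicates.  These sizes exercise
every code path and boundary (zero-row collections occur naturally in the
batch) while keeping the whole suite in the tens of seconds on one CPU.

## Known limitations

- Security properties are behavioural contracts enforced by the API surface
  and tests, not OS/filesystem controls: the transfer partition and
  workspaces are access-checked objects, not real ACLs.
- The escrow bridge models observable behaviour; no claim is made about the
  real system's cipher.
- The closed transform language cannot express bespoke per-collection
  scripts; anything outside it is out of scope by design.
- Turnaround comparisons are simulation-based and qualitative; the package
  deliberately does not attempt to reproduce any published operational
  table values.
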