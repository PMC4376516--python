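# cares

A desk-scale, fully testable **custodian-administered research extract
server**: the central hub pattern for delivering linked administrative
health data to researchers without ever violating the separation principle.

## The problem

In a jurisdictional data-linkage setting, a linkage branch holds
demographics and person-level linkage keys, while service content (hospital
admissions, emergency presentations, cancer and vital registries, …) stays
with each collection's custodian.  The classical delivery model fans a
project's key files out to every participating collection, each of which
extracts its own data with its own staff, software, file formats and date
conventions — slow, unpredictable, and requiring downstream standardisation
of every heterogeneous file.

The hub model replaces that fan-out with a central server holding
*de-identified partial copies* of each collection, so one operator can run a
whole multi-collection extraction.  Privacy is preserved structurally:

- each record is keyed by a **one-way encrypted record ID**
  (HMAC-SHA256 of the collection's own UID under a per-collection secret,
  truncated to a fixed 32-hex token); loading encrypts, nothing on the hub
  decrypts, and only a linkage officer holding the escrowed mapping can
  cross back (`bridge_decrypt`);
- the hub stores **only custodian-approved fields** — no demographics, no
  clear source UIDs — and offers no person-level join: records are isolated,
  unlinked and de-identified until a project's key file is imported;
- a **three-tier governance check** (confidentiality agreement → custodian
  dataset grant, with inclusive expiry dates → per-task custodian approval)
  gates every retrieval, with a tamper-evident audit log;
- researcher outputs carry a **project-scoped person key**
  (HMAC(secret, project‖person), so two projects' extracts cannot be joined)
  and are emitted in one canonical form: RFC-4180 CSV, `YYYYMMDD` dates, a
  layout file and a QA report covering content checksums, date coverage,
  category groupings, missing values and missing records.

An extraction "module" runs six steps per collection: authenticate → import
the `cares_id,person_key` key file → retrieve matching hub records → append
person keys and drop the record token → apply optional transform steps
(field maps, filters, exclusions, derived fields from a closed predicate
language) → emit the standardised file, layout and QA summary.

Everything is driven by a synthetic-data module that generates populations,
collections (with per-collection date dialects and zero-truncated-Poisson
record multiplicity), key files and — crucially — **brute-force ground-truth
expected outputs computed independently of the engine**, so every end-to-end
run is checkable against an oracle.  A validation module replays the go-live
practice of parallel runs (central vs reference extract, field-level diff,
cause classification), and a metrics module summarises turnaround days
(mean, Q1/median/Q3, sample SD) and simulates the central-vs-classical
delay regimes with lognormal models.

## Worked example

```python
from cares import build_environment, run_module
from cares.workflow import make_project, pick_cohort

env = build_environment(seed=7, n_persons=200, collection_ids=("HMD", "EDC", "BTH"))
cohort = pick_cohort(env, 40, seed=7)
task, fixture = make_project(env, task_id="T1", project_id="ASTHMA-2013",
                             collection_ids=["HMD", "EDC", "BTH"], cohort=cohort)
outputs = run_module(env.operator_session(), task, env.hub)
for cid, out in sorted(outputs.items()):
    qa = out.qa
    print(f"{cid}: {qa.rows_in} key rows -> {qa.rows_matched} matched, "
          f"{qa.rows_out} rows out, {qa.unmatched_key_rows} missing records")
```

prints

```
BTH: 23 key rows -> 23 matched, 23 rows out, 0 missing records
EDC: 59 key rows -> 59 matched, 59 rows out, 0 missing records
HMD: 57 key rows -> 57 matched, 57 rows out, 0 missing records
```

— a 40-person cohort had 23 birth records, 59 emergency presentations and
57 admissions on the hub; every key row found its record, every output row
survived QA, and `out.records == fixture.expected_output[cid]` holds for
each collection (the engine agrees with the independent brute-force join).
The first extract rows look like

```
person_key,admission_date,separation_date,diagnosis_code,length_of_stay,hospital_type
049668c20c61042715f77ec37b71ac9f,19960528,20070602,6rtpee,277,private
```

— a project-scoped person key plus approved content only: no record token,
no source UID, no demographics.

A CLI wraps the same flows:

```bash
cares simulate --n-persons 200 --collections 3 --cohort-size 40 --seed 7 --out demo/
cares extract --dir demo/
cares compare --a demo/T7_HMD_extract.csv --b other.csv --key-fields person_key,admission_date
cares metrics --log turnaround.csv --group collection
```

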