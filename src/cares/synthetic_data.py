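"""Synthetic populations, collections, linkage keys and ground-truth fixtures.

This module stands in for the upstream world of a data-linkage branch: a
population with demographics, per-collection service-record tables (each with
its own record-UID scheme and date dialect), project-scoped person keys, and
complete project fixtures whose expected outputs are computed by an
independent brute-force join — never by the extraction engine itself.

Separation principle, enforced structurally: :class:`Person` objects (names,
birth dates, addresses) exist only here and in tests.  Nothing demographic is
ever handed to the hub; collections deliver only a record UID, an owner token
used to build linkage key files, and approved content fields.

Demographic values are deliberately disjoint from service content so that a
leak scan is exact: birth dates fall in 1920–1985 while service dates fall in
1990–2014, names are capitalised words while content text fields are lowercase
alphanumeric tokens.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import hmac
import math
import re
from dataclasses import dataclass

import numpy as np

from ._dates import DIALECTS, parse_date, parse_date_any, render_date
from .crypto_ids import CollectionKey, encrypt_id
from .errors import ConfigurationError, InvalidParameterError, SchemaError

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

FIELD_TYPES = ("text", "integer", "date", "category")

#: demographic field names that must never appear in hub-side artifacts
DEMOGRAPHIC_FIELDS = ("name", "date_of_birth", "address")


@dataclass(frozen=True)
class Person:
    """A member of the synthetic population.  Never leaves this module."""

    root_id: str
    name: str
    date_of_birth: _dt.date
    address: str


@dataclass(frozen=True)
class FieldSpec:
    name: str
    ftype: str  # one of FIELD_TYPES
    dialect: str | None = None  # required iff ftype == "date"
    levels: tuple[str, ...] | None = None  # required iff ftype == "category"

    def __post_init__(self) -> None:
        if self.ftype not in FIELD_TYPES:
            raise SchemaError(f"field {self.name!r}: unknown type {self.ftype!r}")
        if self.ftype == "date":
            if self.dialect is None:
                raise SchemaError(f"date field {self.name!r} must declare a dialect")
            if self.dialect not in DIALECTS:
                raise SchemaError(
                    f"date field {self.name!r}: unknown dialect {self.dialect!r}"
                )
        elif self.dialect is not None:
            raise SchemaError(f"non-date field {self.name!r} must not declare a dialect")
        if self.ftype == "category" and not self.levels:
            raise SchemaError(f"category field {self.name!r} must declare levels")


@dataclass(frozen=True)
class CollectionSchema:
    """Layout of one source collection and the subset approved for the hub."""

    collection_id: str
    name: str
    source_uid_field: str
    fields: tuple[FieldSpec, ...]
    approved_items: tuple[str, ...]
    max_records_per_person: int | None = None  # 1 for registry-style collections

    def __post_init__(self) -> None:
        names = [f.name for f in self.fields]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate field names in schema")
        if self.source_uid_field in self.approved_items:
            raise SchemaError(
                "source UID field may never be approved for hub storage"
            )
        unknown = set(self.approved_items) - set(names)
        if unknown:
            raise SchemaError(f"approved_items not in schema: {sorted(unknown)}")
        bad = set(DEMOGRAPHIC_FIELDS) & set(names)
        if bad:
            raise SchemaError(f"demographic fields may not appear in a schema: {sorted(bad)}")

    def field_spec(self, name: str) -> FieldSpec:
        for f in self.fields:
            if f.name == name:
                return f
        raise SchemaError(f"no field {name!r} in collection {self.collection_id}")


@dataclass(frozen=True)
class SourceRow:
    source_uid: str
    owner_root_id: str
    content: dict[str, object]


@dataclass(frozen=True)
class SourceRecordTable:
    collection_id: str
    rows: tuple[SourceRow, ...]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class InjectedChange:
    kind: str  # "drop" | "perturb"
    row_index: int
    row: dict | None = None  # the dropped row, for drops
    field: str | None = None
    old: object = None
    new: object = None


@dataclass
class ProjectFixture:
    """A complete extraction scenario plus its ground-truth expected output.

    ``expected_output`` is computed here by a literal brute-force join +
    transform + render, entirely independent of the extraction engine.
    """

    project_id: str
    cohort: set[str]
    key_files: dict[str, list]  # collection_id -> list of (cares_id, person_key)
    task: object  # an extraction_engine.ExtractionTask
    expected_output: dict[str, list[dict[str, str]]]  # collection_id -> rows


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

_FIRST_NAMES = (
    "Alex Brooke Casey Dana Evan Frances Grey Harper Indra Jules Kerry Lee "
    "Morgan Noor Owen Piper Quinn Riley Sasha Tal Uma Vesna Wren Xan Yusra Zed "
    "Ainsley Bevan Carmel Dervla Eamon Freya Gideon Halle Imre Jonty Keziah Lorcan"
).split()
_LAST_NAMES = (
    "Abbott Barnes Cole Dunne Ellis Fraser Gillan Hale Ingram Jarvis Keane "
    "Lowe Mercer Nash Ogden Pryce Quill Rhodes Slater Tobin Urwin Vance Webb "
    "Yates Zouch Ashworth Bright Carver Dalton Eastman Fenwick Garrow Hobbs"
).split()
_STREETS = (
    "Banksia Jarrah Marri Karri Wattle Boronia Tuart Sheoak Melaleuca Acacia "
    "Grevillea Hakea Quandong Mulga Saltbush Bluegum Peppermint Paperbark"
).split()
_STREET_SUFFIXES = ("St", "Rd", "Ave", "Cres", "Way")
_TOWNS = (
    "Nedlands Subiaco Fremantle Joondalup Armadale Midland Bunbury Albany "
    "Geraldton Kalgoorlie Broome Mandurah Rockingham Karratha Busselton"
).split()

# lowercase alphanumeric alphabet for content text tokens (no overlap with
# capitalised demographic words)
_TOKEN_ALPHABET = np.array(list("abcdefghijkmnpqrstuvwxyz23456789"))

_DOB_START = _dt.date(1920, 1, 1)
_DOB_END = _dt.date(1985, 12, 31)
_SERVICE_START = _dt.date(1990, 1, 1)
_SERVICE_END = _dt.date(2014, 6, 30)


def _random_date(rng: np.random.Generator, start: _dt.date, end: _dt.date) -> _dt.date:
    span = (end - start).days
    return start + _dt.timedelta(days=int(rng.integers(0, span + 1)))


def _token(rng: np.random.Generator, length: int = 6) -> str:
    return "".join(rng.choice(_TOKEN_ALPHABET, size=length))


def generate_population(n: int, seed: int) -> list[Person]:
    """Generate exactly *n* persons, deterministically for a fixed seed."""
    if n < 1:
        raise InvalidParameterError(f"population size must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    people: list[Person] = []
    for i in range(n):
        root_id = "R" + hashlib.sha256(f"pop|{seed}|{i}".encode()).hexdigest()[:12]
        name = f"{rng.choice(_FIRST_NAMES)} {rng.choice(_LAST_NAMES)}"
        dob = _random_date(rng, _DOB_START, _DOB_END)
        address = (
            f"{int(rng.integers(1, 1000))} {rng.choice(_STREETS)} "
            f"{rng.choice(_STREET_SUFFIXES)}, {rng.choice(_TOWNS)}"
        )
        people.append(Person(root_id=root_id, name=name, date_of_birth=dob, address=address))
    if len({p.root_id for p in people}) != n:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("root_id collision in generated population")
    return people


# ---------------------------------------------------------------------------
# collection generation
# ---------------------------------------------------------------------------

def _ztp_rate_for_mean(mean: float) -> float:
    """Rate λ of a zero-truncated Poisson whose mean is *mean*.

    The ZTP mean is λ/(1−e^−λ) ≥ 1; for mean → 1 the distribution degenerates
    to a point mass at 1.
    """
    if mean < 1.0:
        raise InvalidParameterError("zero-truncated Poisson mean must be >= 1")
    if mean <= 1.0 + 1e-9:
        return 0.0
    from scipy.optimize import brentq

    return float(brentq(lambda lam: lam / (1.0 - math.exp(-lam)) - mean, 1e-9, mean))


def _sample_ztp(rng: np.random.Generator, rate: float) -> int:
    if rate <= 0.0:
        return 1
    while True:  # rejection sampling; deterministic given the generator state
        k = int(rng.poisson(rate))
        if k > 0:
            return k


def generate_collection(
    population: list[Person],
    schema: CollectionSchema,
    coverage: float,
    mean_records_per_person: float,
    seed: int,
    count_distribution: str = "ztp",
    missing_rate: float = 0.02,
) -> SourceRecordTable:
    """Generate a source-side service record table.

    Each person is included with probability ``coverage``; an included person
    receives a record count drawn from a zero-truncated Poisson with the
    stated mean (``count_distribution="constant"`` forces exactly
    ``round(mean)`` records), capped by the schema's
    ``max_records_per_person``.  All date fields are rendered in the schema's
    declared input dialect; non-date fields are left blank ("missing") at
    ``missing_rate``.
    """
    if not 0.0 <= coverage <= 1.0:
        raise InvalidParameterError(f"coverage must be in [0, 1], got {coverage}")
    if mean_records_per_person <= 0:
        raise InvalidParameterError("mean_records_per_person must be positive")
    if count_distribution not in ("ztp", "constant"):
        raise InvalidParameterError(
            f"unknown count distribution {count_distribution!r}"
        )
    rng = np.random.default_rng(seed)
    include = rng.random(len(population)) < coverage
    rate = _ztp_rate_for_mean(mean_records_per_person) if count_distribution == "ztp" else 0.0

    rows: list[SourceRow] = []
    serial = 0
    for person, included in zip(population, include):
        if not included:
            continue
        if count_distribution == "constant":
            k = max(1, round(mean_records_per_person))
        else:
            k = _sample_ztp(rng, rate)
        if schema.max_records_per_person is not None:
            k = min(k, schema.max_records_per_person)
        for _ in range(k):
            serial += 1
            uid = f"{schema.collection_id}-{serial:07d}"
            content: dict[str, object] = {}
            for spec in schema.fields:
                if spec.name == schema.source_uid_field:
                    continue
                if spec.ftype != "date" and rng.random() < missing_rate:
                    content[spec.name] = ""
                    continue
                if spec.ftype == "date":
                    content[spec.name] = render_date(
                        _random_date(rng, _SERVICE_START, _SERVICE_END), spec.dialect
                    )
                elif spec.ftype == "integer":
                    content[spec.name] = int(rng.integers(0, 500))
                elif spec.ftype == "category":
                    content[spec.name] = str(rng.choice(list(spec.levels)))
                else:
                    content[spec.name] = _token(rng)
            rows.append(
                SourceRow(source_uid=uid, owner_root_id=person.root_id, content=content)
            )
    return SourceRecordTable(collection_id=schema.collection_id, rows=tuple(rows))


# ---------------------------------------------------------------------------
# project-scoped person keys
# ---------------------------------------------------------------------------

def derive_project_keys(
    cohort: set[str], project_id: str, secret: bytes
) -> dict[str, str]:
    """Keyed one-way person keys, scoped to one project.

    The same person receives different keys under different projects, so two
    projects' extracts cannot be joined on person key without the secret.
    """
    if not cohort:
        raise InvalidParameterError("cohort must be non-empty")
    if not secret:
        raise ConfigurationError("project key secret must be non-empty")
    keys = {
        root_id: hmac.new(
            secret, f"{project_id}|{root_id}".encode(), hashlib.sha256
        ).hexdigest()[:32]
        for root_id in cohort
    }
    if len(set(keys.values())) != len(keys):  # pragma: no cover
        raise RuntimeError("person-key collision within cohort")
    return keys


# ---------------------------------------------------------------------------
# brute-force oracle: expected extraction output
# ---------------------------------------------------------------------------
# Everything below re-derives the researcher-facing output from first
# principles (filter by cohort, restrict to approved items, apply transform
# steps literally, render, sort).  It deliberately shares no code with the
# extraction engine.


def _oracle_typed_value(spec: FieldSpec, raw: object):
    if raw is None or raw == "":
        return None
    if spec.ftype == "date":
        return parse_date(str(raw), spec.dialect)
    if spec.ftype == "integer":
        return int(raw)
    return str(raw)


def _oracle_literal(value, reference):
    """Coerce a predicate literal to the type of the row value it meets."""
    if isinstance(reference, _dt.date):
        return value if isinstance(value, _dt.date) else parse_date_any(str(value))
    if isinstance(reference, (int, float)) and not isinstance(reference, bool):
        return float(value)
    return str(value)


def _oracle_predicate(row: dict, params: dict) -> bool:
    v = row.get(params["field"])
    if v is None:
        return False
    op = params["op"]
    if op == "in-set":
        return v in {_oracle_literal(x, v) for x in params["value"]}
    if op == "in-date-range":
        lo, hi = params["value"]
        return _oracle_literal(lo, v) <= v <= _oracle_literal(hi, v)
    lit = _oracle_literal(params["value"], v)
    if isinstance(v, (int, float)) and not isinstance(v, _dt.date):
        v = float(v)
    if op == "=":
        return v == lit
    if op == "!=":
        return v != lit
    if op == "<":
        return v < lit
    if op == "<=":
        return v <= lit
    if op == ">":
        return v > lit
    if op == ">=":
        return v >= lit
    raise InvalidParameterError(f"unknown comparator {op!r}")


def _oracle_operand(row: dict, arg):
    if isinstance(arg, str):
        return row.get(arg)
    return arg


def _oracle_derive(row: dict, expr: dict):
    op = expr["op"]
    if op == "recode":
        v = _oracle_operand(row, expr["args"][0])
        if v is None:
            return None
        return expr["mapping"].get(v, v)
    a = _oracle_operand(row, expr["args"][0])
    b = _oracle_operand(row, expr["args"][1])
    if a is None or b is None:
        return None
    if op == "days_between":
        return (a - b).days
    if op == "years_between":
        return math.floor((a - b).days / 365.25)
    if op == "+":
        return a + b
    if op == "-":
        return a - b
    if op == "*":
        return a * b
    if op == "/":
        return a / b
    raise InvalidParameterError(f"unknown derived-field op {op!r}")


def _oracle_apply_steps(rows: list[dict], field_order: list[str], steps) -> tuple[list[dict], list[str]]:
    for step in steps:
        kind, params = step.kind, step.params
        if kind == "filter":
            rows = [r for r in rows if _oracle_predicate(r, params)]
        elif kind == "exclusion":
            rows = [r for r in rows if not _oracle_predicate(r, params)]
        elif kind == "field_map":
            src = params["field"]
            dst = params.get("rename") or src
            recode = params.get("recode")
            for r in rows:
                v = r.pop(src, None)
                if recode is not None and v in recode:
                    v = recode[v]
                r[dst] = v
            field_order = [dst if f == src else f for f in field_order]
        elif kind == "derived_field":
            name = params["name"]
            for r in rows:
                r[name] = _oracle_derive(r, params["expr"])
            field_order = field_order + [name]
        else:
            raise InvalidParameterError(f"unknown step kind {kind!r}")
    return rows, field_order


def _oracle_render(value) -> str:
    if value is None:
        return ""
    if isinstance(value, _dt.date):
        return value.strftime("%Y%m%d")
    if isinstance(value, bool):  # guard: bools are ints
        return str(int(value))
    if isinstance(value, float):
        return str(int(value)) if value.is_integer() else repr(value)
    return str(value)


def brute_force_extract(
    table: SourceRecordTable,
    schema: CollectionSchema,
    cohort: set[str],
    person_keys: dict[str, str],
    steps,
    keep_record_token: bool = False,
    collection_key: CollectionKey | None = None,
) -> list[dict[str, str]]:
    """Ground-truth researcher output for one collection, by literal join."""
    rows: list[dict] = []
    for src in table.rows:
        if src.owner_root_id not in cohort:
            continue
        row: dict[str, object] = {"person_key": person_keys[src.owner_root_id]}
        if keep_record_token:
            row["cares_id"] = encrypt_id(
                schema.collection_id, src.source_uid, collection_key
            ).value
        for name in schema.approved_items:
            row[name] = _oracle_typed_value(schema.field_spec(name), src.content.get(name))
        rows.append(row)
    field_order = ["person_key"] + (["cares_id"] if keep_record_token else []) + list(
        schema.approved_items
    )
    rows, field_order = _oracle_apply_steps(rows, field_order, steps)
    rendered = [
        {name: _oracle_render(r.get(name)) for name in field_order} for r in rows
    ]
    rendered.sort(key=lambda r: tuple(r[name] for name in field_order))
    return rendered


def build_fixture(
    population: list[Person],
    collections: dict[str, tuple[CollectionSchema, SourceRecordTable]],
    cohort: set[str],
    task_config,
    seed: int = 0,
    *,
    collection_keys: dict[str, CollectionKey],
    project_secret: bytes,
) -> ProjectFixture:
    """Assemble key files and independent expected outputs for a task.

    The key files pair the hub's CARES IDs (computed with the collection
    keys, as a linkage officer would) with project person keys — one row per
    (cohort person, matching record).  ``expected_output`` comes from
    :func:`brute_force_extract`, never from the extraction engine.
    """
    pop_ids = {p.root_id for p in population}
    if not cohort <= pop_ids:
        raise InvalidParameterError("cohort contains root_ids outside the population")
    for cid in task_config.collection_ids:
        if cid not in collections:
            raise ConfigurationError(f"task references unregistered collection {cid!r}")

    person_keys = (
        derive_project_keys(cohort, task_config.project_id, project_secret)
        if cohort
        else {}
    )
    key_files: dict[str, list] = {}
    expected: dict[str, list[dict[str, str]]] = {}
    for cid in task_config.collection_ids:
        schema, table = collections[cid]
        key = collection_keys[cid]
        pairs = [
            (encrypt_id(cid, src.source_uid, key).value, person_keys[src.owner_root_id])
            for src in table.rows
            if src.owner_root_id in cohort
        ]
        pairs.sort()
        key_files[cid] = pairs
        expected[cid] = brute_force_extract(
            table,
            schema,
            cohort,
            person_keys,
            task_config.steps_for(cid),
            keep_record_token=getattr(task_config, "keep_record_token", False),
            collection_key=key,
        )
    return ProjectFixture(
        project_id=task_config.project_id,
        cohort=set(cohort),
        key_files=key_files,
        task=task_config,
        expected_output=expected,
    )


# ---------------------------------------------------------------------------
# discrepancy injection (for parallel-run validation)
# ---------------------------------------------------------------------------

def inject_discrepancies(
    table: list[dict],
    n_drop: int,
    n_perturb: int,
    seed: int,
    key_fields: tuple[str, ...] = (),
) -> tuple[list[dict], list[InjectedChange]]:
    """Remove ``n_drop`` rows and alter exactly one non-key field in each of
    ``n_perturb`` other rows; return the perturbed table and a full ledger.

    Replaying the ledger against the original (:func:`replay_ledger`)
    reproduces the perturbed table exactly.
    """
    if n_drop < 0 or n_perturb < 0:
        raise InvalidParameterError("drop/perturb counts must be non-negative")
    if n_drop + n_perturb > len(table):
        raise InvalidParameterError(
            f"cannot alter {n_drop + n_perturb} rows of a {len(table)}-row table"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(table), size=n_drop + n_perturb, replace=False)
    drop_idx = set(int(i) for i in chosen[:n_drop])
    perturb_idx = [int(i) for i in chosen[n_drop:]]

    ledger: list[InjectedChange] = []
    perturbations: dict[int, tuple[str, str, str]] = {}
    for i in sorted(perturb_idx):
        row = table[i]
        mutable = [f for f in row if f not in key_fields]
        if not mutable:
            raise InvalidParameterError("row has no non-key field to perturb")
        fname = str(rng.choice(mutable))
        old = row[fname]
        new = (str(old) + "~") if str(old) else "x"
        perturbations[i] = (fname, old, new)
        ledger.append(
            InjectedChange(kind="perturb", row_index=i, field=fname, old=old, new=new)
        )
    for i in sorted(drop_idx):
        ledger.append(InjectedChange(kind="drop", row_index=i, row=dict(table[i])))

    out: list[dict] = []
    for i, row in enumerate(table):
        if i in drop_idx:
            continue
        if i in perturbations:
            fname, _, new = perturbations[i]
            row = {**row, fname: new}
        out.append(dict(row))
    return out, ledger


def replay_ledger(original: list[dict], ledger: list[InjectedChange]) -> list[dict]:
    """Apply an injection ledger to the original table."""
    drops = {c.row_index for c in ledger if c.kind == "drop"}
    perturbs = {c.row_index: c for c in ledger if c.kind == "perturb"}
    out = []
    for i, row in enumerate(original):
        if i in drops:
            continue
        if i in perturbs:
            c = perturbs[i]
            row = {**row, c.field: c.new}
        out.append(dict(row))
    return out


# ---------------------------------------------------------------------------
# separation-principle leak scanning
# ---------------------------------------------------------------------------

def find_identifier_leaks(
    artifacts: dict[str, str],
    population: list[Person],
    source_tables: list[SourceRecordTable] = (),
) -> list[tuple[str, str, str]]:
    """Scan artifact texts for any demographic value, root_id or source UID.

    ``artifacts`` maps an artifact label to its full text.  Returns a list of
    (artifact label, kind, leaked value) hits; an empty list means the
    separation principle held.
    """
    needles: list[tuple[str, str]] = []
    for p in population:
        needles.append(("name", p.name))
        needles.append(("address", p.address))
        needles.append(("root_id", p.root_id))
        for dialect in DIALECTS:
            needles.append(("date_of_birth", render_date(p.date_of_birth, dialect)))
        needles.append(("date_of_birth", p.date_of_birth.isoformat()))
    for table in source_tables:
        for row in table.rows:
            needles.append(("source_uid", row.source_uid))
    field_patterns = [
        (f"field:{f}", re.compile(rf"\b{f}\b")) for f in DEMOGRAPHIC_FIELDS
    ]

    hits: list[tuple[str, str, str]] = []
    for label, text in artifacts.items():
        for kind, value in needles:
            if value in text:
                hits.append((label, kind, value))
        for kind, pattern in field_patterns:
            if pattern.search(text):
                hits.append((label, kind, pattern.pattern))
    return hits


# ---------------------------------------------------------------------------
# stock schemas (a realistic mix of admission-style and registry-style sets)
# ---------------------------------------------------------------------------

def default_schemas() -> dict[str, CollectionSchema]:
    """Six collections emulating a state linkage environment: repeated-event
    sets (hospital, emergency), registries capped at one record per person
    (births, deaths), and low-multiplicity sets (cancer, electoral roll).
    Date dialects deliberately differ across collections."""
    schemas = [
        CollectionSchema(
            collection_id="HMD",
            name="Hospital Morbidity",
            source_uid_field="hmd_uid",
            fields=(
                FieldSpec("admission_date", "date", dialect="DD/MM/YYYY"),
                FieldSpec("separation_date", "date", dialect="DD/MM/YYYY"),
                FieldSpec("diagnosis_code", "text"),
                FieldSpec("length_of_stay", "integer"),
                FieldSpec("hospital_type", "category", levels=("metro", "rural", "private")),
            ),
            approved_items=(
                "admission_date",
                "separation_date",
                "diagnosis_code",
                "length_of_stay",
                "hospital_type",
            ),
        ),
        CollectionSchema(
            collection_id="EDC",
            name="Emergency Department",
            source_uid_field="edc_uid",
            fields=(
                FieldSpec("presentation_date", "date", dialect="YYYYMMDD"),
                FieldSpec("triage_category", "category", levels=("1", "2", "3", "4", "5")),
                FieldSpec("disposition", "category", levels=("admitted", "discharged", "transferred")),
            ),
            approved_items=("presentation_date", "triage_category", "disposition"),
        ),
        CollectionSchema(
            collection_id="CAN",
            name="Cancer Registry",
            source_uid_field="can_uid",
            fields=(
                FieldSpec("diagnosis_date", "date", dialect="YYYY-MM-DD"),
                FieldSpec("site_code", "text"),
                FieldSpec("laterality", "category", levels=("left", "right", "bilateral", "unknown")),
            ),
            approved_items=("diagnosis_date", "site_code", "laterality"),
            max_records_per_person=3,
        ),
        CollectionSchema(
            collection_id="BTH",
            name="Birth Registrations",
            source_uid_field="bth_uid",
            fields=(
                FieldSpec("event_date", "date", dialect="DD/MM/YYYY"),
                FieldSpec("plurality", "category", levels=("singleton", "twin", "higher")),
                FieldSpec("birth_weight_g", "integer"),
            ),
            approved_items=("event_date", "plurality", "birth_weight_g"),
            max_records_per_person=1,
        ),
        CollectionSchema(
            collection_id="DTH",
            name="Death Registrations",
            source_uid_field="dth_uid",
            fields=(
                FieldSpec("death_date", "date", dialect="YYYYMMDD"),
                FieldSpec("cause_code", "text"),
            ),
            approved_items=("death_date", "cause_code"),
            max_records_per_person=1,
        ),
        CollectionSchema(
            collection_id="ELC",
            name="Electoral Roll",
            source_uid_field="elc_uid",
            fields=(
                FieldSpec("enrolment_date", "date", dialect="YYYY-MM-DD"),
                FieldSpec("electorate", "category", levels=("swan", "curtin", "perth", "forrest")),
            ),
            approved_items=("enrolment_date", "electorate"),
            max_records_per_person=2,
        ),
    ]
    return {s.collection_id: s for s in schemas}
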