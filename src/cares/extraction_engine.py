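"""The six-step extraction "module" procedure, central and classical modes.

Each registered collection is handled by the same scripted procedure:

1. authenticate the operator against the local registry;
2. import the project's linkage key file (CARES ID, person key pairs);
3. retrieve the matching records from the hub (three-tier governance check
   first — a task touching several collections is refused outright if *any*
   of them is denied);
4. append the person key to each retrieved record and drop the CARES ID from
   the researcher-facing output (kept only under an explicit
   ``keep_record_token`` flag for QA workflows);
5. apply the task's optional transform steps — field mapping, filtering,
   exclusions, derived fields — in listed order;
6. emit the standardised file, its layout file and a QA summary.

``run_classical`` produces the same record content but renders each
collection's file in that collection's own dialect (its date format, a
collection-specific field order and delimiter) with a simulated
per-collection completion delay — the heterogeneous baseline that
standardisation and the turnaround metrics are demonstrated against.
"""

from __future__ import annotations

import csv
import datetime as _dt
import hashlib
import io
import math
import os
from dataclasses import dataclass, field

import numpy as np

from ._dates import parse_date_any, render_date
from .errors import (
    AuthorisationError,
    InvalidParameterError,
    KeyfileError,
    TaskError,
)
from .governance import GovernanceRegistry, authenticate_user
from .hub_store import Hub, ServiceRecord
from .qa_standardisation import (
    ExtractOutput,
    make_layout,
    qa_report,
    records_to_csv,
    standardise,
)

COMPARATORS = ("=", "!=", "<", "<=", ">", ">=", "in-set", "in-date-range")
STEP_KINDS = ("field_map", "filter", "exclusion", "derived_field")
DERIVED_OPS = ("+", "-", "*", "/", "days_between", "years_between", "recode")


@dataclass(frozen=True)
class LinkageKeyRow:
    cares_id: str  # 32-hex token
    person_key: str


@dataclass
class ImportReport:
    n_rows: int = 0
    n_duplicates: int = 0
    n_malformed: int = 0
    malformed: list[tuple[int, str]] = field(default_factory=list)


@dataclass(frozen=True)
class TransformStep:
    """One optional processing step; the predicate/expression language is a
    small closed set, fully enumerated in COMPARATORS and DERIVED_OPS."""

    kind: str
    params: dict

    def __post_init__(self) -> None:
        if self.kind not in STEP_KINDS:
            raise InvalidParameterError(f"unknown step kind {self.kind!r}")
        if self.kind in ("filter", "exclusion"):
            if self.params.get("op") not in COMPARATORS:
                raise InvalidParameterError(
                    f"unknown comparator {self.params.get('op')!r}"
                )
            if "field" not in self.params or "value" not in self.params:
                raise InvalidParameterError("predicate needs 'field' and 'value'")
        elif self.kind == "field_map":
            if "field" not in self.params:
                raise InvalidParameterError("field_map needs 'field'")
        else:  # derived_field
            expr = self.params.get("expr", {})
            if "name" not in self.params or expr.get("op") not in DERIVED_OPS:
                raise InvalidParameterError("derived_field needs 'name' and a known op")


@dataclass
class ExtractionTask:
    """A project's extraction request.

    ``steps`` may be a single list (applied to every collection) or a
    mapping collection_id -> list, since in practice each collection's
    module carries its own standard processing.
    """

    task_id: str
    project_id: str
    collection_ids: list[str]
    key_files: dict[str, object]  # collection_id -> path or CSV text
    steps: object = ()
    requested_on: _dt.date = _dt.date(2013, 1, 1)
    completed_on: _dt.date | None = None
    mode: str = "cares"
    date_window: tuple | None = None  # (start, end) inclusive, for QA
    keep_record_token: bool = False

    def __post_init__(self) -> None:
        if self.completed_on is not None and self.completed_on < self.requested_on:
            raise InvalidParameterError("completed_on precedes requested_on")

    def steps_for(self, collection_id: str) -> list[TransformStep]:
        if isinstance(self.steps, dict):
            return list(self.steps.get(collection_id, ()))
        return list(self.steps)


@dataclass(frozen=True)
class Session:
    user_id: str
    started: _dt.datetime


@dataclass
class ClassicalOutput:
    """One collection's file as the collection itself would deliver it."""

    collection_id: str
    records: list[dict[str, str]]  # dialect-rendered, collection field order
    field_order: list[str]
    dialect: str
    delimiter: str
    file_text: str
    completed_on: _dt.date


# ---------------------------------------------------------------------------
# step 1: authentication
# ---------------------------------------------------------------------------

def authenticate(registry: GovernanceRegistry, user_id: str, password: str) -> Session:
    """Verify operator credentials; failures are audited and the error does
    not reveal whether the user exists."""
    user = authenticate_user(registry, user_id, password)
    return Session(user_id=user.user_id, started=_dt.datetime.now(_dt.timezone.utc))


# ---------------------------------------------------------------------------
# step 2: key file import
# ---------------------------------------------------------------------------

def import_keyfile(source) -> tuple[list[LinkageKeyRow], ImportReport]:
    """Parse and validate a two-column ``cares_id,person_key`` CSV.

    Exact duplicate rows are dropped with a warning count; malformed rows go
    to the report; a CARES ID mapped to two *different* person keys is an
    ambiguous identity and aborts the import naming the id.
    """
    if isinstance(source, (list, tuple)):
        text = "cares_id,person_key\n" + "".join(
            f"{a},{b}\n" for a, b in source
        )
    elif isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = str(source)

    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise KeyfileError("key file is empty (header row required)") from None
    if [h.strip() for h in header] != ["cares_id", "person_key"]:
        raise KeyfileError(f"bad key file header {header!r}")

    report = ImportReport()
    seen: dict[tuple[str, str], bool] = {}
    by_id: dict[str, str] = {}
    rows: list[LinkageKeyRow] = []
    for lineno, parts in enumerate(reader, start=2):
        if not parts:
            continue
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            report.n_malformed += 1
            report.malformed.append((lineno, f"malformed row {parts!r}"))
            continue
        cares_id, person_key = parts[0].strip(), parts[1].strip()
        if cares_id in by_id and by_id[cares_id] != person_key:
            raise KeyfileError(
                f"ambiguous identity: CARES ID {cares_id} maps to two person keys"
            )
        by_id[cares_id] = person_key
        if (cares_id, person_key) in seen:
            report.n_duplicates += 1
            continue
        seen[(cares_id, person_key)] = True
        rows.append(LinkageKeyRow(cares_id=cares_id, person_key=person_key))
    report.n_rows = len(rows)
    return rows, report


# ---------------------------------------------------------------------------
# step 5: the transform interpreter
# ---------------------------------------------------------------------------

def _literal(value, reference):
    if isinstance(reference, _dt.date):
        return value if isinstance(value, _dt.date) else parse_date_any(str(value))
    if isinstance(reference, (int, float)) and not isinstance(reference, bool):
        return float(value)
    return str(value)


def _predicate(row: dict, params: dict) -> bool:
    """Missing values satisfy no predicate (including '!=')."""
    v = row.get(params["field"])
    if v is None:
        return False
    op = params["op"]
    if op == "in-set":
        return v in {_literal(x, v) for x in params["value"]}
    if op == "in-date-range":
        lo, hi = params["value"]
        return _literal(lo, v) <= v <= _literal(hi, v)
    lit = _literal(params["value"], v)
    if isinstance(v, (int, float)) and not isinstance(v, _dt.date):
        v = float(v)
    return {
        "=": v == lit,
        "!=": v != lit,
        "<": v < lit,
        "<=": v <= lit,
        ">": v > lit,
        ">=": v >= lit,
    }[op]


def _evaluate_expr(row: dict, expr: dict):
    op = expr["op"]
    if op == "recode":
        v = row.get(expr["args"][0]) if isinstance(expr["args"][0], str) else expr["args"][0]
        return None if v is None else expr["mapping"].get(v, v)
    operands = [
        row.get(a) if isinstance(a, str) else a for a in expr["args"]
    ]
    if any(o is None for o in operands):
        return None
    a, b = operands
    if op == "days_between":
        return (a - b).days
    if op == "years_between":
        return math.floor((a - b).days / 365.25)
    return {"+": a + b, "-": a - b, "*": a * b, "/": a / b}[op]


def apply_steps(
    rows: list[dict], field_order: list[str], steps: list[TransformStep]
) -> tuple[list[dict], list[str]]:
    """Apply transform steps in listed order to typed rows.

    A step referencing a field absent at that point in the pipeline raises
    :class:`TaskError` naming the step index.
    """
    fields = list(field_order)
    for index, step in enumerate(steps):
        referenced = []
        if step.kind in ("filter", "exclusion", "field_map"):
            referenced = [step.params["field"]]
        elif step.kind == "derived_field":
            expr = step.params["expr"]
            referenced = [a for a in expr["args"] if isinstance(a, str)]
        missing = [f for f in referenced if f not in fields]
        if missing:
            raise TaskError(
                f"step {index} ({step.kind}) references missing field(s) {missing}"
            )
        if step.kind == "filter":
            rows = [r for r in rows if _predicate(r, step.params)]
        elif step.kind == "exclusion":
            rows = [r for r in rows if not _predicate(r, step.params)]
        elif step.kind == "field_map":
            src = step.params["field"]
            dst = step.params.get("rename") or src
            recode = step.params.get("recode")
            for r in rows:
                v = r.pop(src, None)
                if recode is not None and v in recode:
                    v = recode[v]
                r[dst] = v
            fields = [dst if f == src else f for f in fields]
        else:
            name = step.params["name"]
            for r in rows:
                r[name] = _evaluate_expr(r, step.params["expr"])
            fields = fields + [name]
    return rows, fields


# ---------------------------------------------------------------------------
# steps 3-6: the module run
# ---------------------------------------------------------------------------

def _retrieve_typed_rows(
    session: Session,
    task: ExtractionTask,
    hub: Hub,
    collection_id: str,
) -> tuple[list[dict], list[LinkageKeyRow], list[ServiceRecord], ImportReport]:
    key_rows, report = import_keyfile(task.key_files[collection_id])
    records, _unmatched = hub.query_records(
        session.user_id,
        collection_id,
        [k.cares_id for k in key_rows],
        governance_ctx=(task.task_id, task.requested_on),
    )
    person_key_of = {k.cares_id: k.person_key for k in key_rows}
    rows: list[dict] = []
    for record in records:
        row: dict = {"person_key": person_key_of[record.cares_id.value]}
        if task.keep_record_token:
            row["cares_id"] = record.cares_id.value
        row.update(record.content)
        rows.append(row)
    return rows, key_rows, records, report


def run_module(
    session: Session,
    task: ExtractionTask,
    hub: Hub,
    out_dir: str | None = None,
    on_date: _dt.date | None = None,
) -> dict[str, ExtractOutput]:
    """Execute the module procedure for every collection in the task.

    Fail-closed: governance is checked for *all* collections before any data
    is touched; one denial refuses the whole task.  Output rows are sorted by
    (person_key, content) and standardised; the QA report is recomputed from
    the rendered file.
    """
    governance = hub.governance
    for cid in task.collection_ids:
        decision = governance.check_access(
            session.user_id, cid, task.task_id, task.requested_on
        )
        if not decision:
            raise AuthorisationError(
                f"task {task.task_id!r} refused: access to {cid!r} denied "
                f"({decision.reason}); no data touched"
            )

    outputs: dict[str, ExtractOutput] = {}
    for cid in task.collection_ids:
        schema = hub.get_schema(cid)
        rows, key_rows, retrieved, _import_report = _retrieve_typed_rows(
            session, task, hub, cid
        )
        steps = task.steps_for(cid)
        rows, _fields = apply_steps(
            rows,
            ["person_key"]
            + (["cares_id"] if task.keep_record_token else [])
            + list(schema.approved_items),
            steps,
        )
        layout = make_layout(
            schema, steps, keep_record_token=task.keep_record_token
        )
        records = standardise(rows, layout)
        records.sort(key=lambda r: tuple(r[name] for name in layout.field_names))
        csv_text = records_to_csv(records, layout.field_names)
        qa = qa_report(key_rows, retrieved, csv_text, task, layout)
        output = ExtractOutput(collection_id=cid, records=records, layout=layout, qa=qa)
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            paths = {
                "extract": os.path.join(out_dir, f"{task.task_id}_{cid}_extract.csv"),
                "layout": os.path.join(out_dir, f"{task.task_id}_{cid}_layout.csv"),
                "qa": os.path.join(out_dir, f"{task.task_id}_{cid}_qa.json"),
            }
            with open(paths["extract"], "w", encoding="utf-8", newline="") as fh:
                fh.write(csv_text)
            with open(paths["layout"], "w", encoding="utf-8", newline="") as fh:
                fh.write(layout.to_text())
            with open(paths["qa"], "w", encoding="utf-8") as fh:
                fh.write(qa.to_text())
            output.paths = paths
        outputs[cid] = output

    task.completed_on = on_date if on_date is not None else task.requested_on
    governance.audit.append(
        actor=session.user_id,
        action="extraction-run",
        subject=task.task_id,
        outcome=f"collections={len(task.collection_ids)} mode=cares",
    )
    return outputs


def run_classical(
    task: ExtractionTask,
    hub: Hub,
    session: Session,
    delay_model=None,
    seed: int = 0,
) -> dict[str, ClassicalOutput]:
    """Produce the classical fan-out baseline: same record content as
    :func:`run_module`, but one heterogeneous file per collection (its own
    date dialect, field order and delimiter) with a simulated per-collection
    completion delay."""
    governance = hub.governance
    for cid in task.collection_ids:
        decision = governance.check_access(
            session.user_id, cid, task.task_id, task.requested_on
        )
        if not decision:
            raise AuthorisationError(
                f"classical task {task.task_id!r} refused: {cid!r} denied "
                f"({decision.reason})"
            )

    rng = np.random.default_rng(seed)
    delimiters = (",", "\t", "|")
    outputs: dict[str, ClassicalOutput] = {}
    for cid in task.collection_ids:
        schema = hub.get_schema(cid)
        rows, _keys, _retrieved, _report = _retrieve_typed_rows(session, task, hub, cid)
        steps = task.steps_for(cid)
        base_order = ["person_key"] + (
            ["cares_id"] if task.keep_record_token else []
        ) + list(schema.approved_items)
        rows, fields = apply_steps(rows, base_order, steps)
        layout = make_layout(schema, steps, keep_record_token=task.keep_record_token)

        # deterministic per-collection heterogeneity
        order = list(layout.field_names)
        order_seed = int.from_bytes(hashlib.sha256(cid.encode()).digest()[:4], "big")
        perm = np.random.default_rng(order_seed).permutation(len(order))
        order = [order[i] for i in perm]
        dialect = next(
            (f.dialect for f in schema.fields if f.ftype == "date"), "DD/MM/YYYY"
        )
        delimiter = delimiters[sum(map(ord, cid)) % len(delimiters)]

        # sort on the canonical rendering so record content matches run_module
        canonical = standardise(rows, layout)
        paired = sorted(
            zip(canonical, rows),
            key=lambda p: tuple(p[0][name] for name in layout.field_names),
        )
        rendered: list[dict[str, str]] = []
        for _canon_row, row in paired:
            out_row: dict[str, str] = {}
            for name in order:
                v = row.get(name)
                spec = layout.field_spec(name)
                if v is None or v == "":
                    out_row[name] = ""
                elif spec.ftype == "date" and isinstance(v, _dt.date):
                    out_row[name] = render_date(v, dialect)
                elif isinstance(v, float):
                    out_row[name] = str(int(v)) if v.is_integer() else repr(v)
                else:
                    out_row[name] = str(v)
            rendered.append(out_row)

        buf = io.StringIO()
        writer = csv.DictWriter(
            buf, fieldnames=order, delimiter=delimiter, lineterminator="\n"
        )
        writer.writeheader()
        writer.writerows(rendered)

        delay = 0 if delay_model is None else int(delay_model.sample(rng))
        outputs[cid] = ClassicalOutput(
            collection_id=cid,
            records=rendered,
            field_order=order,
            dialect=dialect,
            delimiter=delimiter,
            file_text=buf.getvalue(),
            completed_on=task.requested_on + _dt.timedelta(days=delay),
        )
    governance.audit.append(
        actor=session.user_id,
        action="extraction-run",
        subject=task.task_id,
        outcome=f"collections={len(task.collection_ids)} mode=classical",
    )
    return outputs
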