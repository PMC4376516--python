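"""Standardised outputs, layout (data dictionary) files and QA reports.

Whatever collection an extract comes from, the researcher receives the same
thing: an RFC-4180 CSV (UTF-8, LF, header row) with a fixed field order, all
dates rendered ``YYYYMMDD``, canonical category labels and empty strings for
missing values; a layout file describing every output field; and a QA report
covering correctness of content (structural checksums recomputed from the
rendered output), date coverage against the task's window, field groupings
(per-level category counts), missing values and missing records (key rows
whose CARES ID matched nothing on the hub).

``standardise`` is idempotent, so an output that is already canonical passes
through unchanged — central-mode extracts need no post-extraction
standardisation at all, while classical per-collection files in their own
dialects normalise to byte-identical canonical files.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import json
from dataclasses import dataclass, field

from ._dates import CANONICAL_DIALECT, parse_date, parse_date_any
from .errors import StandardisationError
from .synthetic_data import CollectionSchema

CANONICAL_DATE_PATTERN = "%Y%m%d"


@dataclass(frozen=True)
class LayoutField:
    name: str
    ftype: str  # text | integer | date | category | number
    format: str = ""  # "YYYYMMDD" for dates
    levels: tuple[str, ...] = ()
    description: str = ""


@dataclass(frozen=True)
class LayoutFile:
    """Data dictionary for one extract; field order matches the output file."""

    fields: tuple[LayoutField, ...]

    @property
    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]

    def field_spec(self, name: str) -> LayoutField:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    def to_text(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["field", "type", "format", "levels", "description"])
        for f in self.fields:
            writer.writerow([f.name, f.ftype, f.format, "|".join(f.levels), f.description])
        return buf.getvalue()


def parse_layout(text: str) -> LayoutFile:
    reader = csv.reader(io.StringIO(text))
    header = next(reader)
    if header != ["field", "type", "format", "levels", "description"]:
        raise StandardisationError(f"not a layout file (header {header!r})")
    fields = [
        LayoutField(
            name=row[0],
            ftype=row[1],
            format=row[2],
            levels=tuple(row[3].split("|")) if row[3] else (),
            description=row[4],
        )
        for row in reader
        if row
    ]
    return LayoutFile(fields=tuple(fields))


@dataclass
class QAReport:
    rows_in: int  # validated key rows
    rows_matched: int  # key rows whose CARES ID matched a hub record
    rows_out: int  # rows in the final output
    unmatched_key_rows: int  # "missing records"
    date_coverage: dict[str, dict]  # field -> {min, max, out_of_window}
    category_counts: dict[str, dict[str, int]]  # field -> level -> count
    missing_counts: dict[str, int]  # field -> empty-value count
    checksum: dict  # structural content-correctness summary

    def to_text(self) -> str:
        return json.dumps(
            {
                "rows_in": self.rows_in,
                "rows_matched": self.rows_matched,
                "rows_out": self.rows_out,
                "unmatched_key_rows": self.unmatched_key_rows,
                "date_coverage": self.date_coverage,
                "category_counts": self.category_counts,
                "missing_counts": self.missing_counts,
                "checksum": self.checksum,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class ExtractOutput:
    """Everything a researcher receives for one collection."""

    collection_id: str
    records: list[dict[str, str]]  # standardised rows
    layout: LayoutFile
    qa: QAReport
    paths: dict[str, str] = field(default_factory=dict)

    def to_csv_text(self) -> str:
        return records_to_csv(self.records, self.layout.field_names)


# ---------------------------------------------------------------------------
# standardisation
# ---------------------------------------------------------------------------

def _render_value(value, spec: LayoutField, dialect: str, where: str) -> str:
    if value is None or value == "":
        return ""
    if spec.ftype == "date":
        if isinstance(value, _dt.date):
            return value.strftime(CANONICAL_DATE_PATTERN)
        try:
            if dialect == "canonical":
                parsed = parse_date_any(str(value))
            else:
                try:
                    parsed = parse_date(str(value), dialect)
                except ValueError:
                    parsed = parse_date_any(str(value))
        except ValueError:
            raise StandardisationError(f"{where}: unparseable date {value!r}") from None
        return parsed.strftime(CANONICAL_DATE_PATTERN)
    if spec.ftype == "integer":
        try:
            return str(int(str(value)))
        except ValueError:
            raise StandardisationError(f"{where}: invalid integer {value!r}") from None
    if spec.ftype == "number":
        if isinstance(value, float):
            return str(int(value)) if value.is_integer() else repr(value)
        if isinstance(value, int):
            return str(value)
        return str(value)
    if spec.ftype == "category":
        text = str(value)
        if spec.levels and text not in spec.levels:
            raise StandardisationError(
                f"{where}: {text!r} is not a level of {spec.name!r}"
            )
        return text
    return str(value)


def standardise(
    records: list[dict], layout: LayoutFile, dialect: str = "canonical"
) -> list[dict[str, str]]:
    """Render rows into the canonical output form.

    ``dialect`` names the date dialect the *input* uses; "canonical" accepts
    already-standardised (or ISO) dates, which makes the operation
    idempotent.  Field order follows the layout; values not coercible to
    their declared type raise :class:`StandardisationError` naming the row
    and field.  Row order is preserved.
    """
    out: list[dict[str, str]] = []
    for i, row in enumerate(records):
        rendered: dict[str, str] = {}
        for spec in layout.fields:
            rendered[spec.name] = _render_value(
                row.get(spec.name), spec, dialect, where=f"row {i}, field {spec.name!r}"
            )
        out.append(rendered)
    return out


def records_to_csv(records: list[dict[str, str]], field_names: list[str]) -> str:
    """RFC-4180 CSV, UTF-8, LF line endings, header row."""
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=field_names, lineterminator="\n")
    writer.writeheader()
    writer.writerows(records)
    return buf.getvalue()


def csv_to_records(text: str) -> list[dict[str, str]]:
    return list(csv.DictReader(io.StringIO(text)))


# ---------------------------------------------------------------------------
# layout construction
# ---------------------------------------------------------------------------

def _describe_expr(expr: dict) -> str:
    op = expr["op"]
    if op == "recode":
        pairs = ", ".join(f"{k}->{v}" for k, v in expr["mapping"].items())
        return f"recode({expr['args'][0]}: {pairs})"
    a, b = expr["args"]
    if op in ("days_between", "years_between"):
        return f"{op}({a}, {b})"
    return f"({a} {op} {b})"


def _derived_spec(params: dict) -> LayoutField:
    expr = params["expr"]
    if expr["op"] == "recode":
        ftype = "text"
    elif expr["op"] in ("days_between", "years_between"):
        ftype = "integer"
    else:
        ftype = "number"
    return LayoutField(
        name=params["name"],
        ftype=ftype,
        description=f"derived: {_describe_expr(expr)}",
    )


def make_layout(
    schema: CollectionSchema,
    steps=(),
    include_person_key: bool = True,
    keep_record_token: bool = False,
) -> LayoutFile:
    """Build the data dictionary for one collection's extract.

    Starts from the approved items in schema order, then applies the task's
    transform steps: renames/recodes adjust the entry in place, derived
    fields append an entry documenting their generating expression.
    """
    entries: list[LayoutField] = []
    if include_person_key:
        entries.append(
            LayoutField(
                name="person_key",
                ftype="text",
                description="project-scoped person-level linkage key",
            )
        )
    if keep_record_token:
        entries.append(
            LayoutField(
                name="cares_id",
                ftype="text",
                description="one-way encrypted record token (QA workflows only)",
            )
        )
    for item in schema.approved_items:
        spec = schema.field_spec(item)
        entries.append(
            LayoutField(
                name=spec.name,
                ftype=spec.ftype,
                format=CANONICAL_DIALECT if spec.ftype == "date" else "",
                levels=tuple(spec.levels) if spec.levels else (),
                description="as provided by the collection",
            )
        )
    for step in steps:
        if step.kind == "field_map":
            src = step.params["field"]
            dst = step.params.get("rename") or src
            recode = step.params.get("recode")
            for i, entry in enumerate(entries):
                if entry.name == src:
                    levels = entry.levels
                    if recode and levels:
                        levels = tuple(
                            sorted({recode.get(l, l) for l in levels})
                        )
                    entries[i] = LayoutField(
                        name=dst,
                        ftype=entry.ftype,
                        format=entry.format,
                        levels=levels,
                        description=entry.description,
                    )
                    break
        elif step.kind == "derived_field":
            entries.append(_derived_spec(step.params))
    return LayoutFile(fields=tuple(entries))


# ---------------------------------------------------------------------------
# QA reporting
# ---------------------------------------------------------------------------

def qa_report(
    key_rows: list,
    retrieved: list,
    output,
    task,
    layout: LayoutFile | None = None,
) -> QAReport:
    """Quality/validity summary for one module run.

    All counts are recomputed from the rendered output itself (the CSV text
    if given, else the standardised records), not taken from the engine's
    internal state.  ``key_rows`` are the validated linkage key rows;
    ``retrieved`` the hub records they matched.
    """
    if isinstance(output, str):
        records = csv_to_records(output)
        names = records[0].keys() if records else (
            next(iter(csv.reader(io.StringIO(output))), [])
        )
        field_names = list(names)
    else:
        records = list(output)
        field_names = layout.field_names if layout is not None else (
            list(records[0].keys()) if records else []
        )

    matched_values = {r.cares_id.value for r in retrieved}
    key_values = [getattr(k, "cares_id", k) for k in key_rows]
    key_values = [v.value if hasattr(v, "value") else str(v) for v in key_values]
    rows_in = len(key_values)
    rows_matched = sum(1 for v in key_values if v in matched_values)
    unmatched = rows_in - rows_matched
    rows_out = len(records)

    date_fields: list[str] = []
    category_fields: dict[str, tuple[str, ...]] = {}
    if layout is not None:
        for f in layout.fields:
            if f.ftype == "date":
                date_fields.append(f.name)
            elif f.ftype == "category":
                category_fields[f.name] = f.levels
    else:
        date_fields = [
            n for n in field_names
            if all(_looks_like_date(r.get(n, "")) for r in records) and records
        ]

    window = getattr(task, "date_window", None)
    date_coverage: dict[str, dict] = {}
    for name in date_fields:
        values = [r[name] for r in records if r.get(name)]
        entry: dict = {
            "min": min(values) if values else "",
            "max": max(values) if values else "",
            "out_of_window": 0,
        }
        if window is not None:
            lo = _canon(window[0])
            hi = _canon(window[1])
            entry["out_of_window"] = sum(1 for v in values if not (lo <= v <= hi))
        date_coverage[name] = entry

    category_counts: dict[str, dict[str, int]] = {}
    for name, levels in category_fields.items():
        counts: dict[str, int] = {level: 0 for level in levels}
        for r in records:
            v = r.get(name, "")
            if v:
                counts[v] = counts.get(v, 0) + 1
        category_counts[name] = counts

    missing_counts = {
        name: sum(1 for r in records if not r.get(name)) for name in field_names
    }
    non_null = {
        name: rows_out - missing_counts[name] for name in field_names
    }
    checksum = {
        "rows": rows_out,
        "fields": len(field_names),
        "cells": rows_out * len(field_names),
        "non_null": non_null,
    }
    return QAReport(
        rows_in=rows_in,
        rows_matched=rows_matched,
        rows_out=rows_out,
        unmatched_key_rows=unmatched,
        date_coverage=date_coverage,
        category_counts=category_counts,
        missing_counts=missing_counts,
        checksum=checksum,
    )


def _canon(value) -> str:
    if isinstance(value, _dt.date):
        return value.strftime(CANONICAL_DATE_PATTERN)
    return parse_date_any(str(value)).strftime(CANONICAL_DATE_PATTERN)


def _looks_like_date(text: str) -> bool:
    if text == "":
        return True
    try:
        parse_date(text, CANONICAL_DIALECT)
        return True
    except ValueError:
        return False
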