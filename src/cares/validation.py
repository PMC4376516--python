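"""Parallel-run validation: compare a central extract against a reference.

Before a collection goes live on the hub, every extract is produced twice —
once centrally and once by the collection itself — and the two files are
compared to ensure the same records came out.  The comparison matches
records on a caller-chosen composite key (by default the person key plus all
date fields, since researcher-facing extracts carry no record-level token),
then diffs matched records field by field.  All comparisons are exact typed
string equality on standardised values: these are administrative fields, not
measurements, so there is no tolerance.

``classify_discrepancies`` buckets each finding by its apparent cause —
records missing because they fall outside a cut-off date window, records
absent entirely, and single-field deltas — mirroring how real parallel-run
failures decompose into exclusion-criteria, cut-off-date, missing-data and
script-bug causes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._dates import parse_date_any
from .errors import ComparisonError
from .qa_standardisation import LayoutFile


@dataclass
class ComparisonReport:
    key_fields: list[str]
    n_only_in_a: int
    n_only_in_b: int
    n_matched: int
    field_mismatches: list[tuple]  # (key, field, value_a, value_b), sorted
    only_in_a: list[tuple]  # keys, sorted
    only_in_b: list[tuple]
    rows_only_in_a: list[dict]
    rows_only_in_b: list[dict]

    @property
    def verdict(self) -> str:
        clean = (
            self.n_only_in_a == 0
            and self.n_only_in_b == 0
            and not self.field_mismatches
        )
        return "identical" if clean else "discrepant"

    @property
    def n_discrepancies(self) -> int:
        return self.n_only_in_a + self.n_only_in_b + len(self.field_mismatches)


def default_key_fields(layout: LayoutFile) -> list[str]:
    """person_key plus every date field: the natural composite key for a
    researcher-facing extract with no record token."""
    keys = [f.name for f in layout.fields if f.name == "person_key"]
    keys += [f.name for f in layout.fields if f.ftype == "date"]
    return keys


def compare_extracts(
    a: list[dict[str, str]],
    b: list[dict[str, str]],
    key_fields: list[str],
) -> ComparisonReport:
    """Match rows of A and B on ``key_fields`` and diff matched rows.

    Keys must uniquely identify records within each input; duplicates raise
    :class:`ComparisonError` listing them.  Mismatches are reported in a
    deterministic (key, field) order.
    """
    for label, rows in (("A", a), ("B", b)):
        missing = [f for f in key_fields if rows and f not in rows[0]]
        if missing:
            raise ComparisonError(f"input {label} lacks key field(s) {missing}")

    def index(rows, label):
        by_key: dict[tuple, dict] = {}
        dups = []
        for row in rows:
            key = tuple(row[f] for f in key_fields)
            if key in by_key:
                dups.append(key)
            by_key[key] = row
        if dups:
            raise ComparisonError(
                f"duplicate keys in input {label}: {sorted(set(dups))[:10]}"
            )
        return by_key

    index_a = index(a, "A")
    index_b = index(b, "B")

    only_a = sorted(set(index_a) - set(index_b))
    only_b = sorted(set(index_b) - set(index_a))
    matched = sorted(set(index_a) & set(index_b))

    mismatches: list[tuple] = []
    for key in matched:
        row_a, row_b = index_a[key], index_b[key]
        for name in sorted(set(row_a) | set(row_b)):
            va, vb = row_a.get(name, ""), row_b.get(name, "")
            if va != vb:
                mismatches.append((key, name, va, vb))

    return ComparisonReport(
        key_fields=list(key_fields),
        n_only_in_a=len(only_a),
        n_only_in_b=len(only_b),
        n_matched=len(matched),
        field_mismatches=mismatches,
        only_in_a=only_a,
        only_in_b=only_b,
        rows_only_in_a=[dict(index_a[k]) for k in only_a],
        rows_only_in_b=[dict(index_b[k]) for k in only_b],
    )


#: mismatch pattern -> cause bucket (the observed causes of real
#: parallel-run discrepancies)
DEFAULT_TAXONOMY = {
    "date-window-edge": "cut-off dates",
    "whole-record-absence": "missing data",
    "single-field-delta": "script bugs",
}

BUCKETS = ("cut-off dates", "missing data", "script bugs", "other")


def classify_discrepancies(
    report: ComparisonReport,
    taxonomy: dict[str, str] | None = None,
    date_window: tuple | None = None,
    date_fields: list[str] | None = None,
) -> Counter:
    """Assign every discrepancy to exactly one cause bucket.

    An absent record whose date fields fall outside ``date_window`` is a
    cut-off-date discrepancy; any other absent record is missing data; a
    field-level delta on a matched record is a script bug; anything the
    taxonomy does not cover lands in "other".
    """
    taxonomy = dict(DEFAULT_TAXONOMY if taxonomy is None else taxonomy)
    counts: Counter = Counter({b: 0 for b in BUCKETS})
    counts.update({b: 0 for b in taxonomy.values()})

    def bucket(pattern: str) -> str:
        return taxonomy.get(pattern, "other")

    def outside_window(row: dict) -> bool:
        if date_window is None or not date_fields:
            return False
        lo = parse_date_any(str(date_window[0])).strftime("%Y%m%d")
        hi = parse_date_any(str(date_window[1])).strftime("%Y%m%d")
        values = [row.get(f, "") for f in date_fields if row.get(f, "")]
        return bool(values) and any(not (lo <= v <= hi) for v in values)

    for row in report.rows_only_in_a + report.rows_only_in_b:
        pattern = "date-window-edge" if outside_window(row) else "whole-record-absence"
        counts[bucket(pattern)] += 1
    for _key, _field, _va, _vb in report.field_mismatches:
        counts[bucket("single-field-delta")] += 1
    return counts
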