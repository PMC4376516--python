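"""The central hub: de-identified partial copies of each collection.

The hub holds, per registered collection, only the custodian-approved content
fields, keyed by one-way encrypted CARES IDs.  Source UIDs never rest here in
clear; demographics never arrive at all.  At rest the hub is isolated,
unlinked and de-identified: there is deliberately no person-level join
operation in its API — records of the same person across collections share
nothing a user could join on without importing a project key file.

Loading normalises every date field from the collection's input dialect to
the canonical internal calendar-date form and rejects unparseable rows
individually (a strict flag aborts the whole load instead).  Updates are
either a full replacement or an append that upserts on CARES ID, so a load
replayed with identical content leaves the table byte-identical.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import itertools
from dataclasses import dataclass, field

from ._dates import parse_date
from .crypto_ids import CaresId, CollectionKey, KeyEscrow, encrypt_id
from .errors import (
    AuthorisationError,
    ConflictError,
    InvalidParameterError,
    NotFoundError,
    SchemaError,
)
from .governance import GovernanceRegistry
from .synthetic_data import CollectionSchema, SourceRecordTable


@dataclass(frozen=True)
class ServiceRecord:
    """One de-identified row held on the hub."""

    cares_id: CaresId
    collection_id: str
    content: dict[str, object]  # approved fields only; dates as datetime.date
    load_batch: int


@dataclass(frozen=True)
class TransferItem:
    sender: str
    recipient: str
    name: str
    payload: bytes
    deposited: _dt.datetime


@dataclass
class LoadReport:
    collection_id: str
    mode: str
    rows_in: int = 0
    rows_stored: int = 0
    rows_rejected: int = 0
    # (0-based input row position, reason); no source identifiers
    rejections: list[tuple[int, str]] = field(default_factory=list)


class Hub:
    """Registration, loading, retrieval and the transfer partition."""

    def __init__(self, governance: GovernanceRegistry) -> None:
        self.governance = governance
        self._schemas: dict[str, CollectionSchema] = {}
        self._tables: dict[str, dict[str, ServiceRecord]] = {}
        self._batch_counters: dict[str, itertools.count] = {}
        self._transfers: dict[int, TransferItem] = {}
        self._transfer_serial = itertools.count(1)

    # -- registration ---------------------------------------------------

    def register_collection(self, schema: CollectionSchema) -> CollectionSchema:
        if schema.collection_id in self._schemas:
            raise ConflictError(f"collection {schema.collection_id!r} already registered")
        self._schemas[schema.collection_id] = schema
        self._tables[schema.collection_id] = {}
        self._batch_counters[schema.collection_id] = itertools.count(1)
        self.governance.register_collection_id(schema.collection_id)
        return schema

    def list_collections(self) -> list[str]:
        return sorted(self._schemas)

    def get_schema(self, collection_id: str) -> CollectionSchema:
        try:
            return self._schemas[collection_id]
        except KeyError:
            raise NotFoundError(f"unknown collection {collection_id!r}") from None

    def table_size(self, collection_id: str) -> int:
        self.get_schema(collection_id)
        return len(self._tables[collection_id])

    # -- loading --------------------------------------------------------

    def load_update(
        self,
        collection_id: str,
        source_table: SourceRecordTable,
        key: CollectionKey,
        mode: str = "full",
        escrow: KeyEscrow | None = None,
        strict: bool = False,
    ) -> LoadReport:
        """Load a source update into the hub.

        Every stored row is keyed by ``encrypt_id(source_uid)``; only
        approved items are retained; dates are normalised to internal
        calendar dates.  Rows that violate the schema are rejected and
        counted, and the load continues (``strict=True`` aborts instead).
        Rows identical to what the hub already holds are left untouched, so
        reloading the same update is a no-op.
        """
        schema = self.get_schema(collection_id)
        if mode not in ("full", "append"):
            raise InvalidParameterError(f"unknown load mode {mode!r}")
        if key.collection_id != collection_id or source_table.collection_id != collection_id:
            raise AuthorisationError(
                f"key/table for {key.collection_id!r}/{source_table.collection_id!r} "
                f"cannot load collection {collection_id!r}"
            )

        batch = next(self._batch_counters[collection_id])
        report = LoadReport(collection_id=collection_id, mode=mode, rows_in=len(source_table.rows))
        incoming: dict[str, ServiceRecord] = {}
        escrow_pairs: list[tuple[CaresId, str]] = []
        for position, src in enumerate(source_table.rows):
            try:
                content = self._coerce_content(schema, src.content)
            except (ValueError, SchemaError) as exc:
                if strict:
                    raise SchemaError(f"row {position}: {exc}") from exc
                report.rows_rejected += 1
                report.rejections.append((position, str(exc)))
                continue
            cid = encrypt_id(collection_id, src.source_uid, key)
            incoming[cid.value] = ServiceRecord(
                cares_id=cid, collection_id=collection_id, content=content, load_batch=batch
            )
            escrow_pairs.append((cid, src.source_uid))

        table = self._tables[collection_id]
        if mode == "full":
            merged: dict[str, ServiceRecord] = {}
            for value, record in incoming.items():
                previous = table.get(value)
                if previous is not None and previous.content == record.content:
                    merged[value] = previous  # unchanged row keeps its batch
                else:
                    merged[value] = record
            self._tables[collection_id] = merged
        else:  # append: upsert on cares_id, new value wins
            for value, record in incoming.items():
                previous = table.get(value)
                if previous is not None and previous.content == record.content:
                    continue
                table[value] = record

        report.rows_stored = len(incoming)
        if escrow is not None:
            for cid, uid in escrow_pairs:
                escrow.record(cid, uid)
        self.governance.audit.append(
            actor=key.holder,
            action="load-update",
            subject=f"{collection_id}:batch{batch}:{mode}",
            outcome=f"in={report.rows_in} stored={report.rows_stored} rejected={report.rows_rejected}",
        )
        return report

    @staticmethod
    def _coerce_content(schema: CollectionSchema, raw: dict[str, object]) -> dict[str, object]:
        unknown = set(raw) - {f.name for f in schema.fields}
        if unknown:
            raise SchemaError(f"unknown field(s) {sorted(unknown)}")
        content: dict[str, object] = {}
        for name in schema.approved_items:
            spec = schema.field_spec(name)
            value = raw.get(name)
            if value is None or value == "":
                content[name] = None
                continue
            if spec.ftype == "date":
                try:
                    content[name] = parse_date(str(value), spec.dialect)
                except ValueError:
                    raise ValueError(f"unparseable date in field {name!r}: {value!r}") from None
            elif spec.ftype == "integer":
                try:
                    content[name] = int(value)
                except (TypeError, ValueError):
                    raise ValueError(f"invalid integer in field {name!r}: {value!r}") from None
            elif spec.ftype == "category":
                if str(value) not in spec.levels:
                    raise ValueError(f"unknown category level in field {name!r}: {value!r}")
                content[name] = str(value)
            else:
                content[name] = str(value)
        return content

    # -- retrieval ------------------------------------------------------

    def query_records(
        self,
        user,
        collection_id: str,
        cares_ids: list,
        governance_ctx: tuple[str, _dt.date],
    ) -> tuple[list[ServiceRecord], list[str]]:
        """Retrieve the stored records for the requested CARES IDs.

        ``governance_ctx`` is (task_id, on_date); the three-tier check must
        allow (user, collection, task) or the query raises, returning no
        rows.  Results are sorted by CARES ID token; ids with no stored
        record are reported separately, never silently dropped.
        """
        self.get_schema(collection_id)
        task_id, on_date = governance_ctx
        decision = self.governance.check_access(user, collection_id, task_id, on_date)
        if not decision:
            raise AuthorisationError(
                f"access to {collection_id!r} denied: {decision.reason}"
            )
        table = self._tables[collection_id]
        requested = [
            cid.value if isinstance(cid, CaresId) else str(cid) for cid in cares_ids
        ]
        found: list[ServiceRecord] = []
        unmatched: list[str] = []
        for value in requested:
            record = table.get(value)
            if record is None:
                unmatched.append(value)
            else:
                found.append(record)
        found.sort(key=lambda r: r.cares_id.value)
        return found, sorted(set(unmatched))

    # -- persistence / inspection --------------------------------------

    def export_table(self, collection_id: str) -> str:
        """Render a collection's hub table as deterministic CSV (internal
        canonical form: ISO dates, rows sorted by CARES ID)."""
        schema = self.get_schema(collection_id)
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["cares_id", "load_batch", *schema.approved_items])
        for value in sorted(self._tables[collection_id]):
            record = self._tables[collection_id][value]
            row = [value, record.load_batch]
            for name in schema.approved_items:
                v = record.content.get(name)
                row.append("" if v is None else (v.isoformat() if isinstance(v, _dt.date) else str(v)))
            writer.writerow(row)
        return buf.getvalue()

    # -- transfer partition --------------------------------------------

    def place_transfer(self, sender: str, recipient: str, name: str, payload: bytes) -> int:
        self.governance.get_user(sender)
        self.governance.get_user(recipient)
        receipt = next(self._transfer_serial)
        self._transfers[receipt] = TransferItem(
            sender=sender,
            recipient=recipient,
            name=name,
            payload=payload,
            deposited=_dt.datetime.now(_dt.timezone.utc),
        )
        self.governance.audit.append(
            actor=sender, action="transfer-place", subject=name, outcome=f"receipt={receipt}"
        )
        return receipt

    def read_transfer(self, user: str, receipt: int) -> bytes:
        item = self._transfers.get(receipt)
        if item is None:
            raise NotFoundError(f"no transfer with receipt {receipt}")
        allowed = user in (item.sender, item.recipient)
        self.governance.audit.append(
            actor=user,
            action="transfer-read",
            subject=item.name,
            outcome="ok" if allowed else "deny",
        )
        if not allowed:
            raise AuthorisationError(
                f"transfer {item.name!r} is readable only by its sender and recipient"
            )
        return item.payload
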