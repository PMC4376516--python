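"""Hub loading, partial-copy guarantees, retrieval and the transfer
partition."""

from __future__ import annotations

import datetime as dt

import pytest

from cares.crypto_ids import KeyEscrow, encrypt_id, generate_collection_key
from cares.errors import (
    AuthorisationError,
    ConflictError,
    NotFoundError,
)
from cares.governance import AccessGrant, GovernanceRegistry, TaskApproval, User
from cares.hub_store import Hub
from cares.synthetic_data import (
    SourceRecordTable,
    SourceRow,
    default_schemas,
    generate_collection,
    generate_population,
)

ON = dt.date(2013, 6, 1)
EARLIER = ON - dt.timedelta(days=30)


def wired_hub() -> tuple[Hub, GovernanceRegistry]:
    reg = GovernanceRegistry()
    reg.register_user(
        User("cust", frozenset({"custodian"}), confidentiality_signed=EARLIER)
    )
    reg.register_user(
        User("alice", frozenset({"cares-user"}), confidentiality_signed=EARLIER)
    )
    return Hub(reg), reg


def approve(reg: GovernanceRegistry, user: str, cid: str, task: str) -> None:
    reg.register_task(task)
    reg.grant_access(AccessGrant(user, cid, granted_by="cust", granted_on=EARLIER))
    reg.approve_task(
        TaskApproval(task, cid, approved_by="cust", evidence="email", approved_on=EARLIER)
    )


def hmd_rows(n: int):
    return tuple(
        SourceRow(
            source_uid=f"HMD-{i:07d}",
            owner_root_id=f"R{i:03d}",
            content={
                "admission_date": "15/03/2005",
                "separation_date": "20/03/2005",
                "diagnosis_code": f"d{i}",
                "length_of_stay": 5,
                "hospital_type": "metro",
            },
        )
        for i in range(n)
    )


class TestRegistration:
    def test_register_then_list(self):
        hub, _ = wired_hub()
        hub.register_collection(default_schemas()["HMD"])
        assert hub.list_collections() == ["HMD"]

    def test_duplicate_register_conflicts(self):
        hub, _ = wired_hub()
        hub.register_collection(default_schemas()["HMD"])
        with pytest.raises(ConflictError):
            hub.register_collection(default_schemas()["HMD"])

    def test_five_schemas_five_empty_tables(self):
        hub, _ = wired_hub()
        for cid in ("HMD", "EDC", "CAN", "BTH", "DTH"):
            hub.register_collection(default_schemas()[cid])
        assert len(hub.list_collections()) == 5
        assert all(hub.table_size(cid) == 0 for cid in hub.list_collections())


class TestLoadUpdate:
    def setup_method(self):
        self.hub, self.reg = wired_hub()
        self.schema = default_schemas()["HMD"]
        self.key = generate_collection_key("HMD", seed=1)
        self.hub.register_collection(self.schema)

    def test_valid_rows_all_stored(self):
        report = self.hub.load_update(
            "HMD", SourceRecordTable("HMD", hmd_rows(10)), self.key
        )
        assert (report.rows_in, report.rows_stored, report.rows_rejected) == (10, 10, 0)

    def test_invalid_calendar_date_rejected_rowwise(self):
        rows = list(hmd_rows(3))
        bad = SourceRow(
            source_uid="HMD-bad",
            owner_root_id="Rbad",
            content={**rows[0].content, "admission_date": "31/02/2010"},
        )
        report = self.hub.load_update(
            "HMD", SourceRecordTable("HMD", tuple(rows + [bad])), self.key
        )
        assert report.rows_rejected == 1
        assert "unparseable date" in report.rejections[0][1]
        assert self.hub.table_size("HMD") == 3

    def test_append_upserts_new_value_wins(self):
        table = SourceRecordTable("HMD", hmd_rows(5))
        self.hub.load_update("HMD", table, self.key, mode="full")
        changed = SourceRow(
            source_uid="HMD-0000002",
            owner_root_id="R002",
            content={**hmd_rows(5)[2].content, "diagnosis_code": "changed"},
        )
        self.hub.load_update(
            "HMD", SourceRecordTable("HMD", (changed,)), self.key, mode="append"
        )
        assert self.hub.table_size("HMD") == 5
        cid = encrypt_id("HMD", "HMD-0000002", self.key)
        record = self.hub._tables["HMD"][cid.value]
        assert record.content["diagnosis_code"] == "changed"

    def test_key_mismatch_stores_nothing(self):
        wrong = generate_collection_key("EDC", seed=1)
        with pytest.raises(AuthorisationError):
            self.hub.load_update("HMD", SourceRecordTable("HMD", hmd_rows(2)), wrong)
        assert self.hub.table_size("HMD") == 0

    def test_full_reload_is_idempotent_byte_identical(self):
        table = SourceRecordTable("HMD", hmd_rows(8))
        self.hub.load_update("HMD", table, self.key, mode="full")
        first = self.hub.export_table("HMD")
        self.hub.load_update("HMD", table, self.key, mode="full")
        assert self.hub.export_table("HMD") == first

    def test_partial_copy_stores_exactly_approved_items(self):
        pop = generate_population(40, seed=2)
        table = generate_collection(pop, self.schema, 1.0, 1.5, seed=3)
        self.hub.load_update("HMD", table, self.key)
        approved = set(self.schema.approved_items)
        for record in self.hub._tables["HMD"].values():
            assert set(record.content) == approved
            assert "hmd_uid" not in record.content

    def test_escrow_populated_at_load(self):
        escrow = KeyEscrow()
        self.hub.load_update(
            "HMD", SourceRecordTable("HMD", hmd_rows(4)), self.key, escrow=escrow
        )
        assert len(escrow) == 4


class TestQueryRecords:
    def setup_method(self):
        self.hub, self.reg = wired_hub()
        self.key = generate_collection_key("HMD", seed=1)
        self.hub.register_collection(default_schemas()["HMD"])
        self.hub.load_update("HMD", SourceRecordTable("HMD", hmd_rows(6)), self.key)
        approve(self.reg, "alice", "HMD", "T1")

    def test_requested_ids_returned_exactly(self):
        wanted = [encrypt_id("HMD", f"HMD-{i:07d}", self.key) for i in (0, 2, 4)]
        records, unmatched = self.hub.query_records("alice", "HMD", wanted, ("T1", ON))
        assert unmatched == []
        assert {r.cares_id.value for r in records} == {c.value for c in wanted}
        assert [r.cares_id.value for r in records] == sorted(
            r.cares_id.value for r in records
        )

    def test_unknown_id_reported_not_dropped(self):
        ghost = encrypt_id("HMD", "HMD-9999999", self.key)
        records, unmatched = self.hub.query_records("alice", "HMD", [ghost], ("T1", ON))
        assert records == [] and unmatched == [ghost.value]

    def test_default_deny_without_grant(self):
        self.reg.register_user(
            User("eve", frozenset({"cares-user"}), confidentiality_signed=EARLIER)
        )
        with pytest.raises(AuthorisationError, match="no-dataset-grant"):
            self.hub.query_records("eve", "HMD", [], ("T1", ON))

    def test_unregistered_collection_is_lookup_error(self):
        with pytest.raises(NotFoundError):
            self.hub.query_records("alice", "ZZZ", [], ("T1", ON))

    def test_no_person_level_join_surface(self):
        """The hub API exposes no operation linking records person-to-person."""
        surface = [m for m in dir(Hub) if not m.startswith("_")]
        assert not any(
            token in name for name in surface for token in ("join", "link", "person")
        )


class TestTransferPartition:
    def setup_method(self):
        self.hub, self.reg = wired_hub()
        self.reg.register_user(
            User("bob", frozenset({"cares-user"}), confidentiality_signed=EARLIER)
        )
        self.receipt = self.hub.place_transfer("alice", "bob", "update.csv", b"data")

    def test_sender_reads_own_deposit(self):
        assert self.hub.read_transfer("alice", self.receipt) == b"data"

    def test_recipient_reads(self):
        assert self.hub.read_transfer("bob", self.receipt) == b"data"

    def test_third_party_denied(self):
        self.reg.register_user(
            User("eve", frozenset({"cares-user"}), confidentiality_signed=EARLIER)
        )
        with pytest.raises(AuthorisationError):
            self.hub.read_transfer("eve", self.receipt)

    def test_reads_audited(self):
        before = self.reg.audit.count("transfer-read")
        self.hub.read_transfer("bob", self.receipt)
        assert self.reg.audit.count("transfer-read") == before + 1
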