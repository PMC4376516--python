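"""Generators: determinism, separation by construction, and the brute-force
fixture oracle."""

from __future__ import annotations

import re

import numpy as np
import pytest

from cares.errors import (
    ConfigurationError,
    InvalidParameterError,
    SchemaError,
)
from cares.synthetic_data import (
    CollectionSchema,
    FieldSpec,
    default_schemas,
    derive_project_keys,
    generate_collection,
    generate_population,
    inject_discrepancies,
    replay_ledger,
)
from cares.workflow import build_environment, make_project, pick_cohort


class TestGeneratePopulation:
    def test_size_contract(self):
        assert len(generate_population(1, seed=7)) == 1
        assert len(generate_population(100, seed=7)) == 100

    def test_deterministic_for_fixed_seed(self):
        assert generate_population(100, seed=7) == generate_population(100, seed=7)

    def test_different_seeds_differ(self):
        a = generate_population(100, seed=7)
        b = generate_population(100, seed=8)
        assert any(
            pa.name != pb.name
            or pa.date_of_birth != pb.date_of_birth
            or pa.address != pb.address
            for pa, pb in zip(a, b)
        )

    def test_root_ids_unique(self):
        pop = generate_population(500, seed=3)
        assert len({p.root_id for p in pop}) == 500

    def test_invalid_size_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_population(0, seed=1)


class TestGenerateCollection:
    def test_zero_coverage_empty(self):
        pop = generate_population(50, seed=1)
        schema = default_schemas()["HMD"]
        assert len(generate_collection(pop, schema, 0.0, 1.5, seed=2)) == 0

    def test_degenerate_count_gives_exactly_n_records(self):
        # a zero-truncated Poisson with mean 1 is a point mass at 1
        pop = generate_population(80, seed=1)
        schema = default_schemas()["HMD"]
        table = generate_collection(pop, schema, 1.0, 1.0, seed=2)
        assert len(table) == 80
        constant = generate_collection(
            pop, schema, 1.0, 1.0, seed=2, count_distribution="constant"
        )
        assert len(constant) == 80

    def test_coverage_sampling_matches_brute_force(self):
        pop = generate_population(1000, seed=5)
        schema = default_schemas()["HMD"]
        table = generate_collection(pop, schema, 0.5, 1.8, seed=11)
        # replay the generator's inclusion draw independently
        rng = np.random.default_rng(11)
        include = rng.random(1000) < 0.5
        expected = {p.root_id for p, inc in zip(pop, include) if inc}
        assert {r.owner_root_id for r in table.rows} == expected

    def test_dates_rendered_in_schema_dialect(self):
        pop = generate_population(30, seed=1)
        table = generate_collection(pop, default_schemas()["HMD"], 1.0, 1.2, seed=3)
        pattern = re.compile(r"^\d{2}/\d{2}/\d{4}$")
        assert table.rows
        for row in table.rows:
            assert pattern.match(str(row.content["admission_date"]))

    def test_registry_cap_limits_multiplicity(self):
        pop = generate_population(100, seed=1)
        table = generate_collection(pop, default_schemas()["BTH"], 1.0, 3.0, seed=4)
        owners = [r.owner_root_id for r in table.rows]
        assert len(owners) == len(set(owners))

    def test_unknown_dialect_is_schema_error(self):
        with pytest.raises(SchemaError):
            FieldSpec("d", "date", dialect="MM-DD-YY")

    def test_bad_coverage_rejected(self):
        pop = generate_population(5, seed=1)
        with pytest.raises(InvalidParameterError):
            generate_collection(pop, default_schemas()["HMD"], 1.5, 1.0, seed=0)


class TestSchemaInvariants:
    def test_source_uid_never_approved(self):
        with pytest.raises(SchemaError):
            CollectionSchema(
                collection_id="X",
                name="X",
                source_uid_field="uid",
                fields=(FieldSpec("uid", "text"),),
                approved_items=("uid",),
            )

    def test_demographic_field_names_banned(self):
        with pytest.raises(SchemaError):
            CollectionSchema(
                collection_id="X",
                name="X",
                source_uid_field="uid",
                fields=(FieldSpec("address", "text"),),
                approved_items=(),
            )


class TestDeriveProjectKeys:
    SECRET = b"test-secret"

    def test_deterministic(self):
        cohort = {"Raaa", "Rbbb"}
        assert derive_project_keys(cohort, "P1", self.SECRET) == derive_project_keys(
            cohort, "P1", self.SECRET
        )

    def test_project_scoped(self):
        keys1 = derive_project_keys({"Raaa"}, "P1", self.SECRET)
        keys2 = derive_project_keys({"Raaa"}, "P2", self.SECRET)
        assert keys1["Raaa"] != keys2["Raaa"]

    def test_injective_at_scale(self):
        cohort = {f"R{i:05d}" for i in range(10_000)}
        keys = derive_project_keys(cohort, "P1", self.SECRET)
        assert len(set(keys.values())) == 10_000

    def test_empty_secret_rejected(self):
        with pytest.raises(ConfigurationError):
            derive_project_keys({"Raaa"}, "P1", b"")

    def test_empty_cohort_rejected(self):
        with pytest.raises(InvalidParameterError):
            derive_project_keys(set(), "P1", self.SECRET)


class TestBuildFixture:
    def test_empty_cohort_boundary(self):
        env = build_environment(seed=9, n_persons=40, collection_ids=("HMD",))
        _task, fixture = make_project(
            env, "T1", "P1", ["HMD"], cohort=set()
        )
        assert fixture.key_files["HMD"] == []
        assert fixture.expected_output["HMD"] == []

    def test_full_cohort_row_count_matches_collection(self):
        env = build_environment(seed=9, n_persons=40, collection_ids=("HMD",))
        cohort = {p.root_id for p in env.population}
        _task, fixture = make_project(env, "T1", "P1", ["HMD"], cohort=cohort)
        _schema, table = env.collections["HMD"]
        assert len(fixture.expected_output["HMD"]) == len(table)

    def test_exclusion_step_equals_brute_force_filter(self):
        from cares.extraction_engine import TransformStep

        env = build_environment(seed=9, n_persons=60, collection_ids=("HMD",))
        cohort = pick_cohort(env, 30, seed=1)
        _t0, plain = make_project(env, "T1", "P1", ["HMD"], cohort=cohort)
        step = TransformStep(
            kind="exclusion",
            params={"field": "admission_date", "op": "<", "value": "2000-01-01"},
        )
        _t1, filtered = make_project(
            env, "T2", "P1", ["HMD"], cohort=cohort, steps=[step]
        )
        manual = [
            row for row in plain.expected_output["HMD"]
            if not (row["admission_date"] and row["admission_date"] < "20000101")
        ]
        assert filtered.expected_output["HMD"] == manual

    def test_unregistered_collection_rejected(self):
        env = build_environment(seed=9, n_persons=20, collection_ids=("HMD",))
        with pytest.raises(ConfigurationError):
            make_project(env, "T1", "P1", ["HMD", "ZZZ"], cohort=set())

    def test_expected_output_independent_of_engine(self, monkeypatch):
        """Mutating the engine's transform interpreter must not change the
        fixture's ground truth."""
        import cares.extraction_engine as engine

        env = build_environment(seed=9, n_persons=40, collection_ids=("HMD",))
        cohort = pick_cohort(env, 20, seed=2)
        _t, before = make_project(env, "T1", "P1", ["HMD"], cohort=cohort)

        def sabotage(rows, field_order, steps):  # pragma: no cover - must not run
            raise AssertionError("fixture construction called the engine")

        monkeypatch.setattr(engine, "apply_steps", sabotage)
        _t, after = make_project(env, "T2", "P1", ["HMD"], cohort=cohort)
        assert before.expected_output == after.expected_output


class TestInjectDiscrepancies:
    def _table(self, n=10):
        return [
            {"person_key": f"k{i:03d}", "code": f"c{i}", "value": str(i)}
            for i in range(n)
        ]

    def test_identity(self):
        table = self._table()
        out, ledger = inject_discrepancies(table, 0, 0, seed=1)
        assert out == table
        assert ledger == []

    def test_counting(self):
        table = self._table(10)
        out, ledger = inject_discrepancies(
            table, 3, 2, seed=1, key_fields=("person_key",)
        )
        assert len(out) == 7
        assert len(ledger) == 5
        unaltered = [r for r in out if r in table]
        assert len(unaltered) == 5  # 10 - 3 dropped - 2 perturbed

    def test_replay_reproduces_perturbed_table(self):
        table = self._table(25)
        out, ledger = inject_discrepancies(
            table, 4, 6, seed=7, key_fields=("person_key",)
        )
        assert replay_ledger(table, ledger) == out

    def test_over_budget_rejected(self):
        with pytest.raises(InvalidParameterError):
            inject_discrepancies(self._table(5), 3, 3, seed=1)

    def test_perturbation_never_touches_key_fields(self):
        table = self._table(20)
        _out, ledger = inject_discrepancies(
            table, 0, 10, seed=3, key_fields=("person_key",)
        )
        assert all(c.field != "person_key" for c in ledger)
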