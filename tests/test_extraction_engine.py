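"""The six-step module procedure: key import, fail-closed governance,
transform semantics and the classical baseline."""

from __future__ import annotations

import re

import pytest

from cares.errors import (
    AuthenticationError,
    AuthorisationError,
    KeyfileError,
    TaskError,
)
from cares.extraction_engine import (
    TransformStep,
    authenticate,
    import_keyfile,
    run_classical,
    run_module,
)
from cares.metrics import ZERO_DELAY
from cares.qa_standardisation import records_to_csv, standardise
from cares.workflow import OPERATOR, OPERATOR_PASSWORD, make_project, pick_cohort

TOKEN = "0" * 32


class TestAuthenticate:
    def test_correct_credentials_open_session(self, small_env):
        session = authenticate(small_env.governance, OPERATOR, OPERATOR_PASSWORD)
        assert session.user_id == OPERATOR

    def test_wrong_password_rejected(self, small_env):
        with pytest.raises(AuthenticationError):
            authenticate(small_env.governance, OPERATOR, "wrong")

    def test_unknown_user_message_identical_to_wrong_password(self, small_env):
        with pytest.raises(AuthenticationError) as wrong:
            authenticate(small_env.governance, OPERATOR, "wrong")
        with pytest.raises(AuthenticationError) as ghost:
            authenticate(small_env.governance, "nobody", "wrong")
        assert str(wrong.value) == str(ghost.value)


class TestImportKeyfile:
    def test_valid_rows(self):
        text = "cares_id,person_key\n" + "".join(
            f"{i:032x},k{i}\n" for i in range(5)
        )
        rows, report = import_keyfile(text)
        assert len(rows) == 5
        assert (report.n_duplicates, report.n_malformed) == (0, 0)

    def test_exact_duplicates_dropped_with_count(self):
        text = (
            "cares_id,person_key\n"
            f"{1:032x},ka\n{2:032x},kb\n{1:032x},ka\n{3:032x},kc\n{1:032x},ka\n"
        )
        rows, report = import_keyfile(text)
        assert len(rows) == 3
        assert report.n_duplicates == 2

    def test_ambiguous_identity_aborts_naming_id(self):
        text = f"cares_id,person_key\n{7:032x},ka\n{7:032x},kb\n"
        with pytest.raises(KeyfileError, match=f"{7:032x}"):
            import_keyfile(text)

    def test_malformed_rows_reported(self):
        text = f"cares_id,person_key\n{1:032x},ka\nonly-one-column\n,empty\n"
        rows, report = import_keyfile(text)
        assert len(rows) == 1
        assert report.n_malformed == 2

    def test_missing_header_rejected(self):
        with pytest.raises(KeyfileError):
            import_keyfile("a,b\nxx,yy\n")

    def test_reads_from_path(self, tmp_path):
        path = tmp_path / "keys.csv"
        path.write_text(f"cares_id,person_key\n{5:032x},kz\n")
        rows, _ = import_keyfile(path)
        assert rows[0].person_key == "kz"


class TestRunModule:
    def test_output_matches_ground_truth_without_steps(self, small_env):
        cohort = pick_cohort(small_env, 25, seed=3)
        task, fixture = make_project(
            small_env, "T10", "P10", ["HMD", "BTH"], cohort=cohort
        )
        outputs = run_module(small_env.operator_session(), task, small_env.hub)
        for cid in task.collection_ids:
            assert outputs[cid].records == fixture.expected_output[cid]

    def test_exclusion_step_matches_oracle(self, small_env):
        cohort = pick_cohort(small_env, 25, seed=3)
        step = TransformStep(
            kind="exclusion",
            params={"field": "triage_category", "op": "in-set", "value": ["1", "2"]},
        )
        task, fixture = make_project(
            small_env, "T11", "P11", ["EDC"], cohort=cohort, steps=[step]
        )
        outputs = run_module(small_env.operator_session(), task, small_env.hub)
        assert outputs["EDC"].records == fixture.expected_output["EDC"]

    def test_empty_key_file_boundary(self, small_env):
        task, _ = make_project(small_env, "T12", "P12", ["HMD"], cohort=set())
        outputs = run_module(small_env.operator_session(), task, small_env.hub)
        qa = outputs["HMD"].qa
        assert (qa.rows_in, qa.rows_out) == (0, 0)
        assert outputs["HMD"].records == []

    def test_fail_closed_when_any_collection_denied(self, small_env):
        cohort = pick_cohort(small_env, 10, seed=4)
        task, _ = make_project(small_env, "T13", "P13", ["HMD"], cohort=cohort)
        # extend the task to a collection the operator was never granted
        task.collection_ids.append("EDC")
        task.key_files["EDC"] = []
        session = small_env.operator_session()
        runs_before = small_env.governance.audit.count("extraction-run")
        with pytest.raises(AuthorisationError, match="no data touched"):
            run_module(session, task, small_env.hub)
        assert small_env.governance.audit.count("extraction-run") == runs_before

    def test_step_referencing_missing_field_names_index(self, small_env):
        cohort = pick_cohort(small_env, 5, seed=5)
        steps = [
            TransformStep(
                kind="filter",
                params={"field": "length_of_stay", "op": ">", "value": 1},
            ),
            TransformStep(
                kind="filter", params={"field": "no_such_field", "op": "=", "value": 0}
            ),
        ]
        task, _ = make_project(small_env, "T14", "P14", ["HMD"], cohort=cohort, steps=steps)
        with pytest.raises(TaskError, match="step 1"):
            run_module(small_env.operator_session(), task, small_env.hub)

    def test_step_order_sensitivity_matches_oracle(self, small_env):
        """Permuting a recode and a filter on the recoded value changes the
        output exactly as the brute-force oracle predicts."""
        cohort = pick_cohort(small_env, 30, seed=6)
        recode = TransformStep(
            kind="field_map",
            params={"field": "hospital_type", "recode": {"metro": "urban"}},
        )
        keep_urban = TransformStep(
            kind="filter",
            params={"field": "hospital_type", "op": "=", "value": "urban"},
        )
        task_a, fix_a = make_project(
            small_env, "T15", "P15", ["HMD"], cohort=cohort, steps=[recode, keep_urban]
        )
        task_b, fix_b = make_project(
            small_env, "T16", "P15", ["HMD"], cohort=cohort, steps=[keep_urban, recode]
        )
        out_a = run_module(small_env.operator_session(), task_a, small_env.hub)
        out_b = run_module(small_env.operator_session(), task_b, small_env.hub)
        assert out_a["HMD"].records == fix_a.expected_output["HMD"]
        assert out_b["HMD"].records == fix_b.expected_output["HMD"]
        assert out_a["HMD"].records and not out_b["HMD"].records

    def test_researcher_output_drops_record_token_by_default(self, small_env):
        cohort = pick_cohort(small_env, 10, seed=7)
        task, _ = make_project(small_env, "T17", "P17", ["HMD"], cohort=cohort)
        outputs = run_module(small_env.operator_session(), task, small_env.hub)
        assert "cares_id" not in outputs["HMD"].layout.field_names

    def test_keep_record_token_flag_for_qa_workflows(self, small_env):
        cohort = pick_cohort(small_env, 10, seed=7)
        task, fixture = make_project(
            small_env, "T18", "P18", ["HMD"], cohort=cohort, keep_record_token=True
        )
        outputs = run_module(small_env.operator_session(), task, small_env.hub)
        assert "cares_id" in outputs["HMD"].layout.field_names
        assert outputs["HMD"].records == fixture.expected_output["HMD"]

    def test_single_operator_runs_multi_collection_task(self, small_env):
        """One session, no per-collection credentials."""
        cohort = pick_cohort(small_env, 15, seed=8)
        task, _ = make_project(
            small_env, "T19", "P19", ["HMD", "EDC", "BTH"], cohort=cohort
        )
        session = small_env.operator_session()
        outputs = run_module(session, task, small_env.hub)
        assert set(outputs) == {"HMD", "EDC", "BTH"}
        assert task.completed_on is not None


class TestRunClassical:
    def test_record_content_equals_central_mode(self, small_env):
        cohort = pick_cohort(small_env, 20, seed=9)
        task, _ = make_project(small_env, "T20", "P20", ["HMD", "EDC"], cohort=cohort)
        session = small_env.operator_session()
        central = run_module(session, task, small_env.hub)
        classical = run_classical(task, small_env.hub, session, delay_model=ZERO_DELAY)
        for cid in task.collection_ids:
            layout = central[cid].layout
            normalised = standardise(
                classical[cid].records, layout, dialect=classical[cid].dialect
            )
            assert records_to_csv(normalised, layout.field_names) == central[
                cid
            ].to_csv_text()

    def test_dates_rendered_in_collection_dialect(self, small_env):
        cohort = pick_cohort(small_env, 20, seed=9)
        task, _ = make_project(small_env, "T21", "P21", ["HMD"], cohort=cohort)
        session = small_env.operator_session()
        classical = run_classical(task, small_env.hub, session, delay_model=ZERO_DELAY)
        rows = classical["HMD"].records
        assert rows
        assert all(
            re.match(r"^\d{2}/\d{2}/\d{4}$", r["admission_date"]) for r in rows
        )

    def test_zero_delay_completes_on_request_date(self, small_env):
        cohort = pick_cohort(small_env, 5, seed=9)
        task, _ = make_project(small_env, "T22", "P22", ["HMD"], cohort=cohort)
        classical = run_classical(
            task, small_env.hub, small_env.operator_session(), delay_model=ZERO_DELAY
        )
        assert classical["HMD"].completed_on == task.requested_on
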