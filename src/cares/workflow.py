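"""End-to-end wiring: build a populated hub, tasks and fixtures in one call.

Convenience layer over the individual modules — nothing here adds behaviour,
it only assembles populations, collections, keys, governance and the hub into
ready-to-run scenarios.  The randomised fixture factory is the workhorse of
the oracle-equivalence and separation test suites.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
from dataclasses import dataclass, field

import numpy as np

from .crypto_ids import CollectionKey, KeyEscrow, generate_collection_key
from .extraction_engine import ExtractionTask, Session, TransformStep, authenticate
from .governance import AccessGrant, GovernanceRegistry, TaskApproval, User
from .hub_store import Hub
from .synthetic_data import (
    CollectionSchema,
    Person,
    ProjectFixture,
    SourceRecordTable,
    build_fixture,
    default_schemas,
    generate_collection,
    generate_population,
)

ON_DATE = _dt.date(2013, 1, 1)

OPERATOR = "ops.analyst"
OPERATOR_PASSWORD = "module-operator-pw"
CUSTODIAN = "cust.owner"
LINKAGE_OFFICER = "dlb.officer"
OUTSIDER = "ext.researcher"


def _derived_seed(seed: int, label: str) -> int:
    digest = hashlib.sha256(f"{seed}|{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class Environment:
    """A fully wired desk-scale deployment."""

    seed: int
    population: list[Person]
    collections: dict[str, tuple[CollectionSchema, SourceRecordTable]]
    keys: dict[str, CollectionKey]
    escrow: KeyEscrow
    governance: GovernanceRegistry
    hub: Hub
    project_secret: bytes
    load_reports: dict[str, object] = field(default_factory=dict)

    def operator_session(self) -> Session:
        return authenticate(self.governance, OPERATOR, OPERATOR_PASSWORD)

    def authorise(self, user_id: str, task_id: str, collection_ids) -> None:
        """Grant dataset access and task approval for every collection."""
        self.governance.register_task(task_id)
        for cid in collection_ids:
            self.governance.grant_access(
                AccessGrant(
                    user_id=user_id,
                    collection_id=cid,
                    granted_by=CUSTODIAN,
                    granted_on=ON_DATE - _dt.timedelta(days=30),
                )
            )
            self.governance.approve_task(
                TaskApproval(
                    task_id=task_id,
                    collection_id=cid,
                    approved_by=CUSTODIAN,
                    evidence="email of confirmation",
                    approved_on=ON_DATE - _dt.timedelta(days=7),
                )
            )


def build_environment(
    seed: int,
    n_persons: int = 300,
    collection_ids: tuple[str, ...] | None = None,
    coverage: float = 0.7,
    mean_records_per_person: float = 2.0,
) -> Environment:
    """Population + collections + governance + loaded hub, reproducibly."""
    schemas = default_schemas()
    chosen = collection_ids if collection_ids is not None else tuple(sorted(schemas))
    population = generate_population(n_persons, seed=_derived_seed(seed, "pop"))

    governance = GovernanceRegistry()
    signed = ON_DATE - _dt.timedelta(days=365)
    governance.register_user(
        User(CUSTODIAN, frozenset({"custodian"}), confidentiality_signed=signed),
        password="custodian-pw",
    )
    governance.register_user(
        User(OPERATOR, frozenset({"cares-user"}), confidentiality_signed=signed),
        password=OPERATOR_PASSWORD,
    )
    governance.register_user(
        User(
            LINKAGE_OFFICER,
            frozenset({"linkage-officer", "cares-user"}),
            confidentiality_signed=signed,
        ),
        password="officer-pw",
    )
    governance.register_user(
        User(OUTSIDER, frozenset({"cares-user"})), password="outsider-pw"
    )

    hub = Hub(governance)
    escrow = KeyEscrow()
    collections: dict[str, tuple[CollectionSchema, SourceRecordTable]] = {}
    keys: dict[str, CollectionKey] = {}
    env = Environment(
        seed=seed,
        population=population,
        collections=collections,
        keys=keys,
        escrow=escrow,
        governance=governance,
        hub=hub,
        project_secret=hashlib.sha256(f"project-secret|{seed}".encode()).digest(),
    )
    for cid in chosen:
        schema = schemas[cid]
        table = generate_collection(
            population,
            schema,
            coverage=coverage,
            mean_records_per_person=mean_records_per_person,
            seed=_derived_seed(seed, f"col|{cid}"),
        )
        key = generate_collection_key(cid, seed=_derived_seed(seed, f"key|{cid}"))
        hub.register_collection(schema)
        report = hub.load_update(cid, table, key, mode="full", escrow=escrow)
        collections[cid] = (schema, table)
        keys[cid] = key
        env.load_reports[cid] = report
    return env


def pick_cohort(env: Environment, size: int, seed: int) -> set[str]:
    rng = np.random.default_rng(seed)
    ids = sorted(p.root_id for p in env.population)
    size = min(size, len(ids))
    chosen = rng.choice(len(ids), size=size, replace=False)
    return {ids[int(i)] for i in chosen}


def make_project(
    env: Environment,
    task_id: str,
    project_id: str,
    collection_ids: list[str],
    cohort: set[str],
    steps=(),
    date_window=None,
    keep_record_token: bool = False,
    requested_on: _dt.date = ON_DATE,
) -> tuple[ExtractionTask, ProjectFixture]:
    """Build the task + its ground-truth fixture and wire up governance."""
    task = ExtractionTask(
        task_id=task_id,
        project_id=project_id,
        collection_ids=list(collection_ids),
        key_files={},
        steps=steps,
        requested_on=requested_on,
        date_window=date_window,
        keep_record_token=keep_record_token,
    )
    fixture = build_fixture(
        env.population,
        env.collections,
        cohort,
        task,
        collection_keys=env.keys,
        project_secret=env.project_secret,
    )
    task.key_files = {cid: pairs for cid, pairs in fixture.key_files.items()}
    env.authorise(OPERATOR, task_id, collection_ids)
    return task, fixture


# ---------------------------------------------------------------------------
# randomised fixtures (oracle-equivalence workhorse)
# ---------------------------------------------------------------------------

def _random_predicate(rng, name: str, info) -> dict | None:
    kind, extra = info
    if kind == "date":
        start = _dt.date(1990, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 6000)))
        if rng.random() < 0.5:
            end = start + _dt.timedelta(days=int(rng.integers(200, 4000)))
            return {"field": name, "op": "in-date-range",
                    "value": (start.isoformat(), end.isoformat())}
        op = str(rng.choice([">=", "<", ">", "<="]))
        return {"field": name, "op": op, "value": start.isoformat()}
    if kind == "integer":
        op = str(rng.choice(["<", "<=", ">", ">=", "=", "!="]))
        return {"field": name, "op": op, "value": int(rng.integers(0, 500))}
    if kind == "category":
        levels = list(extra)
        if rng.random() < 0.5:
            take = max(1, int(rng.integers(1, len(levels) + 1)))
            picked = [levels[int(i)] for i in rng.choice(len(levels), size=take, replace=False)]
            return {"field": name, "op": "in-set", "value": picked}
        op = str(rng.choice(["=", "!="]))
        return {"field": name, "op": op, "value": str(rng.choice(levels))}
    return None


def random_steps_for_schema(
    schema: CollectionSchema, n_steps: int, seed: int
) -> list[TransformStep]:
    """A valid random step list referencing only fields live at each point."""
    rng = np.random.default_rng(seed)
    # live field info: name -> (kind, extra)
    info: dict[str, tuple] = {}
    for name in schema.approved_items:
        spec = schema.field_spec(name)
        info[name] = (spec.ftype, spec.levels)
    steps: list[TransformStep] = []
    derived_serial = 0
    attempts = 0
    while len(steps) < n_steps and attempts < 20 * (n_steps + 1):
        attempts += 1
        kind = str(rng.choice(["filter", "exclusion", "field_map", "derived_field"]))
        if kind in ("filter", "exclusion"):
            candidates = [n for n, (k, _) in info.items() if k in ("date", "integer", "category")]
            if not candidates:
                break
            name = str(rng.choice(sorted(candidates)))
            params = _random_predicate(rng, name, info[name])
            if params is None:
                continue
            steps.append(TransformStep(kind=kind, params=params))
        elif kind == "field_map":
            name = str(rng.choice(sorted(info)))
            new_name = f"{name}_r"
            if new_name in info:
                continue
            fkind, extra = info.pop(name)
            params: dict = {"field": name, "rename": new_name}
            if fkind == "category" and rng.random() < 0.5:
                levels = list(extra)
                src = str(rng.choice(levels))
                params["recode"] = {src: f"{src}x"}
                extra = tuple(sorted({(f"{src}x" if l == src else l) for l in levels}))
            info[new_name] = (fkind, extra)
            steps.append(TransformStep(kind="field_map", params=params))
        else:
            dates = sorted(n for n, (k, _) in info.items() if k == "date")
            ints = sorted(n for n, (k, _) in info.items() if k == "integer")
            cats = sorted(n for n, (k, _) in info.items() if k == "category")
            derived_serial += 1
            dname = f"derived_{derived_serial}"
            if len(dates) >= 2 and rng.random() < 0.6:
                op = str(rng.choice(["days_between", "years_between"]))
                a, b = dates[1], dates[0]
                expr = {"op": op, "args": [a, b]}
                info[dname] = ("integer", None)
            elif ints:
                op = str(rng.choice(["+", "-", "*"]))
                expr = {"op": op, "args": [str(rng.choice(ints)), int(rng.integers(1, 10))]}
                info[dname] = ("integer", None)
            elif cats:
                cname = str(rng.choice(cats))
                levels = list(info[cname][1])
                expr = {
                    "op": "recode",
                    "args": [cname],
                    "mapping": {levels[0]: "grp_a"},
                }
                info[dname] = ("text", None)
            else:
                continue
            steps.append(
                TransformStep(kind="derived_field", params={"name": dname, "expr": expr})
            )
    return steps


@dataclass
class RandomScenario:
    env: Environment
    task: ExtractionTask
    fixture: ProjectFixture
    session: Session


def random_scenario(
    seed: int,
    max_cohort: int = 500,
    max_collections: int = 6,
    max_steps: int = 4,
) -> RandomScenario:
    """A random project over random collections, cohort and transform steps,
    with the brute-force fixture attached."""
    rng = np.random.default_rng(seed)
    cohort_size = int(rng.integers(0, max_cohort + 1))
    n_persons = max(cohort_size + int(rng.integers(20, 80)), 30)
    all_ids = tuple(sorted(default_schemas()))
    n_collections = int(rng.integers(1, max_collections + 1))
    chosen = tuple(
        all_ids[int(i)]
        for i in rng.choice(len(all_ids), size=min(n_collections, len(all_ids)), replace=False)
    )
    env = build_environment(
        seed=_derived_seed(seed, "env"),
        n_persons=n_persons,
        collection_ids=chosen,
        coverage=float(rng.uniform(0.3, 1.0)),
        mean_records_per_person=float(rng.uniform(1.0, 2.5)),
    )
    cohort = pick_cohort(env, cohort_size, seed=_derived_seed(seed, "cohort"))
    steps = {
        cid: random_steps_for_schema(
            env.collections[cid][0],
            int(rng.integers(0, max_steps + 1)),
            seed=_derived_seed(seed, f"steps|{cid}"),
        )
        for cid in chosen
    }
    window = None
    if rng.random() < 0.5:
        window = (_dt.date(2000, 1, 1), _dt.date(2010, 12, 31))
    task, fixture = make_project(
        env,
        task_id=f"T{seed}",
        project_id=f"PRJ{seed}",
        collection_ids=list(chosen),
        cohort=cohort,
        steps=steps,
        date_window=window,
    )
    return RandomScenario(env=env, task=task, fixture=fixture, session=env.operator_session())
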