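"""Shared fixtures.

The randomised-scenario batch is session-scoped because several independent
checks (oracle equivalence, separation scanning, QA conservation) all consume
the same set of end-to-end runs.
"""

from __future__ import annotations

import pytest

from cares.extraction_engine import run_module
from cares.workflow import build_environment, random_scenario

#: seeds for the randomised oracle-equivalence batch
BATCH_SEEDS = list(range(100, 150))


@pytest.fixture(scope="session")
def scenario_batch():
    """50 random project scenarios, each executed once through the engine.

    Returns a list of (scenario, outputs) pairs covering cohort sizes 0-500,
    1-6 collections and 0-4 transform steps.
    """
    batch = []
    for seed in BATCH_SEEDS:
        scenario = random_scenario(seed)
        outputs = run_module(scenario.session, scenario.task, scenario.env.hub)
        batch.append((scenario, outputs))
    return batch


@pytest.fixture()
def small_env():
    """A small wired deployment over three collections."""
    return build_environment(
        seed=42, n_persons=60, collection_ids=("HMD", "EDC", "BTH"), coverage=0.9
    )
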