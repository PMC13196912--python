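import numpy as np
import pandas as pd
import pytest

from maiclab.synthetic_data import (
    default_scenario,
    generate_index_ipd,
    generate_trial,
    summarize_to_target,
)
from maiclab.trial_data import IPDTable


@pytest.fixture(scope="session")
def default_bundle():
    """One realistic synthetic ecosystem shared across the suite:
    pooled index IPD, the comparator trial's aggregate target, and
    per-outcome comparator counts."""
    scenario = default_scenario(seed=42)
    ipd = generate_index_ipd(scenario)
    cmp_ipd = generate_trial(scenario, scenario.comparator.trial_id)
    target, comparators = summarize_to_target(cmp_ipd)
    return {
        "scenario": scenario,
        "ipd": ipd,
        "comparator_ipd": cmp_ipd,
        "target": target,
        "comparators": comparators,
    }


def build_ipd(rows, covariates=("race", "cigarettes_per_day"), outcomes=("quit",)):
    """Construct a small validated IPDTable from a list of row dicts."""
    df = pd.DataFrame(rows)
    return IPDTable(df.reset_index(drop=True), tuple(covariates), tuple(outcomes))


@pytest.fixture
def tiny_ipd():
    """One trial, two arms, four participants per arm."""
    rows = []
    for i, (arm, race, cigs, quit) in enumerate(
        [
            ("active", 0, 12.0, 1), ("active", 1, 20.0, 1),
            ("active", 0, 15.0, 0), ("active", 1, 30.0, 0),
            ("control", 0, 14.0, 1), ("control", 1, 22.0, 0),
            ("control", 0, 18.0, 0), ("control", 1, 25.0, 0),
        ]
    ):
        rows.append(
            {
                "patient_id": f"P{i}", "trial_id": "T1", "arm": arm,
                "race": float(race), "cigarettes_per_day": cigs, "quit": float(quit),
            }
        )
    return build_ipd(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
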