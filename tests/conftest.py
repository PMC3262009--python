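import numpy as np
import pandas as pd
import pytest

from ambigen import dp_generalization as dp
from ambigen import task_paradigm as tp


@pytest.fixture(scope="session")
def default_task():
    """One default task realization (600 trials, bernoulli outcomes)."""
    return tp.generate_task(tp.TaskConfig(seed=11))


@pytest.fixture(scope="session")
def small_chain():
    """Short chain settings for fast trajectory tests."""
    return dp.DPConfig(n_samples=300, burn_in=60, seed=3)


@pytest.fixture(scope="session")
def m1_trajectory(default_task, small_chain):
    trials, _ = default_task
    return dp.run_m1_trajectory(trials, small_chain)


def make_trials(records):
    """Build a minimal trial table from (cue, context, outcome) tuples."""
    rows = []
    for t, (cue, ctx, lam) in enumerate(records):
        rows.append(
            {
                "trial": t,
                "block": 0,
                "within_block": t + 1,
                "cue_id": cue,
                "context": ctx,
                "outcome": lam,
                "choice": np.nan,
                "reward": np.nan,
                "choice_onset": 4.0 * t,
                "outcome_onset": 4.0 * t + 1.5,
            }
        )
    return pd.DataFrame(rows, columns=tp.TRIAL_COLUMNS)
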