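"""Shared fixtures: hand-built trial logs and session-scoped simulated
cohorts/fits reused by several test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from probswitch.cohort import CohortSpec, generate_cohort
from probswitch.fitting import McmcSettings, fit_hierarchical
from probswitch.task import TRIAL_COLUMNS


def make_log(choices, rewards, correct=None, responded=None, reversal=None,
             pid="p0", block=0) -> pd.DataFrame:
    """Build a tidy trial log from short hand-written sequences.

    ``choices``/``rewards`` may contain None for non-responded trials.
    """
    n = len(choices)
    if correct is None:
        correct = [0] * n
    if responded is None:
        responded = [c is not None for c in choices]
    if reversal is None:
        reversal = [False] * n
    rows = []
    for t in range(n):
        rows.append((
            pid, block, t, correct[t],
            pd.NA if choices[t] is None else choices[t],
            pd.NA if rewards[t] is None else rewards[t],
            bool(responded[t]), bool(reversal[t]),
        ))
    log = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    log["chosen_side"] = log["chosen_side"].astype("Int64")
    log["rewarded"] = log["rewarded"].astype("Int64")
    return log


@pytest.fixture(scope="session")
def rl_cohort20():
    """20 RL-generated participants x 2 blocks with known true parameters."""
    return generate_cohort(CohortSpec(n_participants=20, blocks_per_participant=2, seed=11))


@pytest.fixture(scope="session")
def rl_fit20(rl_cohort20):
    """Hierarchical RL fit of the 20-participant cohort at reduced settings
    (2 chains, 500 warm-up, 500 kept draws)."""
    return fit_hierarchical(
        rl_cohort20.logs, "rl",
        settings=McmcSettings(n_chains=2, n_warmup=500, n_iterations=1000, seed=1),
    )
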