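"""Probabilistic switching (reversal learning) task engine.

The task is a two-armed bandit with reversals: one of two boxes is "correct"
and pays a coin with probability ``p_reward_correct`` (0.75 by default); the
other never pays. After a uniformly sampled number of rewarded choices on the
correct side (5-15 inclusive), the correct box reverses immediately following
a rewarded correct choice. Reward outcomes for correct choices and the switch
criteria are pre-randomized (sampled offline) so that realized reward
proportions match the nominal probabilities exactly.

Sides are encoded ``left=0``, ``right=1`` throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LEFT = 0
RIGHT = 1
SIDES = (LEFT, RIGHT)

#: Column order of a trial log (one row per trial).
TRIAL_COLUMNS = [
    "participant_id",
    "block_id",
    "trial",
    "correct_side",
    "chosen_side",
    "rewarded",
    "responded",
    "reversal_trial",
]


class TaskConfigError(ValueError):
    """Raised for invalid task configurations or schedule requests."""


@dataclass(frozen=True)
class TaskConfig:
    """Design parameters of one task block.

    Defaults reproduce the study design: 150 trials, 75% reward on the
    correct box, 0% on the incorrect box, switch criteria uniform on 5-15
    rewarded trials, correct box starting on the left, four pre-randomized
    sequence versions.
    """

    n_trials: int = 150
    p_reward_correct: float = 0.75
    p_reward_incorrect: float = 0.0
    criterion_min: int = 5
    criterion_max: int = 15
    first_correct_side: int = LEFT
    n_sequence_versions: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise TaskConfigError("n_trials must be a positive integer")
        if not 0.0 <= self.p_reward_incorrect <= self.p_reward_correct <= 1.0:
            raise TaskConfigError(
                "require 0 <= p_reward_incorrect <= p_reward_correct <= 1"
            )
        if not 1 <= self.criterion_min <= self.criterion_max:
            raise TaskConfigError("require 1 <= criterion_min <= criterion_max")
        if self.first_correct_side not in SIDES:
            raise TaskConfigError("first_correct_side must be 0 (left) or 1 (right)")
        if self.n_sequence_versions < 1:
            raise TaskConfigError("n_sequence_versions must be positive")


# Pre-randomized reward flags are built in shuffled fixed-proportion chunks so
# that every fully consumed chunk realizes p_reward_correct exactly.
_FLAG_CHUNK = 20


@dataclass
class BlockSchedule:
    """Pre-randomized outcome sequence and switch criteria for one block.

    ``reward_flags`` is consumed once per responded correct choice;
    ``switch_criteria`` once per reversal. Both auto-extend (seeded) if a
    session outruns the pre-generated material, so sessions never truncate.
    """

    reward_flags: np.ndarray
    switch_criteria: np.ndarray
    version_id: int
    config: TaskConfig
    _rng: np.random.Generator = field(repr=False, default=None)

    def _extend_flags(self) -> None:
        self.reward_flags = np.concatenate(
            [self.reward_flags, _reward_flag_chunks(self.config, self._rng, 1)]
        )

    def _extend_criteria(self) -> None:
        extra = self._rng.integers(
            self.config.criterion_min, self.config.criterion_max + 1, size=8
        )
        self.switch_criteria = np.concatenate([self.switch_criteria, extra])

    def flag(self, i: int) -> int:
        while i >= len(self.reward_flags):
            self._extend_flags()
        return int(self.reward_flags[i])

    def criterion(self, j: int) -> int:
        while j >= len(self.switch_criteria):
            self._extend_criteria()
        return int(self.switch_criteria[j])


def _reward_flag_chunks(
    config: TaskConfig, rng: np.random.Generator, n_chunks: int
) -> np.ndarray:
    """Shuffled fixed-proportion reward flags in chunks of ``_FLAG_CHUNK``."""
    n_ones = int(round(config.p_reward_correct * _FLAG_CHUNK))
    chunks = []
    for _ in range(n_chunks):
        chunk = np.zeros(_FLAG_CHUNK, dtype=np.int64)
        chunk[:n_ones] = 1
        rng.shuffle(chunk)
        chunks.append(chunk)
    return np.concatenate(chunks)


def build_block_schedule(config: TaskConfig, version: int = 0) -> BlockSchedule:
    """Build the pre-randomized schedule for one sequence version.

    The RNG stream is derived from ``(config.rng_seed, version)`` so each
    version is an independent, reproducible sequence. Enough reward flags and
    criteria are generated to cover ``n_trials`` under any play pattern
    (auto-extension covers pathological policies).
    """
    if not 0 <= version < config.n_sequence_versions:
        raise TaskConfigError(
            f"version {version} out of range [0, {config.n_sequence_versions})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, version]))
    n_chunks = -(-config.n_trials // _FLAG_CHUNK) + 1
    flags = _reward_flag_chunks(config, rng, n_chunks)
    # At most n_trials/criterion_min reversals can occur in a block.
    n_crit = config.n_trials // config.criterion_min + 2
    criteria = rng.integers(
        config.criterion_min, config.criterion_max + 1, size=n_crit
    )
    return BlockSchedule(
        reward_flags=flags,
        switch_criteria=criteria,
        version_id=version,
        config=config,
        _rng=rng,
    )


def run_session(
    schedule: BlockSchedule,
    config: TaskConfig,
    policy,
    participant_id: str = "p0",
    block_id: int = 0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Play one block of the task with a choice-producing policy.

    The policy must expose ``choose(t, correct_side) -> {0, 1, None}`` (None
    = no response within the 3-s window) and ``observe(t, choice, reward)``,
    called only on responded trials. Honest agents ignore ``correct_side``;
    it is passed so oracle policies can be built for analysis baselines.

    Reversal logic: rewarded choices of the correct box accumulate; when the
    count reaches the active switch criterion the correct box flips starting
    with the next trial, which is flagged ``reversal_trial``. Non-responses
    consume no reward flag and do not advance the count.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.rng_seed, schedule.version_id, 977])
        )
    if hasattr(policy, "reset"):
        policy.reset()

    correct = config.first_correct_side
    flag_ptr = 0
    crit_ptr = 0
    reward_count = 0
    reversal_next = False

    rows = []
    for t in range(config.n_trials):
        is_reversal = reversal_next
        if reversal_next:
            correct = 1 - correct
            reversal_next = False

        choice = policy.choose(t, correct)
        if choice is None:
            rows.append(
                (participant_id, block_id, t, correct, pd.NA, pd.NA, False, is_reversal)
            )
            continue
        if choice not in SIDES:
            raise ValueError(f"policy returned unknown side label {choice!r}")

        if choice == correct:
            rewarded = schedule.flag(flag_ptr)
            flag_ptr += 1
            if rewarded:
                reward_count += 1
                if reward_count >= schedule.criterion(crit_ptr):
                    crit_ptr += 1
                    reward_count = 0
                    reversal_next = True  # correct box flips on the next trial
        else:
            p = config.p_reward_incorrect
            rewarded = int(rng.random() < p) if p > 0 else 0

        policy.observe(t, choice, rewarded)
        rows.append(
            (participant_id, block_id, t, correct, choice, rewarded, True, is_reversal)
        )

    log = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    log["chosen_side"] = log["chosen_side"].astype("Int64")
    log["rewarded"] = log["rewarded"].astype("Int64")
    return log
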