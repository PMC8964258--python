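"""Scripted (analytic) task policies used as oracles and test baselines."""

from __future__ import annotations

import numpy as np

from .task import LEFT, RIGHT

POLICY_TAGS = ("wsls", "always-stay", "always-switch", "random", "oracle", "lag1-oracle")


class ScriptedPolicy:
    """Base class: deterministic or seeded rule-based policies."""

    def reset(self) -> None:
        self.last_choice: int | None = None
        self.last_reward: int | None = None

    def observe(self, t: int, choice: int, reward: int) -> None:
        self.last_choice = choice
        self.last_reward = reward


class WSLSPolicy(ScriptedPolicy):
    """Win-stay/lose-switch: repeat rewarded actions, abandon unrewarded ones."""

    def __init__(self, first_choice: int = LEFT):
        self.first_choice = first_choice
        self.reset()

    def choose(self, t: int, correct_side: int) -> int:
        if self.last_choice is None:
            return self.first_choice
        if self.last_reward == 1:
            return self.last_choice
        return 1 - self.last_choice


class AlwaysStayPolicy(ScriptedPolicy):
    def __init__(self, first_choice: int = LEFT):
        self.first_choice = first_choice
        self.reset()

    def choose(self, t: int, correct_side: int) -> int:
        return self.first_choice if self.last_choice is None else self.last_choice


class AlwaysSwitchPolicy(ScriptedPolicy):
    def __init__(self, first_choice: int = LEFT):
        self.first_choice = first_choice
        self.reset()

    def choose(self, t: int, correct_side: int) -> int:
        return self.first_choice if self.last_choice is None else 1 - self.last_choice


class RandomPolicy(ScriptedPolicy):
    """Uniform random choice (the beta=0 policy)."""

    def __init__(self, rng: np.random.Generator | None = None):
        self.rng = rng if rng is not None else np.random.default_rng()
        self.reset()

    def choose(self, t: int, correct_side: int) -> int:
        return int(self.rng.integers(2))


class OraclePolicy(ScriptedPolicy):
    """Always selects the currently correct box (knows the latent state)."""

    def choose(self, t: int, correct_side: int) -> int:
        return correct_side


class Lag1OraclePolicy(ScriptedPolicy):
    """Tracks the true correct side with a one-trial lag.

    Correct everywhere except the reversal trial itself, where it is always
    wrong - a sharp baseline for switch-aligned accuracy analyses.
    """

    def reset(self) -> None:
        super().reset()
        self.prev_correct: int | None = None

    def choose(self, t: int, correct_side: int) -> int:
        choice = correct_side if self.prev_correct is None else self.prev_correct
        self.prev_correct = correct_side
        return choice


class AlwaysIncorrectPolicy(ScriptedPolicy):
    """Always selects the incorrect box (never rewarded under default config)."""

    def choose(self, t: int, correct_side: int) -> int:
        return 1 - correct_side


def scripted_policies(name: str, rng: np.random.Generator | None = None):
    """Return a fresh policy instance for a named rule."""
    table = {
        "wsls": lambda: WSLSPolicy(),
        "always-stay": lambda: AlwaysStayPolicy(),
        "always-switch": lambda: AlwaysSwitchPolicy(),
        "random": lambda: RandomPolicy(rng),
        "oracle": lambda: OraclePolicy(),
        "lag1-oracle": lambda: Lag1OraclePolicy(),
        "always-incorrect": lambda: AlwaysIncorrectPolicy(),
    }
    if name not in table:
        raise ValueError(f"unknown policy tag {name!r}; known: {sorted(table)}")
    return table[name]()
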