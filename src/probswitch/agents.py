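"""Generative choice models for the probabilistic switching task.

Two four-parameter models, usable both as simulators (policies for
:func:`probswitch.task.run_session`) and as per-trial likelihood evaluators:

* **RL** — Q-learning with outcome-dependent learning rates (``alpha_pos``
  on rewarded trials, ``alpha_neg`` on unrewarded), counterfactual updating
  of the unchosen action toward the opposite outcome with the same
  outcome-selected rate, a sticky-choice bonus ``st`` on the previously
  chosen action, and a softmax policy with inverse temperature ``beta``.

* **BI** — Bayesian latent-state filtering: the agent tracks its belief
  that the correct box is on the left, updating by Bayes' rule with emission
  probabilities ``p_reward`` (correct box rewarded) and ``epsilon``
  (incorrect box rewarded, fixed small), then propagating the posterior
  through a symmetric switch kernel with per-trial switch probability
  ``p_switch``. The choice policy is the same softmax-plus-stickiness as RL,
  with beliefs in place of Q-values.

Both models start symmetric: Q(left)=Q(right)=0.5 and prior belief
p(C=left)=0.5; no stickiness bonus is applied before the first choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .task import LEFT, RIGHT

MODEL_TAGS = ("rl", "bi")

#: Fixed probability that the incorrect box is rewarded, under the agent's
#: task model. Small but nonzero to avoid a degenerate likelihood.
EPSILON_DEFAULT = 1e-4


@dataclass(frozen=True)
class RLParams:
    """Q-learning parameters: learning rates, inverse temperature, stickiness."""

    alpha_pos: float
    alpha_neg: float
    beta: float
    st: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_pos <= 1.0 or not 0.0 <= self.alpha_neg <= 1.0:
            raise ValueError("learning rates must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not -1.0 <= self.st <= 1.0:
            raise ValueError("st must lie in [-1, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_pos, self.alpha_neg, self.beta, self.st])


@dataclass(frozen=True)
class BIParams:
    """Bayesian-inference parameters: emission/switch probabilities, policy."""

    p_reward: float
    p_switch: float
    beta: float
    st: float
    epsilon: float = EPSILON_DEFAULT

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_reward <= 1.0 or not 0.0 <= self.p_switch <= 1.0:
            raise ValueError("p_reward and p_switch must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not -1.0 <= self.st <= 1.0:
            raise ValueError("st must lie in [-1, 1]")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_reward, self.p_switch, self.beta, self.st])


@dataclass
class AgentState:
    """Internal state of an agent: action values (RL) or belief (BI).

    For RL, ``values`` holds (Q(left), Q(right)); for BI it holds the belief
    pair (p(C=left), p(C=right)). ``last_action`` is None before the first
    responded trial.
    """

    values: np.ndarray
    last_action: int | None = None

    @classmethod
    def initial(cls, model: str) -> "AgentState":
        if model not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {model!r}")
        return cls(values=np.array([0.5, 0.5]), last_action=None)


def _validate_action_reward(action: int, reward: int) -> None:
    if action not in (LEFT, RIGHT):
        raise ValueError(f"unknown side label {action!r}")
    if reward not in (0, 1):
        raise ValueError(f"reward must be binary, got {reward!r}")


def rl_update(state: AgentState, params: RLParams, action: int, reward: int) -> AgentState:
    """One Q-learning step with counterfactual updating.

    The chosen action moves toward ``reward`` and the unchosen action toward
    ``1 - reward``, both at the outcome-selected rate (``alpha_pos`` if
    rewarded, ``alpha_neg`` if not) and both from pre-update values.
    """
    _validate_action_reward(action, reward)
    alpha = params.alpha_pos if reward == 1 else params.alpha_neg
    q = state.values.copy()
    other = 1 - action
    q_chosen, q_other = q[action], q[other]
    q[action] = q_chosen + alpha * (reward - q_chosen)
    q[other] = q_other + alpha * ((1 - reward) - q_other)
    return AgentState(values=q, last_action=action)


def _softmax_pair(w_left: float, w_right: float, beta: float) -> np.ndarray:
    # numerically stable two-option softmax: p(left) = sigmoid(beta * (wl - wr))
    d = beta * (w_left - w_right)
    if d >= 0:
        p_left = 1.0 / (1.0 + np.exp(-d))
    else:
        e = np.exp(d)
        p_left = e / (1.0 + e)
    return np.array([p_left, 1.0 - p_left])


def _choice_probs(state: AgentState, beta: float, st: float) -> np.ndarray:
    w = state.values.astype(float).copy()
    if state.last_action is not None:
        w[state.last_action] += st
    return _softmax_pair(w[LEFT], w[RIGHT], beta)


def rl_choice_probs(state: AgentState, params: RLParams) -> np.ndarray:
    """Softmax over sticky-boosted Q-values; returns (p(left), p(right))."""
    return _choice_probs(state, params.beta, params.st)


def bi_update(state: AgentState, params: BIParams, action: int, reward: int) -> AgentState:
    """One Bayesian filtering step.

    Computes the posterior over the correct side from the outcome likelihood,
    then mixes with ``p_switch`` to form the prior for the next trial (which
    is what the returned state holds).
    """
    _validate_action_reward(action, reward)
    b_left = float(state.values[LEFT])
    # emission likelihood p(r | C=side, action)
    lik = np.empty(2)
    for side in (LEFT, RIGHT):
        p1 = params.p_reward if action == side else params.epsilon
        lik[side] = p1 if reward == 1 else 1.0 - p1
    prior = np.array([b_left, 1.0 - b_left])
    joint = lik * prior
    z = joint.sum()
    if z <= 0.0:
        raise FloatingPointError("degenerate belief update: zero normalizer")
    post_left = joint[LEFT] / z
    next_left = (1.0 - params.p_switch) * post_left + params.p_switch * (1.0 - post_left)
    return AgentState(values=np.array([next_left, 1.0 - next_left]), last_action=action)


def bi_choice_probs(state: AgentState, params: BIParams) -> np.ndarray:
    """Softmax over sticky-boosted beliefs; returns (p(left), p(right))."""
    return _choice_probs(state, params.beta, params.st)


def session_loglik(log, params, model: str):
    """Log-likelihood of the observed choices in one participant-block log.

    Walks the trial sequence, computing choice probabilities before each
    responded trial and updating the agent state afterwards. Non-responded
    trials contribute nothing and trigger no update; ``last_action`` carries
    over. Returns ``(total, per_trial)`` where ``per_trial`` has one entry
    per responded trial, in trial order (as needed for WAIC).

    ``log`` may be a DataFrame holding a single contiguous participant-block
    sequence (columns ``chosen_side``, ``rewarded``, ``responded``).
    """
    if model == "rl":
        probs_fn, update_fn = rl_choice_probs, rl_update
    elif model == "bi":
        probs_fn, update_fn = bi_choice_probs, bi_update
    else:
        raise ValueError(f"unknown model tag {model!r}")

    state = AgentState.initial(model)
    per_trial = []
    for _, row in log.iterrows():
        if not row["responded"]:
            continue
        action = int(row["chosen_side"])
        reward = int(row["rewarded"])
        p = probs_fn(state, params)
        per_trial.append(np.log(p[action]))
        state = update_fn(state, params, action, reward)
    per_trial = np.asarray(per_trial)
    return float(per_trial.sum()), per_trial


class AgentPolicy:
    """Wraps a generative model as a task policy (simulator).

    Samples actions from the model's choice probabilities; never times out.
    """

    def __init__(self, params, model: str, rng: np.random.Generator | None = None):
        if model not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {model!r}")
        self.params = params
        self.model = model
        self.rng = rng if rng is not None else np.random.default_rng()
        self.reset()

    def reset(self) -> None:
        self.state = AgentState.initial(self.model)

    def choose(self, t: int, correct_side: int) -> int:
        probs_fn = rl_choice_probs if self.model == "rl" else bi_choice_probs
        p = probs_fn(self.state, self.params)
        return int(self.rng.random() >= p[LEFT])

    def observe(self, t: int, choice: int, reward: int) -> None:
        update_fn = rl_update if self.model == "rl" else bi_update
        self.state = update_fn(self.state, self.params, choice, reward)
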