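"""Compiled likelihood kernels for the RL and BI models.

These operate on responded trials only (non-responses are skipped for both
the likelihood and the internal update, so they are dropped upstream), with
agent state reset wherever ``new_block`` is set. They are the hot path of the
hierarchical sampler; :func:`probswitch.agents.session_loglik` is the plain
reference implementation of the same recursion.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _log_sigmoid(d):
    # log(1 / (1 + exp(-d))), stable
    if d >= 0.0:
        return -math.log1p(math.exp(-d))
    return d - math.log1p(math.exp(d))


@njit(cache=True)
def rl_trial_logliks(choices, rewards, new_block, alpha_pos, alpha_neg, beta, st,
                     counterfactual, out):
    """Per-trial choice log-likelihoods under the Q-learning model.

    ``choices``/``rewards`` are int64 arrays over responded trials;
    ``new_block`` marks trials where the agent state resets. Returns the
    total; per-trial values are written into ``out``.
    """
    ql = 0.5
    qr = 0.5
    last = -1
    total = 0.0
    for i in range(choices.shape[0]):
        if new_block[i]:
            ql = 0.5
            qr = 0.5
            last = -1
        wl = ql + (st if last == 0 else 0.0)
        wr = qr + (st if last == 1 else 0.0)
        d = beta * (wl - wr)
        a = choices[i]
        ll = _log_sigmoid(d) if a == 0 else _log_sigmoid(-d)
        out[i] = ll
        total += ll
        r = rewards[i]
        alpha = alpha_pos if r == 1 else alpha_neg
        if a == 0:
            ql = ql + alpha * (r - ql)
            if counterfactual:
                qr = qr + alpha * ((1 - r) - qr)
        else:
            qr = qr + alpha * (r - qr)
            if counterfactual:
                ql = ql + alpha * ((1 - r) - ql)
        last = a
    return total


@njit(cache=True)
def bi_trial_logliks(choices, rewards, new_block, p_reward, p_switch, beta, st,
                     epsilon, out):
    """Per-trial choice log-likelihoods under the Bayesian-inference model.

    ``b`` is the prior belief p(C=left) entering each trial; after the
    outcome it is updated by Bayes' rule and propagated through the switch
    kernel.
    """
    b = 0.5
    last = -1
    total = 0.0
    for i in range(choices.shape[0]):
        if new_block[i]:
            b = 0.5
            last = -1
        wl = b + (st if last == 0 else 0.0)
        wr = (1.0 - b) + (st if last == 1 else 0.0)
        d = beta * (wl - wr)
        a = choices[i]
        ll = _log_sigmoid(d) if a == 0 else _log_sigmoid(-d)
        out[i] = ll
        total += ll
        r = rewards[i]
        if a == 0:
            p_l = p_reward if r == 1 else 1.0 - p_reward
            p_r = epsilon if r == 1 else 1.0 - epsilon
        else:
            p_l = epsilon if r == 1 else 1.0 - epsilon
            p_r = p_reward if r == 1 else 1.0 - p_reward
        num = p_l * b
        z = num + p_r * (1.0 - b)
        post = num / z
        b = (1.0 - p_switch) * post + p_switch * (1.0 - post)
        last = a
    return total


@njit(cache=True)
def loglik_batch(kind, choices, rewards, new_block, offsets, params, epsilon,
                 counterfactual, out_total):
    """Total log-likelihood per subject for a stacked cohort.

    ``offsets`` delimits each subject's slice of the flat trial arrays;
    ``params`` is (n_subjects, 4) on the natural scale. ``kind`` 0 = RL,
    1 = BI.
    """
    n = offsets.shape[0] - 1
    scratch = np.empty(choices.shape[0])
    for s in range(n):
        lo = offsets[s]
        hi = offsets[s + 1]
        if kind == 0:
            out_total[s] = rl_trial_logliks(
                choices[lo:hi], rewards[lo:hi], new_block[lo:hi],
                params[s, 0], params[s, 1], params[s, 2], params[s, 3],
                counterfactual, scratch[lo:hi],
            )
        else:
            out_total[s] = bi_trial_logliks(
                choices[lo:hi], rewards[lo:hi], new_block[lo:hi],
                params[s, 0], params[s, 1], params[s, 2], params[s, 3],
                epsilon, scratch[lo:hi],
            )


@njit(cache=True)
def pointwise_batch(kind, choices, rewards, new_block, offsets, params, epsilon,
                    counterfactual, out):
    """Per-trial log-likelihoods for all subjects into the flat ``out``."""
    n = offsets.shape[0] - 1
    for s in range(n):
        lo = offsets[s]
        hi = offsets[s + 1]
        if kind == 0:
            rl_trial_logliks(
                choices[lo:hi], rewards[lo:hi], new_block[lo:hi],
                params[s, 0], params[s, 1], params[s, 2], params[s, 3],
                counterfactual, out[lo:hi],
            )
        else:
            bi_trial_logliks(
                choices[lo:hi], rewards[lo:hi], new_block[lo:hi],
                params[s, 0], params[s, 1], params[s, 2], params[s, 3],
                epsilon, out[lo:hi],
            )
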