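"""Model-free behavioral statistics for probabilistic switching trial logs.

All functions accept tidy trial-log DataFrames (columns as in
:data:`probswitch.task.TRIAL_COLUMNS`) holding one or many participant-blocks.
History windows never cross block boundaries, and any window containing a
non-responded trial is ineligible (outcome symbols are undefined there).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Case convention for the action-conditioned (aB) analysis: with the default
#: ``lowercase_unrewarded=True``, "ab" reads "unrewarded a at t-2, then an
#: unrewarded switch to b at t-1". Flippable for sensitivity analyses.
LOWERCASE_UNREWARDED = True

HISTORY3_KEYS = [a + b + c for a in "+-" for b in "+-" for c in "+-"]
AB_KEYS = ["aa", "ab", "aA", "aB", "Aa", "Ab", "AA", "AB"]


class UndefinedMeasureError(ValueError):
    """A behavioral measure is undefined for the given log (e.g. no responses)."""


def _iter_blocks(logs: pd.DataFrame):
    for (pid, bid), grp in logs.groupby(["participant_id", "block_id"], sort=True):
        yield pid, bid, grp.sort_values("trial")


def _block_arrays(grp: pd.DataFrame):
    responded = grp["responded"].to_numpy(dtype=bool)
    choice = grp["chosen_side"].to_numpy(dtype="float64", na_value=np.nan)
    reward = grp["rewarded"].to_numpy(dtype="float64", na_value=np.nan)
    correct = grp["correct_side"].to_numpy(dtype="int64")
    reversal = grp["reversal_trial"].to_numpy(dtype=bool)
    return responded, choice, reward, correct, reversal


def overall_performance(log: pd.DataFrame) -> float:
    """Fraction correct among responded trials (non-responses excluded)."""
    responded = log["responded"].to_numpy(dtype=bool)
    if not responded.any():
        raise UndefinedMeasureError("no responded trials: performance undefined")
    sub = log.loc[responded]
    return float(
        (sub["chosen_side"].to_numpy() == sub["correct_side"].to_numpy()).mean()
    )


def per_participant_performance(logs: pd.DataFrame) -> pd.Series:
    """Overall performance per participant, pooling their blocks."""
    return logs.groupby("participant_id").apply(
        overall_performance, include_groups=False
    )


def reversals_per_block(logs: pd.DataFrame) -> float:
    """Mean number of reversals per participant-block."""
    counts = [grp["reversal_trial"].sum() for _, _, grp in _iter_blocks(logs)]
    return float(np.mean(counts))


def switch_aligned_accuracy(
    logs: pd.DataFrame, window: tuple[int, int] = (-4, 5)
) -> pd.DataFrame:
    """Mean accuracy at trial offsets around each reversal (t=0 = first trial
    under the new contingency), averaged over all reversals and participants.

    Returns a tidy frame (offset, accuracy, sem, n). Offsets falling outside
    the block, or on non-responded trials, are skipped.
    """
    lo, hi = window
    offsets = np.arange(lo, hi + 1)
    acc: dict[int, list[float]] = {o: [] for o in offsets}
    n_rev = 0
    for _, _, grp in _iter_blocks(logs):
        responded, choice, _, correct, reversal = _block_arrays(grp)
        n = len(grp)
        for t0 in np.flatnonzero(reversal):
            n_rev += 1
            for o in offsets:
                t = t0 + o
                if 0 <= t < n and responded[t]:
                    acc[o].append(float(choice[t] == correct[t]))
    if n_rev == 0:
        import warnings

        warnings.warn("no reversals found in logs; switch-aligned curve is empty")
    rows = [
        (o, np.mean(v) if v else np.nan,
         np.std(v, ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
         len(v))
        for o, v in acc.items()
    ]
    return pd.DataFrame(rows, columns=["offset", "accuracy", "sem", "n"])


def _stay_events_3back(grp: pd.DataFrame):
    """Yield (key, stayed) for each eligible trial of one block."""
    responded, choice, reward, _, _ = _block_arrays(grp)
    n = len(grp)
    for t in range(3, n):
        if not (responded[t] and responded[t - 1] and responded[t - 2] and responded[t - 3]):
            continue
        key = "".join("+" if reward[t - i] == 1 else "-" for i in (3, 2, 1))
        yield key, choice[t] == choice[t - 1]


def stay_probability_table_3back(logs: pd.DataFrame) -> pd.DataFrame:
    """p(stay) by three-trial-back outcome history, per participant.

    The condition key orders outcomes (t-3, t-2, t-1) with "+" = rewarded.
    Conditions with zero eligible trials appear with ``n_trials=0`` and a
    missing probability. Pool with :func:`pooled_condition_table`.
    """
    rows = []
    for pid, grp in logs.groupby("participant_id", sort=True):
        stays = {k: [] for k in HISTORY3_KEYS}
        for _, _, block in _iter_blocks(grp):
            for key, stayed in _stay_events_3back(block):
                stays[key].append(stayed)
        for key in HISTORY3_KEYS:
            v = stays[key]
            rows.append(
                (pid, key, len(v), float(np.mean(v)) if v else np.nan)
            )
    return pd.DataFrame(rows, columns=["participant_id", "condition", "n_trials", "p_stay"])


def stay_after_unrewarded(logs: pd.DataFrame) -> pd.Series:
    """1-back marginal: per-participant p(stay | previous trial unrewarded)."""
    out = {}
    for pid, grp in logs.groupby("participant_id", sort=True):
        events = []
        for _, _, block in _iter_blocks(grp):
            responded, choice, reward, _, _ = _block_arrays(block)
            for t in range(1, len(block)):
                if responded[t] and responded[t - 1] and reward[t - 1] == 0:
                    events.append(choice[t] == choice[t - 1])
        out[pid] = float(np.mean(events)) if events else np.nan
    return pd.Series(out, name="p_stay_unrewarded")


def _ab_key(o2: float, stayed1: bool, o1: float, lowercase_unrewarded: bool) -> str:
    def cased(letter: str, rewarded: bool) -> str:
        if lowercase_unrewarded:
            return letter.upper() if rewarded else letter
        return letter if rewarded else letter.upper()

    first = cased("a", o2 == 1)
    second = cased("a" if stayed1 else "b", o1 == 1)
    return first + second


def ab_table(
    logs: pd.DataFrame, lowercase_unrewarded: bool | None = None
) -> pd.DataFrame:
    """Action-conditioned two-back analysis: p(return to the t-2 action).

    Each eligible trial (t, t-1, t-2 responded, in-block) is assigned one of
    8 keys from the outcome at t-2, stay/switch at t-1, and the outcome at
    t-1; ``p_a`` is the fraction of those trials whose choice equals the
    choice at t-2. Under the default case convention, lowercase = unrewarded
    (so "ab" = unrewarded a, then an unrewarded switch to b).
    """
    if lowercase_unrewarded is None:
        lowercase_unrewarded = LOWERCASE_UNREWARDED
    rows = []
    for pid, grp in logs.groupby("participant_id", sort=True):
        returns: dict[str, list] = {k: [] for k in AB_KEYS}
        for _, _, block in _iter_blocks(grp):
            responded, choice, reward, _, _ = _block_arrays(block)
            for t in range(2, len(block)):
                if not (responded[t] and responded[t - 1] and responded[t - 2]):
                    continue
                key = _ab_key(
                    reward[t - 2],
                    choice[t - 1] == choice[t - 2],
                    reward[t - 1],
                    lowercase_unrewarded,
                )
                returns[key].append(choice[t] == choice[t - 2])
        for key in AB_KEYS:
            v = returns[key]
            rows.append((pid, key, len(v), float(np.mean(v)) if v else np.nan))
    return pd.DataFrame(rows, columns=["participant_id", "condition", "n_trials", "p_a"])


def ab_condition_series(
    table: pd.DataFrame, condition: str, exclude_zero_outliers: bool | None = None
) -> pd.Series:
    """Per-participant p(a) for one aB condition, for correlation analyses.

    For the "ab" condition (unrewarded a, then an unrewarded switch),
    participants who never return to the original action (p(a|ab) = 0) are
    flagged as outliers and dropped by default; pass
    ``exclude_zero_outliers=False`` to keep them.
    """
    if exclude_zero_outliers is None:
        exclude_zero_outliers = condition == "ab"
    sub = table[(table["condition"] == condition) & (table["n_trials"] > 0)]
    series = sub.set_index("participant_id")["p_a"]
    if exclude_zero_outliers:
        series = series[series > 0]
    return series


def pooled_condition_table(per_participant: pd.DataFrame, value: str) -> pd.DataFrame:
    """Pool a per-participant condition table over all trials (count-weighted)."""
    def agg(grp):
        n = grp["n_trials"].sum()
        if n == 0:
            return pd.Series({"n_trials": 0, value: np.nan})
        w = grp["n_trials"] * grp[value].fillna(0.0)
        return pd.Series({"n_trials": n, value: w.sum() / n})

    return (
        per_participant.groupby("condition")
        .apply(agg, include_groups=False)
        .reset_index()
    )


@dataclass
class ExclusionCriteria:
    """Participant exclusion rules; the performance criterion is configurable
    (the study excluded below-criterion participants without printing the
    threshold)."""

    min_accuracy: float = 0.55
    min_response_rate: float = 0.8
    require_both_blocks: bool = False
    n_blocks_expected: int = 2


def preprocess_sessions(
    logs: pd.DataFrame, exclusion: ExclusionCriteria | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter participants by completeness and performance.

    Returns ``(filtered_logs, report)``; the report lists every excluded
    participant with the first rule they violated.
    """
    if exclusion is None:
        exclusion = ExclusionCriteria()
    report_rows = []
    keep = []
    for pid, grp in logs.groupby("participant_id", sort=True):
        n_blocks = grp["block_id"].nunique()
        resp_rate = float(grp["responded"].mean())
        reason = None
        if exclusion.require_both_blocks and n_blocks < exclusion.n_blocks_expected:
            reason = f"completed {n_blocks}/{exclusion.n_blocks_expected} blocks"
        elif resp_rate < exclusion.min_response_rate:
            reason = f"response rate {resp_rate:.2f} < {exclusion.min_response_rate}"
        else:
            try:
                acc = overall_performance(grp)
            except UndefinedMeasureError:
                acc = np.nan
            if not acc >= exclusion.min_accuracy:
                reason = f"accuracy {acc:.2f} < {exclusion.min_accuracy}"
        if reason is None:
            keep.append(pid)
        else:
            report_rows.append((pid, reason))
    report = pd.DataFrame(report_rows, columns=["participant_id", "reason"])
    return logs[logs["participant_id"].isin(keep)].copy(), report


@dataclass
class BehaviorSummary:
    """Bundle of all model-free summaries for one log collection."""

    overall_accuracy: float
    p_stay_after_unrewarded: float
    switch_aligned_curve: pd.DataFrame
    three_back_table: pd.DataFrame
    ab_table: pd.DataFrame
    reversals_per_block: float
    per_participant: pd.DataFrame = field(default=None, repr=False)


def behavior_summary(logs: pd.DataFrame) -> BehaviorSummary:
    """Compute every behavioral statistic on a (preprocessed) log collection."""
    perf = per_participant_performance(logs)
    stay_unrew = stay_after_unrewarded(logs)
    per_part = pd.DataFrame(
        {"performance": perf, "p_stay_unrewarded": stay_unrew}
    )
    return BehaviorSummary(
        overall_accuracy=float(perf.mean()),
        p_stay_after_unrewarded=float(stay_unrew.mean()),
        switch_aligned_curve=switch_aligned_accuracy(logs),
        three_back_table=stay_probability_table_3back(logs),
        ab_table=ab_table(logs),
        reversals_per_block=reversals_per_block(logs),
        per_participant=per_part,
    )
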