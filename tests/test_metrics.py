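"""Behavioral statistics: hand tallies, scripted-agent oracles, partitions."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_log
from probswitch.cohort import CohortSpec, generate_cohort
from probswitch.metrics import (AB_KEYS, HISTORY3_KEYS, ExclusionCriteria,
                                UndefinedMeasureError, ab_table,
                                overall_performance, pooled_condition_table,
                                preprocess_sessions, stay_after_unrewarded,
                                stay_probability_table_3back,
                                switch_aligned_accuracy)
from probswitch.policies import Lag1OraclePolicy, scripted_policies
from probswitch.task import TaskConfig, build_block_schedule, run_session


class TestOverallPerformance:
    def test_hand_log_seven_of_nine(self):
        # 10 trials, 1 non-response, 7 correct among the 9 answered
        log = make_log(
            choices=[0, 0, 1, 0, None, 0, 1, 0, 0, 0],
            rewards=[1, 1, 0, 1, None, 0, 0, 1, 1, 0],
            correct=[0] * 10,
        )
        assert overall_performance(log) == pytest.approx(7 / 9)

    def test_perfect_and_zero(self):
        cfg = TaskConfig()
        log = run_session(build_block_schedule(cfg, 0), cfg, scripted_policies("oracle"))
        assert overall_performance(log) == 1.0
        log = run_session(build_block_schedule(cfg, 0), cfg,
                          scripted_policies("always-incorrect"))
        assert overall_performance(log) == 0.0

    def test_no_responses_undefined(self):
        log = make_log(choices=[None, None], rewards=[None, None])
        with pytest.raises(UndefinedMeasureError):
            overall_performance(log)


class TestSwitchAligned:
    def test_lag1_oracle_sharp_curve(self):
        cfg = TaskConfig(rng_seed=1)
        logs = pd.concat(
            [run_session(build_block_schedule(TaskConfig(rng_seed=s), s % 4),
                         TaskConfig(rng_seed=s), Lag1OraclePolicy(),
                         participant_id=f"p{s}")
             for s in range(10)],
            ignore_index=True,
        )
        acc = switch_aligned_accuracy(logs).set_index("offset")["accuracy"]
        assert acc[0] == 0.0
        assert acc[1] == 1.0 and acc[2] == 1.0

    def test_hand_tally_single_reversal(self):
        log = make_log(
            choices=[0, 0, 1, 1, 0],
            rewards=[1, 1, 0, 1, 0],
            correct=[0, 0, 1, 1, 1],
            reversal=[False, False, True, False, False],
        )
        acc = switch_aligned_accuracy(log, window=(-2, 2)).set_index("offset")
        assert acc.loc[-2, "accuracy"] == 1.0   # trial 0: chose 0, correct 0
        assert acc.loc[-1, "accuracy"] == 1.0
        assert acc.loc[0, "accuracy"] == 1.0    # trial 2: chose 1, correct 1
        assert acc.loc[1, "accuracy"] == 1.0
        assert acc.loc[2, "accuracy"] == 0.0    # trial 4: chose 0, correct 1

    def test_warns_without_reversals(self):
        log = make_log(choices=[0, 0], rewards=[1, 1])
        with pytest.warns(UserWarning, match="no reversals"):
            switch_aligned_accuracy(log)


def _wsls_cohort(n_blocks=6):
    logs = []
    for s in range(n_blocks):
        cfg = TaskConfig(rng_seed=100 + s)
        logs.append(run_session(build_block_schedule(cfg, s % 4), cfg,
                                scripted_policies("wsls"), participant_id="w0"))
        logs[-1]["block_id"] = s
    return pd.concat(logs, ignore_index=True)


class TestThreeBack:
    def test_wsls_agent_extremes(self):
        table = stay_probability_table_3back(_wsls_cohort())
        for key in HISTORY3_KEYS:
            row = table[table["condition"] == key].iloc[0]
            if row["n_trials"] == 0:
                continue
            assert row["p_stay"] == (1.0 if key.endswith("+") else 0.0), key

    def test_hand_enumeration_12_trials(self):
        log = make_log(
            choices=[0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 0, 0],
            rewards=[1, 0, 1, 1, 0, 0, 1, 1, 0, 1, 0, 1],
        )
        table = stay_probability_table_3back(log).set_index("condition")
        # eligible trials are t=3..11; histories and stays tallied by hand
        expect = {
            "+-+": (2, 0.5),   # t=3 (stay), t=10 (switch)
            "-++": (2, 0.5),   # t=4 (stay), t=8 (switch)
            "++-": (2, 0.5),   # t=5 (switch), t=9 (stay)
            "+--": (1, 1.0),   # t=6 (stay)
            "--+": (1, 1.0),   # t=7 (stay)
            "-+-": (1, 1.0),   # t=11 (stay)
        }
        total_counted = 0
        for key, (n, p) in expect.items():
            assert table.loc[key, "n_trials"] == n, key
            assert table.loc[key, "p_stay"] == pytest.approx(p), key
            total_counted += n
        assert total_counted == 9
        assert table["n_trials"].sum() == 9  # partition of eligible trials

    def test_always_stay_all_ones(self):
        cfg = TaskConfig(rng_seed=9)
        log = run_session(build_block_schedule(cfg, 0), cfg,
                          scripted_policies("always-stay"))
        table = stay_probability_table_3back(log)
        populated = table[table["n_trials"] > 0]
        assert (populated["p_stay"] == 1.0).all()

    def test_nonresponse_breaks_history(self):
        log = make_log(
            choices=[0, None, 0, 0, 0, 0, 0, 0],
            rewards=[1, None, 1, 1, 1, 1, 1, 1],
        )
        table = stay_probability_table_3back(log)
        # only t=5,6,7 have three responded predecessors
        assert table["n_trials"].sum() == 3

    def test_one_back_marginal_consistency(self):
        """The count-weighted average of the four 3-back conditions ending
        unrewarded equals an independent brute-force 1-back tally restricted
        to the same eligible trials."""
        logs = _wsls_cohort()
        table = stay_probability_table_3back(logs)
        ending_minus = table[table["condition"].str.endswith("-")]
        w = ending_minus["n_trials"].sum()
        avg = (ending_minus["n_trials"] * ending_minus["p_stay"].fillna(0)).sum() / w
        # brute-force tally over the identical eligibility window
        events = []
        for (_, _), grp in logs.groupby(["participant_id", "block_id"]):
            grp = grp.sort_values("trial")
            ch = grp["chosen_side"].to_numpy(dtype=float)
            rw = grp["rewarded"].to_numpy(dtype=float)
            resp = grp["responded"].to_numpy(dtype=bool)
            for t in range(3, len(grp)):
                if resp[t - 3 : t + 1].all() and rw[t - 1] == 0:
                    events.append(ch[t] == ch[t - 1])
        assert avg == pytest.approx(np.mean(events))


class TestABTable:
    def test_wsls_matches_enumeration_oracle(self):
        """Key assignment and p(a) match a brute-force tally over a long
        win-stay/lose-switch run (lowercase = unrewarded)."""
        logs = _wsls_cohort(10)
        table = ab_table(logs).set_index("condition")
        tally = {k: [0, 0] for k in AB_KEYS}
        for (_, _), grp in logs.groupby(["participant_id", "block_id"]):
            grp = grp.sort_values("trial")
            ch = grp["chosen_side"].to_numpy(dtype=float)
            rw = grp["rewarded"].to_numpy(dtype=float)
            for t in range(2, len(grp)):
                first = "A" if rw[t - 2] == 1 else "a"
                letter = "a" if ch[t - 1] == ch[t - 2] else "b"
                second = letter.upper() if rw[t - 1] == 1 else letter
                key = first + second
                tally[key][0] += 1
                tally[key][1] += int(ch[t] == ch[t - 2])
        for key in AB_KEYS:
            n, hits = tally[key][0], tally[key][1]
            assert table.loc[key, "n_trials"] == n, key
            if n:
                assert table.loc[key, "p_a"] == pytest.approx(hits / n), key
        # WSLS mechanics: after an unrewarded switch the agent switches back
        assert table.loc["ab", "p_a"] == 1.0

    def test_always_stay_only_stay_keys(self):
        cfg = TaskConfig(rng_seed=5)
        log = run_session(build_block_schedule(cfg, 0), cfg,
                          scripted_policies("always-stay"))
        table = ab_table(log)
        populated = table[table["n_trials"] > 0]
        assert set(populated["condition"]) <= {"aa", "aA", "Aa", "AA"}
        assert (populated["p_a"] == 1.0).all()

    def test_hand_log_key_assignment(self):
        log = make_log(
            choices=[0, 1, 1, 0, 0, 1, 1, 1, 0, 0],
            rewards=[1, 0, 1, 0, 0, 1, 1, 0, 0, 1],
        )
        table = ab_table(log).set_index("condition")
        # hand-coded keys for t=2..9 (a = action at t-2, case = outcome):
        # t2: A? t-2 (ch0,r1)->'A'; t-1 switch unrewarded->'b'; ch2==ch0? 1!=0 no
        # t3: t-2 (ch1,r0)->'a'; t-1 stay rewarded->'A'; ch3==ch1? 0!=1 no
        # t4: t-2 (ch2,r1)->'A'; t-1 switch unrewarded->'b'; ch4==ch2? 0!=1 no
        # t5: t-2 (ch3,r0)->'a'; t-1 stay unrewarded->'a'; ch5==ch3? 1!=0 no
        # t6: t-2 (ch4,r0)->'a'; t-1 switch rewarded->'B'; ch6==ch4? 1!=0 no
        # t7: t-2 (ch5,r1)->'A'; t-1 stay rewarded->'A'; ch7==ch5? yes
        # t8: t-2 (ch6,r1)->'A'; t-1 stay unrewarded->'a'; ch8==ch6? no
        # t9: t-2 (ch7,r0)->'a'; t-1 switch unrewarded->'b'; ch9==ch7? no
        assert table.loc["Ab", "n_trials"] == 2
        assert table.loc["Ab", "p_a"] == 0.0
        assert table.loc["aA", "n_trials"] == 1
        assert table.loc["aa", "n_trials"] == 1
        assert table.loc["aB", "n_trials"] == 1
        assert table.loc["AA", "n_trials"] == 1 and table.loc["AA", "p_a"] == 1.0
        assert table.loc["Aa", "n_trials"] == 1
        assert table.loc["ab", "n_trials"] == 1 and table.loc["ab", "p_a"] == 0.0
        assert table["n_trials"].sum() == 8

    def test_partition_property(self, rl_cohort20):
        logs = rl_cohort20.logs
        table = ab_table(logs)
        per = table.groupby("participant_id")["n_trials"].sum()
        # every eligible trial in exactly one key: 2 blocks x (150 - 2) trials
        assert (per == 2 * 148).all()


class TestPreprocess:
    def test_planted_violations_reported(self):
        good = make_log(choices=[0] * 20, rewards=[1] * 20, pid="good")
        silent = make_log(choices=[None] * 20, rewards=[None] * 20, pid="silent")
        bad = make_log(choices=[1] * 20, rewards=[0] * 20, correct=[0] * 20, pid="bad")
        logs = pd.concat([good, silent, bad], ignore_index=True)
        kept, report = preprocess_sessions(
            logs, ExclusionCriteria(min_accuracy=0.55, min_response_rate=0.5)
        )
        assert set(kept["participant_id"]) == {"good"}
        assert set(report["participant_id"]) == {"silent", "bad"}

    def test_threshold_semantics(self):
        # accuracy exactly 0.50 fails a 0.55 criterion
        half = make_log(choices=[0, 1] * 10, rewards=[1, 0] * 10,
                        correct=[0] * 20, pid="h")
        _, report = preprocess_sessions(half, ExclusionCriteria(min_accuracy=0.55,
                                                                min_response_rate=0.0))
        assert len(report) == 1

    def test_two_block_requirement(self):
        one = make_log(choices=[0] * 10, rewards=[1] * 10, pid="p1", block=0)
        kept, report = preprocess_sessions(
            one, ExclusionCriteria(require_both_blocks=True, min_accuracy=0.0,
                                   min_response_rate=0.0),
        )
        assert kept.empty and len(report) == 1


def test_ab_zero_outliers_dropped_by_default():
    from probswitch.metrics import ab_condition_series

    table = pd.DataFrame({
        "participant_id": ["a", "b", "c"],
        "condition": ["ab"] * 3,
        "n_trials": [10, 8, 0],
        "p_a": [0.5, 0.0, np.nan],
    })
    kept = ab_condition_series(table, "ab")
    assert list(kept.index) == ["a"]
    everyone = ab_condition_series(table, "ab", exclude_zero_outliers=False)
    assert list(everyone.index) == ["a", "b"]


def test_pooled_table_weights_by_counts():
    per = pd.DataFrame({
        "participant_id": ["a", "b"],
        "condition": ["---", "---"],
        "n_trials": [10, 30],
        "p_stay": [1.0, 0.5],
    })
    pooled = pooled_condition_table(per, "p_stay")
    assert pooled.loc[0, "p_stay"] == pytest.approx((10 * 1.0 + 30 * 0.5) / 40)
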