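"""Questionnaire scoring, gated correlations, design coding, mixed model."""

import subprocess
import sys
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_log
from probswitch.traits import (HISTORY_TERMS, CorrelationReport,
                               QuestionnaireSchema, TraitError,
                               build_history_design, cronbach_alpha,
                               fit_history_glmm, gated_correlation,
                               median_split_summary, multiple_comparison_gate,
                               reverse_code, score_supps)

SCHEMA = QuestionnaireSchema()


def responses_frame(rows):
    return pd.DataFrame(rows, columns=SCHEMA.item_columns,
                        index=[f"p{i}" for i in range(len(rows))])


class TestScoring:
    def test_maximum_total_is_80(self):
        row = [1 if i in SCHEMA.reverse_items else 4 for i in range(1, 21)]
        scores = score_supps(responses_frame([row, [2] * 20]))
        assert scores.loc["p0", "total"] == 80
        assert all(scores.loc["p0", s] == 16 for s in SCHEMA.subscale_map)

    def test_minimum_total_is_20(self):
        row = [4 if i in SCHEMA.reverse_items else 1 for i in range(1, 21)]
        scores = score_supps(responses_frame([row, [2] * 20]))
        assert scores.loc["p0", "total"] == 20

    def test_reverse_items_scored_as_complement(self):
        # three reverse items answered 1 contribute 4 each; rest answered 2
        row = [2] * 20
        for i in list(SCHEMA.reverse_items)[:3]:
            row[i - 1] = 1
        scores = score_supps(responses_frame([row, [3] * 20]))
        n_rev = len(SCHEMA.reverse_items)
        # hand sum: 3 reversed '1's -> 4; other 9 reversed '2's -> 3;
        # 8 normal '2's -> 2
        assert scores.loc["p0", "total"] == 3 * 4 + (n_rev - 3) * 3 + 8 * 2

    def test_out_of_range_and_missing_rejected(self):
        with pytest.raises(TraitError, match="lie in"):
            score_supps(responses_frame([[5] + [2] * 19]))
        bad = responses_frame([[2] * 20]).astype(float)
        bad.iloc[0, 3] = np.nan
        with pytest.raises(TraitError, match="missing"):
            score_supps(bad)

    @given(st.lists(st.integers(1, 4), min_size=20, max_size=20))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_reverse_coding_is_involution(self, row):
        frame = responses_frame([row])
        twice = reverse_code(reverse_code(frame, SCHEMA), SCHEMA)
        assert (twice == frame).all().all()


class TestCronbach:
    def test_duplicated_items_alpha_one(self):
        base = np.array([1, 2, 3, 4, 2, 3])
        items = pd.DataFrame({f"item_{i}": base for i in range(1, 5)})
        assert cronbach_alpha(items) == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(0)
        items = pd.DataFrame(rng.integers(1, 5, size=(4000, 6)))
        assert abs(cronbach_alpha(items)) < 0.15

    def test_hand_table(self):
        items = pd.DataFrame(
            [[1, 2, 2, 3], [2, 3, 3, 3], [3, 3, 2, 4], [4, 4, 4, 4], [2, 2, 1, 3]]
        )
        k = 4
        iv = items.var(axis=0, ddof=1).sum()
        tv = items.sum(axis=1).var(ddof=1)
        assert cronbach_alpha(items) == pytest.approx(k / (k - 1) * (1 - iv / tv),
                                                      abs=1e-12)

    def test_matches_pingouin(self):
        import pingouin

        rng = np.random.default_rng(1)
        latent = rng.normal(size=50)
        items = pd.DataFrame(
            {f"i{j}": latent + rng.normal(scale=0.8, size=50) for j in range(5)}
        )
        ours = cronbach_alpha(items)
        ref = pingouin.cronbach_alpha(items)[0]
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(TraitError):
            cronbach_alpha(pd.DataFrame({"a": [1, 1], "b": [2, 2]}))


class TestGatedCorrelation:
    def test_normal_pair_uses_pearson(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=70)
        y = 0.5 * x + rng.normal(size=70)
        rep = gated_correlation(x, y)
        assert rep.method == "pearson"

    def test_skewed_sample_triggers_spearman(self):
        from scipy.stats import shapiro

        rng = np.random.default_rng(3)
        x = np.exp(rng.normal(size=70) * 1.5)
        y = rng.normal(size=70)
        rep = gated_correlation(x, y)
        assert rep.method == "spearman"
        # the gate decision agrees with a direct recomputation of both tests
        assert rep.shapiro_p_x == pytest.approx(shapiro(x).pvalue)
        assert rep.shapiro_p_x <= 0.05 or rep.shapiro_p_y <= 0.05

    def test_perfect_linear_association(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        rep = gated_correlation(x, 2 * x + 1)
        assert rep.statistic == pytest.approx(1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(TraitError, match="constant"):
            gated_correlation(np.ones(10), np.arange(10))


class TestHistoryDesign:
    def test_hand_coded_six_trial_log(self):
        log = make_log(
            choices=[0, 1, 1, 0, 1, 0],
            rewards=[1, 0, 1, 0, 1, 0],
        )
        design = build_history_design(log)
        # rows only for t=3,4,5
        assert len(design) == 3
        r3 = design.iloc[0]
        # t=3: lag1=trial2 (right, rewarded) -> pos_1=+1, neg_1=0
        #      lag2=trial1 (right, unrewarded) -> neg_2=+1
        #      lag3=trial0 (left, rewarded) -> pos_3=-1
        assert (r3["action"], r3["pos_1"], r3["neg_1"]) == (0, 1.0, 0.0)
        assert (r3["pos_2"], r3["neg_2"]) == (0.0, 1.0)
        assert (r3["pos_3"], r3["neg_3"]) == (-1.0, 0.0)
        r4 = design.iloc[1]
        # t=4: lag1=trial3 (left, unrewarded) -> neg_1=-1
        assert (r4["action"], r4["pos_1"], r4["neg_1"]) == (1, 0.0, -1.0)
        r5 = design.iloc[2]
        assert (r5["action"], r5["pos_1"], r5["neg_1"]) == (0, 1.0, 0.0)

    def test_signed_coding_mutually_exclusive(self, rl_cohort20):
        design = build_history_design(rl_cohort20.logs)
        for i in (1, 2, 3):
            both = design[f"pos_{i}"].abs() + design[f"neg_{i}"].abs()
            assert (both == 1.0).all()

    def test_first_three_trials_excluded(self):
        log = make_log(choices=[0] * 10, rewards=[1] * 10)
        design = build_history_design(log)
        assert len(design) == 7

    def test_interactions_require_traits(self):
        log = make_log(choices=[0] * 6, rewards=[1] * 6)
        with pytest.raises(TraitError):
            build_history_design(log, with_interactions=True)


def _simulate_logistic_cohort(coefs, n_sub=70, n_trials=300, tau=0.3, seed=0):
    """Data simulated directly from the random-intercept logistic model with
    known coefficients (not from the task engine)."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        intercept = rng.normal(0, tau)
        x = rng.choice([-1.0, 0.0, 1.0], size=(n_trials, 6))
        eta = intercept + x @ coefs
        y = (rng.random(n_trials) < 1 / (1 + np.exp(-eta))).astype(int)
        for t in range(n_trials):
            rows.append({"participant_id": f"s{s}", "action": y[t],
                         **{term: x[t, j] for j, term in enumerate(HISTORY_TERMS)}})
    return pd.DataFrame(rows)


class TestGlmm:
    def test_known_coefficients_recovered_within_2se(self):
        coefs = np.array([2.0, -0.4, 0.0, 0.0, 0.0, 0.0])
        design = _simulate_logistic_cohort(coefs, seed=12)
        res = fit_history_glmm(design)
        table = res.coefficients.set_index("term")
        for j, term in enumerate(HISTORY_TERMS):
            est, se = table.loc[term, "estimate"], table.loc[term, "se"]
            assert abs(est - coefs[j]) < 2 * se, term
        assert table.loc["pos_1", "p"] < 1e-6
        assert table.loc["neg_1", "p"] < 1e-6

    def test_all_zero_predictors_intercept_only(self):
        design = pd.DataFrame({
            "participant_id": ["a"] * 50 + ["b"] * 50,
            "action": [0, 1] * 50,
            "pos_1": 0.0,
        })
        res = fit_history_glmm(design)
        assert list(res.coefficients["term"]) == ["(Intercept)"]

    def test_matches_lme4_reference(self, tmp_path):
        """Fixed effects agree with an independent glmer fit (R lme4)."""
        coefs = np.array([1.5, -0.5, 0.4, 0.0, 0.0, 0.0])
        design = _simulate_logistic_cohort(coefs, n_sub=25, n_trials=120, seed=5)
        res = fit_history_glmm(design)
        csv = tmp_path / "design.csv"
        design.to_csv(csv, index=False)
        rscript = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- glmer(action ~ pos_1+neg_1+pos_2+neg_2+pos_3+neg_3+(1|participant_id),"
            " data=d, family=binomial);"
            "cat(fixef(m), sep=',')"
        )
        proc = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                              text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        ref = np.array([float(v) for v in proc.stdout.strip().split(",")])
        ours = res.coefficients["estimate"].to_numpy()
        assert np.allclose(ours, ref, atol=0.08)


class TestMedianSplitAndGate:
    def test_planted_direction_visible_in_split(self):
        rng = np.random.default_rng(6)
        scores = pd.Series(rng.normal(40, 8, 70), index=[f"p{i}" for i in range(70)])
        measure = pd.Series(0.6 - 0.01 * (scores - 40) + rng.normal(0, 0.02, 70),
                            index=scores.index)
        split = median_split_summary(scores, measure)
        summary = split.summary.set_index("group")
        assert summary.loc["high", "mean"] < summary.loc["low", "mean"]

    def test_ties_go_low_and_degenerate_flagged(self):
        scores = pd.Series([3.0, 3.0, 3.0], index=list("abc"))
        with pytest.warns(UserWarning, match="degenerate"):
            split = median_split_summary(scores, scores)
        assert split.degenerate and (split.groups == "low").all()

    def test_two_participants_one_per_group(self):
        scores = pd.Series([30.0, 50.0], index=["a", "b"])
        split = median_split_summary(scores, scores)
        assert split.groups["a"] == "low" and split.groups["b"] == "high"

    def test_bonferroni_decisions(self):
        out = multiple_comparison_gate([0.0046, 0.03], family_size=8)
        assert bool(out.loc[0, "significant_bonferroni"]) is True
        assert bool(out.loc[1, "significant_bonferroni"]) is False
        single = multiple_comparison_gate([0.04], family_size=1)
        assert bool(single.loc[0, "significant_bonferroni"]) is True

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(TraitError):
            multiple_comparison_gate([0.01, 0.02], family_size=1)
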