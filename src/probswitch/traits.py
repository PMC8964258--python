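"""Impulsivity trait scoring and trait-behavior statistics.

Covers scoring of the short 20-item UPPS-P impulsivity questionnaire
(responses 1-4, twelve reverse-scored items, five 4-item subscales),
Cronbach's alpha, normality-gated correlations (Pearson unless either
variable fails Shapiro-Wilk, then Spearman), the lagged-outcome logistic
mixed model with trait interactions, median splits, and Bonferroni gating.

The published questionnaire does not enumerate which items are
reverse-scored per subscale, so the default schema ships a documented
placeholder layout (editable): items grouped in blocks of four per subscale,
with the first three subscales' items reverse-scored. All analyses depend
only on the schema's structure, not the item semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr, shapiro, spearmanr

SUBSCALES = (
    "negative_urgency",
    "lack_premeditation",
    "lack_perseverance",
    "sensation_seeking",
    "positive_urgency",
)


class TraitError(ValueError):
    pass


@dataclass(frozen=True)
class QuestionnaireSchema:
    """Structure of the 20-item impulsivity questionnaire."""

    n_items: int = 20
    response_min: int = 1
    response_max: int = 4
    subscale_map: dict = field(
        default_factory=lambda: {
            sub: tuple(range(4 * i + 1, 4 * i + 5)) for i, sub in enumerate(SUBSCALES)
        }
    )
    reverse_items: frozenset = field(
        default_factory=lambda: frozenset(range(1, 13))
    )

    def __post_init__(self):
        items = [i for v in self.subscale_map.values() for i in v]
        if sorted(items) != list(range(1, self.n_items + 1)):
            raise TraitError("every item must belong to exactly one subscale")
        if not set(self.reverse_items) <= set(items):
            raise TraitError("reverse_items must be a subset of the item set")

    @property
    def item_columns(self):
        return [f"item_{i}" for i in range(1, self.n_items + 1)]


def reverse_code(responses: pd.DataFrame, schema: QuestionnaireSchema) -> pd.DataFrame:
    """Map reverse-scored items r -> (min+max) - r; an involution."""
    scored = responses[schema.item_columns].copy()
    flip = schema.response_min + schema.response_max
    for i in schema.reverse_items:
        col = f"item_{i}"
        scored[col] = flip - scored[col]
    return scored


def score_supps(
    responses: pd.DataFrame, schema: QuestionnaireSchema | None = None
) -> pd.DataFrame:
    """Score the questionnaire: reverse-coding, subscale sums, total, z-total.

    ``responses`` is participant x item_1..item_20 (index = participant).
    Higher scores reflect more impulsivity; the possible total range is
    20-80 with subscales 4-16. z-scoring is over the scored cohort.
    """
    if schema is None:
        schema = QuestionnaireSchema()
    missing = [c for c in schema.item_columns if c not in responses.columns]
    if missing:
        raise TraitError(f"missing item columns: {missing}")
    vals = responses[schema.item_columns]
    if vals.isna().any().any():
        raise TraitError("missing item responses (no imputation policy configured)")
    if ((vals < schema.response_min) | (vals > schema.response_max)).any().any():
        raise TraitError(
            f"responses must lie in [{schema.response_min}, {schema.response_max}]"
        )
    scored = reverse_code(responses, schema)
    out = pd.DataFrame(index=responses.index)
    for sub, items in schema.subscale_map.items():
        out[sub] = scored[[f"item_{i}" for i in items]].sum(axis=1)
    out["total"] = out[list(schema.subscale_map)].sum(axis=1)
    sd = out["total"].std(ddof=1)
    if sd > 0:
        out["z_total"] = (out["total"] - out["total"].mean()) / sd
    else:
        out["z_total"] = 0.0
    return out


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum item variances / total variance)."""
    k = items.shape[1]
    if k < 2 or items.shape[0] < 2:
        raise TraitError("alpha requires >= 2 items and >= 2 participants")
    item_vars = items.var(axis=0, ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise TraitError("zero total-score variance: alpha undefined")
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))


@dataclass(frozen=True)
class CorrelationReport:
    method: str          # "pearson" or "spearman"
    statistic: float
    p_value: float
    n: int
    shapiro_p_x: float
    shapiro_p_y: float


def gated_correlation(x, y, alpha_norm: float = 0.05) -> CorrelationReport:
    """Pearson correlation unless either variable fails Shapiro-Wilk
    normality at ``alpha_norm``, in which case Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 4:
        raise TraitError("gated correlation requires at least 4 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise TraitError("constant input: correlation undefined")
    pw_x = float(shapiro(x).pvalue)
    pw_y = float(shapiro(y).pvalue)
    if pw_x > alpha_norm and pw_y > alpha_norm:
        res = pearsonr(x, y)
        method = "pearson"
    else:
        res = spearmanr(x, y)
        method = "spearman"
    return CorrelationReport(
        method=method,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size),
        shapiro_p_x=pw_x,
        shapiro_p_y=pw_y,
    )


# ---------------------------------------------------------------------------
# lagged-outcome design and mixed-effects logistic regression

HISTORY_TERMS = ["pos_1", "neg_1", "pos_2", "neg_2", "pos_3", "neg_3"]


def build_history_design(
    logs: pd.DataFrame,
    traits: pd.DataFrame | None = None,
    with_interactions: bool = False,
    n_lags: int = 3,
) -> pd.DataFrame:
    """Signed lagged-outcome design matrix for the choice regression.

    One row per trial whose ``n_lags`` predecessors (and the trial itself)
    were all responded, within-block. ``action`` is 0=left, 1=right. For lag
    i, ``pos_i`` is -1 if the left box was rewarded at t-i, +1 if the right
    box was rewarded, 0 if the outcome was not positive; ``neg_i`` codes
    unrewarded outcomes the same way. With interactions, the z-scored trait
    total multiplies each predictor (columns ``imp_x_<term>``), plus the
    trait main effect ``imp_score_z``.
    """
    if with_interactions and traits is None:
        raise TraitError("traits required when with_interactions=True")
    terms = [f"{s}_{i}" for i in range(1, n_lags + 1) for s in ("pos", "neg")]
    rows = []
    for (pid, _), grp in logs.groupby(["participant_id", "block_id"], sort=True):
        grp = grp.sort_values("trial")
        responded = grp["responded"].to_numpy(dtype=bool)
        choice = grp["chosen_side"].to_numpy(dtype="float64", na_value=np.nan)
        reward = grp["rewarded"].to_numpy(dtype="float64", na_value=np.nan)
        for t in range(n_lags, len(grp)):
            if not responded[t - n_lags : t + 1].all():
                continue
            row = {"participant_id": pid, "action": int(choice[t])}
            for i in range(1, n_lags + 1):
                signed = -1.0 if choice[t - i] == 0 else 1.0
                row[f"pos_{i}"] = signed if reward[t - i] == 1 else 0.0
                row[f"neg_{i}"] = signed if reward[t - i] == 0 else 0.0
            rows.append(row)
    design = pd.DataFrame(rows, columns=["participant_id", "action"] + terms)
    if with_interactions:
        z = traits["z_total"]
        missing = set(design["participant_id"]) - set(z.index)
        if missing:
            raise TraitError(f"trait scores missing for participants: {sorted(missing)}")
        zvals = design["participant_id"].map(z).astype(float)
        design["imp_score_z"] = zvals
        for term in terms:
            design[f"imp_x_{term}"] = zvals * design[term]
    return design


@dataclass
class GlmmResult:
    """Random-intercept logistic regression output (Table-style layout)."""

    coefficients: pd.DataFrame       # term, estimate, se, z, p
    random_intercept_var: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_participants: int
    converged: bool
    diagnostics: str = ""

    def coef(self, term: str) -> pd.Series:
        return self.coefficients.set_index("term").loc[term]


def fit_history_glmm(design: pd.DataFrame) -> GlmmResult:
    """Fit ``action ~ predictors + (1 | participant)`` by variational Bayes
    (statsmodels ``BinomialBayesMixedGLM``), with Wald-style z and p values
    from the posterior mean and SD, and Nakagawa marginal/conditional
    pseudo-R2."""
    from scipy import sparse
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    if design["participant_id"].nunique() < 2:
        raise TraitError("mixed model requires >= 2 participants")
    fixed_cols = [
        c for c in design.columns if c not in ("participant_id", "action")
    ]
    # drop all-zero predictors (rank deficiency guard); intercept-only is legal
    fixed_cols = [c for c in fixed_cols if design[c].abs().sum() > 0]
    endog = design["action"].to_numpy(dtype=float)
    exog = np.column_stack(
        [np.ones(len(design))] + [design[c].to_numpy(dtype=float) for c in fixed_cols]
    )
    pid_codes, pid_index = pd.factorize(design["participant_id"], sort=True)
    n_pid = len(pid_index)
    exog_vc = sparse.csr_matrix(
        (np.ones(len(design)), (np.arange(len(design)), pid_codes)),
        shape=(len(design), n_pid),
    )
    ident = np.zeros(n_pid, dtype=int)
    converged, diag = True, ""
    model = BinomialBayesMixedGLM(
        endog, exog, exog_vc, ident,
        fep_names=["(Intercept)"] + fixed_cols,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit_vb()
        except Exception as exc:  # separation / numerical failure
            raise TraitError(f"mixed model failed to fit: {exc}") from exc
    if not getattr(res, "converged", True):
        converged = False
        diag = "variational optimization did not report convergence"

    est = res.fe_mean
    se = res.fe_sd
    z = est / se
    p = 2.0 * norm.sf(np.abs(z))
    coef = pd.DataFrame(
        {"term": ["(Intercept)"] + fixed_cols, "estimate": est, "se": se, "z": z, "p": p}
    )
    # vcp holds log-SDs of the variance components
    re_var = float(np.exp(2.0 * res.vcp_mean[0]))
    lin_fixed = exog[:, 1:] @ est[1:] if len(fixed_cols) else np.zeros(len(design))
    var_f = float(np.var(lin_fixed))
    resid = np.pi**2 / 3.0
    r2m = var_f / (var_f + re_var + resid)
    r2c = (var_f + re_var) / (var_f + re_var + resid)
    return GlmmResult(
        coefficients=coef,
        random_intercept_var=re_var,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_obs=len(design),
        n_participants=n_pid,
        converged=converged,
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# median splits and multiple-comparison gating


@dataclass
class MedianSplit:
    groups: pd.Series                # participant -> "low" / "high"
    summary: pd.DataFrame            # group, n, mean, sem
    median: float
    degenerate: bool


def median_split_summary(scores: pd.Series, measure: pd.Series) -> MedianSplit:
    """Split participants at the score median (ties go to the low group) and
    summarize a behavioral measure per group."""
    scores = scores.dropna()
    if len(scores) < 2:
        raise TraitError("median split requires >= 2 participants")
    med = float(scores.median())
    groups = pd.Series(
        np.where(scores <= med, "low", "high"), index=scores.index, name="group"
    )
    degenerate = bool((groups == "low").all() or (groups == "high").all())
    if degenerate:
        warnings.warn("degenerate median split: all participants in one group")
    rows = []
    for g in ("low", "high"):
        vals = measure.reindex(groups.index[groups == g]).dropna()
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan
        rows.append((g, len(vals), vals.mean() if len(vals) else np.nan, sem))
    return MedianSplit(
        groups=groups,
        summary=pd.DataFrame(rows, columns=["group", "n", "mean", "sem"]),
        median=med,
        degenerate=degenerate,
    )


def multiple_comparison_gate(
    p_values, family_size: int, level: float = 0.05
) -> pd.DataFrame:
    """Bonferroni decisions: reject iff p < level / family_size."""
    p_values = list(p_values)
    if family_size < len(p_values):
        raise TraitError("family_size must be >= number of p-values")
    threshold = level / family_size
    return pd.DataFrame(
        {
            "p": p_values,
            "significant_raw": [p < level for p in p_values],
            "significant_bonferroni": [p < threshold for p in p_values],
            "adjusted_threshold": threshold,
        }
    )
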