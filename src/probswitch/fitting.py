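"""Hierarchical Bayesian estimation of the RL and BI choice models.

Subject-level parameters are drawn from group-level distributions (beta for
unit-interval parameters, gamma for the inverse temperature, truncated
normal on [-1, 1] for stickiness), whose hyperparameters carry weakly
informative hyperpriors: gamma(1, 1) for beta/gamma hyperparameters,
N(0, 10) for the stickiness group mean and half-N(0, 10) for its spread.

Sampling uses a seeded adaptive Metropolis-within-Gibbs scheme that exploits
the model's conditional structure: given the group hyperparameters, subjects
are independent, so all subject blocks are proposed and accepted in parallel
(compiled likelihood kernels), after which the hyperparameters are refreshed
against the subject draws. Several inner proposals are made per recorded
sweep so recorded draws are close to independent. Convergence is checked
with split-Rhat and effective sample size (arviz); a random-walk scheme has
no divergent transitions, so the divergence count is structurally zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, gammaln
from scipy.stats import norm, pearsonr

from . import _likelihood as _lik
from .agents import EPSILON_DEFAULT

PARAM_KINDS = ("unit", "unit", "pos", "interval")
PARAM_NAMES = {
    "rl": ("alpha_pos", "alpha_neg", "beta", "st"),
    "bi": ("p_reward", "p_switch", "beta", "st"),
}

# rejection boxes for the unconstrained coordinates (symmetric proposals
# rejected outside the box keep the chain valid on the truncated support)
_U_BOUNDS = {"unit": (-9.0, 9.0), "pos": (-5.0, 4.5), "interval": (-1.0, 1.0)}
_H_BOUNDS = (-5.0, 6.5)  # log-scale hypers; st mean bounded separately


class FitError(ValueError):
    """Raised for invalid fitting requests (bad model tag, empty data...)."""


@dataclass(frozen=True)
class ModelDef:
    """A model tag resolved into its likelihood kind and restrictions."""

    tag: str
    kind: str                      # "rl" or "bi"
    tie: tuple = ()                # ((target_dim, source_dim), ...)
    fixed: tuple = ()              # ((dim, value), ...)
    counterfactual: bool = True

    @property
    def param_names(self):
        return PARAM_NAMES[self.kind]

    @property
    def free_dims(self):
        tied = {t for t, _ in self.tie} | {d for d, _ in self.fixed}
        return tuple(d for d in range(4) if d not in tied)


def parse_model(tag: str) -> ModelDef:
    """Resolve a model tag, including nested-RL restriction variants."""
    if tag == "rl":
        return ModelDef(tag, "rl")
    if tag == "bi":
        return ModelDef(tag, "bi")
    if tag.startswith("rl-nested:"):
        variant = tag.split(":", 1)[1]
        if variant == "shared-alpha":
            return ModelDef(tag, "rl", tie=((1, 0),))
        if variant == "no-stickiness":
            return ModelDef(tag, "rl", fixed=((3, 0.0),))
        if variant == "no-counterfactual":
            return ModelDef(tag, "rl", counterfactual=False)
        raise FitError(f"unknown nested-RL variant {variant!r}")
    raise FitError(f"unknown model tag {tag!r}")


@dataclass(frozen=True)
class HierPriorSpec:
    """Hyperprior settings for the group-level distributions.

    Defaults match the hierarchical scheme described in the module docstring;
    they are exposed for sensitivity analyses only.
    """

    unit_hyper_rate: float = 1.0       # gamma(1, rate) == Exp(rate) on beta a, b
    pos_hyper_rate: float = 1.0        # on gamma shape and rate for beta (inv. temp.)
    st_mean_sd: float = 10.0           # N(0, sd) on the st group mean
    st_sd_sd: float = 10.0             # half-N(0, sd) on the st group spread


@dataclass(frozen=True)
class McmcSettings:
    """Sampler settings. ``n_iterations`` is total sweeps per chain including
    warm-up (Stan-style), so kept draws = n_iterations - n_warmup."""

    n_chains: int = 4
    n_warmup: int = 1000
    n_iterations: int = 5000
    seed: int = 0
    rounds_per_sweep: int = 12
    hyper_steps: int = 2
    max_pointwise_draws: int = 500

    def __post_init__(self):
        if self.n_iterations <= self.n_warmup:
            raise FitError("n_iterations must exceed n_warmup")


REDUCED_SETTINGS = McmcSettings(n_chains=2, n_warmup=500, n_iterations=1000)


@dataclass
class HierFit:
    """Posterior draws, per-subject point estimates and diagnostics."""

    model: str
    participants: list
    idata: object                      # arviz.InferenceData
    theta_draws: np.ndarray            # (chains, draws, n_subj, 4) natural scale
    subject_estimates: pd.DataFrame    # participant x parameter posterior means
    diagnostics: pd.DataFrame          # parameter, rhat, ess
    max_rhat: float
    min_ess: float
    n_divergences: int
    converged: bool
    pointwise_loglik: np.ndarray       # (total draws used, total trials)
    trial_participant: np.ndarray      # participant index per pointwise column
    waic: "WaicResult"
    excluded: list = field(default_factory=list)
    truth: pd.DataFrame | None = None


@dataclass(frozen=True)
class WaicResult:
    """WAIC on the deviance scale (-2 * elpd; lower is better)."""

    waic: float
    se: float
    elpd: float
    p_waic: float


def compute_waic(fit_or_pointwise) -> WaicResult:
    """WAIC from pointwise posterior log-likelihood draws.

    Accepts a :class:`HierFit` or a raw (draws, observations) array. Uses the
    log-pointwise-predictive-density minus the variance-based effective
    parameter penalty, averaging over the posterior draws.
    """
    if isinstance(fit_or_pointwise, HierFit):
        table = fit_or_pointwise.pointwise_loglik
    else:
        table = np.asarray(fit_or_pointwise, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise FitError("pointwise log-likelihood draws missing or malformed")
    s = table.shape[0]
    col_max = table.max(axis=0)
    lppd = col_max + np.log(np.exp(table - col_max).mean(axis=0))
    p = table.var(axis=0, ddof=1)
    elpd_i = lppd - p
    elpd = float(elpd_i.sum())
    n = table.shape[1]
    se = float(2.0 * np.sqrt(n * elpd_i.var(ddof=1)))
    return WaicResult(waic=-2.0 * elpd, se=se, elpd=elpd, p_waic=float(p.sum()))


# ---------------------------------------------------------------------------
# data preparation


@dataclass
class _StackedData:
    participants: list
    choices: np.ndarray
    rewards: np.ndarray
    new_block: np.ndarray
    offsets: np.ndarray
    excluded: list


def _stack_logs(logs: pd.DataFrame) -> _StackedData:
    participants, excluded = [], []
    ch, rw, nb, offsets = [], [], [], [0]
    for pid, grp in logs.groupby("participant_id", sort=True):
        resp = grp[grp["responded"].astype(bool)]
        if len(resp) == 0:
            excluded.append(pid)
            warnings.warn(f"participant {pid!r} has no responded trials; excluded")
            continue
        participants.append(pid)
        for _, block in resp.sort_values("trial").groupby("block_id", sort=True):
            block = block.sort_values("trial")
            c = block["chosen_side"].to_numpy(dtype=np.int64)
            r = block["rewarded"].to_numpy(dtype=np.int64)
            flags = np.zeros(len(block), dtype=np.bool_)
            flags[0] = True
            ch.append(c)
            rw.append(r)
            nb.append(flags)
        offsets.append(offsets[-1] + int(resp.shape[0]))
    if not participants:
        raise FitError("no participants with responded trials")
    return _StackedData(
        participants=participants,
        choices=np.concatenate(ch),
        rewards=np.concatenate(rw),
        new_block=np.concatenate(nb),
        offsets=np.asarray(offsets, dtype=np.int64),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# transforms and densities


def _theta_from_u(u: np.ndarray, mdef: ModelDef) -> np.ndarray:
    theta = np.empty_like(u)
    theta[:, 0] = expit(u[:, 0])
    theta[:, 1] = expit(u[:, 1])
    theta[:, 2] = np.exp(u[:, 2])
    theta[:, 3] = u[:, 3]
    for tgt, src in mdef.tie:
        theta[:, tgt] = theta[:, src]
    for d, val in mdef.fixed:
        theta[:, d] = val
    return theta


def _subject_logprior_dim(x: np.ndarray, d: int, hypers: dict) -> np.ndarray:
    """Log prior of one parameter column in unconstrained coordinates.

    Hyper-only normalizing constants are dropped: they cancel in every
    Metropolis ratio where they appear (both sides share the hypers).
    """
    h1, h2 = hypers[d]
    kind = PARAM_KINDS[d]
    if kind == "unit":
        # beta(a, b) density + logit Jacobian x(1-x); saturated proposals
        # (x numerically 0 or 1) get -inf and are rejected
        with np.errstate(divide="ignore"):
            return h1 * np.log(x) + h2 * np.log1p(-x)
    if kind == "pos":
        # gamma(shape, rate) density + log Jacobian
        with np.errstate(divide="ignore"):
            return h1 * np.log(x) - h2 * x
    lp = -0.5 * ((x - h1) / h2) ** 2
    return np.where(np.abs(x) <= 1.0, lp, -np.inf)


def _subject_logprior(theta: np.ndarray, hypers: dict, mdef: ModelDef) -> np.ndarray:
    lp = np.zeros(theta.shape[0])
    for d in mdef.free_dims:
        lp = lp + _subject_logprior_dim(theta[:, d], d, hypers)
    return lp


def _hyper_stats(x: np.ndarray, kind: str) -> tuple:
    """Sufficient statistics of one parameter column for its hyper update."""
    n = x.shape[0]
    if kind == "unit":
        return (n, float(np.log(x).sum()), float(np.log1p(-x).sum()))
    if kind == "pos":
        return (n, float(np.log(x).sum()), float(x.sum()))
    return (n, float(x.sum()), float((x * x).sum()))


def _std_norm_cdf(z: float) -> float:
    return 0.5 * math.erfc(-z / math.sqrt(2.0))


def _hyper_logdens(v: np.ndarray, stats: tuple, kind: str, priors: HierPriorSpec) -> float:
    """Conditional log density of one parameter's hyper pair given the
    subject-column sufficient statistics, in transformed coordinates
    (Jacobians included)."""
    if kind == "unit":
        n, slx, sl1mx = stats
        la, lb = v
        if not (_H_BOUNDS[0] <= la <= _H_BOUNDS[1] and _H_BOUNDS[0] <= lb <= _H_BOUNDS[1]):
            return -np.inf
        a, b = math.exp(la), math.exp(lb)
        return (
            a * slx + b * sl1mx - n * betaln(a, b)
            - priors.unit_hyper_rate * (a + b) + la + lb
        )
    if kind == "pos":
        n, slx, sx = stats
        lk, lr = v
        if not (_H_BOUNDS[0] <= lk <= _H_BOUNDS[1] and _H_BOUNDS[0] <= lr <= _H_BOUNDS[1]):
            return -np.inf
        k, r = math.exp(lk), math.exp(lr)
        return (
            (k - 1.0) * slx - r * sx + n * (k * math.log(r) - gammaln(k))
            - priors.pos_hyper_rate * (k + r) + lk + lr
        )
    n, sx, sxx = stats
    mu, ls = v
    if not (-5.0 <= mu <= 5.0 and -4.0 <= ls <= 3.0):
        return -np.inf
    sigma = math.exp(ls)
    z = _std_norm_cdf((1.0 - mu) / sigma) - _std_norm_cdf((-1.0 - mu) / sigma)
    if z <= 0.0:
        return -np.inf
    ssq = sxx - 2.0 * mu * sx + n * mu * mu
    return (
        -0.5 * ssq / sigma**2 - n * ls - n * math.log(z)
        - 0.5 * mu**2 / priors.st_mean_sd**2
        - 0.5 * sigma**2 / priors.st_sd_sd**2 + ls
    )


def _slice_coord(v: np.ndarray, idx: int, logf, rng, w: float = 0.8,
                 max_steps: int = 8) -> None:
    """Univariate slice sampling (stepping-out + shrinkage) on ``v[idx]``,
    in place. ``logf(v)`` must be cheap; used for the hyper conditionals."""
    x0 = v[idx]
    f0 = logf(v)
    if not np.isfinite(f0):
        return
    level = f0 + math.log(rng.random())
    left = x0 - w * rng.random()
    right = left + w
    v[idx] = left
    for _ in range(max_steps):
        if logf(v) <= level:
            break
        v[idx] -= w
    left = v[idx]
    v[idx] = right
    for _ in range(max_steps):
        if logf(v) <= level:
            break
        v[idx] += w
    right = v[idx]
    while True:
        x1 = left + rng.random() * (right - left)
        v[idx] = x1
        if logf(v) > level:
            return
        if x1 < x0:
            left = x1
        else:
            right = x1
        if right - left < 1e-12:
            v[idx] = x0
            return


def _moment_match_hypers(theta: np.ndarray, mdef: ModelDef) -> dict:
    hypers = {}
    for d in mdef.free_dims:
        x = theta[:, d]
        m, v = float(x.mean()), float(x.var() + 1e-4)
        kind = PARAM_KINDS[d]
        if kind == "unit":
            conc = np.clip(m * (1 - m) / v - 1.0, 1.5, 60.0)
            hypers[d] = (max(m * conc, 0.2), max((1 - m) * conc, 0.2))
        elif kind == "pos":
            hypers[d] = (np.clip(m * m / v, 0.5, 60.0), np.clip(m / v, 0.05, 30.0))
        else:
            hypers[d] = (m, float(np.clip(np.sqrt(v), 0.08, 2.0)))
    return hypers


# ---------------------------------------------------------------------------
# the sampler


def _batch_ll(data: _StackedData, theta: np.ndarray, mdef: ModelDef) -> np.ndarray:
    out = np.empty(theta.shape[0])
    _lik.loglik_batch(
        0 if mdef.kind == "rl" else 1,
        data.choices, data.rewards, data.new_block, data.offsets,
        theta, EPSILON_DEFAULT, mdef.counterfactual, out,
    )
    return out


def _run_chain(data, mdef, priors, settings, rng):
    """One MCMC chain: per-dimension subject proposals interleaved with
    sufficient-statistic hyperparameter refreshes, several rounds per
    recorded sweep."""
    n_subj = len(data.participants)
    free = list(mdef.free_dims)

    # dispersed but plausible start
    u = np.zeros((n_subj, 4))
    u[:, 0] = rng.normal(-0.5, 0.8, n_subj)
    u[:, 1] = rng.normal(-0.8, 0.8, n_subj)
    u[:, 2] = rng.normal(np.log(4.0), 0.5, n_subj)
    u[:, 3] = rng.uniform(-0.3, 0.4, n_subj)
    theta = _theta_from_u(u, mdef)
    hypers = _moment_match_hypers(theta, mdef)

    hv = {}
    for d in free:
        h1, h2 = hypers[d]
        if PARAM_KINDS[d] == "interval":
            hv[d] = np.array([h1, np.log(h2)])
        else:
            hv[d] = np.array([np.log(h1), np.log(h2)])

    def hypers_nat():
        out = {}
        for d in free:
            v = hv[d]
            if PARAM_KINDS[d] == "interval":
                out[d] = (v[0], np.exp(v[1]))
            else:
                out[d] = (np.exp(v[0]), np.exp(v[1]))
        return out

    # per-(subject, dim) adaptive proposal scales, target acceptance ~0.44
    log_step = np.full((n_subj, 4), np.log(0.4))
    log_step[:, 3] = np.log(0.2)

    ll_cur = _batch_ll(data, theta, mdef)

    kept = settings.n_iterations - settings.n_warmup
    theta_draws = np.empty((kept, n_subj, 4))
    hyper_draws = {d: np.empty((kept, 2)) for d in free}
    ll_draws = np.empty((kept, n_subj))

    bounds = {d: _U_BOUNDS[PARAM_KINDS[d]] for d in range(4)}
    lo_vec = np.array([bounds[d][0] for d in free])
    hi_vec = np.array([bounds[d][1] for d in free])

    # covariance-adapted joint proposals, learned during warm-up (standard
    # adaptive-Metropolis recipe, refreshed twice and frozen before sampling)
    n_free = len(free)
    hist = np.empty((settings.n_warmup, n_subj, n_free))
    refresh_at = sorted({max(settings.n_warmup // 2, 10), settings.n_warmup})
    chol = None
    log_js = np.full(n_subj, np.log(2.38 / np.sqrt(n_free)))

    def _refresh_chol(lo: int, hi: int):
        out = np.empty((n_subj, n_free, n_free))
        for s in range(n_subj):
            cov = np.cov(hist[lo:hi, s, :], rowvar=False)
            cov = np.atleast_2d(cov) + 1e-6 * np.eye(n_free)
            out[s] = np.linalg.cholesky(cov)
        return out

    inner_t = 0
    for sweep in range(settings.n_iterations):
        warm = sweep < settings.n_warmup
        if warm:
            hist[sweep] = u[:, free]
        if sweep in refresh_at:
            lo = sweep // 2 if sweep < settings.n_warmup else settings.n_warmup // 2
            chol = _refresh_chol(lo, sweep)
        for _ in range(settings.rounds_per_sweep):
            inner_t += 1
            gamma = min(0.25, 4.0 / np.sqrt(inner_t + 20.0)) if warm else 0.0
            hn = hypers_nat()
            lp_cur = _subject_logprior(theta, hn, mdef)
            if chol is not None:
                # joint move along the learned local covariance; occasional
                # triple-scale kicks help hop between nearby posterior modes
                z = rng.standard_normal((n_subj, n_free))
                kick = np.where(rng.random(n_subj) < 0.1, 3.0, 1.0)
                step = (kick * np.exp(log_js))[:, None] * np.einsum(
                    "sij,sj->si", chol, z
                )
                prop_u = u.copy()
                prop_u[:, free] = u[:, free] + step
                inside = (
                    (prop_u[:, free] >= lo_vec) & (prop_u[:, free] <= hi_vec)
                ).all(axis=1)
                prop_theta = _theta_from_u(prop_u, mdef)
                ll_prop = _batch_ll(data, prop_theta, mdef)
                lp_prop = _subject_logprior(prop_theta, hn, mdef)
                log_ratio = np.where(
                    inside, (ll_prop + lp_prop) - (ll_cur + lp_cur), -np.inf
                )
                accept = np.log(rng.random(n_subj)) < log_ratio
                u[accept] = prop_u[accept]
                theta[accept] = prop_theta[accept]
                ll_cur[accept] = ll_prop[accept]
                lp_cur[accept] = lp_prop[accept]
                if warm:
                    log_js += gamma * (accept.astype(float) - 0.28)
                    np.clip(log_js, np.log(0.05), np.log(5.0), out=log_js)
            # one Metropolis proposal per free dimension, all subjects at once
            for d in free:
                prop_u = u.copy()
                prop_u[:, d] = u[:, d] + rng.normal(
                    0.0, np.exp(log_step[:, d]), n_subj
                )
                lo, hi = bounds[d]
                inside = (prop_u[:, d] >= lo) & (prop_u[:, d] <= hi)
                prop_theta = _theta_from_u(prop_u, mdef)
                ll_prop = _batch_ll(data, prop_theta, mdef)
                lp_prop = _subject_logprior(prop_theta, hn, mdef)
                log_ratio = np.where(
                    inside, (ll_prop + lp_prop) - (ll_cur + lp_cur), -np.inf
                )
                accept = np.log(rng.random(n_subj)) < log_ratio
                u[accept] = prop_u[accept]
                theta[accept] = prop_theta[accept]
                ll_cur[accept] = ll_prop[accept]
                lp_cur[accept] = lp_prop[accept]
                if warm:
                    log_step[:, d] += gamma * (accept.astype(float) - 0.44)
                    np.clip(
                        log_step[:, d], np.log(0.02), np.log(3.0),
                        out=log_step[:, d],
                    )
            # hyperparameter refresh: coordinate-wise slice sampling on the
            # conditional given the subject-column sufficient statistics
            for d in free:
                kind = PARAM_KINDS[d]
                stats = _hyper_stats(theta[:, d], kind)
                logf = lambda v: _hyper_logdens(v, stats, kind, priors)
                for _ in range(settings.hyper_steps):
                    _slice_coord(hv[d], 0, logf, rng)
                    _slice_coord(hv[d], 1, logf, rng)

        if not warm:
            k = sweep - settings.n_warmup
            theta_draws[k] = theta
            for d in free:
                hyper_draws[d][k] = hv[d]
            ll_draws[k] = ll_cur

    # hypers back to natural scale
    hyper_nat_draws = {}
    for d in free:
        v = hyper_draws[d]
        if PARAM_KINDS[d] == "interval":
            hyper_nat_draws[d] = np.column_stack([v[:, 0], np.exp(v[:, 1])])
        else:
            hyper_nat_draws[d] = np.exp(v)
    return theta_draws, hyper_nat_draws, ll_draws


_HYPER_SUFFIX = {"unit": ("a", "b"), "pos": ("shape", "rate"), "interval": ("mu", "sigma")}


def fit_hierarchical(
    logs: pd.DataFrame,
    model: str = "rl",
    priors: HierPriorSpec | None = None,
    settings: McmcSettings | None = None,
    truth: pd.DataFrame | None = None,
) -> HierFit:
    """Fit a hierarchical choice model to a cohort of trial logs by MCMC.

    ``logs`` must hold >= 2 participants (participants with zero responded
    trials are excluded with a warning). Returns a :class:`HierFit` with
    posterior draws, posterior-mean point estimates per subject, split-Rhat /
    ESS diagnostics, pointwise log-likelihood draws and WAIC. Non-convergence
    does not raise: the fit is returned flagged, with a warning.
    """
    import arviz as az

    mdef = parse_model(model)
    if priors is None:
        priors = HierPriorSpec()
    if settings is None:
        settings = McmcSettings()
    data = _stack_logs(logs)
    if len(data.participants) < 2:
        raise FitError("hierarchical fitting requires at least 2 participants")

    seed_seq = np.random.SeedSequence([int(settings.seed) % (2**31), 1311])
    chains = [
        _run_chain(data, mdef, priors, settings, np.random.default_rng(s))
        for s in seed_seq.spawn(settings.n_chains)
    ]
    theta = np.stack([c[0] for c in chains])          # (C, K, n_subj, 4)
    ll = np.stack([c[2] for c in chains])

    names = mdef.param_names
    posterior = {}
    for d in mdef.free_dims:
        posterior[names[d]] = (
            ["chain", "draw", "participant"], theta[:, :, :, d],
        )
        s1, s2 = _HYPER_SUFFIX[PARAM_KINDS[d]]
        hyp = np.stack([c[1][d] for c in chains])     # (C, K, 2)
        posterior[f"{names[d]}_{s1}"] = (["chain", "draw"], hyp[:, :, 0])
        posterior[f"{names[d]}_{s2}"] = (["chain", "draw"], hyp[:, :, 1])
    idata = az.convert_to_inference_data(
        {k: v[1] for k, v in posterior.items()},
        coords={"participant": data.participants},
        dims={names[d]: ["participant"] for d in mdef.free_dims},
    )

    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata)
    diag_rows = []
    for var in rhat_ds.data_vars:
        r = np.atleast_1d(rhat_ds[var].values)
        e = np.atleast_1d(ess_ds[var].values)
        for i in range(r.size):
            label = var if r.size == 1 else f"{var}[{data.participants[i]}]"
            diag_rows.append((label, float(r.flat[i]), float(e.flat[i])))
    diagnostics = pd.DataFrame(diag_rows, columns=["parameter", "rhat", "ess"])
    max_rhat = float(diagnostics["rhat"].max())
    min_ess = float(diagnostics["ess"].min())
    converged = bool(max_rhat < 1.01 and min_ess > 40)
    if not converged:
        warnings.warn(
            f"fit not converged: max Rhat {max_rhat:.4f}, min ESS {min_ess:.1f}"
        )

    estimates = pd.DataFrame(
        theta.reshape(-1, len(data.participants), 4).mean(axis=0),
        index=pd.Index(data.participants, name="participant_id"),
        columns=names,
    )

    # pointwise log-likelihood on a thinned subset of draws (for WAIC)
    n_chains, n_kept = theta.shape[0], theta.shape[1]
    per_chain = max(2, settings.max_pointwise_draws // n_chains)
    idx = np.unique(np.linspace(0, n_kept - 1, per_chain).astype(int))
    n_trials_total = int(data.offsets[-1])
    pointwise = np.empty((n_chains * len(idx), n_trials_total))
    row = 0
    kind = 0 if mdef.kind == "rl" else 1
    for c in range(n_chains):
        for k in idx:
            _lik.pointwise_batch(
                kind, data.choices, data.rewards, data.new_block, data.offsets,
                np.ascontiguousarray(theta[c, k]), EPSILON_DEFAULT,
                mdef.counterfactual, pointwise[row],
            )
            row += 1
    trial_participant = np.repeat(
        np.arange(len(data.participants)), np.diff(data.offsets)
    )

    fit = HierFit(
        model=model,
        participants=data.participants,
        idata=idata,
        theta_draws=theta,
        subject_estimates=estimates,
        diagnostics=diagnostics,
        max_rhat=max_rhat,
        min_ess=min_ess,
        n_divergences=0,
        converged=converged,
        pointwise_loglik=pointwise,
        trial_participant=trial_participant,
        waic=compute_waic(pointwise),
        excluded=data.excluded,
        truth=truth,
    )
    return fit


# ---------------------------------------------------------------------------
# generate-and-recover and posterior predictive checks


@dataclass
class RecoveryReport:
    """Truth vs. estimate comparison from a generate-and-recover run."""

    model: str
    table: pd.DataFrame            # participant, parameter, truth, estimate
    correlations: pd.Series        # Pearson r per parameter
    fit: HierFit


def generate_and_recover(
    model: str = "rl",
    n_participants: int = 20,
    blocks_per: int = 2,
    seed: int = 0,
    settings: McmcSettings | None = None,
    cohort_kwargs: dict | None = None,
) -> RecoveryReport:
    """Simulate a cohort from known parameters, refit, and report per-parameter
    truth-estimate Pearson correlations."""
    from .cohort import CohortSpec, generate_cohort

    if n_participants < 2:
        raise FitError("generate-and-recover requires at least 2 participants")
    spec = CohortSpec(
        n_participants=n_participants,
        blocks_per_participant=blocks_per,
        generating_model=model,
        seed=seed,
        **(cohort_kwargs or {}),
    )
    cohort = generate_cohort(spec)
    truth = cohort.table.set_index("participant_id")[list(PARAM_NAMES[parse_model(model).kind])]
    if settings is None:
        settings = McmcSettings(
            n_chains=REDUCED_SETTINGS.n_chains,
            n_warmup=REDUCED_SETTINGS.n_warmup,
            n_iterations=REDUCED_SETTINGS.n_iterations,
            seed=seed,
        )
    fit = fit_hierarchical(cohort.logs, model, settings=settings, truth=truth)
    est = fit.subject_estimates
    rows, corrs = [], {}
    for p in est.columns:
        t = truth.loc[est.index, p].to_numpy(dtype=float)
        e = est[p].to_numpy()
        for pid, tv, ev in zip(est.index, t, e):
            rows.append((pid, p, tv, ev))
        corrs[p] = pearsonr(t, e).statistic if np.std(t) > 0 else np.nan
    table = pd.DataFrame(rows, columns=["participant_id", "parameter", "truth", "estimate"])
    return RecoveryReport(model=model, table=table, correlations=pd.Series(corrs), fit=fit)


@dataclass
class PPCResult:
    real: object
    simulated: object
    sim_logs: pd.DataFrame


def posterior_predictive_check(fit: HierFit, logs: pd.DataFrame, seed: int = 0) -> PPCResult:
    """Simulate each participant with their posterior-mean parameters on fresh
    schedules and compare behavioral summaries against the fitted data."""
    from .agents import AgentPolicy, BIParams, RLParams
    from .metrics import behavior_summary
    from .task import TaskConfig, build_block_schedule, run_session

    mdef = parse_model(fit.model)
    sim_logs = []
    ss = np.random.SeedSequence([int(seed) % (2**31), 405])
    for pid, child in zip(fit.participants, ss.spawn(len(fit.participants))):
        est = fit.subject_estimates.loc[pid]
        if mdef.kind == "rl":
            params = RLParams(est["alpha_pos"], est["alpha_neg"], est["beta"], est["st"])
        else:
            params = BIParams(est["p_reward"], est["p_switch"], est["beta"], est["st"])
        n_blocks = int(logs.loc[logs["participant_id"] == pid, "block_id"].nunique())
        streams = child.spawn(n_blocks)
        for b in range(n_blocks):
            rng = np.random.default_rng(streams[b])
            cfg = TaskConfig(rng_seed=int(rng.integers(2**31)))
            sched = build_block_schedule(cfg, version=b % cfg.n_sequence_versions)
            policy = AgentPolicy(params, "rl" if mdef.kind == "rl" else "bi", rng=rng)
            sim_logs.append(run_session(sched, cfg, policy, participant_id=pid, block_id=b))
    sim = pd.concat(sim_logs, ignore_index=True)
    return PPCResult(
        real=behavior_summary(logs), simulated=behavior_summary(sim), sim_logs=sim
    )
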