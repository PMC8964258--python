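"""Readers/writers, run configuration and the staged pipeline driver.

Trial logs travel as tidy CSV (header mandatory, missing values as empty
fields, one row per trial); every pipeline output directory carries a
manifest with the config hash, seed, stage timings and library versions.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import TRIAL_COLUMNS, TaskConfig


class IOError_(ValueError):
    pass


def write_trial_log(logs: pd.DataFrame, path) -> None:
    logs.to_csv(path, index=False)


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a tidy trial-log CSV.

    Malformed rows raise with line numbers; a rewarded incorrect choice (not
    possible under the default task design) is retained with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such file: {path}")
    logs = pd.read_csv(path)
    if logs.empty:
        raise IOError_(f"empty trial log: {path}")
    missing = [c for c in TRIAL_COLUMNS if c not in logs.columns]
    if missing:
        raise IOError_(f"{path}: missing columns {missing}")
    logs["chosen_side"] = logs["chosen_side"].astype("Int64")
    logs["rewarded"] = logs["rewarded"].astype("Int64")
    logs["responded"] = logs["responded"].astype(bool)
    logs["reversal_trial"] = logs["reversal_trial"].astype(bool)

    bad = logs.index[logs["responded"] & logs["chosen_side"].isna()] + 2
    if len(bad):
        raise IOError_(f"{path}: responded rows missing chosen_side at lines {list(bad[:10])}")
    bad = logs.index[~logs["responded"] & logs["rewarded"].notna()] + 2
    if len(bad):
        raise IOError_(f"{path}: non-responded rows carry outcomes at lines {list(bad[:10])}")
    odd = logs["responded"] & (logs["rewarded"] == 1) & (
        logs["chosen_side"] != logs["correct_side"]
    )
    if odd.any():
        warnings.warn(
            f"{path}: {int(odd.sum())} rewarded incorrect-choice rows "
            "(impossible under the default task design); rows retained"
        )
    return logs


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    task: dict = field(default_factory=dict)
    model: dict = field(default_factory=lambda: {"generating_model": "rl"})
    cohort: dict = field(default_factory=dict)
    fitting: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    traits: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise IOError_(
                f"unknown config keys {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def task_config(self) -> TaskConfig:
        return TaskConfig(**self.task) if self.task else TaskConfig(rng_seed=self.seed)


PIPELINE_STAGES = ("simulate", "analyze", "fit", "traits")


def run_pipeline(config: RunConfig, stages, out_dir) -> dict:
    """Execute pipeline stages in order, writing versioned outputs plus a
    manifest. Downstream stages require their upstream artifacts."""
    from . import __version__
    from .cohort import CohortSpec, Plant, generate_cohort
    from .fitting import REDUCED_SETTINGS, McmcSettings, fit_hierarchical
    from .metrics import (ExclusionCriteria, ab_table, behavior_summary,
                          preprocess_sessions, stay_probability_table_3back)
    from .traits import (build_history_design, fit_history_glmm,
                         gated_correlation, score_supps)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in PIPELINE_STAGES]
    if unknown:
        raise IOError_(f"unknown stages {unknown}; valid: {list(PIPELINE_STAGES)}")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "library_versions": {
            "numpy": np.__version__, "pandas": pd.__version__,
        },
        "stages": {},
    }

    log_path = out_dir / "trial_logs.csv"
    items_path = out_dir / "questionnaire.csv"

    def _require(path, producer):
        if not Path(path).exists():
            raise IOError_(
                f"missing upstream artifact {path}; run the {producer!r} stage first"
            )

    for stage in stages:
        t0 = time.perf_counter()
        if stage == "simulate":
            plant_cfg = config.cohort.get("plant")
            spec = CohortSpec(
                n_participants=int(config.cohort.get("n_participants", 20)),
                blocks_per_participant=int(config.cohort.get("blocks_per_participant", 2)),
                generating_model=config.model.get("generating_model", "rl"),
                plant=Plant(**plant_cfg) if plant_cfg else None,
                task=config.task_config(),
                seed=config.seed,
            )
            cohort = generate_cohort(spec)
            write_trial_log(cohort.logs, log_path)
            cohort.items.to_csv(items_path)
            truth = {
                "seed": config.seed,
                "generating_model": spec.generating_model,
                "plant": plant_cfg,
                "parameters": cohort.table.to_dict(orient="list"),
            }
            (out_dir / "ground_truth.json").write_text(json.dumps(truth, default=str))
        elif stage == "analyze":
            _require(log_path, "simulate")
            logs = read_trial_log(log_path)
            logs, report = preprocess_sessions(
                logs, ExclusionCriteria(**config.analysis.get("exclusion", {}))
            )
            report.to_csv(out_dir / "exclusions.csv", index=False)
            summary = behavior_summary(logs)
            summary.switch_aligned_curve.to_csv(out_dir / "switch_curve.csv", index=False)
            summary.three_back_table.to_csv(out_dir / "three_back.csv", index=False)
            summary.ab_table.to_csv(out_dir / "ab_table.csv", index=False)
            summary.per_participant.to_csv(out_dir / "per_participant.csv")
        elif stage == "fit":
            _require(log_path, "simulate")
            logs = read_trial_log(log_path)
            fit_cfg = dict(config.fitting)
            model = fit_cfg.pop("model", config.model.get("generating_model", "rl"))
            settings = McmcSettings(
                n_chains=int(fit_cfg.get("n_chains", REDUCED_SETTINGS.n_chains)),
                n_warmup=int(fit_cfg.get("n_warmup", REDUCED_SETTINGS.n_warmup)),
                n_iterations=int(fit_cfg.get("n_iterations", REDUCED_SETTINGS.n_iterations)),
                seed=config.seed,
            )
            fit = fit_hierarchical(logs, model, settings=settings)
            fit.subject_estimates.to_csv(out_dir / f"fit_{model}_estimates.csv")
            fit.diagnostics.to_csv(out_dir / f"fit_{model}_diagnostics.csv", index=False)
            pd.DataFrame(
                [{"model": model, "waic": fit.waic.waic, "se": fit.waic.se,
                  "elpd": fit.waic.elpd, "p_waic": fit.waic.p_waic,
                  "max_rhat": fit.max_rhat, "min_ess": fit.min_ess,
                  "converged": fit.converged}]
            ).to_csv(out_dir / f"fit_{model}_summary.csv", index=False)
        elif stage == "traits":
            _require(log_path, "simulate")
            _require(items_path, "simulate")
            logs = read_trial_log(log_path)
            items = pd.read_csv(items_path, index_col=0)
            scores = score_supps(items)
            scores.to_csv(out_dir / "trait_scores.csv")
            tb = stay_probability_table_3back(logs)
            pstay = tb[tb["condition"] == "---"].set_index("participant_id")["p_stay"]
            corr = gated_correlation(
                scores.loc[pstay.index, "total"], pstay
            )
            pd.DataFrame([corr.__dict__]).to_csv(out_dir / "trait_correlations.csv", index=False)
            design = build_history_design(logs, traits=scores, with_interactions=True)
            res = fit_history_glmm(design)
            res.coefficients.to_csv(out_dir / "glmm_coefficients.csv", index=False)
        manifest["stages"][stage] = {
            "status": "complete",
            "seconds": round(time.perf_counter() - t0, 3),
        }

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
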