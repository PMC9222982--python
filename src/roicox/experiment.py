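"""Cross-validation harness: stratified folds, per-fold fitting and scoring.

Protocol: stratified ten-fold cross-validation on the primary outcome's
event status.  Within each fold, features are standardized on the
training portion only (leakage-safe default; a "global" switch exists for
the alternative reading), the requested models are fitted on the training
patients — ROI models additionally see the *training* patients' auxiliary
outcome — and the held-out fold is scored with features only through the
primary head.  The C-index is computed within each fold and aggregated by
mean (and median) across folds, one value per task per model.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cox_core, deep_cox
from .cox_core import OptimizerConfig, fit_cph, fit_cph_roi, predict_risk
from .data_model import PairedSurvivalTask, standardize
from .deep_cox import DeepTrainConfig, ExtractorSpec, fit_deep, predict_risk_deep
from .evaluation import ConcordanceResult, concordance_index, paired_model_comparison
from .exceptions import ConfigurationError, DegenerateTestError, UndefinedMetricError

__all__ = [
    "MODEL_NAMES",
    "ExperimentConfig",
    "CVReport",
    "stratified_folds",
    "run_task",
    "summarize_benchmark",
    "run_synthetic_benchmark",
]

logger = logging.getLogger("roicox")

MODEL_NAMES = ("CPH", "CPH_ROI", "CPH_DL", "CPH_DL_ROI")


@dataclass
class ExperimentConfig:
    models: tuple[str, ...] = MODEL_NAMES
    n_folds: int = 10
    roi_weight: float = 0.2
    l2_weight: float = 1e-4
    extractor: ExtractorSpec = field(default_factory=ExtractorSpec)
    deep_epochs: int = 200
    deep_learning_rate: float = 1e-3
    master_seed: int = 0
    standardization: str = "train-fold"  # or "global"

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("fold count must be at least 2")
        if not 0 <= self.roi_weight <= 1:
            raise ConfigurationError("roi_weight must lie in [0, 1]")
        bad = [m for m in self.models if m not in MODEL_NAMES]
        if bad:
            raise ConfigurationError(f"unknown models {bad}; choose from {MODEL_NAMES}")
        if self.standardization not in ("train-fold", "global"):
            raise ConfigurationError("standardization must be 'train-fold' or 'global'")


@dataclass
class CVReport:
    task_name: str
    fold_assignment: np.ndarray
    fold_results: dict[str, list[ConcordanceResult | None]]
    config: ExperimentConfig
    seeds: dict[str, int]
    skipped_folds: list[int] = field(default_factory=list)

    def c_indices(self, model: str) -> np.ndarray:
        return np.array(
            [r.c_index for r in self.fold_results[model] if r is not None], dtype=float
        )

    def mean_c_index(self, model: str) -> float:
        return float(self.c_indices(model).mean())

    def median_c_index(self, model: str) -> float:
        return float(np.median(self.c_indices(model)))

    def to_tidy_frame(self) -> pd.DataFrame:
        rows = []
        for model, results in self.fold_results.items():
            for fold, r in enumerate(results):
                if r is None:
                    continue
                rows.append(
                    {
                        "task": self.task_name,
                        "model": model,
                        "fold": fold,
                        "c_index": r.c_index,
                        "n_permissible_pairs": r.n_permissible_pairs,
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "task": self.task_name,
                "fold_assignment": self.fold_assignment.tolist(),
                "models": {
                    m: {
                        "fold_c_indices": [
                            None if r is None else r.c_index for r in res
                        ],
                        "mean_c_index": self.mean_c_index(m),
                        "median_c_index": self.median_c_index(m),
                    }
                    for m, res in self.fold_results.items()
                },
                "skipped_folds": self.skipped_folds,
                "seeds": self.seeds,
                "config": {
                    **{
                        k: v
                        for k, v in dataclasses.asdict(self.config).items()
                        if k != "extractor"
                    },
                    "extractor": dataclasses.asdict(self.config.extractor),
                },
            }
        )


def stratified_folds(e: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Assign each patient to one of k folds, balancing events across folds.

    Within each status class the patients are shuffled and dealt
    round-robin, so per-class fold sizes differ by at most one.  A class
    smaller than k triggers a warning and is spread as evenly as possible.
    """
    e = np.asarray(e, dtype=int)
    n = e.shape[0]
    if k > n:
        raise ConfigurationError(f"k={k} exceeds the number of patients {n}")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    for cls in (1, 0):
        idx = np.flatnonzero(e == cls)
        if idx.size == 0:
            raise ConfigurationError(f"status class {cls} is empty; cannot stratify")
        if idx.size < k:
            warnings.warn(
                f"status class {cls} has {idx.size} < {k} patients; "
                "some folds will lack this class",
                stacklevel=2,
            )
        perm = rng.permutation(idx)
        folds[perm] = np.arange(idx.size) % k
    return folds


def _derive_seeds(master_seed: int, n_folds: int) -> dict[str, int]:
    """Deterministic seed hierarchy below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    state = ss.generate_state(2 + n_folds * len(MODEL_NAMES)) % (2**31)
    seeds = {"fold": int(state[0]), "generator": int(state[1])}
    k = 2
    for fold in range(n_folds):
        for model in MODEL_NAMES:
            seeds[f"{model}_fold{fold}"] = int(state[k])
            k += 1
    return seeds


def run_task(paired: PairedSurvivalTask, config: ExperimentConfig | None = None) -> CVReport:
    """Run the full cross-validated protocol on one paired task."""
    config = config or ExperimentConfig()
    seeds = _derive_seeds(config.master_seed, config.n_folds)
    base = paired.base
    folds = stratified_folds(base.e, config.n_folds, seeds["fold"])

    if config.standardization == "global":
        Xg, _, _ = standardize(base.X)

    results: dict[str, list[ConcordanceResult | None]] = {m: [] for m in config.models}
    skipped: list[int] = []
    for fold in range(config.n_folds):
        test_idx = np.flatnonzero(folds == fold)
        train_idx = np.flatnonzero(folds != fold)
        if base.e[test_idx].sum() == 0:
            warnings.warn(f"fold {fold} has no test events; skipped", stacklevel=2)
            skipped.append(fold)
            for m in config.models:
                results[m].append(None)
            continue

        if config.standardization == "train-fold":
            X_tr, X_te, _ = standardize(base.X[train_idx], base.X[test_idx])
        else:
            X_tr, X_te = Xg[train_idx], Xg[test_idx]

        train = paired.subset(train_idx)
        train.base.X = X_tr  # fitted on fold-standardized features
        train_single = train.base
        t_te, e_te = base.t[test_idx], base.e[test_idx]

        for model_name in config.models:
            seed = seeds[f"{model_name}_fold{fold}"]
            if model_name == "CPH":
                m = fit_cph(
                    train_single, l2_weight=config.l2_weight, opt=OptimizerConfig(seed=seed)
                )
                risk = predict_risk(m, X_te)
            elif model_name == "CPH_ROI":
                m = fit_cph_roi(
                    train,
                    roi_weight=config.roi_weight,
                    l2_weight=config.l2_weight,
                    opt=OptimizerConfig(seed=seed),
                )
                risk = predict_risk(m, X_te)
            else:
                cfg = DeepTrainConfig(
                    epochs=config.deep_epochs,
                    learning_rate=config.deep_learning_rate,
                    l2_weight=config.l2_weight,
                    roi_weight=config.roi_weight,
                    seed=seed,
                )
                data = train if model_name == "CPH_DL_ROI" else train_single
                m = fit_deep(data, spec=config.extractor, config=cfg)
                risk = predict_risk_deep(m, X_te)
            try:
                results[model_name].append(concordance_index(risk, t_te, e_te))
            except UndefinedMetricError:
                results[model_name].append(None)
                if fold not in skipped:
                    skipped.append(fold)

    return CVReport(
        task_name=base.name,
        fold_assignment=folds,
        fold_results=results,
        config=config,
        seeds=seeds,
        skipped_folds=skipped,
    )


def summarize_benchmark(
    reports: list[CVReport], baseline: str, comparison: str
) -> dict:
    """Per-task comparison table, win/loss/tie counts and Wilcoxon p-value."""
    if len(reports) < 2:
        raise ConfigurationError("need at least 2 task reports to compare")
    for r in reports:
        if baseline not in r.fold_results or comparison not in r.fold_results:
            raise ConfigurationError(
                f"report for task {r.task_name!r} lacks model {baseline!r} or {comparison!r}"
            )
    c_base = np.array([r.mean_c_index(baseline) for r in reports])
    c_comp = np.array([r.mean_c_index(comparison) for r in reports])
    wins = int(np.sum(c_comp > c_base))
    losses = int(np.sum(c_comp < c_base))
    ties = int(np.sum(c_comp == c_base))
    try:
        pvalue = paired_model_comparison(c_base, c_comp, alternative="greater")
    except DegenerateTestError:
        pvalue = None  # "no difference"
    table = pd.DataFrame(
        {
            "task": [r.task_name for r in reports],
            baseline: c_base,
            comparison: c_comp,
            "improvement": c_comp - c_base,
        }
    )
    return {
        "table": table,
        "wins": wins,
        "losses": losses,
        "ties": ties,
        "mean_improvement": float(np.mean(c_comp - c_base)),
        "p_value": pvalue,
        "baseline": baseline,
        "comparison": comparison,
    }


def run_synthetic_benchmark(
    n_seeds: int = 10,
    models: tuple[str, ...] = MODEL_NAMES,
    swap_outcomes: bool = False,
    master_seed: int = 0,
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Repeat the simulation benchmark over fresh synthetic cohorts.

    Each repetition draws one paired cohort from the default generator
    (seeded from ``master_seed``), optionally swaps the two outcomes, and
    runs the cross-validated protocol; returns a tidy frame with one row
    per (seed, model) holding the per-task mean C-index.
    """
    from .synthetic import GeneratorConfig, generate

    rng = np.random.default_rng(master_seed)
    gen_seeds = rng.integers(0, 2**31 - 1, size=n_seeds)
    rows = []
    for rep, gseed in enumerate(gen_seeds):
        paired, _ = generate(GeneratorConfig(seed=int(gseed)))
        if swap_outcomes:
            paired = paired.swapped()
        cfg = config or ExperimentConfig(models=models)
        cfg = dataclasses.replace(cfg, models=models, master_seed=int(gseed))
        report = run_task(paired, cfg)
        for m in models:
            rows.append(
                {
                    "replicate": rep,
                    "generator_seed": int(gseed),
                    "swapped": swap_outcomes,
                    "model": m,
                    "mean_c_index": report.mean_c_index(m),
                    "median_c_index": report.median_c_index(m),
                }
            )
        logger.info(
            "replicate %d (seed %d, swapped=%s): %s",
            rep,
            gseed,
            swap_outcomes,
            {m: round(report.mean_c_index(m), 4) for m in models},
        )
    return pd.DataFrame(rows)
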