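"""Synthetic paired survival data: exponential Cox with correlated coefficients.

The generator emulates a high-dimensional prognosis cohort: M = 300
patients, p = 150 features drawn uniformly on [-1, 1], and two related
outcomes.  Latent event times follow a proportional-hazards model with a
constant baseline rate,

    T_i = E_i / exp(beta . x_i),     E_i ~ Exponential(mean 3000 days),

drawn independently per outcome.  The auxiliary coefficients are a noisy
copy of the primary ones, beta'_j = beta_j + xi_j with xi_j ~ U(0, 1),
redrawn until the Pearson correlation corr(beta, beta') reaches the
configured floor (0.8).  End-of-study (administrative) censoring is
applied per outcome at the k-th smallest latent time so that exactly
``n_events_target`` patients (200 by default) have observed events and
the remainder are censored at the cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cox_core import LinearCoxModel
from .data_model import PairedSurvivalTask, SurvivalTask, write_survival_csv
from .exceptions import GeneratorError, ShapeError

__all__ = ["GeneratorConfig", "SyntheticTruth", "generate", "recovery_score"]


@dataclass
class GeneratorConfig:
    n_patients: int = 300
    n_features: int = 150
    n_events_target: int = 200
    baseline_mean: float = 3000.0  # mean of the exponential baseline, in days
    correlation_floor: float = 0.8
    noise_range: tuple[float, float] = (0.0, 1.0)  # support of xi
    feature_range: tuple[float, float] = (-1.0, 1.0)
    beta_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0
    max_redraws: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.n_events_target < self.n_patients:
            raise ValueError("n_events_target must lie strictly between 0 and n_patients")
        if not 0 < self.correlation_floor < 1:
            raise ValueError("correlation_floor must lie in (0, 1)")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")


@dataclass
class SyntheticTruth:
    beta_true: np.ndarray
    beta_aux_true: np.ndarray
    correlation: float
    cutoff_primary: float
    cutoff_aux: float
    seed: int = 0

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "beta_true": self.beta_true.tolist(),
                    "beta_aux_true": self.beta_aux_true.tolist(),
                    "correlation": self.correlation,
                    "cutoff_primary": self.cutoff_primary,
                    "cutoff_aux": self.cutoff_aux,
                    "seed": self.seed,
                }
            )
        )


def _administrative_censor(
    latent: np.ndarray, n_events: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Censor at the n_events-th smallest latent time (end of study)."""
    cutoff = float(np.sort(latent)[n_events - 1])
    observed = latent <= cutoff
    times = np.where(observed, latent, cutoff)
    return times, observed.astype(int), cutoff


def generate(config: GeneratorConfig | None = None) -> tuple[PairedSurvivalTask, SyntheticTruth]:
    """Draw one paired cohort plus the ground-truth coefficients.

    Deterministic given ``config.seed``.  Raises :class:`GeneratorError`
    if the coefficient-correlation floor cannot be met within
    ``max_redraws`` noise redraws (it essentially never triggers at the
    default dimensionality).
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    M, p = cfg.n_patients, cfg.n_features
    X = rng.uniform(*cfg.feature_range, size=(M, p))
    beta = rng.uniform(*cfg.beta_range, size=p)

    lo, hi = cfg.noise_range
    for attempt in range(cfg.max_redraws):
        xi = rng.uniform(lo, hi, size=p)
        beta_aux = beta + xi
        if lo == hi == 0.0:
            corr = 1.0  # degenerate noise: beta' = beta exactly
        elif np.std(beta) == 0 or np.std(beta_aux) == 0:
            corr = float("nan")  # constant coefficients: correlation undefined
            break
        else:
            corr = float(np.corrcoef(beta, beta_aux)[0, 1])
        if corr >= cfg.correlation_floor:
            break
    else:
        raise GeneratorError(
            f"corr(beta, beta') < {cfg.correlation_floor} after {cfg.max_redraws} redraws"
        )

    def outcome(b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        baseline_draws = rng.exponential(cfg.baseline_mean, size=M)
        latent = baseline_draws / np.exp(X @ b)
        return _administrative_censor(latent, cfg.n_events_target)

    t1, e1, cut1 = outcome(beta)
    t2, e2, cut2 = outcome(beta_aux)

    base = SurvivalTask(
        sample_ids=[f"S{i:04d}" for i in range(M)],
        X=X,
        t=t1,
        e=e1,
        name=f"synthetic_seed{cfg.seed}",
    )
    paired = PairedSurvivalTask(base=base, t_aux=t2, e_aux=e2)
    truth = SyntheticTruth(
        beta_true=beta,
        beta_aux_true=beta_aux,
        correlation=corr,
        cutoff_primary=cut1,
        cutoff_aux=cut2,
        seed=cfg.seed,
    )
    return paired, truth


def write_dataset(
    paired: PairedSurvivalTask, truth: SyntheticTruth, csv_path: str | Path, truth_path: str | Path
) -> None:
    """Emit the standard paired survival CSV plus the truth JSON."""
    write_survival_csv(paired, csv_path)
    truth.write_json(truth_path)


def recovery_score(truth: SyntheticTruth, model: LinearCoxModel) -> float:
    """Cosine similarity between the true and fitted primary coefficients.

    Scale-free on purpose: penalised Cox coefficients are shrunk, so only
    the direction is comparable across fitters.
    """
    a = np.asarray(truth.beta_true, dtype=float)
    b = np.asarray(model.beta, dtype=float)
    if a.shape != b.shape:
        raise ShapeError("coefficient vectors have mismatched lengths")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    return float(a @ b / (na * nb))
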