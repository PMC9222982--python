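"""Cox partial-likelihood machinery and the two linear fitters.

The baseline model (CPH) minimises the L2-penalised negative log partial
likelihood

    loss(beta, b) = -sum_{i: e_i=1} [ h_i - log sum_{j: t_j >= t_i} exp(h_j) ]
                    + lambda1 * (||beta||^2 + b^2),        h_i = x_i . beta + b

with risk sets R(T_i) = {j : t_j >= t_i} and the Breslow convention for
tied event times (tied events share the full risk-set denominator).  The
bias b cancels between numerator and denominator, so with any positive
penalty the optimum drives b to zero; it is carried anyway because the
joint (ROI) model shares it across outcomes.

The related-outcome-incorporator fit (CPH_ROI) minimises the convex
combination

    (1 - lambda) * loss(beta1, b | primary) + lambda * loss(beta2, b | auxiliary)

over (beta1, beta2, b) with a single shared bias; prediction for new
patients uses beta1 (and b) only, so the auxiliary outcome is never needed
at test time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .data_model import PairedSurvivalTask, SurvivalTask
from .exceptions import ShapeError, UndefinedLikelihoodError, ValidationError

__all__ = [
    "OptimizerConfig",
    "FitDiagnostics",
    "LinearCoxModel",
    "linear_hazard",
    "neg_log_partial_likelihood",
    "cph_loss",
    "roi_loss",
    "fit_cph",
    "fit_cph_roi",
    "predict_risk",
]

DEFAULT_L2_WEIGHT = 1e-4  # coefficient penalty used by the baseline fit
DEFAULT_ROI_WEIGHT = 0.2  # weight of the auxiliary outcome in the joint loss


@dataclass
class OptimizerConfig:
    max_iterations: int = 2000
    gradient_tolerance: float = 1e-6
    init_scale: float = 0.01  # coefficients start uniform on [-init_scale, init_scale]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gradient_tolerance <= 0:
            raise ValueError("gradient_tolerance must be positive")


@dataclass
class FitDiagnostics:
    loss: float
    gradient_norm: float
    n_iterations: int
    converged: bool


@dataclass
class LinearCoxModel:
    """Fitted linear Cox model; ``beta_aux`` present only for ROI fits."""

    beta: np.ndarray
    bias: float
    beta_aux: np.ndarray | None = None
    l2_weight: float = DEFAULT_L2_WEIGHT
    roi_weight: float = 0.0
    fit_diagnostics: FitDiagnostics | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)) or not np.isfinite(self.bias):
            raise ValidationError("model parameters must be finite")
        if self.beta_aux is not None:
            self.beta_aux = np.asarray(self.beta_aux, dtype=float)
            if self.beta_aux.shape != self.beta.shape:
                raise ShapeError("beta_aux must have the same length as beta")

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta": self.beta.tolist(),
                "beta_aux": None if self.beta_aux is None else self.beta_aux.tolist(),
                "bias": self.bias,
                "l2_weight": self.l2_weight,
                "roi_weight": self.roi_weight,
                "diagnostics": None
                if self.fit_diagnostics is None
                else dataclasses.asdict(self.fit_diagnostics),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearCoxModel":
        d = json.loads(text)
        diag = d.get("diagnostics")
        return cls(
            beta=np.array(d["beta"], dtype=float),
            bias=float(d["bias"]),
            beta_aux=None if d.get("beta_aux") is None else np.array(d["beta_aux"]),
            l2_weight=float(d.get("l2_weight", DEFAULT_L2_WEIGHT)),
            roi_weight=float(d.get("roi_weight", 0.0)),
            fit_diagnostics=None if diag is None else FitDiagnostics(**diag),
        )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def linear_hazard(X: np.ndarray, beta: np.ndarray, bias: float) -> np.ndarray:
    """Log relative hazard h_i = x_i . beta + bias for every row of X."""
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.ndim != 2 or X.shape[1] != beta.shape[0]:
        raise ShapeError(
            f"X has {X.shape[1] if X.ndim == 2 else '?'} columns, beta has length {beta.shape[0]}"
        )
    return X @ beta + bias


def _npll_value_grad(
    h: np.ndarray, t: np.ndarray, e: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative log partial likelihood and its gradient with respect to h.

    Vectorised over a single descending-time sort; tied times share one
    risk-set denominator (Breslow).  The value is computed through a
    cumulative log-sum-exp after a global shift, so large hazards do not
    overflow.
    """
    h = np.asarray(h, dtype=float)
    t = np.asarray(t, dtype=float)
    e = np.asarray(e, dtype=float)
    n = h.shape[0]
    if t.shape[0] != n or e.shape[0] != n:
        raise ShapeError("h, t, e must have equal lengths")
    if e.sum() == 0:
        raise UndefinedLikelihoodError("partial likelihood undefined with zero events")

    order = np.argsort(-t, kind="stable")
    hs = h[order] - h.max()  # shift-invariant; keeps exponentials bounded
    ts = t[order]
    es = e[order]

    # index of the last member of each tied-time group (descending order)
    group_last = np.flatnonzero(np.r_[ts[1:] != ts[:-1], True])
    gend = group_last[np.searchsorted(group_last, np.arange(n))]

    log_cum = np.logaddexp.accumulate(hs)
    log_denom = log_cum[gend]
    value = -float(np.sum(es * (hs - log_denom)))

    # d/dh_k = -e_k + exp(h_k) * sum_{events i with k in R(T_i)} 1/S_i;
    # k in R(T_i) iff k <= gend(i) in sorted order, so a suffix cumsum of
    # the per-event 1/S_i scattered to gend(i) gives the inner sum.
    inv_denom = np.zeros(n)
    np.add.at(inv_denom, gend, es * np.exp(-log_denom))
    suffix = np.cumsum(inv_denom[::-1])[::-1]
    grad_sorted = -es + np.exp(hs) * suffix
    grad = np.empty(n)
    grad[order] = grad_sorted
    return value, grad


def neg_log_partial_likelihood(h: np.ndarray, t: np.ndarray, e: np.ndarray) -> float:
    """Breslow negative log partial likelihood of log-hazards ``h``."""
    return _npll_value_grad(h, t, e)[0]


def cph_loss(
    beta: np.ndarray, bias: float, task: SurvivalTask, l2_weight: float = DEFAULT_L2_WEIGHT
) -> float:
    """Regularised objective: partial likelihood + lambda1 * (||beta||^2 + b^2)."""
    h = linear_hazard(task.X, beta, bias)
    penalty = l2_weight * (float(np.sum(np.square(beta))) + bias**2)
    return neg_log_partial_likelihood(h, task.t, task.e) + penalty


def roi_loss(
    beta1: np.ndarray,
    beta2: np.ndarray,
    bias: float,
    paired: PairedSurvivalTask,
    roi_weight: float = DEFAULT_ROI_WEIGHT,
    l2_weight: float = DEFAULT_L2_WEIGHT,
) -> float:
    """Joint objective (1-lambda)*loss(beta1,b|primary) + lambda*loss(beta2,b|aux)."""
    if not 0 <= roi_weight <= 1:
        raise ValueError("roi_weight must lie in [0, 1]")
    try:
        primary = cph_loss(beta1, bias, paired.base, l2_weight)
    except UndefinedLikelihoodError as err:
        raise UndefinedLikelihoodError(f"primary outcome: {err}") from None
    try:
        aux = cph_loss(beta2, bias, paired.aux_task(), l2_weight)
    except UndefinedLikelihoodError as err:
        raise UndefinedLikelihoodError(f"auxiliary outcome: {err}") from None
    return (1.0 - roi_weight) * primary + roi_weight * aux


# ---------------------------------------------------------------------------
# Fitters
# ---------------------------------------------------------------------------

def _check_features(X: np.ndarray) -> None:
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature matrix contains non-finite values; preprocess first")


def _run_lbfgs(fun, x0, opt: OptimizerConfig):
    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": opt.max_iterations,
            "gtol": opt.gradient_tolerance,
            "ftol": 1e-14,
        },
    )
    loss, grad = fun(res.x)
    diag = FitDiagnostics(
        loss=float(loss),
        gradient_norm=float(np.max(np.abs(grad))),
        n_iterations=int(res.nit),
        converged=bool(res.success),
    )
    return res.x, diag


def fit_cph(
    task: SurvivalTask,
    l2_weight: float = DEFAULT_L2_WEIGHT,
    opt: OptimizerConfig | None = None,
) -> LinearCoxModel:
    """Fit the L2-penalised linear Cox model by quasi-Newton minimisation.

    Deterministic given the optimizer seed (which only controls the small
    random initialisation of the coefficients).
    """
    opt = opt or OptimizerConfig()
    _check_features(task.X)
    X, t, e = task.X, task.t, task.e
    p = X.shape[1]
    rng = np.random.default_rng(opt.seed)
    x0 = np.r_[rng.uniform(-opt.init_scale, opt.init_scale, size=p), 0.0]

    def fun(theta):
        beta, b = theta[:p], theta[p]
        value, gh = _npll_value_grad(X @ beta + b, t, e)
        value += l2_weight * (np.sum(beta**2) + b**2)
        grad = np.r_[X.T @ gh + 2 * l2_weight * beta, gh.sum() + 2 * l2_weight * b]
        return value, grad

    theta, diag = _run_lbfgs(fun, x0, opt)
    return LinearCoxModel(
        beta=theta[:p],
        bias=float(theta[p]),
        l2_weight=l2_weight,
        roi_weight=0.0,
        fit_diagnostics=diag,
    )


def fit_cph_roi(
    paired: PairedSurvivalTask,
    roi_weight: float = DEFAULT_ROI_WEIGHT,
    l2_weight: float = DEFAULT_L2_WEIGHT,
    opt: OptimizerConfig | None = None,
) -> LinearCoxModel:
    """Jointly fit (beta1, beta2, b) on the primary + auxiliary outcomes.

    The shared bias is the only coupling between the two coefficient
    vectors; the auxiliary term nevertheless regularises beta1 indirectly
    through the optimizer when features are shared, and prediction uses
    beta1 (and b) only.
    """
    if not 0 <= roi_weight <= 1:
        raise ValueError("roi_weight must lie in [0, 1]")
    opt = opt or OptimizerConfig()
    _check_features(paired.X)
    X = paired.X
    t1, e1 = paired.base.t, paired.base.e
    t2, e2 = paired.t_aux, paired.e_aux
    if e1.sum() == 0:
        raise UndefinedLikelihoodError("primary outcome has zero events")
    if e2.sum() == 0:
        raise UndefinedLikelihoodError("auxiliary outcome has zero events")
    p = X.shape[1]
    rng = np.random.default_rng(opt.seed)
    x0 = np.r_[rng.uniform(-opt.init_scale, opt.init_scale, size=2 * p), 0.0]
    w1, w2 = 1.0 - roi_weight, roi_weight

    def fun(theta):
        b1, b2, b = theta[:p], theta[p : 2 * p], theta[2 * p]
        v1, g1 = _npll_value_grad(X @ b1 + b, t1, e1)
        v2, g2 = _npll_value_grad(X @ b2 + b, t2, e2)
        value = (
            w1 * (v1 + l2_weight * (np.sum(b1**2) + b**2))
            + w2 * (v2 + l2_weight * (np.sum(b2**2) + b**2))
        )
        grad = np.r_[
            w1 * (X.T @ g1 + 2 * l2_weight * b1),
            w2 * (X.T @ g2 + 2 * l2_weight * b2),
            w1 * (g1.sum() + 2 * l2_weight * b) + w2 * (g2.sum() + 2 * l2_weight * b),
        ]
        return value, grad

    theta, diag = _run_lbfgs(fun, x0, opt)
    return LinearCoxModel(
        beta=theta[:p],
        bias=float(theta[2 * p]),
        beta_aux=theta[p : 2 * p],
        l2_weight=l2_weight,
        roi_weight=roi_weight,
        fit_diagnostics=diag,
    )


def predict_risk(model: LinearCoxModel, X: np.ndarray) -> np.ndarray:
    """Risk scores from the PRIMARY coefficients only; higher = earlier event."""
    return linear_hazard(X, model.beta, model.bias)
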