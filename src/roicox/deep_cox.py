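"""Deep Cox models: an MLP feature extractor with one or two Cox heads.

CPH_DL composes a small fully connected network F (default 100 -> dropout
0.5 -> 50 -> dropout 0.5, rectified-linear activations) with a Cox
regression layer C, and minimises

    l(F, C) = npll(h)  +  lambda1 * (||W||^2 + ||beta||^2 + b^2),
    h_i = F(x_i) . beta + b

where npll is the Breslow negative log partial likelihood from
:mod:`roicox.cox_core` and W collects every extractor weight and bias.

CPH_DL_ROI adds a second Cox head C2 on the SAME embedding, sharing the
scalar bias b, and minimises the convex combination

    (1 - lambda) * l(F, C1 | primary) + lambda * l(F, C2 | auxiliary)

with lambda = 0.2 by default.  Prediction always runs the extractor in
eval mode (dropout off) through the primary head only.

The network is implemented directly on numpy arrays with hand-written
backpropagation and a full-batch Adam optimizer: cohorts are a few hundred
patients, the partial likelihood is only exact over the full risk set, and
the architecture is fixed, so a tensor framework would add nothing here.
Training is bitwise-reproducible on CPU for a fixed seed; the dropout
masks are drawn from a dedicated stream so that a lambda = 0 joint fit
follows the exact same trajectory as a plain deep fit with the same seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cox_core import _npll_value_grad, neg_log_partial_likelihood
from .data_model import PairedSurvivalTask, SurvivalTask
from .exceptions import (
    ConfigurationError,
    ShapeError,
    TrainingError,
    UndefinedLikelihoodError,
    ValidationError,
)

__all__ = [
    "ExtractorSpec",
    "DeepTrainConfig",
    "DeepCoxModel",
    "extract_features",
    "deep_cox_loss",
    "deep_roi_loss",
    "fit_deep",
    "predict_risk_deep",
    "save_checkpoint",
    "load_checkpoint",
]

_ACTIVATIONS = ("relu", "identity")


@dataclass
class ExtractorSpec:
    """Architecture of the feature extractor F.

    ``hidden_widths=()`` gives the identity extractor, under which every
    deep operation reduces to its linear counterpart.
    """

    hidden_widths: tuple[int, ...] = (100, 50)
    dropout: float = 0.5
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if any(w <= 0 for w in self.hidden_widths):
            raise ConfigurationError("layer widths must be positive")
        if not 0 <= self.dropout < 1:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ConfigurationError(f"activation must be one of {_ACTIVATIONS}")

    def embedding_width(self, n_inputs: int) -> int:
        return self.hidden_widths[-1] if self.hidden_widths else n_inputs


@dataclass
class DeepTrainConfig:
    epochs: int = 200
    learning_rate: float = 1e-3
    l2_weight: float = 1e-4
    roi_weight: float = 0.2
    seed: int = 0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


@dataclass
class DeepCoxModel:
    spec: ExtractorSpec
    weights: list[np.ndarray]  # per hidden layer: W (in x out)
    biases: list[np.ndarray]  # per hidden layer: b (out,)
    head: np.ndarray  # beta over the embedding
    bias: float  # shared scalar Cox bias
    head_aux: np.ndarray | None = None
    config: DeepTrainConfig = field(default_factory=DeepTrainConfig)
    loss_history: list[float] = field(default_factory=list)

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0] if self.weights else self.head.shape[0]


def _act(A: np.ndarray, name: str) -> np.ndarray:
    return np.maximum(A, 0.0) if name == "relu" else A


def _act_grad(A: np.ndarray, name: str) -> np.ndarray:
    return (A > 0).astype(float) if name == "relu" else np.ones_like(A)


def _forward(
    model: DeepCoxModel,
    X: np.ndarray,
    training_mode: bool,
    mask_rng: np.random.Generator | None = None,
):
    """Forward pass; returns the embedding and per-layer caches for backprop."""
    spec = model.spec
    Z = np.asarray(X, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != model.n_inputs:
        raise ShapeError(f"X must have {model.n_inputs} columns")
    caches = []
    keep = 1.0 - spec.dropout
    for W, b in zip(model.weights, model.biases):
        A = Z @ W + b
        H = _act(A, spec.activation)
        if training_mode and spec.dropout > 0:
            # inverted dropout: scale kept units so eval needs no rescaling
            mask = (mask_rng.random(H.shape) < keep).astype(float) / keep
        else:
            mask = None
        out = H if mask is None else H * mask
        caches.append((Z, A, mask))
        Z = out
    return Z, caches


def extract_features(
    model: DeepCoxModel,
    X: np.ndarray,
    training_mode: bool = False,
    mask_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Embed X through the extractor; dropout active only in training mode."""
    if training_mode and model.spec.dropout > 0 and mask_rng is None:
        mask_rng = np.random.default_rng(model.config.seed)
    Z, _ = _forward(model, X, training_mode, mask_rng)
    return Z


def _penalty(model: DeepCoxModel, head: np.ndarray, l2: float) -> float:
    total = sum(float(np.sum(W**2)) for W in model.weights)
    total += sum(float(np.sum(b**2)) for b in model.biases)
    total += float(np.sum(head**2)) + model.bias**2
    return l2 * total


def deep_cox_loss(model: DeepCoxModel, task: SurvivalTask) -> float:
    """Eval-mode regularised objective on a single outcome."""
    Z = extract_features(model, task.X, training_mode=False)
    h = Z @ model.head + model.bias
    return (
        neg_log_partial_likelihood(h, task.t, task.e)
        + _penalty(model, model.head, model.config.l2_weight)
    )


def deep_roi_loss(model: DeepCoxModel, paired: PairedSurvivalTask) -> float:
    """Eval-mode joint objective over primary and auxiliary outcomes."""
    if model.head_aux is None:
        raise ConfigurationError("model has no auxiliary head; fit with a paired task")
    lam = model.config.roi_weight
    if not 0 <= lam <= 1:
        raise ValueError("roi_weight must lie in [0, 1]")
    Z = extract_features(model, paired.X, training_mode=False)
    h1 = Z @ model.head + model.bias
    h2 = Z @ model.head_aux + model.bias
    l2 = model.config.l2_weight
    primary = (
        neg_log_partial_likelihood(h1, paired.base.t, paired.base.e)
        + _penalty(model, model.head, l2)
    )
    aux = (
        neg_log_partial_likelihood(h2, paired.t_aux, paired.e_aux)
        + _penalty(model, model.head_aux, l2)
    )
    return (1.0 - lam) * primary + lam * aux


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], cfg: DeepTrainConfig):
        self.cfg = cfg
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= c.adam_beta1
            m += (1 - c.adam_beta1) * g
            v *= c.adam_beta2
            v += (1 - c.adam_beta2) * g * g
            mhat = m / (1 - c.adam_beta1**self.t)
            vhat = v / (1 - c.adam_beta2**self.t)
            p -= c.learning_rate * mhat / (np.sqrt(vhat) + c.adam_eps)


def _init_model(
    spec: ExtractorSpec, n_inputs: int, cfg: DeepTrainConfig, with_aux: bool
) -> DeepCoxModel:
    """Fan-in-scaled uniform initialisation from seed-derived streams.

    Extractor and primary head come from stream (seed, 0); the auxiliary
    head from (seed, 2); dropout masks later use (seed, 1).  Keeping the
    streams separate means adding the auxiliary head does not shift the
    randomness seen by the shared parameters.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    weights, biases = [], []
    fan_in = n_inputs
    for width in spec.hidden_widths:
        bound = 1.0 / np.sqrt(fan_in)
        weights.append(rng.uniform(-bound, bound, size=(fan_in, width)))
        biases.append(rng.uniform(-bound, bound, size=width))
        fan_in = width
    bound = 1.0 / np.sqrt(fan_in)
    head = rng.uniform(-bound, bound, size=fan_in)
    head_aux = None
    if with_aux:
        rng_aux = np.random.default_rng([cfg.seed, 2])
        head_aux = rng_aux.uniform(-bound, bound, size=fan_in)
    return DeepCoxModel(
        spec=spec,
        weights=weights,
        biases=biases,
        head=head,
        bias=0.0,
        head_aux=head_aux,
        config=cfg,
    )


def fit_deep(
    data: SurvivalTask | PairedSurvivalTask,
    spec: ExtractorSpec | None = None,
    config: DeepTrainConfig | None = None,
) -> DeepCoxModel:
    """Train CPH_DL (on a plain task) or CPH_DL_ROI (on a paired task).

    Full-batch gradient descent with Adam: risk sets are exact only over
    the whole cohort, and the cohorts here are small enough that a full
    pass per update is cheap.  Raises :class:`TrainingError` naming the
    epoch if the loss becomes non-finite.
    """
    spec = spec or ExtractorSpec()
    cfg = config or DeepTrainConfig()
    paired = isinstance(data, PairedSurvivalTask)
    base = data.base if paired else data
    X = base.X
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature matrix contains non-finite values")
    if base.e.sum() == 0:
        raise UndefinedLikelihoodError("primary outcome has zero events")
    if paired and data.e_aux.sum() == 0:
        raise UndefinedLikelihoodError("auxiliary outcome has zero events")

    model = _init_model(spec, X.shape[1], cfg, with_aux=paired)
    mask_rng = np.random.default_rng([cfg.seed, 1])
    lam = cfg.roi_weight if paired else 0.0
    l2 = cfg.l2_weight

    params = [*model.weights, *model.biases, model.head]
    bias_box = np.array([model.bias])
    params.append(bias_box)
    if paired:
        params.append(model.head_aux)
    adam = _Adam(params, cfg)

    history: list[float] = []
    for epoch in range(cfg.epochs):
        Z, caches = _forward(model, X, training_mode=True, mask_rng=mask_rng)
        b = bias_box[0]
        h1 = Z @ model.head + b
        v1, g1 = _npll_value_grad(h1, base.t, base.e)
        loss = (1.0 - lam) * (v1 + _p_sum(model, model.head, b, l2))
        g1 = (1.0 - lam) * g1
        if paired:
            h2 = Z @ model.head_aux + b
            v2, g2 = _npll_value_grad(h2, data.t_aux, data.e_aux)
            loss += lam * (v2 + _p_sum(model, model.head_aux, b, l2))
            g2 = lam * g2
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite training loss at epoch {epoch}")
        history.append(float(loss))

        # backprop: head(s) -> embedding -> hidden layers
        dZ = np.outer(g1, model.head)
        d_head = Z.T @ g1 + 2 * l2 * (1.0 - lam) * model.head
        d_bias = g1.sum() + 2 * l2 * (1.0 - lam) * b
        grads: list[np.ndarray]
        if paired:
            dZ += np.outer(g2, model.head_aux)
            d_head_aux = Z.T @ g2 + 2 * l2 * lam * model.head_aux
            d_bias += g2.sum() + 2 * l2 * lam * b
        dW, db = _backprop_layers(model, caches, dZ, l2)
        grads = [*dW, *db, d_head, np.array([d_bias])]
        if paired:
            grads.append(d_head_aux)
        adam.step(params, grads)
        model.bias = float(bias_box[0])

    model.loss_history = history
    model.bias = float(bias_box[0])
    return model


def _p_sum(model: DeepCoxModel, head: np.ndarray, bias: float, l2: float) -> float:
    total = sum(float(np.sum(W**2)) for W in model.weights)
    total += sum(float(np.sum(bv**2)) for bv in model.biases)
    return l2 * (total + float(np.sum(head**2)) + bias**2)


def _backprop_layers(model: DeepCoxModel, caches, dZ: np.ndarray, l2: float):
    """Push dZ back through dropout, activation and each affine layer."""
    dW = [None] * len(model.weights)
    db = [None] * len(model.biases)
    grad_out = dZ
    for li in range(len(model.weights) - 1, -1, -1):
        Z_in, A, mask = caches[li]
        dH = grad_out if mask is None else grad_out * mask
        dA = dH * _act_grad(A, model.spec.activation)
        # the extractor penalty appears in both joint terms with total weight 1
        dW[li] = Z_in.T @ dA + 2 * l2 * model.weights[li]
        db[li] = dA.sum(axis=0) + 2 * l2 * model.biases[li]
        grad_out = dA @ model.weights[li].T
    return dW, db


def predict_risk_deep(model: DeepCoxModel, X: np.ndarray) -> np.ndarray:
    """Eval-mode risk scores from the primary head; auxiliary data never used."""
    Z = extract_features(model, X, training_mode=False)
    return Z @ model.head + model.bias


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: DeepCoxModel, path: str | Path) -> None:
    """Single-archive checkpoint (npz) holding spec, parameters and config."""
    arrays = {
        "head": model.head,
        "bias": np.array([model.bias]),
        "loss_history": np.array(model.loss_history),
    }
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    if model.head_aux is not None:
        arrays["head_aux"] = model.head_aux
    import json

    arrays["meta"] = np.frombuffer(
        json.dumps(
            {
                "spec": dataclasses.asdict(model.spec),
                "config": dataclasses.asdict(model.config),
                "n_layers": len(model.weights),
            }
        ).encode(),
        dtype=np.uint8,
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> DeepCoxModel:
    import json

    with np.load(path) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        spec = ExtractorSpec(
            hidden_widths=tuple(meta["spec"]["hidden_widths"]),
            dropout=meta["spec"]["dropout"],
            activation=meta["spec"]["activation"],
        )
        cfg = DeepTrainConfig(**meta["config"])
        n = meta["n_layers"]
        model = DeepCoxModel(
            spec=spec,
            weights=[z[f"W{i}"] for i in range(n)],
            biases=[z[f"b{i}"] for i in range(n)],
            head=z["head"],
            bias=float(z["bias"][0]),
            head_aux=z["head_aux"] if "head_aux" in z.files else None,
            config=cfg,
            loss_history=list(z["loss_history"]),
        )
    return model
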