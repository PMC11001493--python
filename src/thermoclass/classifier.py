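"""Per-threshold binary classifier and its training loop.

The model is a small multilayer perceptron — two fully connected hidden
layers of 256 and 128 units with rectifier activations and a logistic
output — trained with mini-batches of 24 drawn by a class-weighted random
sampler (with replacement, weight 1/class-count, so expected batch
composition is balanced even on heavily imbalanced data), the Adam
optimizer at learning rate 1e-4 with weight decay 1e-4, and binary
cross-entropy loss.  After every epoch the model is scored on the full
validation set and the weights snapshot with the highest validation MCC is
returned (ties go to the earliest epoch).

Everything is plain numpy with an explicitly seeded generator, so training
is bit-reproducible single-threaded.

Five such classifiers trained under different seeds form a threshold
ensemble whose prediction is the arithmetic mean of member probabilities.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import LabeledExample
from .io_formats import CheckpointBundle
from .metrics import confusion, mcc

__all__ = [
    "ClassifierSpec",
    "TrainConfig",
    "MLPClassifier",
    "TrainedClassifier",
    "ThresholdEnsemble",
    "sampler_weights",
    "train_classifier",
    "train_ensemble",
    "ensemble_predict",
]


@dataclass(frozen=True)
class ClassifierSpec:
    input_dim: int = 1024
    hidden: tuple[int, int] = (256, 128)

    def __post_init__(self) -> None:
        if self.input_dim < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("all layer sizes must be positive")
        if len(self.hidden) != 2:
            raise ValueError("reference architecture has exactly two hidden layers")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.input_dim, *self.hidden, 1]

    @property
    def activations(self) -> list[str]:
        return ["relu"] * len(self.hidden) + ["sigmoid"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 24
    max_epochs: int = 30
    seed: int = 0
    weighted_sampling: bool = True  # class-balanced batches; False = uniform

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.weight_decay) < 0:
            raise ValueError("learning rate / weight decay must be non-negative")
        if self.learning_rate == 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch size and max_epochs must be positive")
        if self.seed is None:
            raise ValueError("a seed is required; unseeded training is not supported")


class MLPClassifier:
    """Feed-forward network input -> 256 -> 128 -> 1 (configurable widths).

    Weights are initialised with the seeded uniform fan-in scheme
    U(-1/sqrt(fan_in), +1/sqrt(fan_in)) for both weights and biases.
    """

    def __init__(self, spec: ClassifierSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.Generator(np.random.PCG64(seed))
        sizes = spec.layer_sizes
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes, sizes[1:]):
            bound = 1.0 / math.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(rng.uniform(-bound, bound, size=fan_out))

    # -- inference ---------------------------------------------------------

    def logits(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.spec.input_dim:
            raise ValueError(
                f"input dimension {X.shape[1]} != model input_dim {self.spec.input_dim}"
            )
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        return (h @ self.weights[-1] + self.biases[-1]).ravel()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.logits(X)
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out

    def forward(self, x: np.ndarray) -> float:
        """Probability for a single embedding vector."""
        return float(self.predict_proba(np.asarray(x, dtype=np.float64)[None, :])[0])

    # -- training internals --------------------------------------------------

    def _backward(self, X: np.ndarray, y: np.ndarray) -> tuple[float, list, list]:
        """Mean BCE loss over the batch and gradients w.r.t. all parameters."""
        acts = [X]
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
            acts.append(h)
        z = (h @ self.weights[-1] + self.biases[-1]).ravel()
        # numerically stable BCE from logits: softplus(z) - y*z
        loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
        p = np.empty_like(z)
        pos = z >= 0
        p[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        p[~pos] = ez / (1.0 + ez)
        n = len(y)
        delta = ((p - y) / n)[:, None]
        grads_W: list[np.ndarray] = [None] * len(self.weights)
        grads_b: list[np.ndarray] = [None] * len(self.biases)
        grads_W[-1] = acts[-1].T @ delta
        grads_b[-1] = delta.sum(axis=0)
        back = delta @ self.weights[-1].T
        for layer in range(len(self.weights) - 2, -1, -1):
            back = back * (acts[layer + 1] > 0)
            grads_W[layer] = acts[layer].T @ back
            grads_b[layer] = back.sum(axis=0)
            if layer > 0:
                back = back @ self.weights[layer].T
        return loss, grads_W, grads_b

    def parameters(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            out[f"W{i}"] = W
            out[f"b{i}"] = b
        return out

    def to_checkpoint(
        self, threshold: float, seed: int, selected_epoch: int, validation_mcc: float
    ) -> CheckpointBundle:
        return CheckpointBundle(
            arrays={k: v.copy() for k, v in self.parameters().items()},
            layer_sizes=self.spec.layer_sizes,
            activations=self.spec.activations,
            threshold=threshold,
            seed=seed,
            selected_epoch=selected_epoch,
            validation_mcc=validation_mcc,
        )

    @classmethod
    def from_checkpoint(cls, bundle: CheckpointBundle) -> "MLPClassifier":
        sizes = bundle.layer_sizes
        spec = ClassifierSpec(input_dim=sizes[0], hidden=tuple(sizes[1:-1]))
        model = cls.__new__(cls)
        model.spec = spec
        model.weights = [
            np.asarray(bundle.arrays[f"W{i}"], dtype=np.float64)
            for i in range(len(sizes) - 1)
        ]
        model.biases = [
            np.asarray(bundle.arrays[f"b{i}"], dtype=np.float64)
            for i in range(len(sizes) - 1)
        ]
        return model


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, weight_decay: float):
        self.lr = lr
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            g = g + self.wd * p  # decoupled-from-loss L2, Adam-style
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def sampler_weights(labels: Sequence[int]) -> np.ndarray:
    """Per-example sampling weight 1/(count of its class).

    Drawing with replacement under these weights yields expected 1:1 class
    balance regardless of the raw imbalance.
    """
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("weighted sampling requires both classes present")
    w = np.where(y == 1, 1.0 / n_pos, 1.0 / n_neg)
    return w


@dataclass
class TrainedClassifier:
    model: MLPClassifier
    threshold: float
    seed: int
    selected_epoch: int
    validation_mcc: float
    log: list[dict] = field(default_factory=list)  # epoch, loss, val_mcc


def _xy(examples: Sequence[LabeledExample], threshold: float) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([ex.embedding for ex in examples])
    y = np.array([ex.labels[threshold] for ex in examples], dtype=np.float64)
    return X, y


def train_classifier(
    train: Sequence[LabeledExample],
    val: Sequence[LabeledExample],
    threshold: float,
    spec: ClassifierSpec | None = None,
    cfg: TrainConfig | None = None,
) -> TrainedClassifier:
    """Train one threshold classifier with max-validation-MCC selection.

    One epoch is ceil(N/batch_size) batches drawn with replacement under
    the class-balancing sampler weights (uniform when
    ``cfg.weighted_sampling`` is off).  Validation MCC is computed on the
    whole, unweighted validation set after every epoch; the returned model
    is the snapshot from the best epoch (earliest on ties).
    """
    cfg = cfg or TrainConfig()
    X_train, y_train = _xy(train, threshold)
    X_val, y_val = _xy(val, threshold)
    if spec is None:
        spec = ClassifierSpec(input_dim=X_train.shape[1])
    for name, y in (("train", y_train), ("validation", y_val)):
        if len(np.unique(y)) < 2:
            raise ValueError(f"{name} set has a single class at threshold {threshold:g}")
    if X_train.shape[1] != spec.input_dim:
        raise ValueError(
            f"embedding dimension {X_train.shape[1]} != spec.input_dim {spec.input_dim}"
        )

    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    model = MLPClassifier(spec, seed=cfg.seed)
    params = model.weights + model.biases
    adam = _Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    if cfg.weighted_sampling:
        w = sampler_weights(y_train.astype(int))
        probs = w / w.sum()
    else:
        probs = None  # uniform

    n = len(y_train)
    batches_per_epoch = max(1, math.ceil(n / cfg.batch_size))
    best_mcc = -np.inf
    best_epoch = -1
    best_state: tuple[list, list] | None = None
    log: list[dict] = []

    for epoch in range(1, cfg.max_epochs + 1):
        losses = []
        for _ in range(batches_per_epoch):
            idx = rng.choice(n, size=cfg.batch_size, replace=True, p=probs)
            loss, gW, gb = model._backward(X_train[idx], y_train[idx])
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(threshold {threshold:g}, seed {cfg.seed})"
                )
            adam.step(params, gW + gb)
            losses.append(loss)
        val_calls = (model.predict_proba(X_val) >= 0.5).astype(int)
        val_mcc = mcc(confusion(y_val.astype(int), val_calls))
        log.append({"epoch": epoch, "loss": float(np.mean(losses)), "val_mcc": val_mcc})
        if val_mcc > best_mcc:
            best_mcc = val_mcc
            best_epoch = epoch
            best_state = (
                [W.copy() for W in model.weights],
                [b.copy() for b in model.biases],
            )

    assert best_state is not None
    model.weights, model.biases = best_state
    return TrainedClassifier(
        model=model,
        threshold=threshold,
        seed=cfg.seed,
        selected_epoch=best_epoch,
        validation_mcc=float(best_mcc),
        log=log,
    )


@dataclass
class ThresholdEnsemble:
    """Trained classifiers for one threshold; predictions are averaged."""

    threshold: float
    members: list[MLPClassifier]
    member_seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble must have at least one member")
        specs = {m.spec for m in self.members}
        if len(specs) != 1:
            raise ValueError("all ensemble members must share one architecture")


def member_seed(base_seed: int, threshold_index: int, member_index: int) -> int:
    """Deterministic per-member training seed below 2**31."""
    return (base_seed * 100003 + threshold_index * 1009 + member_index * 101 + 7) % (2**31)


def train_ensemble(
    train: Sequence[LabeledExample],
    val: Sequence[LabeledExample],
    threshold: float,
    spec: ClassifierSpec | None = None,
    cfg: TrainConfig | None = None,
    n_members: int = 5,
    threshold_index: int = 0,
) -> tuple[ThresholdEnsemble, list[TrainedClassifier]]:
    """Train an ensemble whose members differ only by their training seed."""
    cfg = cfg or TrainConfig()
    members: list[MLPClassifier] = []
    seeds: list[int] = []
    trained: list[TrainedClassifier] = []
    for m in range(n_members):
        seed_m = member_seed(cfg.seed, threshold_index, m)
        cfg_m = TrainConfig(
            learning_rate=cfg.learning_rate,
            weight_decay=cfg.weight_decay,
            batch_size=cfg.batch_size,
            max_epochs=cfg.max_epochs,
            seed=seed_m,
            weighted_sampling=cfg.weighted_sampling,
        )
        tc = train_classifier(train, val, threshold, spec=spec, cfg=cfg_m)
        trained.append(tc)
        members.append(tc.model)
        seeds.append(seed_m)
    return ThresholdEnsemble(threshold=threshold, members=members, member_seeds=seeds), trained


def ensemble_predict(ensemble: ThresholdEnsemble, x: np.ndarray) -> float:
    """Arithmetic mean of member probabilities for one embedding vector."""
    return float(np.mean([m.forward(x) for m in ensemble.members]))


def ensemble_predict_batch(ensemble: ThresholdEnsemble, X: np.ndarray) -> np.ndarray:
    return np.mean([m.predict_proba(X) for m in ensemble.members], axis=0)
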