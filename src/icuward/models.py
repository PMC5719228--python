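"""Elastic-net logistic regression and dropout-regularized MLPs.

The classifier is p(y=1|x) = logistic(H_n(...H_1(x))) with rectified-linear
hidden layers H_i(z) = max(0, W_i z + b_i); with no hidden layers this is
plain logistic regression.  Parameters maximize the penalized log-likelihood

    L(D, W) = sum_i log p(y_i | x_i) - a1 * ||W||_1 - a2 * ||W||_2^2

over all layer weights (biases are unpenalized) by minibatch stochastic
gradient ascent.  The L1 term is handled with a proximal (soft-threshold)
step so weights reach exact zeros — the penalty performs implicit feature
selection.  Dropout randomly elides hidden units during training only, with
inverted scaling, so prediction is a plain forward pass.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import sparse
from scipy.special import expit, log_expit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelHyperparams:
    """Training configuration.

    ``a1``/``a2`` are the L1/L2 penalty strengths of the penalized
    likelihood; ``hidden_layers`` empty means logistic regression.  The
    learning rate decays geometrically per epoch (step decay).
    """

    a1: float = 0.001
    a2: float = 0.01
    hidden_layers: tuple[int, ...] = ()
    dropout_rate: float = 0.0
    epochs: int = 30
    learning_rate: float = 0.5
    lr_decay: float = 0.95
    minibatch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("a1 and a2 must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.dropout_rate > 0 and not self.hidden_layers:
            raise ValueError("dropout requires hidden layers")


@dataclass
class TrainedModel:
    """Per-layer weights/biases plus the vocabulary they were fit against."""

    weights: list[np.ndarray]  # each (fan_in, fan_out); output fan_out == 1
    biases: list[np.ndarray]
    hyperparams: ModelHyperparams
    feature_names: list[str] | None = None
    vocabulary_checksum: str | None = None
    training_log: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]

    def decision_function(self, X) -> np.ndarray:
        A = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            A = np.maximum(A @ W + b, 0.0)
        z = A @ self.weights[-1] + self.biases[-1]
        return np.asarray(z).ravel()

    def predict_proba(self, X) -> np.ndarray:
        """Forward pass without dropout; probabilities in (0, 1)."""
        return expit(self.decision_function(X))

    def penalty(self) -> float:
        hp = self.hyperparams
        l1 = sum(np.abs(W).sum() for W in self.weights)
        l2 = sum((W ** 2).sum() for W in self.weights)
        return hp.a1 * l1 + hp.a2 * l2

    def to_json(self, path) -> None:
        payload = {
            "hyperparams": {
                **{k: getattr(self.hyperparams, k)
                   for k in ("a1", "a2", "dropout_rate", "epochs",
                             "learning_rate", "lr_decay", "minibatch_size",
                             "seed")},
                "hidden_layers": list(self.hyperparams.hidden_layers),
            },
            "layer_shapes": [list(W.shape) for W in self.weights],
            "weights": [W.ravel().tolist() for W in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_names": self.feature_names,
            "vocabulary_checksum": self.vocabulary_checksum,
            "training_log": self.training_log,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        hp_raw = dict(payload["hyperparams"])
        hp_raw["hidden_layers"] = tuple(hp_raw["hidden_layers"])
        hp = ModelHyperparams(**hp_raw)
        weights = [np.array(w, dtype=float).reshape(shape)
                   for w, shape in zip(payload["weights"],
                                       payload["layer_shapes"])]
        biases = [np.array(b, dtype=float) for b in payload["biases"]]
        return cls(weights=weights, biases=biases, hyperparams=hp,
                   feature_names=payload.get("feature_names"),
                   vocabulary_checksum=payload.get("vocabulary_checksum"),
                   training_log=payload.get("training_log", {}))


def _signed_logits(z: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.where(y == 1, z, -z)


def log_likelihood(model: TrainedModel, X, y: np.ndarray) -> float:
    z = model.decision_function(X)
    return float(log_expit(_signed_logits(z, y)).sum())


def penalized_log_likelihood(model: TrainedModel, X, y: np.ndarray) -> float:
    """sum_i log p(y_i|x_i) - a1 ||W||_1 - a2 ||W||_2^2 over all layers."""
    return log_likelihood(model, X, y) - model.penalty()


def _forward_train(weights, biases, X, dropout_rate, rng):
    """Forward pass recording activations and inverted-dropout masks."""
    acts = [X]
    masks = []
    A = X
    for W, b in zip(weights[:-1], biases[:-1]):
        Z = A @ W + b
        A = np.maximum(np.asarray(Z), 0.0)
        if dropout_rate > 0:
            mask = (rng.random(A.shape) >= dropout_rate) / (1.0 - dropout_rate)
            A = A * mask
        else:
            mask = None
        masks.append(mask)
        acts.append(A)
    z = np.asarray(acts[-1] @ weights[-1] + biases[-1]).ravel()
    return acts, masks, z


def _backprop(weights, acts, masks, z, y):
    """Gradients of the mean log-likelihood w.r.t. weights and biases."""
    n = len(y)
    delta = ((y - expit(z)) / n)[:, None]  # (n, 1)
    grads_W = []
    grads_b = []
    for layer in range(len(weights) - 1, -1, -1):
        A = acts[layer]
        grads_W.append(np.asarray(A.T @ delta if sparse.issparse(A)
                                  else A.T @ delta))
        grads_b.append(delta.sum(axis=0))
        if layer > 0:
            delta = delta @ weights[layer].T
            delta = delta * (acts[layer] > 0)
            if masks[layer - 1] is not None:
                delta = delta * masks[layer - 1]
    return grads_W[::-1], grads_b[::-1]


def likelihood_gradient(model: TrainedModel, X, y: np.ndarray):
    """Analytic full-batch gradient of the penalized log-likelihood.

    The L1 term contributes -a1 * sign(W) (a subgradient; exact away from
    zero).  Returned as (grads_W, grads_b) lists matching the layers.
    """
    hp = model.hyperparams
    acts, masks, z = _forward_train(model.weights, model.biases, X, 0.0, None)
    grads_W, grads_b = _backprop(model.weights, acts, masks, z, y)
    n = len(y)
    out_W = []
    for W, gW in zip(model.weights, grads_W):
        out_W.append(gW * n - hp.a1 * np.sign(W) - 2.0 * hp.a2 * W)
    out_b = [gb * n for gb in grads_b]
    return out_W, out_b


def _init_params(rng, n_features: int, hidden_layers: tuple[int, ...]):
    dims = [n_features, *hidden_layers, 1]
    weights, biases = [], []
    for i in range(len(dims) - 1):
        fan_in, fan_out = dims[i], dims[i + 1]
        if i < len(dims) - 2:
            W = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
        else:
            W = np.zeros((fan_in, fan_out))
        weights.append(W)
        biases.append(np.zeros(fan_out))
    return weights, biases


def train(X, y, hp: ModelHyperparams | None = None,
          feature_names: list[str] | None = None,
          vocabulary_checksum: str | None = None) -> TrainedModel:
    """Fit by stochastic gradient ascent on the penalized log-likelihood.

    Deterministic under a fixed seed.  The per-epoch penalized likelihood is
    recorded in ``training_log["penalized_log_likelihood"]`` so the upward
    trend can be monitored.  Raises on single-class data.
    """
    hp = hp or ModelHyperparams()
    y = np.asarray(y, dtype=int)
    if len(y) == 0 or len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    n = X.shape[0]
    rng = np.random.default_rng(hp.seed)
    weights, biases = _init_params(rng, X.shape[1], hp.hidden_layers)
    model = TrainedModel(weights=weights, biases=biases, hyperparams=hp,
                         feature_names=feature_names,
                         vocabulary_checksum=vocabulary_checksum)
    log = []
    for epoch in range(hp.epochs):
        lr = hp.learning_rate * (hp.lr_decay ** epoch)
        perm = rng.permutation(n)
        for start in range(0, n, hp.minibatch_size):
            idx = perm[start:start + hp.minibatch_size]
            Xb = X[idx]
            yb = y[idx]
            acts, masks, z = _forward_train(weights, biases, Xb,
                                            hp.dropout_rate, rng)
            grads_W, grads_b = _backprop(weights, acts, masks, z, yb)
            thresh = lr * hp.a1 / n
            for i, (gW, gb) in enumerate(zip(grads_W, grads_b)):
                W = weights[i] + lr * (gW - 2.0 * hp.a2 * weights[i] / n)
                # proximal L1 step: exact zeros, implicit feature selection
                weights[i] = np.sign(W) * np.maximum(np.abs(W) - thresh, 0.0)
                biases[i] = biases[i] + lr * gb
        log.append(penalized_log_likelihood(model, X, y))
    model.training_log = {"penalized_log_likelihood": log}
    return model


def cross_validate(X, y, hp_grid, k: int = 5, seed: int = 0):
    """Stratified k-fold selection of hyperparameters by mean fold auROC.

    Ties break toward stronger regularization (larger a1, then larger a2).
    A fold realizing only one class triggers a re-split with a fresh seed
    (logged).  Returns (best_hp, records DataFrame).
    """
    import pandas as pd
    from sklearn.model_selection import StratifiedKFold

    from .evaluation import auroc

    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(y, dtype=int)
    hp_grid = list(hp_grid)
    if not hp_grid:
        raise ValueError("empty hyperparameter grid")

    folds = None
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=seed + attempt)
        candidate = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2
               for tr, te in candidate):
            folds = candidate
            if attempt:
                logger.info("refolded %d times to keep both classes in "
                            "every fold", attempt)
            break
    if folds is None:
        raise ValueError("could not form stratified folds with both classes")

    records = []
    means = []
    for hp in hp_grid:
        fold_scores = []
        for fold_id, (tr, te) in enumerate(folds):
            model = train(X[tr], y[tr], replace(hp, seed=hp.seed + fold_id))
            scores = model.predict_proba(X[te])
            a = auroc(scores[y[te] == 1], scores[y[te] == 0])
            fold_scores.append(a)
            records.append({"a1": hp.a1, "a2": hp.a2,
                            "hidden_layers": hp.hidden_layers,
                            "fold": fold_id, "auroc": a})
        means.append(float(np.mean(fold_scores)))
    best = max(range(len(hp_grid)),
               key=lambda i: (means[i], hp_grid[i].a1, hp_grid[i].a2))
    return hp_grid[best], pd.DataFrame(records)
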