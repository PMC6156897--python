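"""Feed-forward DTI classifier with a negative-class-penalized objective.

The classifier maps a fused 2n-dimensional drug+gene sample through
fully-connected ReLU hidden layers (default 2n-200-10-2) to a two-class
softmax output: row i of the classification matrix CM holds
(P(negative | x_i), P(positive | x_i)).

Training minimizes, over parameters (theta, b),

    (1/m) [ sum_i ( -y_i ln p_i - (1 - y_i) ln(1 - p_i) )
            - eta * sum_{i in negatives} CM_{i,0} ]

where p_i = CM_{i,1}. The second term is *subtracted*: it rewards confident
negative-class probability on true negatives, deliberately pushing the
decision boundary toward the positive cluster so that fewer unlabeled pairs
are called positive (a lower PoPC) at a small cost in validation accuracy.
With eta = 0 the objective is plain cross-entropy. Because the penalty is
subtracted the objective may be negative; probabilities are clipped to
[eps, 1-eps] inside the logarithms so it stays finite.

Optimization is minibatch Adam with inverted dropout on the hidden
activations; everything is seeded, so a fixed seed and dataset reproduce the
final weights exactly on one thread.

The module follows the model/results idiom: construct a
:class:`DTIClassifier` from data, call :meth:`~DTIClassifier.fit`, and work
with the returned :class:`DTIClassifierResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from dtiscope.dataset import FusedSample

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "DTIClassifier",
    "DTIClassifierResults",
    "softmax",
    "penalized_cross_entropy",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture: layer widths, dropout rate, ReLU activations.

    ``layer_sizes`` runs input to output; the last entry must be 2 (binary
    softmax). Default mirrors the reference architecture for 978-feature
    profiles: 1956 inputs, hidden layers of 200 and 10, two outputs.
    """

    layer_sizes: Tuple[int, ...] = (1956, 200, 10, 2)
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if len(self.layer_sizes) < 2:
            raise ValueError("need at least input and output layers")
        if self.layer_sizes[-1] != 2:
            raise ValueError("output layer must have 2 units (binary softmax)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    eta is the penalty weight on the negative-class term (default 10);
    prob_floor is the eps used to clip probabilities inside logs and logits.
    """

    eta: float = 10.0
    learning_rate: float = 1e-4
    epochs: int = 200
    batch_size: int = 128
    seed: int = 0
    prob_floor: float = 1e-7
    patience: int = 20  # early stop on validation loss; 0 disables

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("learning_rate, epochs, batch_size must be positive")
        if not 0 < self.prob_floor < 0.5:
            raise ValueError("prob_floor must lie in (0, 0.5)")


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for numerical stability."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def penalized_cross_entropy(
    cm: np.ndarray, labels: np.ndarray, eta: float, eps: float = 1e-7
) -> float:
    """The training objective evaluated on a classification matrix.

    ``cm`` is (m, 2) with rows (P(neg), P(pos)); ``labels`` in {0, 1}.
    Cross-entropy uses eps-clipped probabilities; the penalty term uses the
    raw CM_{i,0} of the true negatives and is subtracted.
    """
    cm = np.asarray(cm, dtype=float)
    labels = np.asarray(labels)
    if cm.ndim != 2 or cm.shape[1] != 2:
        raise ValueError("cm must be (m, 2)")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    p = cm[:, 1]
    pc = np.clip(p, eps, 1.0 - eps)
    ce = -labels * np.log(pc) - (1 - labels) * np.log(1.0 - pc)
    penalty = eta * cm[labels == 0, 0].sum()
    return float((ce.sum() - penalty) / cm.shape[0])


Params = List[Tuple[np.ndarray, np.ndarray]]  # [(W, b)] per layer


def _init_params(net: NetworkConfig, rng: np.random.Generator) -> Params:
    """He-normal weights (ReLU-appropriate), zero biases."""
    params: Params = []
    for fan_in, fan_out in zip(net.layer_sizes[:-1], net.layer_sizes[1:]):
        W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        params.append((W, np.zeros(fan_out)))
    return params


def _forward(
    params: Params,
    X: np.ndarray,
    net: NetworkConfig,
    dropout_rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, List[np.ndarray], List[np.ndarray]]:
    """Forward pass. Returns (CM, hidden activations, dropout masks).

    Dropout (inverted scaling) is applied to hidden activations only when a
    ``dropout_rng`` is supplied, i.e. during training; inference is
    deterministic and unscaled.
    """
    if X.shape[1] != net.layer_sizes[0]:
        raise ValueError(
            f"input width {X.shape[1]} != network input {net.layer_sizes[0]}"
        )
    h = X
    acts: List[np.ndarray] = [X]
    masks: List[np.ndarray] = []
    for li, (W, b) in enumerate(params[:-1]):
        h = np.maximum(h @ W + b, 0.0)
        if dropout_rng is not None and net.dropout_rate > 0:
            keep = 1.0 - net.dropout_rate
            mask = (dropout_rng.random(h.shape) < keep) / keep
            h = h * mask
            masks.append(mask)
        else:
            masks.append(np.ones_like(h))
        acts.append(h)
    W, b = params[-1]
    logits = h @ W + b
    return softmax(logits), acts, masks


def _loss_and_grads(
    params: Params,
    X: np.ndarray,
    y: np.ndarray,
    net: NetworkConfig,
    tc: TrainConfig,
    dropout_rng: Optional[np.random.Generator],
) -> Tuple[float, List[Tuple[np.ndarray, np.ndarray]]]:
    """Objective value and analytic gradients for one batch."""
    m = X.shape[0]
    cm, acts, masks = _forward(params, X, net, dropout_rng)
    loss = penalized_cross_entropy(cm, y, tc.eta, tc.prob_floor)

    p = cm[:, 1]
    eps = tc.prob_floor
    inside = (p > eps) & (p < 1.0 - eps)  # clip gate for the log terms
    pc = np.clip(p, eps, 1.0 - eps)
    dL_dp = np.where(y == 1, -1.0 / pc, 1.0 / (1.0 - pc)) * inside
    dL_dp = dL_dp + np.where(y == 0, tc.eta, 0.0)  # d/dp of -eta*(1-p)
    dL_dp /= m
    # two-class softmax: p = sigma(z1 - z0), so dp/dz = p(1-p) * (-1, +1)
    s = dL_dp * p * (1.0 - p)
    dZ = np.column_stack([-s, s])

    grads: List[Tuple[np.ndarray, np.ndarray]] = [None] * len(params)  # type: ignore
    W_out, _ = params[-1]
    grads[-1] = (acts[-1].T @ dZ, dZ.sum(axis=0))
    dH = dZ @ W_out.T
    for li in range(len(params) - 2, -1, -1):
        dH = dH * masks[li]
        pre_relu_pos = acts[li + 1] > 0  # post-mask zeros coincide with mask zeros
        dA = dH * pre_relu_pos
        W, _ = params[li]
        grads[li] = (acts[li].T @ dA, dA.sum(axis=0))
        if li > 0:
            dH = dA @ W.T
    return loss, grads


class DTIClassifier:
    """Model object: fused samples plus architecture and training settings.

    Parameters
    ----------
    X, y : arrays
        Training matrix (m, 2n) of fused vectors and 0/1 labels
        (1 = positive interaction).
    network, train : configs
        Architecture and optimization settings; the network's input width
        must match X. If ``network`` is omitted, the default hidden sizes
        (200, 10) are used with the observed input width.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        network: Optional[NetworkConfig] = None,
        train: Optional[TrainConfig] = None,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be 2-D and aligned with y")
        classes = set(np.unique(self.y))
        if not classes <= {0, 1}:
            raise ValueError("labels must be 0/1")
        if classes != {0, 1}:
            raise ValueError("training fold must contain both classes")
        self.network = network or NetworkConfig(
            layer_sizes=(self.X.shape[1], 200, 10, 2)
        )
        if self.network.layer_sizes[0] != self.X.shape[1]:
            raise ValueError("network input width does not match X")
        self.train_config = train or TrainConfig()

    @classmethod
    def from_samples(
        cls,
        samples: Sequence[FusedSample],
        network: Optional[NetworkConfig] = None,
        train: Optional[TrainConfig] = None,
    ) -> "DTIClassifier":
        """Build from labelled FusedSamples (positive -> 1, negative -> 0)."""
        X = np.vstack([s.vector for s in samples])
        y = np.array([1 if s.label == "positive" else 0 for s in samples])
        return cls(X, y, network=network, train=train)

    def fit(
        self,
        X_val: Optional[np.ndarray] = None,
        y_val: Optional[np.ndarray] = None,
        verbose: bool = False,
    ) -> "DTIClassifierResults":
        """Train with minibatch Adam; returns a results object.

        If validation data is given, per-epoch validation loss/accuracy are
        recorded and early stopping (patience from TrainConfig) restores the
        best-validation-loss weights.
        """
        tc = self.train_config
        net = self.network
        rng = np.random.default_rng(tc.seed)
        params = _init_params(net, rng)
        mom = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
        vel = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
        beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
        t = 0
        m = self.X.shape[0]
        history: Dict[str, List[float]] = {
            "loss": [], "train_accuracy": [], "val_loss": [], "val_accuracy": []
        }
        best = (np.inf, None, -1)  # (val loss, params snapshot, epoch)

        for epoch in range(tc.epochs):
            order = rng.permutation(m)
            epoch_loss = 0.0
            for start in range(0, m, tc.batch_size):
                idx = order[start : start + tc.batch_size]
                loss, grads = _loss_and_grads(
                    params, self.X[idx], self.y[idx], net, tc, rng
                )
                epoch_loss += loss * idx.size
                t += 1
                new_params = []
                for li, ((W, b), (gW, gb)) in enumerate(zip(params, grads)):
                    mW = beta1 * mom[li][0] + (1 - beta1) * gW
                    mB = beta1 * mom[li][1] + (1 - beta1) * gb
                    vW = beta2 * vel[li][0] + (1 - beta2) * gW**2
                    vB = beta2 * vel[li][1] + (1 - beta2) * gb**2
                    mom[li], vel[li] = (mW, mB), (vW, vB)
                    mW_h, mB_h = mW / (1 - beta1**t), mB / (1 - beta1**t)
                    vW_h, vB_h = vW / (1 - beta2**t), vB / (1 - beta2**t)
                    new_params.append(
                        (
                            W - tc.learning_rate * mW_h / (np.sqrt(vW_h) + adam_eps),
                            b - tc.learning_rate * mB_h / (np.sqrt(vB_h) + adam_eps),
                        )
                    )
                params = new_params

            cm_train, _, _ = _forward(params, self.X, net)
            train_acc = float(((cm_train[:, 1] > 0.5).astype(int) == self.y).mean())
            history["loss"].append(epoch_loss / m)
            history["train_accuracy"].append(train_acc)

            if X_val is not None and y_val is not None:
                cm_val, _, _ = _forward(params, np.asarray(X_val, dtype=float), net)
                val_loss = penalized_cross_entropy(cm_val, y_val, tc.eta, tc.prob_floor)
                val_acc = float(((cm_val[:, 1] > 0.5).astype(int) == y_val).mean())
                history["val_loss"].append(val_loss)
                history["val_accuracy"].append(val_acc)
                if val_loss < best[0]:
                    best = (val_loss, [(W.copy(), b.copy()) for W, b in params], epoch)
                if tc.patience and epoch - best[2] >= tc.patience:
                    break
            if verbose:
                print(f"epoch {epoch}: loss {history['loss'][-1]:.4f} "
                      f"train acc {train_acc:.4f}")

        if best[1] is not None:
            params = best[1]
        return DTIClassifierResults(self, params, history)


class DTIClassifierResults:
    """Fitted classifier: weights, training history, prediction, summary."""

    def __init__(
        self, model: DTIClassifier, params: Params, history: Dict[str, List[float]]
    ) -> None:
        self.model = model
        self.params = params
        self.history = history

    @property
    def network(self) -> NetworkConfig:
        return self.model.network

    @property
    def train_config(self) -> TrainConfig:
        return self.model.train_config

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Classification matrix for new samples (dropout off, deterministic)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cm, _, _ = _forward(self.params, X, self.network)
        return cm

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        """Hard 0/1 calls at the given positive-probability threshold."""
        return (self.predict_proba(X)[:, 1] > threshold).astype(int)

    def predict_samples(self, samples: Sequence[FusedSample]) -> np.ndarray:
        return self.predict_proba(np.vstack([s.vector for s in samples]))

    def summary(self) -> str:
        """Plain-text fit summary in the style of statistical model results."""
        net = self.network
        tc = self.train_config
        n_params = sum(W.size + b.size for W, b in self.params)
        lines = [
            "DTI feed-forward classifier results",
            "=" * 43,
            f"Architecture        {'-'.join(str(s) for s in net.layer_sizes)}",
            f"Parameters          {n_params}",
            f"Dropout rate        {net.dropout_rate}",
            f"Penalty weight eta  {tc.eta}",
            f"Learning rate       {tc.learning_rate}",
            f"Epochs run          {len(self.history['loss'])}",
            f"Final train loss    {self.history['loss'][-1]:.6f}",
            f"Final train acc.    {self.history['train_accuracy'][-1]:.4f}",
        ]
        if self.history["val_accuracy"]:
            best_ep = int(np.argmin(self.history["val_loss"]))
            lines.append(f"Best val loss       {self.history['val_loss'][best_ep]:.6f} "
                         f"(epoch {best_ep})")
            lines.append(f"Val acc. at best    {self.history['val_accuracy'][best_ep]:.4f}")
        lines.append("=" * 43)
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Loss / accuracy learning curves (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["loss"], label="train loss")
        if self.history["val_loss"]:
            ax.plot(self.history["val_loss"], label="val loss")
        ax.set_xlabel("epoch")
        ax.set_ylabel("objective")
        ax.legend()
        return ax

    def save(self, path: str | Path) -> None:
        """Persist weights + configs as a single .npz archive."""
        arrays = {}
        for i, (W, b) in enumerate(self.params):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        meta = {
            "network": asdict(self.network),
            "train": asdict(self.train_config),
            "n_layers": len(self.params),
        }
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DTIClassifierResults":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            params = [
                (archive[f"W{i}"], archive[f"b{i}"]) for i in range(meta["n_layers"])
            ]
        net = NetworkConfig(
            layer_sizes=tuple(meta["network"]["layer_sizes"]),
            dropout_rate=meta["network"]["dropout_rate"],
        )
        tc = TrainConfig(**meta["train"])
        # reconstruct a shell model; data is not stored in the archive
        shell = DTIClassifier.__new__(DTIClassifier)
        shell.network = net
        shell.train_config = tc
        shell.X = np.zeros((0, net.layer_sizes[0]))
        shell.y = np.zeros(0, dtype=int)
        return cls(shell, params, {"loss": [], "train_accuracy": [],
                                   "val_loss": [], "val_accuracy": []})
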