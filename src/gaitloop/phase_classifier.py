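"""Lightweight 3-class gait-phase classifier.

A 3-32-32-3 feed-forward network (ReLU hidden layers, softmax output,
1283 trainable parameters) maps a single frame's (hip, knee, ankle)
angle triple to a posterior over {stance, swing, abnormal}.  Training
minimises categorical cross-entropy with Adam, mini-batches of 128, for
up to 300 epochs with early stopping on validation loss and restoration
of the best checkpoint.  The network is implemented directly in numpy:
the model is small enough that a dependency on a deep-learning framework
would be pure overhead, and the explicit forward pass doubles as the
specification of what gets deployed on a microcontroller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gait_events import PhaseLabel

#: Output class order; fixed so that serialized models are unambiguous.
CLASSES = (PhaseLabel.STANCE, PhaseLabel.SWING, PhaseLabel.ABNORMAL)
CLASS_NAMES = tuple(c.value for c in CLASSES)

_FORMAT_VERSION = 1


class ModelFormatError(ValueError):
    """A serialized model file is truncated, corrupt, or wrong version."""


@dataclass
class LabeledDataset:
    """Frame-wise angle triples with phase labels and an 80/20 split.

    ``features`` is (n, 3) float degrees in (hip, knee, ankle) order;
    ``labels`` integer class indices into :data:`CLASSES`.  The split is
    a random shuffle, disjoint and exhaustive; natural class proportions
    are deliberately preserved (no rebalancing — stance really is the
    longest phase).
    """

    features: np.ndarray
    labels: np.ndarray
    train_mask: np.ndarray
    provenance: list[str] = field(default_factory=list)

    @property
    def val_mask(self) -> np.ndarray:
        return ~self.train_mask

    def __len__(self) -> int:
        return len(self.labels)


def build_dataset(
    sessions: list[tuple[list, list[PhaseLabel]]],
    train_fraction: float = 0.8,
    seed: int = 0,
    provenance: list[str] | None = None,
) -> LabeledDataset:
    """Assemble (angles, label) rows from fully labelled sessions.

    Each element of ``sessions`` is ``(angle_samples, labels)`` of equal
    length; one row is emitted per frame, in source order, then shuffled
    into a train/validation split.
    """
    feats, labs = [], []
    for angle_samples, labels in sessions:
        if len(angle_samples) != len(labels):
            raise ValueError("angle samples and labels disagree in length")
        for s, lab in zip(angle_samples, labels):
            if lab is None:
                raise ValueError("unlabeled frame in session")
            feats.append((s.hip_deg, s.knee_deg, s.ankle_deg))
            labs.append(CLASSES.index(lab))
    features = np.asarray(feats, dtype=float)
    labels_arr = np.asarray(labs, dtype=int)
    n = len(labels_arr)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train_mask = np.zeros(n, dtype=bool)
    train_mask[order[:n_train]] = True
    return LabeledDataset(features, labels_arr, train_mask, provenance or [])


def dataset_to_csv(dataset: LabeledDataset, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(dataset.features, columns=["hip", "knee", "ankle"])
    df["label"] = [CLASS_NAMES[i] for i in dataset.labels]
    df["split"] = np.where(dataset.train_mask, "train", "val")
    df.to_csv(path, index=False)
    return path


@dataclass
class MlpModel:
    """Weights/biases of the feed-forward classifier plus input scaling.

    ``weights[i]`` has shape (fan_in, fan_out); hidden activations are
    ReLU and the output layer is a softmax.  ``input_mean``/``input_sd``
    hold the optional per-feature z-score parameters fitted on the
    training split (identity scaling when absent).
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_mean: np.ndarray | None = None
    input_sd: np.ndarray | None = None

    @classmethod
    def initialize(cls, layer_sizes=(3, 32, 32, 3), seed: int = 0) -> "MlpModel":
        """He-initialised weights, zero biases."""
        rng = np.random.default_rng(seed)
        ws, bs = [], []
        for fan_in, fan_out in zip(layer_sizes, layer_sizes[1:]):
            ws.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
            bs.append(np.zeros(fan_out))
        return cls(tuple(layer_sizes), ws, bs)

    def scale(self, x: np.ndarray) -> np.ndarray:
        if self.input_mean is None:
            return x
        return (x - self.input_mean) / self.input_sd

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batch forward pass -> softmax posteriors, rows summing to 1."""
        h = self.scale(np.atleast_2d(np.asarray(x, dtype=float)))
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ w + b, 0.0)
        logits = h @ self.weights[-1] + self.biases[-1]
        logits -= logits.max(axis=1, keepdims=True)  # stability
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class PhasePosterior:
    p_stance: float
    p_swing: float
    p_abnormal: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_stance, self.p_swing, self.p_abnormal])

    @property
    def label(self) -> PhaseLabel:
        return CLASSES[int(np.argmax(self.as_array()))]


def count_parameters(model: MlpModel) -> int:
    """Total trainable parameters: sum of fan_in*fan_out + fan_out."""
    return int(sum(w.size + b.size for w, b in zip(model.weights, model.biases)))


def predict(model: MlpModel, angles) -> PhasePosterior:
    """Posterior over {stance, swing, abnormal} for one angle triple."""
    arr = np.asarray(angles, dtype=float).reshape(1, 3)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite input angles")
    p = model.forward(arr)[0]
    return PhasePosterior(float(p[0]), float(p[1]), float(p[2]))


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.val_loss)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))))


def train(
    dataset: LabeledDataset,
    epochs_max: int = 300,
    batch: int = 128,
    seed: int = 0,
    learning_rate: float = 1e-3,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
    patience: int = 25,
    scale_inputs: bool = True,
    layer_sizes: tuple[int, ...] = (3, 32, 32, 3),
) -> tuple[MlpModel, TrainingHistory]:
    """Train the classifier with Adam + early stopping.

    Early stopping monitors validation loss with the given patience and
    the returned model carries the best-epoch checkpoint.  Fully
    reproducible under ``seed``.
    """
    x_tr = dataset.features[dataset.train_mask]
    y_tr = dataset.labels[dataset.train_mask]
    x_va = dataset.features[dataset.val_mask]
    y_va = dataset.labels[dataset.val_mask]
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("empty train or validation split")

    model = MlpModel.initialize(layer_sizes, seed=seed)
    if scale_inputs:
        model.input_mean = x_tr.mean(axis=0)
        model.input_sd = np.where(x_tr.std(axis=0) > 0, x_tr.std(axis=0), 1.0)

    params = model.weights + model.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    rng = np.random.default_rng(seed + 1)
    history = TrainingHistory()
    best_loss = np.inf
    best_state = None
    stale = 0
    step = 0

    n_layers = len(model.weights)
    for _epoch in range(epochs_max):
        order = rng.permutation(len(x_tr))
        for start in range(0, len(order), batch):
            idx = order[start : start + batch]
            xb = model.scale(x_tr[idx])
            yb = y_tr[idx]
            # forward with cached activations
            acts = [xb]
            h = xb
            for w, b in zip(model.weights[:-1], model.biases[:-1]):
                h = np.maximum(h @ w + b, 0.0)
                acts.append(h)
            logits = h @ model.weights[-1] + model.biases[-1]
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            probs = e / e.sum(axis=1, keepdims=True)
            # backward: softmax + cross-entropy
            delta = probs.copy()
            delta[np.arange(len(yb)), yb] -= 1.0
            delta /= len(yb)
            grads_w = [None] * n_layers
            grads_b = [None] * n_layers
            for layer in range(n_layers - 1, -1, -1):
                grads_w[layer] = acts[layer].T @ delta
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ model.weights[layer].T) * (acts[layer] > 0)
            # Adam update
            step += 1
            grads = grads_w + grads_b
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = beta1 * m[i] + (1 - beta1) * g
                v[i] = beta2 * v[i] + (1 - beta2) * g * g
                mhat = m[i] / (1 - beta1**step)
                vhat = v[i] / (1 - beta2**step)
                p -= learning_rate * mhat / (np.sqrt(vhat) + eps)

        p_tr = model.forward(x_tr)
        p_va = model.forward(x_va)
        history.train_loss.append(_cross_entropy(p_tr, y_tr))
        history.val_loss.append(_cross_entropy(p_va, y_va))
        history.train_acc.append(float(np.mean(p_tr.argmax(axis=1) == y_tr)))
        history.val_acc.append(float(np.mean(p_va.argmax(axis=1) == y_va)))

        if history.val_loss[-1] < best_loss - 1e-9:
            best_loss = history.val_loss[-1]
            best_state = (
                [w.copy() for w in model.weights],
                [b.copy() for b in model.biases],
            )
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break

    if best_state is not None:
        model.weights, model.biases = best_state
    return model, history


def serialize_model(model: MlpModel, path: str | Path) -> Path:
    """Write the model as a self-describing JSON file (bit-exact weights)."""
    path = Path(path)
    doc = {
        "format": "gaitloop-mlp",
        "version": _FORMAT_VERSION,
        "layer_sizes": list(model.layer_sizes),
        "classes": list(CLASS_NAMES),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "input_mean": None if model.input_mean is None else model.input_mean.tolist(),
        "input_sd": None if model.input_sd is None else model.input_sd.tolist(),
    }
    path.write_text(json.dumps(doc))
    return path


def load_model(path: str | Path) -> MlpModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise ModelFormatError(f"{path}: not a valid model file") from exc
    if not isinstance(doc, dict) or doc.get("format") != "gaitloop-mlp":
        raise ModelFormatError(f"{path}: not a gaitloop model file")
    if doc.get("version") != _FORMAT_VERSION:
        raise ModelFormatError(f"{path}: unsupported version {doc.get('version')}")
    model = MlpModel(
        layer_sizes=tuple(doc["layer_sizes"]),
        weights=[np.asarray(w, dtype=float) for w in doc["weights"]],
        biases=[np.asarray(b, dtype=float) for b in doc["biases"]],
        input_mean=None if doc["input_mean"] is None else np.asarray(doc["input_mean"]),
        input_sd=None if doc["input_sd"] is None else np.asarray(doc["input_sd"]),
    )
    for w, b, (fi, fo) in zip(
        model.weights, model.biases, zip(model.layer_sizes, model.layer_sizes[1:])
    ):
        if w.shape != (fi, fo) or b.shape != (fo,):
            raise ModelFormatError(f"{path}: weight shapes disagree with layer sizes")
    return model
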