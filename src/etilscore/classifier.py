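"""Four-class neural-network cell classifier (tumor / til / stroma / other).

A multilayer perceptron with eight hidden layers (default width 32, ReLU)
trained with a full-batch quasi-Newton optimizer for at most 100 iterations
on z-scored features.  Feature binding is by name, never by column
position, so tables with permuted or extra columns classify identically.
Training is deterministic for a fixed seed.  Models serialize to a single
portable JSON file (weights as base64 float64 blobs).

The pathologist quality-control step is supported as tooling: an overlay
writer paints class-colored cell masks (red tumor, purple immune, green
stroma, yellow other) over the source image for human review.
"""

from __future__ import annotations

import base64
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier

from etilscore.features import FeatureTable

__all__ = ["ClassifierModel", "train", "predict", "write_overlay", "CLASS_NAMES", "OVERLAY_COLORS"]

CLASS_NAMES = ("tumor", "til", "stroma", "other")
N_HIDDEN_LAYERS = 8

OVERLAY_COLORS = {
    "tumor": (220, 30, 30),
    "til": (140, 60, 200),
    "stroma": (40, 170, 60),
    "other": (230, 210, 40),
    "unclassified": (128, 128, 128),
}


@dataclass
class ClassifierModel:
    """Trained MLP: layer weights/biases, feature-name binding contract,
    z-score scaler, seed, and per-class training counts."""

    feature_names: list[str]
    class_names: list[str]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    seed: int
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.weights) != N_HIDDEN_LAYERS + 1:
            raise ValueError(f"expected {N_HIDDEN_LAYERS} hidden layers")
        if self.weights[-1].shape[1] != len(self.class_names):
            raise ValueError("output layer size must match class count")
        if self.weights[0].shape[0] != len(self.feature_names):
            raise ValueError("input size must match feature_names")
        if np.any(self.scaler_sd <= 0):
            raise ValueError("scaler sd must be positive for all used features")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def to_json(self, path: str | Path | None = None) -> str:
        def blob(a: np.ndarray) -> dict:
            return {
                "shape": list(a.shape),
                "data": base64.b64encode(np.ascontiguousarray(a, dtype=np.float64).tobytes()).decode(),
            }

        payload = json.dumps(
            {
                "feature_names": self.feature_names,
                "class_names": self.class_names,
                "weights": [blob(w) for w in self.weights],
                "biases": [blob(b) for b in self.biases],
                "scaler_mean": blob(self.scaler_mean),
                "scaler_sd": blob(self.scaler_sd),
                "seed": self.seed,
                "training_meta": self.training_meta,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "ClassifierModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = json.loads(text)

        def unblob(d: dict) -> np.ndarray:
            return np.frombuffer(base64.b64decode(d["data"]), dtype=np.float64).reshape(d["shape"]).copy()

        return cls(
            feature_names=data["feature_names"],
            class_names=data["class_names"],
            weights=[unblob(w) for w in data["weights"]],
            biases=[unblob(b) for b in data["biases"]],
            scaler_mean=unblob(data["scaler_mean"]),
            scaler_sd=unblob(data["scaler_sd"]),
            seed=data["seed"],
            training_meta=data.get("training_meta", {}),
        )


def train(
    table: FeatureTable,
    labels,
    seed: int = 0,
    max_iter: int = 100,
    hidden_width: int = 32,
    holdout_fraction: float = 0.2,
) -> ClassifierModel:
    """Train the cell classifier.

    Requires at least 2 classes and 10 examples per present class.  Features
    with (near-)zero variance are dropped with a warning and never enter the
    model.  A stratified ``holdout_fraction`` split measures held-out
    accuracy, recorded in ``training_meta`` together with per-class counts.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(table.cell_ids):
        raise ValueError("labels and feature table length mismatch")
    present, counts = np.unique(labels, return_counts=True)
    if len(present) < 2:
        raise ValueError("training requires at least 2 classes")
    if counts.min() < 10:
        raise ValueError("training requires >= 10 examples per present class")
    unknown = set(present) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")

    x = table.values
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 1e-12
    if not keep.all():
        dropped = [n for n, k in zip(table.feature_names, keep) if not k]
        warnings.warn(f"dropping constant features: {dropped}", stacklevel=2)
    feature_names = [n for n, k in zip(table.feature_names, keep) if k]
    mean, sd = mean[keep], sd[keep]
    z = (x[:, keep] - mean) / sd

    from sklearn.model_selection import train_test_split

    z_tr, z_te, y_tr, y_te = train_test_split(
        z, labels, test_size=holdout_fraction, random_state=seed, stratify=labels
    )
    class_names = [c for c in CLASS_NAMES if c in present]
    mlp = MLPClassifier(
        hidden_layer_sizes=(hidden_width,) * N_HIDDEN_LAYERS,
        activation="relu",
        solver="lbfgs",
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(z_tr, y_tr)
    holdout_acc = float((mlp.predict(z_te) == y_te).mean())
    train_acc = float((mlp.predict(z_tr) == y_tr).mean())

    # reorder output units into canonical class order
    order = [list(mlp.classes_).index(c) for c in class_names]
    weights = [np.asarray(w, dtype=np.float64) for w in mlp.coefs_]
    biases = [np.asarray(b, dtype=np.float64) for b in mlp.intercepts_]
    weights[-1] = weights[-1][:, order]
    biases[-1] = biases[-1][order]

    return ClassifierModel(
        feature_names=feature_names,
        class_names=class_names,
        weights=weights,
        biases=biases,
        scaler_mean=mean,
        scaler_sd=sd,
        seed=int(seed),
        training_meta={
            "counts": {c: int(n) for c, n in zip(present, counts)},
            "holdout_accuracy": holdout_acc,
            "train_accuracy": train_acc,
            "max_iter": int(max_iter),
            "hidden_width": int(hidden_width),
        },
    )


def predict(model: ClassifierModel, table: FeatureTable) -> tuple[list[str], pd.DataFrame]:
    """Classify cells: returns (labels, per-class probability frame).

    Features are matched to the model by name; missing columns raise an
    error naming the first absent feature, extra columns are ignored.
    Probabilities form a valid simplex per cell.
    """
    if len(table.cell_ids) == 0:
        return [], pd.DataFrame(columns=list(model.class_names))
    col_index = {name: i for i, name in enumerate(table.feature_names)}
    missing = [n for n in model.feature_names if n not in col_index]
    if missing:
        raise ValueError(f"feature table is missing required feature '{missing[0]}'")
    cols = [col_index[n] for n in model.feature_names]
    z = (table.values[:, cols] - model.scaler_mean) / model.scaler_sd
    probs = _forward(model, z)
    labels = [model.class_names[i] for i in probs.argmax(axis=1)]
    return labels, pd.DataFrame(probs, columns=list(model.class_names))


def _forward(model: ClassifierModel, z: np.ndarray) -> np.ndarray:
    a = z
    for w, b in zip(model.weights[:-1], model.biases[:-1]):
        a = np.maximum(a @ w + b, 0.0)
    logits = a @ model.weights[-1] + model.biases[-1]
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=1, keepdims=True)


def write_overlay(image, cells, path: str | Path, alpha: float = 0.45) -> Path:
    """Write a class-colored QC overlay PNG for pathologist review."""
    from PIL import Image as PILImage, ImageDraw

    base = PILImage.fromarray(np.asarray(image.pixels, dtype=np.uint8)).convert("RGBA")
    layer = PILImage.new("RGBA", base.size, (0, 0, 0, 0))
    draw = ImageDraw.Draw(layer)
    a = int(round(alpha * 255))
    for cell in cells:
        color = OVERLAY_COLORS.get(cell.label, OVERLAY_COLORS["unclassified"])
        ring = [(float(x), float(y)) for x, y in np.asarray(cell.nucleus_polygon.exterior.coords)]
        draw.polygon(ring, fill=color + (a,), outline=color + (255,))
    out = PILImage.alpha_composite(base, layer).convert("RGB")
    out.save(path)
    return Path(path)
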