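"""Nine-class tissue-texture classifier with probability outputs.

`TissueClassifier` is a scikit-learn style estimator: texture/color
features -> standardization -> multilayer perceptron with a softmax
output, one probability per tissue class.  The probability vector
("activation vector") is the unit that flows from images into the
survival statistics downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion, roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .features import batch_features, patch_features
from .tissue import CLASS_CODES, N_CLASSES

PATCH_SIZE = 224


@dataclass
class TrainingConfig:
    """Training hyperparameters for `TissueClassifier`."""

    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 60
    flip_horizontal: bool = True
    flip_vertical: bool = True
    preset: str = "mlp"
    seed: int = 0

    def validate(self) -> None:
        f = np.asarray(self.split_fractions, float)
        if f.shape != (3,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("split_fractions must be 3 positive values summing to 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.preset not in ("mlp", "linear"):
            raise ValueError("preset must be 'mlp' or 'linear'")


def _coerce_patch(patch: np.ndarray) -> np.ndarray:
    arr = np.asarray(patch)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("patch must be an (H, W, 3) RGB array")
    if not np.isfinite(np.asarray(arr, dtype=float)).all():
        raise ValueError("corrupt image: non-finite pixel values")
    if arr.shape[:2] != (PATCH_SIZE, PATCH_SIZE):
        arr = _sk_resize(
            arr.astype(float), (PATCH_SIZE, PATCH_SIZE, 3),
            preserve_range=True, anti_aliasing=True,
        )
    return np.clip(arr, 0, 255)


class TissueClassifier(BaseEstimator, ClassifierMixin):
    """Texture-feature MLP over the nine tissue classes.

    Parameters mirror `TrainingConfig`; ``predict_proba`` returns rows
    on the probability simplex in the fixed class order, and ``predict``
    returns integer class indices (argmax, ties broken by class order).

    Attributes (after ``fit``)
    --------------------------
    scaler_ : fitted feature standardizer
    net_ : fitted MLP (or logistic model for the "linear" preset)
    classes_ : integer class indices present during fit
    history_ : per-epoch training log (loss, validation accuracy)
    """

    def __init__(self, preset: str = "mlp", hidden_layer_sizes=(64, 32),
                 batch_size: int = 32, learning_rate: float = 1e-3,
                 epochs: int = 60, flip_horizontal: bool = True,
                 flip_vertical: bool = True, spatial_pooling: int = 2,
                 seed: int = 0):
        self.preset = preset
        self.hidden_layer_sizes = hidden_layer_sizes
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.flip_horizontal = flip_horizontal
        self.flip_vertical = flip_vertical
        self.spatial_pooling = spatial_pooling
        self.seed = seed

    @classmethod
    def from_config(cls, cfg: TrainingConfig) -> "TissueClassifier":
        cfg.validate()
        return cls(preset=cfg.preset, batch_size=cfg.batch_size,
                   learning_rate=cfg.learning_rate, epochs=cfg.epochs,
                   flip_horizontal=cfg.flip_horizontal,
                   flip_vertical=cfg.flip_vertical, seed=cfg.seed)

    # -- training ----------------------------------------------------------

    def _augmented_features(self, patches, labels):
        X = [batch_features(patches)]
        y = [np.asarray(labels)]
        if self.flip_horizontal:
            X.append(np.stack([patch_features(p[:, ::-1]) for p in patches]))
            y.append(np.asarray(labels))
        if self.flip_vertical:
            X.append(np.stack([patch_features(p[::-1]) for p in patches]))
            y.append(np.asarray(labels))
        return np.concatenate(X), np.concatenate(y)

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on labeled patches.

        X : stack/list of (224, 224, 3) patches; y : integer class
        indices or class codes.  An optional validation set is scored
        once per epoch into ``history_``.
        """
        patches = [_coerce_patch(p) for p in X]
        if len(patches) == 0:
            raise ValueError("empty training set")
        y = np.asarray(
            [CLASS_CODES.index(v) if isinstance(v, str) else int(v) for v in y]
        )
        if np.unique(y).size < 2:
            raise ValueError("degenerate label space: need >= 2 classes to train")

        feats, labels = self._augmented_features(patches, y)
        self.scaler_ = StandardScaler().fit(feats)
        Xs = self.scaler_.transform(feats)

        val_feats = val_labels = None
        if X_val is not None and y_val is not None and len(X_val) > 0:
            val_feats = batch_features([_coerce_patch(p) for p in X_val])
            val_labels = np.asarray(
                [CLASS_CODES.index(v) if isinstance(v, str) else int(v)
                 for v in y_val]
            )

        if self.preset == "linear":
            from sklearn.linear_model import LogisticRegression
            self.net_ = LogisticRegression(max_iter=2000, random_state=self.seed)
        elif self.preset == "mlp":
            self.net_ = MLPClassifier(
                hidden_layer_sizes=tuple(self.hidden_layer_sizes),
                batch_size=min(self.batch_size, len(Xs)),
                learning_rate_init=self.learning_rate,
                max_iter=1,
                warm_start=True,
                random_state=self.seed,
                solver="adam",
            )
        else:
            raise ValueError(f"unknown preset {self.preset!r}")

        def val_acc():
            if val_feats is None:
                return float("nan")
            preds = np.argmax(self._proba_from_features(val_feats), axis=1)
            return float((preds == val_labels).mean())

        history = []
        if self.preset == "linear":
            self.net_.fit(Xs, labels)
            history.append({"epoch": 1, "loss": float("nan"),
                            "val_accuracy": val_acc()})
        else:
            import warnings
            for epoch in range(self.epochs):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")  # max_iter=1 convergence noise
                    self.net_.fit(Xs, labels)
                history.append({
                    "epoch": epoch + 1,
                    "loss": float(self.net_.loss_),
                    "val_accuracy": val_acc(),
                })
        self.classes_ = np.arange(N_CLASSES)
        self.history_ = pd.DataFrame(history)
        return self

    # -- inference ---------------------------------------------------------

    def _proba_from_features(self, feats):
        probs_fit = self.net_.predict_proba(self.scaler_.transform(feats))
        # expand to the full nine-class order if some classes were absent
        out = np.zeros((probs_fit.shape[0], N_CLASSES))
        out[:, self.net_.classes_] = probs_fit
        return out

    def predict_proba(self, X):
        """Per-class probabilities, shape (n, 9); rows sum to 1.

        Inference averages the softmax over a ``spatial_pooling`` x
        ``spatial_pooling`` grid of sub-patches (the analog of a CNN's
        spatial pooling): on pure patches this matches the full-patch
        prediction, while on mixed tiles it keeps the output close to
        area-proportional instead of collapsing onto one class.
        """
        check_is_fitted(self, "net_")
        patches = [_coerce_patch(p) for p in X]
        g = max(int(self.spatial_pooling), 1)
        if g == 1:
            return self._proba_from_features(batch_features(patches))
        step = PATCH_SIZE // g
        subs = []
        for p in patches:
            for i in range(g):
                for j in range(g):
                    subs.append(p[i * step : (i + 1) * step,
                                  j * step : (j + 1) * step])
        proba = self._proba_from_features(batch_features(subs))
        return proba.reshape(len(patches), g * g, N_CLASSES).mean(axis=1)

    def predict_activation(self, patch) -> np.ndarray:
        """Activation vector (length 9, sums to 1) for a single patch."""
        return self.predict_proba([patch])[0]

    def _predict_indices(self, X):
        return np.argmax(self.predict_proba(X), axis=1)

    def predict(self, X):
        return self._predict_indices(X)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Persist to `directory/model.joblib` + JSON sidecar."""
        check_is_fitted(self, "net_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump({"scaler": self.scaler_, "net": self.net_}, directory / "model.joblib")
        sidecar = {
            "class_order": list(CLASS_CODES),
            "preset": self.preset,
            "patch_size": PATCH_SIZE,
            "params": {
                "hidden_layer_sizes": list(self.hidden_layer_sizes),
                "batch_size": self.batch_size,
                "learning_rate": self.learning_rate,
                "epochs": self.epochs,
                "spatial_pooling": self.spatial_pooling,
                "seed": self.seed,
            },
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "TissueClassifier":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        if tuple(sidecar["class_order"]) != CLASS_CODES:
            raise ValueError("model sidecar class order does not match package order")
        obj = cls(preset=sidecar["preset"], **{
            k: tuple(v) if k == "hidden_layer_sizes" else v
            for k, v in sidecar["params"].items()
        })
        blobs = joblib.load(directory / "model.joblib")
        obj.scaler_ = blobs["scaler"]
        obj.net_ = blobs["net"]
        obj.classes_ = np.arange(N_CLASSES)
        obj.history_ = pd.DataFrame()
        return obj


# ---------------------------------------------------------------------------
# dataset splitting and evaluation


def split_dataset(labels, fractions=(0.70, 0.15, 0.15), seed: int = 0):
    """Stratified train/val/test index split.

    Per class, counts are apportioned to the fractions by largest
    remainder, so e.g. 100 patches/class at (0.7, 0.15, 0.15) give
    exactly 70/15/15.  Returns three index arrays.
    """
    f = np.asarray(fractions, float)
    if f.shape != (3,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 3 positive values summing to 1")
    labels = np.asarray(
        [CLASS_CODES.index(v) if isinstance(v, str) else int(v) for v in labels]
    )
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 3:
            raise ValueError(
                f"class {CLASS_CODES[c]} has {idx.size} patches; need >= 3"
            )
        rng.shuffle(idx)
        raw = f * idx.size
        counts = np.floor(raw).astype(int)
        rem = idx.size - counts.sum()
        counts[np.argsort(-(raw - counts))[:rem]] += 1
        n_tr, n_va, _ = counts
        train.append(idx[:n_tr])
        val.append(idx[n_tr : n_tr + n_va])
        test.append(idx[n_tr + n_va :])
    return (np.sort(np.concatenate(train)),
            np.sort(np.concatenate(val)),
            np.sort(np.concatenate(test)))


def evaluate(model, patches, labels):
    """Confusion matrix (9x9, rows = truth) and overall accuracy."""
    if len(patches) == 0:
        raise ValueError("empty evaluation set")
    labels = np.asarray([
        CLASS_CODES.index(v) if isinstance(v, str) else v for v in labels
    ], dtype=object)
    if any(v is None for v in labels):
        raise ValueError("unlabeled patch present in evaluation set")
    labels = labels.astype(int)
    preds = np.asarray(model.predict(patches))
    cm = _sk_confusion(labels, preds, labels=np.arange(N_CLASSES))
    accuracy = float(np.trace(cm)) / float(cm.sum())
    return cm, accuracy


@dataclass
class ClassifierMetrics:
    """Per-class ROC statistics over k random subsets.

    Each entry of ``per_class`` maps a metric name to a (median, p5,
    p95) triple; ``accuracy`` is the overall accuracy on the full set.
    """

    per_class: dict[str, dict[str, tuple[float, float, float]]]
    accuracy: float
    k: int

    def frame(self) -> pd.DataFrame:
        rows = []
        for code, metrics in self.per_class.items():
            for name, (med, p5, p95) in metrics.items():
                rows.append({"class": code, "metric": name,
                             "median": med, "p5": p5, "p95": p95})
        return pd.DataFrame(rows)


def _binary_rates(y_true, y_pred):
    tp = np.sum((y_true == 1) & (y_pred == 1))
    tn = np.sum((y_true == 0) & (y_pred == 0))
    fp = np.sum((y_true == 0) & (y_pred == 1))
    fn = np.sum((y_true == 1) & (y_pred == 0))
    div = lambda a, b: a / b if b > 0 else np.nan
    return (div(tp, tp + fn), div(tn, tn + fp), div(tp, tp + fp), div(tn, tn + fn))


def kfold_roc_stats(model, patches, labels, k: int = 25, seed: int = 0) -> ClassifierMetrics:
    """One-vs-rest ROC statistics over k random subsets.

    The labeled set is split into k random subsets; per subset and class
    the AUC (on the class's activation value), sensitivity, specificity,
    PPV and NPV (on argmax predictions) are computed, and the median /
    5th / 95th percentile over subsets is reported.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.asarray(
        [CLASS_CODES.index(v) if isinstance(v, str) else int(v) for v in labels]
    )
    counts = np.bincount(labels, minlength=N_CLASSES)
    low = [CLASS_CODES[c] for c in range(N_CLASSES) if 0 < counts[c] < k]
    if low:
        raise ValueError(f"classes with fewer than k={k} examples: {low}")

    proba = np.asarray(model.predict_proba(patches))
    preds = np.argmax(proba, axis=1)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    subsets = np.array_split(order, k)

    stats = {c: {m: [] for m in ("auc", "sensitivity", "specificity", "ppv", "npv")}
             for c in range(N_CLASSES)}
    for idx in subsets:
        y_s, p_s, prob_s = labels[idx], preds[idx], proba[idx]
        for c in range(N_CLASSES):
            y_bin = (y_s == c).astype(int)
            if 0 < y_bin.sum() < len(y_bin):
                stats[c]["auc"].append(roc_auc_score(y_bin, prob_s[:, c]))
            sens, spec, ppv, npv = _binary_rates(y_bin, (p_s == c).astype(int))
            stats[c]["sensitivity"].append(sens)
            stats[c]["specificity"].append(spec)
            stats[c]["ppv"].append(ppv)
            stats[c]["npv"].append(npv)

    per_class = {}
    for c in range(N_CLASSES):
        if counts[c] == 0:
            continue
        entry = {}
        for m, vals in stats[c].items():
            vals = np.asarray(vals, dtype=float)
            if np.all(np.isnan(vals)) or vals.size == 0:
                entry[m] = (np.nan, np.nan, np.nan)
            else:
                entry[m] = tuple(np.nanpercentile(vals, [50, 5, 95]))
        per_class[CLASS_CODES[c]] = entry

    accuracy = float((preds == labels).mean())
    return ClassifierMetrics(per_class=per_class, accuracy=accuracy, k=k)
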