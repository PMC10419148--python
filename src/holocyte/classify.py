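"""Cell-level classifiers: logistic regression on morphological parameters
and a small CNN on phase-image crops.

Each model family is trained in two variants: ALL (unrefined donor-status
labels) and SEL (the refined training set from the selective search). The
training protocol is shared: ``repeats`` stratified 90/10 train/validation
splits, per-split sensitivity (SCD positive), specificity and accuracy, with
means and standard deviations reported across repeats, then a final refit on
all data. ROC/AUC is computed on the pooled validation scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.measure import block_reduce
from skimage.transform import resize
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from ._cnn import SimpleCNN
from .exceptions import ConfigurationError
from .morphometry import FEATURE_NAMES, PhaseImage

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "TrainedModel",
    "SamplePrediction",
    "train_logistic",
    "train_cnn",
    "predict_cells",
    "roc_auc",
    "evaluate_sample",
    "prepare_cnn_inputs",
]

POSITIVE_LABEL = "SCD"


@dataclass(frozen=True)
class TrainConfig:
    """Shared training protocol plus per-model hyperparameters.

    train_fraction: fraction of cells used for fitting in each repeat.
    repeats: number of independent stratified splits averaged over.
    l2_c: inverse L2 strength for logistic regression (sklearn's C).
    cnn_*: architecture/optimization settings for the CNN variant;
    phase_cap_rad: phase value mapped to 1.0 when scaling image inputs.
    """

    train_fraction: float = 0.9
    repeats: int = 5
    seed: int = 0
    l2_c: float = 1.0
    cnn_input_side: int = 32
    cnn_channels: tuple[int, ...] = (16, 32, 64)
    cnn_epochs: int = 6
    cnn_batch_size: int = 64
    cnn_lr: float = 1e-3
    phase_cap_rad: float = 2.5

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")


@dataclass
class MetricsReport:
    """Validation metrics averaged over repeated splits (percent scale)."""

    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    accuracy_mean: float
    accuracy_sd: float
    roc_points: list[tuple[float, float]]
    auc: float
    n_train: int
    n_val: int

    def as_dict(self) -> dict:
        return {
            "sensitivity_pct": [self.sensitivity_mean, self.sensitivity_sd],
            "specificity_pct": [self.specificity_mean, self.specificity_sd],
            "accuracy_pct": [self.accuracy_mean, self.accuracy_sd],
            "auc": self.auc,
            "n_train": self.n_train,
            "n_val": self.n_val,
        }


@dataclass
class TrainedModel:
    """A fitted classifier with the schema it expects and its provenance."""

    kind: str  # "LR" | "CNN"
    estimator: object
    schema: tuple  # feature names (LR) or (input_side,) (CNN)
    provenance: dict


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ConfigurationError("both classes must be present in the labels")
    if classes.size > 2:
        raise ConfigurationError(f"expected binary labels, got {classes}")
    return y


def _split_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in percent; SCD/1 is positive."""
    pos = y_true == 1
    neg = ~pos
    sens = 100.0 * np.mean(y_pred[pos] == 1) if pos.any() else np.nan
    spec = 100.0 * np.mean(y_pred[neg] == 0) if neg.any() else np.nan
    acc = 100.0 * np.mean(y_pred == y_true)
    return sens, spec, acc


def _repeat_protocol(fit_score, x, y, config: TrainConfig):
    """Run the repeated stratified split protocol.

    ``fit_score(x_tr, y_tr, x_va, seed) -> scores_va`` fits a fresh model and
    returns validation scores in [0, 1].
    """
    sens, spec, acc = [], [], []
    pooled_scores, pooled_labels = [], []
    n_train = n_val = 0
    for rep in range(config.repeats):
        idx_tr, idx_va = train_test_split(
            np.arange(len(y)),
            train_size=config.train_fraction,
            stratify=y,
            random_state=(config.seed + rep) % (2**31 - 1),
        )
        scores = fit_score(x[idx_tr], y[idx_tr], x[idx_va], config.seed + rep)
        pred = (scores > 0.5).astype(int)
        s, p, a = _split_metrics(y[idx_va], pred)
        sens.append(s)
        spec.append(p)
        acc.append(a)
        pooled_scores.append(scores)
        pooled_labels.append(y[idx_va])
        n_train, n_val = len(idx_tr), len(idx_va)
    points, auc = roc_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
    return MetricsReport(
        sensitivity_mean=float(np.mean(sens)),
        sensitivity_sd=float(np.std(sens)),
        specificity_mean=float(np.mean(spec)),
        specificity_sd=float(np.std(spec)),
        accuracy_mean=float(np.mean(acc)),
        accuracy_sd=float(np.std(acc)),
        roc_points=points,
        auc=auc,
        n_train=n_train,
        n_val=n_val,
    )


def _lr_pipeline(config: TrainConfig, seed: int) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "lr",
                LogisticRegression(C=config.l2_c, max_iter=2000, random_state=seed % (2**31 - 1)),
            ),
        ]
    )


def train_logistic(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence,
    config: TrainConfig | None = None,
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> tuple[TrainedModel, MetricsReport]:
    """Train the logistic-regression classifier on 25-parameter vectors.

    Features are standardized internally (scaler fit on each training split
    only). Labels may be "SCD"/"NOR" strings or 1/0 integers.
    """
    config = config or TrainConfig()
    if isinstance(features, pd.DataFrame):
        x = features[list(feature_names)].to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(x).all(axis=1))[0])
        raise ConfigurationError(f"non-finite features at cell row {bad}")
    y = _encode_labels(labels)
    _check_labels(y)

    def fit_score(x_tr, y_tr, x_va, seed):
        pipe = _lr_pipeline(config, seed)
        pipe.fit(x_tr, y_tr)
        return pipe.predict_proba(x_va)[:, 1]

    report = _repeat_protocol(fit_score, x, y, config)
    final = _lr_pipeline(config, config.seed)
    final.fit(x, y)
    model = TrainedModel(
        kind="LR",
        estimator=final,
        schema=tuple(feature_names),
        provenance={"seed": config.seed, "repeats": config.repeats, "n": len(y)},
    )
    return model, report


def prepare_cnn_inputs(
    images: Sequence, config: TrainConfig | None = None
) -> np.ndarray:
    """Resample phase crops to the CNN input side and scale to [0, 1].

    Accepts :class:`PhaseImage` objects or bare 2-D arrays. Downsampling by an
    integer factor uses block averaging; otherwise bilinear resampling.
    Phase is clipped to [0, phase_cap_rad] and divided by the cap.
    """
    config = config or TrainConfig()
    side = config.cnn_input_side
    out = np.empty((len(images), side, side), dtype=np.float64)
    for i, im in enumerate(images):
        arr = im.phase if isinstance(im, PhaseImage) else np.asarray(im, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ConfigurationError(f"image {i}: expected a square 2-D crop, got {arr.shape}")
        if arr.shape[0] == side:
            res = arr
        elif arr.shape[0] % side == 0:
            f = arr.shape[0] // side
            res = block_reduce(arr, (f, f), np.mean)
        else:
            res = resize(arr, (side, side), anti_aliasing=True, preserve_range=True)
        out[i] = np.clip(res, 0.0, config.phase_cap_rad) / config.phase_cap_rad
    return out


def train_cnn(
    images: Sequence,
    labels: Sequence,
    config: TrainConfig | None = None,
) -> tuple[TrainedModel, MetricsReport]:
    """Train the CNN classifier on phase-image crops.

    Same split/repeat/metric protocol as :func:`train_logistic`.
    """
    config = config or TrainConfig()
    x = images if isinstance(images, np.ndarray) and images.ndim == 3 and \
        images.shape[1] == config.cnn_input_side else prepare_cnn_inputs(images, config)
    y = _encode_labels(labels)
    _check_labels(y)
    if len(x) != len(y):
        raise ConfigurationError("images and labels differ in length")

    def fit_score(x_tr, y_tr, x_va, seed):
        net = SimpleCNN(config.cnn_input_side, config.cnn_channels, seed=seed % (2**31 - 1))
        net.fit(
            x_tr,
            y_tr,
            epochs=config.cnn_epochs,
            batch_size=config.cnn_batch_size,
            lr=config.cnn_lr,
            seed=(seed + 7919) % (2**31 - 1),
        )
        return net.predict_proba(x_va)

    report = _repeat_protocol(fit_score, x, y, config)
    final = SimpleCNN(config.cnn_input_side, config.cnn_channels, seed=config.seed % (2**31 - 1))
    final.fit(
        x,
        y,
        epochs=config.cnn_epochs,
        batch_size=config.cnn_batch_size,
        lr=config.cnn_lr,
        seed=(config.seed + 7919) % (2**31 - 1),
    )
    model = TrainedModel(
        kind="CNN",
        estimator=final,
        schema=(config.cnn_input_side,),
        provenance={"seed": config.seed, "repeats": config.repeats, "n": len(y),
                    "phase_cap_rad": config.phase_cap_rad},
    )
    return model, report


def _encode_labels(labels: Sequence) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "UO":
        return (labels == POSITIVE_LABEL).astype(int)
    return labels.astype(int)


def predict_cells(
    model: TrainedModel, data, config: TrainConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Score cells with a trained model.

    Returns ``(scores, hard_labels)`` where the hard label is SCD (1) iff the
    score strictly exceeds 0.5.
    """
    if model.kind == "LR":
        if isinstance(data, pd.DataFrame):
            missing = [c for c in model.schema if c not in data.columns]
            if missing:
                raise ConfigurationError(f"feature table lacks columns {missing}")
            x = data[list(model.schema)].to_numpy(dtype=float)
        else:
            x = np.asarray(data, dtype=float)
            if x.shape[1] != len(model.schema):
                raise ConfigurationError(
                    f"expected {len(model.schema)} features, got {x.shape[1]}"
                )
        scores = model.estimator.predict_proba(x)[:, 1]
    elif model.kind == "CNN":
        side = model.schema[0]
        cfg = config or TrainConfig(
            cnn_input_side=side,
            phase_cap_rad=model.provenance.get("phase_cap_rad", 2.5),
        )
        x = data if isinstance(data, np.ndarray) and data.ndim == 3 and \
            data.shape[1] == side else prepare_cnn_inputs(data, cfg)
        scores = model.estimator.predict_proba(x)
    else:
        raise ConfigurationError(f"unknown model kind {model.kind!r}")
    if not np.all(np.isfinite(scores)):
        raise ConfigurationError("model produced non-finite scores")
    return scores, (scores > 0.5).astype(int)


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC curve (all score thresholds) and trapezoidal AUC.

    The AUC equals the pairwise-concordance probability that a random SCD
    cell outscores a random normal cell, with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    y = _encode_labels(labels)
    _check_labels(y)
    fpr, tpr, _ = roc_curve(y, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


@dataclass
class SamplePrediction:
    """Cell-count percentages predicted for one sample."""

    sample_id: str
    pct_normal: float
    pct_scd: float
    n_cells: int


def evaluate_sample(
    model: TrainedModel, data, sample_id: str = "", config: TrainConfig | None = None
) -> SamplePrediction:
    """Predicted percent-normal / percent-SCD for one sample's cells."""
    if isinstance(data, pd.DataFrame):
        n = len(data)
    else:
        n = len(data)
    if n == 0:
        raise ConfigurationError("sample is empty")
    _, hard = predict_cells(model, data, config)
    pct_scd = 100.0 * float(np.mean(hard))
    return SamplePrediction(
        sample_id=sample_id, pct_normal=100.0 - pct_scd, pct_scd=pct_scd, n_cells=n
    )
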