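"""Fully connected regression network mapping section features to resistance.

A small multilayer perceptron (default hidden layers 256/64/16/4, ReLU,
linear output) maps the 8 dimensionless section features to the per-segment
flow resistance coefficient.  Training minimizes a mean-squared loss with an
L2 weight penalty using mini-batch Nadam (Nesterov-accelerated Adam);
inverted dropout after each hidden layer is active only during training
passes, so inference is deterministic.  Inputs are standardized with
zero-mean normalization whose statistics are fitted on the training split
only.

The implementation is plain numpy: the network is small enough that a full
training run is a few tens of seconds on one CPU, and keeping the forward /
backward pass explicit makes the optimizer and regularization exactly the
documented ones.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .geometry import FEATURE_COLUMNS

__all__ = [
    "DNNConfig",
    "Normalizer",
    "TrainedModel",
    "CVReport",
    "TrainingFailureError",
    "split_data",
    "kfold_cross_validate",
    "train_final",
    "predict_fr",
    "evaluate_mae",
    "save_model",
    "load_model",
]


class TrainingFailureError(RuntimeError):
    def __init__(self, message: str, epoch: int):
        super().__init__(message)
        self.epoch = epoch


@dataclass(frozen=True)
class DNNConfig:
    """Architecture and training hyperparameters.

    ``hidden_layers`` may be empty, which degenerates to a linear model
    (useful for sanity checks against ordinary least squares).
    """

    hidden_layers: tuple[int, ...] = (256, 64, 16, 4)
    dropout_rate: float = 0.2
    activation_hidden: str = "relu"
    optimizer: str = "nadam"
    epochs: int = 20000
    batch_size: int = 256
    l2_lambda: float = 1e-4
    learning_rate: float = 1e-3
    final_learning_rate: float = 1e-5  # cosine-decayed to over the epochs
    init_std: float = 0.05
    seed: int = 0
    k_folds: int = 5
    test_fraction: float = 0.2

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 2 <= self.k_folds <= 10:
            raise ValueError("k_folds must be between 2 and 10")
        if self.activation_hidden != "relu":
            raise ValueError("only ReLU hidden activation is supported")
        if self.optimizer != "nadam":
            raise ValueError("only the Nadam optimizer is supported")
        if not 0.0 <= self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in [0, 1)")


@dataclass
class Normalizer:
    """Zero-mean / unit-variance feature standardization."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Normalizer":
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        if np.any(std <= 0):
            bad = list(np.flatnonzero(std <= 0))
            raise ValueError(f"constant feature column(s) {bad}: cannot standardize")
        return cls(mean=mean, std=std)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.std + self.mean


@dataclass
class TargetScale:
    """Zero-mean standardization of the regression target.

    The network is trained on the standardized target and predictions are
    mapped back, so callers always see physical resistance units; this keeps
    the optimizer's step size well matched to the output scale regardless of
    the corpus' resistance magnitude.
    """

    mean: float
    std: float

    @classmethod
    def fit(cls, y: np.ndarray) -> "TargetScale":
        std = float(y.std())
        return cls(mean=float(y.mean()), std=std if std > 0 else 1.0)

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (y - self.mean) / self.std

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return y * self.std + self.mean


class _Nadam:
    """Nesterov-accelerated Adam (Dozat) on a flat list of arrays."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            # dead units decay the moments into the subnormal range, which
            # cripples x86 throughput; flush to zero well above that range
            m[np.abs(m) < 1e-24] = 0.0
            v[v < 1e-30] = 0.0
            m_hat = m / c1
            v_hat = v / c2
            p -= self.lr * (b1 * m_hat + (1.0 - b1) * g / c1) / (
                np.sqrt(v_hat) + self.eps
            )
            p[np.abs(p) < 1e-20] = 0.0


def _init_layers(
    n_in: int, config: DNNConfig, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    sizes = [n_in, *config.hidden_layers, 1]
    # float32 throughout training: halves the matmul cost at no measurable
    # accuracy loss for a regression head of this size
    weights = [
        rng.normal(0.0, config.init_std, size=(sizes[i], sizes[i + 1])).astype(
            np.float32
        )
        for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[i + 1], dtype=np.float32) for i in range(len(sizes) - 1)]
    return weights, biases


def _forward(
    X: np.ndarray,
    weights: list[np.ndarray],
    biases: list[np.ndarray],
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """Forward pass; returns output and the per-layer cache for backprop."""
    a = X
    cache = []
    n_hidden = len(weights) - 1
    for k in range(n_hidden):
        z = a @ weights[k] + biases[k]
        h = np.maximum(z, 0.0)
        if dropout_rate > 0.0 and rng is not None:
            mask = (
                rng.random(h.shape, dtype=np.float32) >= dropout_rate
            ).astype(np.float32) / np.float32(1.0 - dropout_rate)
            h = h * mask
        else:
            mask = None
        cache.append((a, z, mask))
        a = h
    out = a @ weights[-1] + biases[-1]
    cache.append((a, None, None))
    return out[:, 0], cache


def _backward(
    d_out: np.ndarray,
    weights: list[np.ndarray],
    cache,
    l2_lambda: float,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    grads_w = [None] * len(weights)
    grads_b = [None] * len(weights)
    delta = d_out[:, None]
    a_last = cache[-1][0]
    grads_w[-1] = a_last.T @ delta + 2.0 * l2_lambda * weights[-1]
    grads_b[-1] = delta.sum(axis=0)
    d_a = delta @ weights[-1].T
    for k in range(len(weights) - 2, -1, -1):
        a_prev, z, mask = cache[k]
        if mask is not None:
            d_a = d_a * mask
        d_z = d_a * (z > 0.0)
        grads_w[k] = a_prev.T @ d_z + 2.0 * l2_lambda * weights[k]
        grads_b[k] = d_z.sum(axis=0)
        if k > 0:
            d_a = d_z @ weights[k].T
    return grads_w, grads_b


@dataclass
class TrainedModel:
    """Frozen normalizer + network weights; prediction is deterministic."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    normalizer: Normalizer
    config: DNNConfig
    target_scale: TargetScale = field(default_factory=lambda: TargetScale(0.0, 1.0))
    metadata: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        X = _coerce_features(X)
        if X.shape[1] != self.weights[0].shape[0]:
            raise ValueError(
                f"expected {self.weights[0].shape[0]} feature columns, got {X.shape[1]}"
            )
        out, _ = _forward(self.normalizer.transform(X), self.weights, self.biases)
        return self.target_scale.inverse(out)


def _coerce_features(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        cols = [c for c in FEATURE_COLUMNS if c in X.columns]
        X = X[cols].to_numpy() if len(cols) == len(FEATURE_COLUMNS) else X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    return X


def _records_to_xy(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = records[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = records["fr_target"].to_numpy(dtype=float)
    return X, y


def split_data(
    records: pd.DataFrame, test_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reproducible train/test split.

    When a ``shape_id`` column is present the split is stratified by shape
    so that sections of one shape never straddle the split (whole shapes are
    assigned to the test set); otherwise rows are split individually.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records to split")
    rng = np.random.default_rng(seed)
    if test_fraction == 0:
        return records.copy(), records.iloc[0:0].copy()
    if "shape_id" in records.columns:
        shapes = records["shape_id"].unique()
        shapes = rng.permutation(shapes)
        n_test = max(int(round(test_fraction * shapes.size)), 1)
        test_shapes = set(shapes[:n_test].tolist())
        mask = records["shape_id"].isin(test_shapes)
    else:
        idx = rng.permutation(len(records))
        n_test = int(round(test_fraction * len(records)))
        mask = np.zeros(len(records), dtype=bool)
        mask[idx[:n_test]] = True
    return records[~np.asarray(mask)].copy(), records[np.asarray(mask)].copy()


def _train_network(
    X: np.ndarray,
    y: np.ndarray,
    config: DNNConfig,
    rng: np.random.Generator,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
):
    """Core training loop; returns weights, biases and per-epoch MAE curves.

    The training-history MAE is the running mini-batch MAE with dropout
    active (as during optimization); the validation history is evaluated
    deterministically each epoch, which is why it typically sits below the
    training curve.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    y = np.ascontiguousarray(y, dtype=np.float32)
    if X_val is not None:
        X_val = np.ascontiguousarray(X_val, dtype=np.float32)
        y_val = np.ascontiguousarray(y_val, dtype=np.float32)
    weights, biases = _init_layers(X.shape[1], config, rng)
    opt = _Nadam(weights + biases, lr=config.learning_rate)
    n = X.shape[0]
    batch = min(config.batch_size, n)
    train_hist = np.empty(config.epochs)
    val_hist = np.empty(config.epochs) if X_val is not None else None
    lr0, lr1 = config.learning_rate, min(config.final_learning_rate, config.learning_rate)
    for epoch in range(config.epochs):
        # cosine learning-rate decay averages out dropout gradient noise
        frac = epoch / max(config.epochs - 1, 1)
        opt.lr = lr1 + 0.5 * (lr0 - lr1) * (1.0 + np.cos(np.pi * frac))
        order = rng.permutation(n)
        abs_err_sum = 0.0
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            xb, yb = X[idx], y[idx]
            out, cache = _forward(
                xb, weights, biases, dropout_rate=config.dropout_rate, rng=rng
            )
            err = out - yb
            abs_err_sum += float(np.abs(err).sum())
            d_out = 2.0 * err / xb.shape[0]
            gw, gb = _backward(d_out, weights, cache, config.l2_lambda)
            opt.step(gw + gb)
        train_hist[epoch] = abs_err_sum / n
        if not np.isfinite(train_hist[epoch]):
            raise TrainingFailureError(
                f"loss diverged (non-finite) at epoch {epoch}", epoch
            )
        if X_val is not None:
            out_val, _ = _forward(X_val, weights, biases)
            val_hist[epoch] = float(np.mean(np.abs(out_val - y_val)))
    return weights, biases, train_hist, val_hist


@dataclass
class CVReport:
    """Per-fold MAE histories and summary statistics of k-fold CV."""

    fold_train_mae: np.ndarray  # (k, epochs)
    fold_val_mae: np.ndarray  # (k, epochs)
    mean_final_val_mae: float
    test_mae: float | None = None
    relative_mae: float | None = None


def kfold_cross_validate(records: pd.DataFrame, config: DNNConfig) -> CVReport:
    """k rotations of train/validation with per-epoch MAE curves.

    Dropout is active in training passes and disabled when evaluating on the
    validation fold.  Folds smaller than the batch size shrink the batch.
    """
    X, y = _records_to_xy(records)
    k = config.k_folds
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(records))
    folds = np.array_split(idx, k)
    train_hists, val_hists = [], []
    for f in range(k):
        val_idx = folds[f]
        tr_idx = np.concatenate([folds[j] for j in range(k) if j != f])
        norm = Normalizer.fit(X[tr_idx])
        scale = TargetScale.fit(y[tr_idx])
        fold_rng = np.random.default_rng([config.seed, f])
        _, _, tr_h, va_h = _train_network(
            norm.transform(X[tr_idx]),
            scale.transform(y[tr_idx]),
            config,
            fold_rng,
            X_val=norm.transform(X[val_idx]),
            y_val=scale.transform(y[val_idx]),
        )
        train_hists.append(tr_h * scale.std)  # histories in physical units
        val_hists.append(va_h * scale.std)
    fold_train = np.vstack(train_hists)
    fold_val = np.vstack(val_hists)
    return CVReport(
        fold_train_mae=fold_train,
        fold_val_mae=fold_val,
        mean_final_val_mae=float(fold_val[:, -1].mean()),
    )


def train_final(records: pd.DataFrame, config: DNNConfig) -> TrainedModel:
    """Train on the full training set with a normalizer fitted on it alone."""
    X, y = _records_to_xy(records)
    norm = Normalizer.fit(X)
    scale = TargetScale.fit(y)
    rng = np.random.default_rng(config.seed)
    weights, biases, tr_h, _ = _train_network(
        norm.transform(X), scale.transform(y), config, rng
    )
    model = TrainedModel(
        weights=weights,
        biases=biases,
        normalizer=norm,
        config=config,
        target_scale=scale,
        metadata={"final_train_mae": float(tr_h[-1] * scale.std), "seed": config.seed},
    )
    return model


def predict_fr(model: TrainedModel, features) -> np.ndarray:
    """Per-segment resistance coefficients for a feature matrix (n x 8)."""
    X = _coerce_features(features)
    if X.shape[1] != len(FEATURE_COLUMNS):
        raise ValueError(f"expected {len(FEATURE_COLUMNS)} feature columns")
    return model.predict(X)


def evaluate_mae(model: TrainedModel, records: pd.DataFrame) -> tuple[float, float]:
    """(MAE, MAE / mean target) of the model on a record table."""
    if len(records) == 0:
        raise ValueError("records must be nonempty")
    X, y = _records_to_xy(records)
    pred = model.predict(X)
    mae = float(np.mean(np.abs(pred - y)))
    mean_y = float(np.mean(y))
    relative = mae / mean_y if mean_y != 0 else float("nan")
    return mae, relative


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model as a single .npz archive (weights + JSON)."""
    meta = {
        "config": {**asdict(model.config), "hidden_layers": list(model.config.hidden_layers)},
        "metadata": model.metadata,
        "n_layers": len(model.weights),
        "target_scale": [model.target_scale.mean, model.target_scale.std],
    }
    arrays = {"norm_mean": model.normalizer.mean, "norm_std": model.normalizer.std}
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        arrays[f"w{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        n = meta["n_layers"]
        weights = [data[f"w{i}"] for i in range(n)]
        biases = [data[f"b{i}"] for i in range(n)]
        norm = Normalizer(mean=data["norm_mean"], std=data["norm_std"])
    cfg = meta["config"]
    cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
    ts = meta.get("target_scale", [0.0, 1.0])
    return TrainedModel(
        weights=weights,
        biases=biases,
        normalizer=norm,
        config=DNNConfig(**cfg),
        target_scale=TargetScale(*ts),
        metadata=meta["metadata"],
    )
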