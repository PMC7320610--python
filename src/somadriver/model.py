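"""Single-kernel classifier over concatenated feature groups.

The learner is a support-vector machine with an RBF kernel (linear
available), preceded by train-fold standardization and followed by a
monotone sigmoid calibration that maps decision values onto [0, 1].  The
decision convention is fixed throughout the package: scores at or above 0.5
are labeled "+" (putative driver), scores below 0.5 are labeled "-".

Everything the model learns — imputation values, standardization statistics,
kernel state and the calibration map — is estimated from training rows only.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.svm import SVC

from .dataset import ConfigError, DegenerateDataError


@dataclass
class KernelModelConfig:
    kernel: str = "rbf"
    bandwidth: Union[float, str] = "median-heuristic"
    regularization: float = 1.0
    standardize: bool = True
    calibration: str = "sigmoid-fit"
    seed: int = 0

    def __post_init__(self):
        if self.kernel not in {"rbf", "linear"}:
            raise ConfigError(f"kernel must be rbf|linear, got {self.kernel!r}")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "median-heuristic":
                raise ConfigError(f"unknown bandwidth {self.bandwidth!r}")
        elif self.bandwidth <= 0:
            raise ConfigError("bandwidth must be positive")
        if self.regularization <= 0:
            raise ConfigError("regularization must be positive")
        if self.calibration not in {"sigmoid-fit", "none"}:
            raise ConfigError(f"unknown calibration {self.calibration!r}")


def standardize_fit(X_train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column means and population SDs of the training matrix.

    Constant columns get SD 1 (with a warning) so the transform maps them to
    all-zero instead of dividing by zero.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.size == 0:
        raise DegenerateDataError("cannot standardize an empty matrix")
    if not np.all(np.isfinite(X_train)):
        raise ValueError("standardization input must be finite (impute first)")
    means = X_train.mean(axis=0)
    sds = X_train.std(axis=0)  # population (ddof=0) convention
    if np.any(sds == 0):
        warnings.warn("constant feature column(s); SD set to 1")
        sds = np.where(sds == 0, 1.0, sds)
    return means, sds


def _median_bandwidth(X: np.ndarray, seed: int, max_rows: int = 500) -> float:
    """Median pairwise Euclidean distance on (a subsample of) the rows."""
    rng = np.random.default_rng(seed)
    if X.shape[0] > max_rows:
        X = X[rng.choice(X.shape[0], size=max_rows, replace=False)]
    d = pdist(X)
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    return float(np.median(d))


@dataclass
class TrainedModel:
    """Fitted kernel machine plus all train-side statistics."""

    config: KernelModelConfig
    means: np.ndarray
    sds: np.ndarray
    svc: SVC
    calib_a: float  # score = sigmoid(a * decision + b); a >= 0 (monotone)
    calib_b: float
    gamma: float
    n_features: int

    def digest(self) -> str:
        """Stable digest of the fitted state, for determinism/leakage checks."""
        h = hashlib.sha256()
        for arr in (
            self.means,
            self.sds,
            np.asarray([self.calib_a, self.calib_b, self.gamma]),
            self.svc.dual_coef_,
            self.svc.support_vectors_,
            self.svc.intercept_,
        ):
            h.update(np.ascontiguousarray(arr, dtype=float).tobytes())
        return h.hexdigest()


def fit(X: np.ndarray, y: np.ndarray, cfg: KernelModelConfig) -> TrainedModel:
    """Fit the kernel machine on labels in {-1, +1}.

    Deterministic for fixed (X, y, cfg): the SVC dual problem has no random
    component at these scales and the bandwidth subsample is seeded from the
    config.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y are misaligned")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite (impute first)")
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [-1, 1]):
        raise DegenerateDataError(f"need both classes -1/+1, got {classes}")

    if cfg.standardize:
        means, sds = standardize_fit(X)
    else:
        means = np.zeros(X.shape[1])
        sds = np.ones(X.shape[1])
    Z = (X - means) / sds

    if cfg.kernel == "rbf":
        if cfg.bandwidth == "median-heuristic":
            bw = _median_bandwidth(Z, cfg.seed)
        else:
            bw = float(cfg.bandwidth)
        gamma = 1.0 / (2.0 * bw * bw)
        svc = SVC(kernel="rbf", gamma=gamma, C=cfg.regularization)
    else:
        gamma = 0.0
        svc = SVC(kernel="linear", C=cfg.regularization)
    svc.fit(Z, y)

    f_train = svc.decision_function(Z)
    if cfg.calibration == "sigmoid-fit":
        a, b = _fit_sigmoid(f_train, y)
    else:
        # squash decision values through a fixed unit-slope sigmoid
        a, b = 1.0, 0.0
    return TrainedModel(cfg, means, sds, svc, a, b, gamma, X.shape[1])


def _fit_sigmoid(f: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt-style sigmoid p(+1|f) = 1/(1+exp(-(a f + b))) by logistic
    regression on the training decision values.

    The slope is clamped at zero so the calibration map is monotone
    non-decreasing; in the clamped (signal-free) case the intercept encodes
    the training positive rate.
    """
    from sklearn.linear_model import LogisticRegression

    pos_rate = float(np.mean(y == 1))
    if np.ptp(f) == 0:
        return 0.0, _logit(pos_rate)
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(f.reshape(-1, 1), (y == 1).astype(int))
    a = float(lr.coef_[0, 0])
    b = float(lr.intercept_[0])
    if a < 0:
        return 0.0, _logit(pos_rate)
    return a, b


def _logit(p: float, eps: float = 1e-12) -> float:
    p = min(max(p, eps), 1 - eps)
    return float(np.log(p / (1 - p)))


def predict_score(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Calibrated scores in [0, 1], one per row."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} feature columns, got {X.shape}"
        )
    Z = (X - model.means) / model.sds
    f = model.svc.decision_function(Z)
    return 1.0 / (1.0 + np.exp(-(model.calib_a * f + model.calib_b)))


def predict_label(scores: np.ndarray) -> np.ndarray:
    """+1 at score >= 0.5 (ties positive), -1 below."""
    return np.where(np.asarray(scores) >= 0.5, 1, -1)


MODEL_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path, groups: list[str] | None = None) -> None:
    """Serialize a fitted model (config + statistics + kernel state)."""
    import pickle

    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": model.config,
        "groups": groups or [],
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> tuple[TrainedModel, list[str]]:
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format {payload.get('format_version')}")
    return payload["model"], payload["groups"]
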