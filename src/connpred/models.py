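"""Regression models: ordinary linear regression and linear-kernel SVR.

Deliberately simple models for an n ~ 40 cohort.  Features are z-scored by
training statistics stored in the model; the target is centred (not scaled)
so predictions come back on the 0-100 behavioural scale.  The SVR epsilon
is specified in standardized-target units (multiples of the training-score
SD) so the same grid is meaningful whatever the score spread.

``gamma`` appears in configuration for fidelity with common SVR parameter
sets, but a linear kernel has no gamma: it is accepted, logged, and ignored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.svm import SVR as _SkSVR

logger = logging.getLogger(__name__)

__all__ = ["ModelSpec", "TrainedModel", "fit", "predict", "svr_objective"]


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit.  ``kind`` is "LR" or "SVR"."""

    kind: str = "LR"
    C: float = 1.0
    epsilon: float = 0.1  # in training-score SD units
    gamma: float | None = None

    def __post_init__(self):
        if self.kind not in ("LR", "SVR"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")

    def sort_key(self):
        return (self.C, self.epsilon)


@dataclass
class TrainedModel:
    weights: np.ndarray  # in standardized-feature space
    intercept: float
    spec: ModelSpec
    feature_indices: list[int]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "weights": self.weights.tolist(),
                "intercept": self.intercept,
                "spec": asdict(self.spec),
                "feature_indices": list(map(int, self.feature_indices)),
                "x_mean": self.x_mean.tolist(),
                "x_sd": self.x_sd.tolist(),
                "y_mean": self.y_mean,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        return cls(
            weights=np.array(d["weights"]),
            intercept=float(d["intercept"]),
            spec=ModelSpec(**d["spec"]),
            feature_indices=list(d["feature_indices"]),
            x_mean=np.array(d["x_mean"]),
            x_sd=np.array(d["x_sd"]),
            y_mean=float(d["y_mean"]),
        )


def fit(X: np.ndarray, y: np.ndarray, spec: ModelSpec,
        feature_indices: list[int] | None = None) -> TrainedModel:
    """Fit LR (minimum-norm least squares) or linear-kernel epsilon-SVR.

    LR uses the pseudoinverse solution, which is the ordinary least-squares
    fit when p < n and the minimum-norm interpolator when p >= n.  SVR
    minimises ½||w||² + C·Σ max(0, |yᵢ − (w·xᵢ + b)| − ε).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p == 0:
        raise ValueError(
            "empty feature set: no model can be fit; the caller must handle "
            "zero-feature folds (e.g. predict the training mean)"
        )
    if n < 2:
        raise ValueError("need at least 2 training subjects")
    if feature_indices is None:
        feature_indices = list(range(p))

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    dead = sd == 0
    if dead.any():
        logger.warning("fit: %d zero-variance feature(s); left at zero weight", dead.sum())
    sd_safe = np.where(dead, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, dead] = 0.0
    y_mean = float(y.mean())
    yc = y - y_mean

    if spec.kind == "LR":
        # Z columns and yc are centred, so the OLS intercept is exactly 0;
        # lstsq gives OLS for p < n and the minimum-norm solution for p >= n
        weights, *_ = np.linalg.lstsq(Z, yc, rcond=None)
        intercept = 0.0
    else:
        if spec.gamma is not None:
            logger.info("SVR with linear kernel: gamma=%s is ignored", spec.gamma)
        y_sd = float(yc.std())
        eps_eff = spec.epsilon * (y_sd if y_sd > 0 else 1.0)
        svr = _SkSVR(kernel="linear", C=spec.C, epsilon=eps_eff, tol=1e-5, max_iter=-1)
        svr.fit(Z, yc)
        weights = svr.coef_.ravel().astype(float)
        intercept = float(svr.intercept_[0])

    return TrainedModel(
        weights=np.asarray(weights, dtype=float),
        intercept=intercept,
        spec=spec,
        feature_indices=list(feature_indices),
        x_mean=mu,
        x_sd=sd_safe,
        y_mean=y_mean,
    )


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Apply stored standardization and the linear form; deterministic."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.weights.size:
        raise ValueError(
            f"feature count mismatch: model has {model.weights.size}, input has {X.shape[1]}"
        )
    Z = (X - model.x_mean) / model.x_sd
    return Z @ model.weights + model.intercept + model.y_mean


def svr_objective(Z: np.ndarray, yc: np.ndarray, w: np.ndarray, b: float,
                  C: float, epsilon: float) -> float:
    """Primal epsilon-SVR objective; used to compare solvers."""
    r = np.abs(yc - (Z @ w + b)) - epsilon
    return 0.5 * float(w @ w) + C * float(np.clip(r, 0.0, None).sum())
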