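"""Randomized-LASSO stability selection.

The feature-engineering step for p >> n edge features: repeatedly subsample
subjects, randomly reweight each feature's L1 penalty (the "weakness" of
the randomized LASSO), fit the LASSO path, and record which features ever
enter the model.  A feature's *selection frequency* is the fraction of
resamples in which it was selected; the sparse feature set is everything at
or above a frequency threshold π.  Randomly reweighting the penalty spreads
selection across groups of correlated predictors instead of letting one
member win every resample, which is what makes the frequencies meaningful
for strongly correlated connectome edges.

Within each resample, features are z-scored and the response centred using
that resample's subjects only, so the procedure never touches held-out
statistics when called inside cross-validation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from ._lars import active_at, lasso_lars_path

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityConfig",
    "SelectionResult",
    "randomized_lasso_frequencies",
    "select_features",
]


@dataclass(frozen=True)
class StabilityConfig:
    """Knobs of the stability-selection procedure.

    n_resamples:        number of subsample-and-fit repetitions (B).
    subsample_fraction: fraction of subjects drawn (without replacement).
    weakness:           α in (0, 1]; per-feature penalty weights are drawn
                        uniformly from [α, 1].  α = 1 disables randomization.
    lambda_grid:        explicit descending penalty grid, or None for an
                        automatic geometric grid of ``n_lambdas`` points from
                        λ_max = max|Xᵀy|/n down to ``lambda_min_ratio``·λ_max,
                        recomputed within each resample.
    selection_threshold: frequency threshold π (inclusive).
    max_active:         per-resample cap q on the number of features the
                        LASSO path may admit; None uses
                        max(3, ceil(sqrt((2π−1) p))), the scale at which
                        the stability-selection expected-false-selection
                        bound q²/((2π−1)p) stays near one.
    mode:               "path" marks a feature selected if its coefficient is
                        nonzero at any grid point; "fixed" uses only the
                        smallest grid penalty.
    """

    n_resamples: int = 200
    subsample_fraction: float = 0.75
    weakness: float = 0.5
    lambda_grid: tuple[float, ...] | None = None
    n_lambdas: int = 30
    lambda_min_ratio: float = 1e-3
    selection_threshold: float = 0.6
    max_active: int | None = None
    seed: int = 0
    mode: str = "path"

    def __post_init__(self):
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if not (0 < self.weakness <= 1):
            raise ValueError("weakness must be in (0, 1]")
        if not (0 < self.selection_threshold <= 1):
            raise ValueError("selection_threshold must be in (0, 1]")
        if self.lambda_grid is not None:
            g = np.asarray(self.lambda_grid, dtype=float)
            if g.ndim != 1 or g.size < 1 or (g <= 0).any() or (np.diff(g) >= 0).any():
                raise ValueError("lambda_grid must be strictly descending positive reals")
        if self.max_active is not None and self.max_active < 1:
            raise ValueError("max_active must be >= 1")
        if self.mode not in ("path", "fixed"):
            raise ValueError("mode must be 'path' or 'fixed'")


@dataclass
class SelectionResult:
    frequencies: np.ndarray
    selected: list[int]
    config: StabilityConfig

    def to_json(self) -> str:
        d = {
            "frequencies": np.asarray(self.frequencies).tolist(),
            "selected": list(map(int, self.selected)),
            "config": asdict(self.config),
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        d = json.loads(text)
        cfg = d["config"]
        if cfg.get("lambda_grid") is not None:
            cfg["lambda_grid"] = tuple(cfg["lambda_grid"])
        return cls(
            frequencies=np.array(d["frequencies"]),
            selected=list(d["selected"]),
            config=StabilityConfig(**cfg),
        )


def _resample_grid(Z: np.ndarray, yc: np.ndarray, config: StabilityConfig) -> np.ndarray:
    if config.lambda_grid is not None:
        return np.asarray(config.lambda_grid, dtype=float)
    m = Z.shape[0]
    lam_max = float(np.max(np.abs(Z.T @ yc))) / m
    if lam_max <= 0:
        return np.array([1.0])
    return np.geomspace(lam_max, config.lambda_min_ratio * lam_max, config.n_lambdas)


def randomized_lasso_frequencies(
    X: np.ndarray, y: np.ndarray, config: StabilityConfig
) -> SelectionResult:
    """Per-feature selection frequencies over randomized-LASSO resamples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 6:
        raise ValueError(f"need at least 6 subjects, got {n}")
    if y.shape != (n,):
        raise ValueError("y length must match number of rows of X")
    if np.ptp(y) == 0:
        raise ValueError("y is constant; selection undefined")

    rng = np.random.default_rng(config.seed)
    m = int(np.floor(config.subsample_fraction * n))
    m = max(m, 2)
    q = config.max_active
    if q is None:
        q = max(3, int(np.ceil(np.sqrt((2 * config.selection_threshold - 1) * p))))
    counts = np.zeros(p)
    warned = False

    for _ in range(config.n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        w = rng.uniform(config.weakness, 1.0, size=p)
        Xs = X[idx]
        ys = y[idx] - y[idx].mean()
        mu = Xs.mean(axis=0)
        sd = Xs.std(axis=0)
        dead = sd == 0
        if dead.any() and not warned:
            logger.warning(
                "stability selection: %d zero-variance column(s) skipped in a resample",
                int(dead.sum()),
            )
            warned = True
        sd_safe = np.where(dead, 1.0, sd)
        Z = ((Xs - mu) / sd_safe) * w
        Z[:, dead] = 0.0
        if np.ptp(ys) == 0:
            continue
        grid = _resample_grid(Z, ys, config)
        lams, coefs = lasso_lars_path(Z, ys, lam_min=float(grid[-1]), max_active=q)
        if config.mode == "path":
            sel = active_at(lams, coefs, grid)
        else:
            sel = active_at(lams, coefs, grid[-1:])
        sel &= ~dead
        counts += sel

    freqs = counts / config.n_resamples
    result = SelectionResult(freqs, [], config)
    result.selected = select_features(result, config.selection_threshold)
    return result


def select_features(result: SelectionResult, threshold: float) -> list[int]:
    """Indices with selection frequency >= threshold, ascending."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    return sorted(int(j) for j in np.where(result.frequencies >= threshold)[0])
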