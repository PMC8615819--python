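"""Nested leave-one-out cross-validation with blind-test feature selection.

Protocol, for N subjects:

1. *Outer pass 1* — for each held-out subject i, run stability selection on
   the other N−1 subjects (blind test: the held-out subject never touches
   feature selection), then tune SVR hyperparameters by an inner LOOCV over
   those N−1 subjects, scoring each grid point by the Pearson r between
   inner predictions and inner truths.
2. *Majority vote* — the hyperparameter pair chosen by the most folds
   becomes the final pair (ties broken toward smaller C, then smaller ε).
3. *Outer pass 2* — each fold is refit on its own training subjects and its
   own selected features, but with the voted hyperparameters, and predicts
   its held-out subject.
4. *Evaluation* — Pearson r between the N held-out predictions and the
   observed scores, with a one-sided t-based p-value (t = r·√((n−2)/(1−r²))
   on n−2 df).

The vote shares a small amount of information across folds (each fold's
hyperparameters were chosen with knowledge of every fold's inner winner);
``hyperparam_mode="per-fold"`` gives the strictly nested variant where each
fold keeps its own inner winner.

A fold whose selection comes back empty predicts its training-score mean.
Note the leave-one-out mean is (S − yᵢ)/(N−1): if *every* fold is empty the
prediction vector is exactly anti-correlated with the scores (r = −1), a
known LOOCV artifact flagged in the fold log.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from . import models
from .models import ModelSpec, TrainedModel
from .selection import StabilityConfig, randomized_lasso_frequencies

logger = logging.getLogger(__name__)

__all__ = [
    "FoldRecord",
    "EvaluationResult",
    "CVResult",
    "default_svr_grid",
    "inner_loocv_tune",
    "majority_vote",
    "outer_loocv",
    "evaluate",
]


@dataclass
class FoldRecord:
    held_out_subject: int
    selected_features: list[int]
    inner_best_hyperparams: ModelSpec | None
    prediction: float = np.nan
    fallback_mean: bool = False


@dataclass
class EvaluationResult:
    r: float
    n: int
    p_one_sided: float
    p_two_sided: float
    df: int
    degenerate: bool = False


@dataclass
class CVResult:
    folds: list[FoldRecord]
    predicted: np.ndarray
    observed: np.ndarray
    evaluation: EvaluationResult
    voted_hyperparams: ModelSpec
    model_kind: str
    pool: str

    @property
    def r(self) -> float:
        return self.evaluation.r

    def to_json(self) -> str:
        import json
        from dataclasses import asdict

        return json.dumps(
            {
                "model_kind": self.model_kind,
                "pool": self.pool,
                "r": self.evaluation.r,
                "n": self.evaluation.n,
                "p_one_sided": self.evaluation.p_one_sided,
                "p_two_sided": self.evaluation.p_two_sided,
                "degenerate": self.evaluation.degenerate,
                "voted_hyperparams": asdict(self.voted_hyperparams),
                "predicted": self.predicted.tolist(),
                "observed": self.observed.tolist(),
                "folds": [
                    {
                        "held_out_subject": f.held_out_subject,
                        "selected_features": list(map(int, f.selected_features)),
                        "inner_best_hyperparams": (
                            asdict(f.inner_best_hyperparams)
                            if f.inner_best_hyperparams
                            else None
                        ),
                        "prediction": f.prediction,
                        "fallback_mean": f.fallback_mean,
                    }
                    for f in self.folds
                ],
            },
            indent=1,
        )


def default_svr_grid() -> list[ModelSpec]:
    """C in {2⁻⁵, 2⁻³, ..., 2⁵} (geometric), ε in {0.01, 0.1, 1} SD units."""
    return [
        ModelSpec("SVR", C=2.0**k, epsilon=e)
        for k in (-5, -3, -1, 1, 3, 5)
        for e in (0.01, 0.1, 1.0)
    ]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def evaluate(predicted: np.ndarray, observed: np.ndarray) -> EvaluationResult:
    """Pearson r with one- and two-sided t-based p-values (df = n − 2).

    A constant prediction vector is degenerate: r is reported as 0 with the
    flag set (one-sided p 0.5, two-sided 1.0).
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = predicted.size
    if observed.size != n:
        raise ValueError("predicted and observed must have equal length")
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(observed) == 0:
        raise ValueError("observed scores are constant")
    df = n - 2
    if np.ptp(predicted) == 0:
        return EvaluationResult(0.0, n, 0.5, 1.0, df, degenerate=True)
    r = _pearson(predicted, observed)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
    tiny = 5e-324  # p stays in (0, 1] even at |r| = 1
    p_one = float(stats.t.sf(t, df))
    p_two = float(2.0 * stats.t.sf(abs(t), df))
    return EvaluationResult(r, n, min(max(p_one, tiny), 1.0), min(max(p_two, tiny), 1.0), df)


def inner_loocv_tune(
    X_train: np.ndarray,
    y_train: np.ndarray,
    model_kind: str,
    grid: list[ModelSpec] | None = None,
) -> ModelSpec:
    """Pick the grid point whose inner-LOOCV predictions correlate best.

    Constant inner predictions score −1 so a fully regularised model never
    wins; ties break toward smaller C, then smaller ε.
    """
    if model_kind == "LR":
        return ModelSpec("LR")
    if grid is None:
        grid = default_svr_grid()
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_train = np.asarray(y_train, dtype=float)
    n = y_train.size
    if n < 3:
        raise ValueError("inner tuning needs at least 3 training subjects")

    best_spec, best_r = None, -np.inf
    for spec in sorted(grid, key=ModelSpec.sort_key):
        preds = np.empty(n)
        for k in range(n):
            mask = np.ones(n, dtype=bool)
            mask[k] = False
            m = models.fit(X_train[mask], y_train[mask], spec)
            preds[k] = models.predict(m, X_train[k : k + 1])[0]
        r = _pearson(preds, y_train)
        if np.isnan(r) or np.ptp(preds) == 0:
            r = -1.0
        if r > best_r:
            best_spec, best_r = spec, r
    return best_spec


def majority_vote(winners: list[ModelSpec]) -> ModelSpec:
    """Most frequent spec; ties toward smaller C, then smaller ε."""
    if not winners:
        raise ValueError("empty winner list")
    counts = Counter(winners)
    top = max(counts.values())
    tied = [s for s, c in counts.items() if c == top]
    return min(tied, key=ModelSpec.sort_key)


def _fold_seed(base_seed: int, fold: int) -> int:
    # documented scheme: an independent 31-bit stream per outer fold
    return int(np.random.SeedSequence(base_seed, spawn_key=(fold,)).generate_state(1)[0] % (2**31))


def fold_feature_selection(
    X: np.ndarray, y: np.ndarray, stability_config: StabilityConfig
) -> list[list[int]]:
    """Pass-1 per-fold stability selections (training subjects only).

    Exposed separately so model comparisons (LR vs SVR on the same pool) can
    reuse the expensive selection stage; selection depends only on the data,
    never on the downstream model kind.
    """
    N = y.size
    selections = []
    for i in range(N):
        mask = np.ones(N, dtype=bool)
        mask[i] = False
        cfg = replace(stability_config, seed=_fold_seed(stability_config.seed, i))
        res = randomized_lasso_frequencies(X[mask], y[mask], cfg)
        selections.append(res.selected)
    return selections


def outer_loocv(
    X: np.ndarray,
    y: np.ndarray,
    model_kind: str,
    pool: str,
    stability_config: StabilityConfig,
    grid: list[ModelSpec] | None = None,
    hyperparam_mode: str = "vote",
    fold_selections: list[list[int]] | None = None,
) -> CVResult:
    """Nested LOOCV: blind per-fold selection, inner tuning, vote, refit.

    ``fold_selections`` may be supplied (from :func:`fold_feature_selection`)
    to reuse selections across model kinds; otherwise they are computed here.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    N = y.size
    if N < 6:
        raise ValueError(f"need at least 6 subjects for nested LOOCV, got {N}")
    if hyperparam_mode not in ("vote", "per-fold"):
        raise ValueError("hyperparam_mode must be 'vote' or 'per-fold'")
    if grid is None and model_kind == "SVR":
        grid = default_svr_grid()

    if fold_selections is None:
        fold_selections = fold_feature_selection(X, y, stability_config)
    if len(fold_selections) != N:
        raise ValueError("fold_selections length must equal the number of subjects")

    # pass 1: inner tuning per fold
    folds: list[FoldRecord] = []
    for i in range(N):
        mask = np.ones(N, dtype=bool)
        mask[i] = False
        sel = list(fold_selections[i])
        if not sel:
            logger.warning(
                "fold %d: stability selection returned no features; "
                "the fold will predict its training mean", i,
            )
            folds.append(FoldRecord(i, sel, None, fallback_mean=True))
            continue
        winner = inner_loocv_tune(X[np.ix_(mask, sel)], y[mask], model_kind, grid)
        folds.append(FoldRecord(i, sel, winner))

    winners = [f.inner_best_hyperparams for f in folds if f.inner_best_hyperparams]
    if winners:
        voted = majority_vote(winners)
    else:
        voted = ModelSpec("LR") if model_kind == "LR" else min(grid, key=ModelSpec.sort_key)

    # pass 2: refit with voted (or per-fold) hyperparameters and predict
    predicted = np.empty(N)
    for f in folds:
        i = f.held_out_subject
        mask = np.ones(N, dtype=bool)
        mask[i] = False
        if f.fallback_mean:
            predicted[i] = y[mask].mean()
        else:
            spec = voted if hyperparam_mode == "vote" else f.inner_best_hyperparams
            m = models.fit(X[np.ix_(mask, f.selected_features)], y[mask], spec,
                           feature_indices=f.selected_features)
            predicted[i] = models.predict(m, X[i : i + 1][:, f.selected_features])[0]
        f.prediction = float(predicted[i])

    ev = evaluate(predicted, y)
    return CVResult(folds, predicted, y.copy(), ev, voted, model_kind, pool)
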