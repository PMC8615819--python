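"""Consensus features across CV folds and the final full-data model.

Fold-wise feature selections rarely agree exactly; the final feature set
keeps only the edges selected in at least half of the leave-one-out folds
(inclusive boundary), re-runs randomized-LASSO stability selection on all
subjects restricted to that consensus set, and fits the winning model on
the full cohort.  Selected features are reported as named atlas edges, each
region pair categorised by which feature pool(s) contributed it:
LOFC-only, HOFC-only, or both.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from . import models
from .models import ModelSpec, TrainedModel
from .selection import StabilityConfig, randomized_lasso_frequencies

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeDescriptor",
    "FinalModel",
    "consensus_features",
    "finalize",
    "name_edges",
    "FINAL_SEED_TAG",
]

# seed-derivation tag for the full-data re-selection (documented scheme:
# SeedSequence(config.seed, spawn_key=(FINAL_SEED_TAG,)))
FINAL_SEED_TAG = 999_983


@dataclass
class EdgeDescriptor:
    region_a: str
    region_b: str
    abbrev_a: str
    abbrev_b: str
    i: int
    j: int
    pool_category: str  # "LOFC-only" | "HOFC-only" | "both"


@dataclass
class FinalModel:
    consensus_features: list[int]
    final_features: list[int]
    trained: TrainedModel
    edges: list[EdgeDescriptor]
    frequencies: np.ndarray

    def to_json(self) -> str:
        return json.dumps(
            {
                "consensus_features": list(map(int, self.consensus_features)),
                "final_features": list(map(int, self.final_features)),
                "trained": json.loads(self.trained.to_json()),
                "edges": [e.__dict__ for e in self.edges],
                "frequencies": np.asarray(self.frequencies).tolist(),
            },
            indent=1,
        )


def consensus_features(fold_selections: list[list[int]], min_fraction: float = 0.5) -> list[int]:
    """Features selected in at least ``ceil(min_fraction * n_folds)`` folds.

    The default (0.5, inclusive comparison) keeps an edge selected in
    exactly half of the folds.
    """
    if not fold_selections:
        raise ValueError("need at least one fold")
    n_folds = len(fold_selections)
    need = math.ceil(min_fraction * n_folds)
    counts: dict[int, int] = {}
    for sel in fold_selections:
        for j in set(sel):
            counts[j] = counts.get(j, 0) + 1
    return sorted(j for j, c in counts.items() if c >= need)


def finalize(
    X: np.ndarray,
    y: np.ndarray,
    consensus: list[int],
    stability_config: StabilityConfig,
    voted_spec: ModelSpec,
    index_map: list[tuple[str, int, int]] | None = None,
    atlas_labels=None,
) -> FinalModel:
    """Re-select within the consensus set on all subjects and fit the final model."""
    if not consensus:
        raise ValueError(
            "empty consensus feature set: relax the selection threshold or "
            "the consensus fraction"
        )
    X = np.asarray(X, dtype=float)
    seed = int(
        np.random.SeedSequence(stability_config.seed, spawn_key=(FINAL_SEED_TAG,))
        .generate_state(1)[0] % (2**31)
    )
    cfg = replace(stability_config, seed=seed)
    res = randomized_lasso_frequencies(X[:, consensus], y, cfg)
    final = [consensus[k] for k in res.selected]
    if not final:
        logger.warning(
            "full-data re-selection kept no feature at threshold %.2f; "
            "falling back to the strongest consensus feature",
            cfg.selection_threshold,
        )
        final = [consensus[int(np.argmax(res.frequencies))]]
    trained = models.fit(X[:, final], y, voted_spec, feature_indices=final)
    edges = []
    if index_map is not None:
        edges = name_edges(final, index_map, atlas_labels)
    freqs = np.zeros(X.shape[1])
    freqs[np.array(consensus)] = res.frequencies
    return FinalModel(list(consensus), final, trained, edges, freqs)


def name_edges(
    feature_indices: list[int],
    index_map: list[tuple[str, int, int]],
    atlas_labels=None,
) -> list[EdgeDescriptor]:
    """Map feature indices to named region-pair edges with pool categories.

    ``atlas_labels`` is a DataFrame-like with columns ``name`` and
    ``abbreviation`` in region order (defaults to generic labels).  The same
    region pair arriving from both the LOFC and the HOFC block collapses to
    one edge with category "both".
    """
    pools_by_pair: dict[tuple[int, int], set[str]] = {}
    for idx in feature_indices:
        if not (0 <= idx < len(index_map)):
            raise IndexError(f"feature index {idx} outside the index map")
        pool, i, j = index_map[idx]
        pools_by_pair.setdefault((i, j), set()).add(pool)

    def label(k: int) -> tuple[str, str]:
        if atlas_labels is None:
            return f"region {k + 1}", f"R{k + 1}"
        row = atlas_labels.iloc[k]
        return str(row["name"]), str(row["abbreviation"])

    out = []
    for (i, j) in sorted(pools_by_pair):
        pools = pools_by_pair[(i, j)]
        if pools == {"LOFC"}:
            cat = "LOFC-only"
        elif pools == {"HOFC"}:
            cat = "HOFC-only"
        else:
            cat = "both"
        name_a, ab_a = label(i)
        name_b, ab_b = label(j)
        out.append(EdgeDescriptor(name_a, name_b, ab_a, ab_b, int(i), int(j), cat))
    return out
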