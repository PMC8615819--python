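"""Convenience orchestration: cohort -> feature pools -> CV -> final model.

Thin glue over the stage modules, shared by the command-line interface,
the test-suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .connectome import (
    ConnectivityMatrix,
    build_feature_pool,
    compute_hofc,
    compute_lofc,
    vectorize,
)
from .synthetic import ConnectomeCohort, GroundTruth, SyntheticCohort

__all__ = ["cohort_connectomes", "cohort_features", "planted_feature_columns"]


def cohort_connectomes(cohort) -> list[ConnectivityMatrix]:
    """Per-subject LOFC matrices: computed from time series, or taken
    directly for a connectome-level cohort."""
    if isinstance(cohort, ConnectomeCohort):
        return cohort.matrices
    return [compute_lofc(ts) for ts in cohort.subjects]


def cohort_features(cohort, pool: str = "LOFC+HOFC"):
    """(X, index_map) for a cohort and feature pool."""
    mats = cohort_connectomes(cohort)
    lofc = [vectorize(m) for m in mats]
    hofc = [vectorize(compute_hofc(m)) for m in mats] if pool == "LOFC+HOFC" else None
    return build_feature_pool(lofc, hofc, pool)


def planted_feature_columns(truth: GroundTruth, pool: str = "LOFC+HOFC") -> list[int]:
    """Column indices of the planted edges within a feature pool.

    Edges planted in the HOFC pool have no column in a LOFC-only pool and
    are omitted there.
    """
    R = truth.n_regions
    iu, ju = np.triu_indices(R, k=1)
    pos = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(iu, ju))}
    n_lofc = len(iu)
    cols = []
    for e in truth.planted_edges:
        if e.pool == "LOFC":
            cols.append(pos[(e.i, e.j)])
        elif pool == "LOFC+HOFC":
            cols.append(pos[(e.i, e.j)] + n_lofc)
    return cols
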