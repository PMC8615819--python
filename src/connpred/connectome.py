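"""Functional connectome construction and edge-feature vectorization.

Two connectivity orders are supported:

* **LOFC** (low-order functional connectivity): the conventional functional
  connectome — the Pearson correlation between every pair of region-wise
  BOLD time courses, giving an R x R symmetric matrix per subject.
* **HOFC** (high-order functional connectivity): the "correlation of the
  correlation" — entry (i, j) is the Pearson correlation between region i's
  and region j's whole-brain connectivity profiles (their rows of the LOFC
  matrix).  By default the entries at positions i and j are removed from
  both profiles before correlating, so neither the unit diagonal nor the
  pair's own edge inflates the profile similarity.

Edge features are the upper-triangle entries (i < j) in row-major order, a
fixed convention so feature indices are stable across runs and poolable
across subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Kind",
    "RegionTimeSeries",
    "ConnectivityMatrix",
    "FeatureVector",
    "compute_lofc",
    "compute_hofc",
    "fisher_z",
    "vectorize",
    "devectorize",
    "build_feature_pool",
]


class Kind(str, Enum):
    LOFC = "LOFC"
    HOFC = "HOFC"


@dataclass
class RegionTimeSeries:
    """One subject's T x R matrix of region-averaged signal."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x R) array")
        if not np.isfinite(self.values).all():
            raise ValueError(f"time series for {self.subject_id!r} contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric R x R connectivity matrix (unit diagonal)."""

    values: np.ndarray
    kind: Kind
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.kind = Kind(self.kind)
        R = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != R:
            raise ValueError("connectivity matrix must be square")
        if not self.region_labels:
            self.region_labels = [f"R{i + 1}" for i in range(R)]
        if len(self.region_labels) != R:
            raise ValueError("region_labels length must match matrix size")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class FeatureVector:
    """Vectorized upper triangle with an index map of (pool, i, j) triples."""

    values: np.ndarray
    index_map: list[tuple[str, int, int]]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size != len(self.index_map):
            raise ValueError("values and index_map length mismatch")


def _check_symmetric_unit_diag(values: np.ndarray, tol: float = 1e-12) -> None:
    if np.abs(values - values.T).max() > tol:
        raise ValueError("matrix is not symmetric")
    if np.abs(np.diag(values) - 1.0).max() > tol:
        raise ValueError("matrix diagonal is not 1")


def compute_lofc(ts: RegionTimeSeries, on_constant: str = "raise") -> ConnectivityMatrix:
    """Pearson-correlation connectome of region time courses.

    Parameters
    ----------
    ts : RegionTimeSeries
    on_constant : {"raise", "zero"}
        A region with a constant time course has an undefined correlation.
        ``"raise"`` names the offending region; ``"zero"`` sets its entries
        to 0 with a logged warning.
    """
    V = ts.values
    T, R = V.shape
    if T < 3:
        raise ValueError(f"need at least 3 time points, got {T}")
    sd = V.std(axis=0)
    constant = np.where(sd == 0)[0]
    if constant.size:
        if on_constant == "raise":
            raise ValueError(
                f"region(s) {constant.tolist()} of subject {ts.subject_id!r} "
                "have constant time courses; correlation undefined"
            )
        logger.warning(
            "subject %r: zero-variance region(s) %s set to 0 in LOFC",
            ts.subject_id, constant.tolist(),
        )
    Z = V - V.mean(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = Z / sd_safe
    C = Z.T @ Z / T
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return ConnectivityMatrix(C, Kind.LOFC)


def compute_hofc(
    lofc: ConnectivityMatrix,
    profile: str = "exclude-pair",
    on_degenerate: str = "raise",
) -> ConnectivityMatrix:
    """High-order connectome: correlate the connectivity profiles of region pairs.

    Parameters
    ----------
    lofc : ConnectivityMatrix of kind LOFC.
    profile : {"exclude-pair", "full-row-with-diagonal"}
        ``exclude-pair`` removes the entries at positions i and j from both
        rows before correlating (profile length R-2); the alternative uses
        the complete rows, diagonal included.
    on_degenerate : {"raise", "zero"}
        Behaviour when a residual profile has zero variance.
    """
    if lofc.kind is not Kind.LOFC:
        raise ValueError("compute_hofc expects a LOFC matrix")
    L = lofc.values
    R = L.shape[0]
    _check_symmetric_unit_diag(L)

    if profile == "exclude-pair":
        if R < 4:
            raise ValueError(
                f"HOFC with pair exclusion needs R >= 4 (profile length R-2 >= 2), got R={R}"
            )
        m = R - 2
        S = L.sum(axis=1)
        Q = (L * L).sum(axis=1)
        P = L @ L
        # row i with entries at columns {i, j} removed: subtract L[i,i](=1) and L[i,j]
        sum_i = S[:, None] - 1.0 - L
        q_i = Q[:, None] - 1.0 - L * L
        dot = P - 2.0 * L  # removes L[i,i]*L[j,i] + L[i,j]*L[j,j]
        cov = dot - sum_i * sum_i.T / m
        var_i = q_i - sum_i**2 / m
    elif profile == "full-row-with-diagonal":
        m = R
        S = L.sum(axis=1)
        Q = (L * L).sum(axis=1)
        P = L @ L
        cov = P - np.outer(S, S) / m
        var_i = np.broadcast_to((Q - S**2 / m)[:, None], (R, R)).copy()
    else:
        raise ValueError(f"unknown profile mode {profile!r}")

    var_i = np.maximum(var_i, 0.0)
    degen = var_i <= 1e-14
    np.fill_diagonal(degen, False)
    if degen.any():
        pairs = np.argwhere(degen & ~np.eye(R, dtype=bool))
        if on_degenerate == "raise":
            i, j = pairs[0]
            raise ValueError(
                f"zero-variance connectivity profile for region pair ({i}, {j}); "
                "HOFC undefined"
            )
        logger.warning("HOFC: %d degenerate profile pair(s) set to 0", len(pairs))
    with np.errstate(divide="ignore", invalid="ignore"):
        H = cov / np.sqrt(var_i * var_i.T)
    H[degen | degen.T] = 0.0
    H = np.clip((H + H.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(H, 1.0)
    return ConnectivityMatrix(H, Kind.HOFC, list(lofc.region_labels))


def fisher_z(matrix: ConnectivityMatrix, clip: float = 1.0 - 1e-7) -> np.ndarray:
    """Fisher r-to-z transform of the off-diagonal entries (plain array out).

    Not part of the default pipeline; provided for variance-stabilised
    downstream analyses.
    """
    V = np.clip(matrix.values, -clip, clip)
    Z = np.arctanh(V)
    np.fill_diagonal(Z, 0.0)
    return Z


def vectorize(matrix: ConnectivityMatrix) -> FeatureVector:
    """Row-major upper-triangle (i < j) flattening of a connectivity matrix."""
    R = matrix.n_regions
    iu, ju = np.triu_indices(R, k=1)
    values = matrix.values[iu, ju]
    index_map = [(matrix.kind.value, int(i), int(j)) for i, j in zip(iu, ju)]
    return FeatureVector(values, index_map)


def devectorize(vec: FeatureVector, n_regions: int) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize`; exact reconstruction."""
    kinds = {pool for pool, _, _ in vec.index_map}
    if len(kinds) != 1:
        raise ValueError("cannot devectorize a mixed-pool feature vector")
    M = np.eye(n_regions)
    for v, (_, i, j) in zip(vec.values, vec.index_map):
        M[i, j] = v
        M[j, i] = v
    return ConnectivityMatrix(M, Kind(kinds.pop()))


def build_feature_pool(
    lofc_vecs: list[FeatureVector],
    hofc_vecs: list[FeatureVector] | None,
    pool: str,
):
    """Stack per-subject edge vectors into an (n_subjects x n_features) matrix.

    ``pool`` is ``"LOFC"`` or ``"LOFC+HOFC"``; in the combined pool the LOFC
    block comes first.  Returns ``(X, index_map)``.
    """
    if pool not in ("LOFC", "LOFC+HOFC"):
        raise ValueError(f"unknown pool {pool!r}")
    X_l = np.vstack([v.values for v in lofc_vecs])
    index_map = list(lofc_vecs[0].index_map)
    if any(v.index_map != lofc_vecs[0].index_map for v in lofc_vecs):
        raise ValueError("inconsistent LOFC index maps across subjects")
    if pool == "LOFC":
        return X_l, index_map
    if hofc_vecs is None:
        raise ValueError("LOFC+HOFC pool requires HOFC vectors")
    if len(hofc_vecs) != len(lofc_vecs):
        raise ValueError(
            f"subject count mismatch: {len(lofc_vecs)} LOFC vs {len(hofc_vecs)} HOFC"
        )
    X_h = np.vstack([v.values for v in hofc_vecs])
    if any(v.index_map != hofc_vecs[0].index_map for v in hofc_vecs):
        raise ValueError("inconsistent HOFC index maps across subjects")
    return np.hstack([X_l, X_h]), index_map + list(hofc_vecs[0].index_map)
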