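"""Synthetic cohorts with a known, planted edge-to-score signal.

The clinical dataset the pipeline targets (a ~40-subject stroke cohort with
region-wise resting-state time series and a 0-100 tactile-discrimination
score per subject) is not publicly deposited, so validation runs on
synthetic cohorts whose generative truth is known:

* a shared **base correlation** matrix from a low-rank factor model
  (``C = ΛΛᵀ + ψI`` normalised to unit diagonal), mimicking the block
  structure of resting-state connectomes while guaranteeing positive
  definiteness;
* per-subject deviations ``δ_s ~ U[-0.3, 0.3]`` applied at planted edges,
  followed by projection back to the nearest valid correlation matrix
  (eigenvalue clipping, then re-normalisation to unit diagonal);
* a behavioural score that is a fixed linear function of the subject's true
  edge values (LOFC-pool edges read off the target matrix, HOFC-pool edges
  read off the HOFC derived from it) plus Gaussian noise, affinely mapped
  to the 0-100 scale and clipped.

LOFC-planted edges shift the edge's own correlation value; HOFC-planted
edges shift a fixed random loading pattern shared by both endpoint rows, so
the pair's *profile similarity* — hence its HOFC value — varies across
subjects while the pair's own LOFC entry does not carry the signal.

Per-subject randomness comes from ``numpy.random.SeedSequence(master_seed,
spawn_key=(s,))`` — a documented counter scheme making each subject an
independent stream while the whole cohort is bit-reproducible from
``master_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .connectome import ConnectivityMatrix, Kind, RegionTimeSeries, compute_hofc

__all__ = [
    "PlantedEdge",
    "GroundTruth",
    "SyntheticCohort",
    "ConnectomeCohort",
    "factor_base_correlation",
    "nearest_pd_correlation",
    "make_default_truth",
    "generate_cohort",
    "generate_connectome_cohort",
    "true_edge_values",
]

DELTA_RANGE = 0.3  # half-width of the per-subject edge deviation
_EIG_FLOOR = 1e-6
_ENTRY_CLIP = 0.97
_HOFC_PARTNERS = 10


@dataclass(frozen=True)
class PlantedEdge:
    i: int
    j: int
    pool: str  # "LOFC" | "HOFC"


@dataclass
class GroundTruth:
    """Generative truth: which edges carry signal, and how strongly."""

    planted_edges: list[PlantedEdge]
    weights: np.ndarray
    noise_sd: float
    base_correlation: np.ndarray
    score_offset: float = 0.0
    score_scale: float = 1.0
    pattern_seed: int = 0  # fixes the HOFC driver loading patterns
    background_sd: float = 0.1  # per-subject background edge variability

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.base_correlation = np.asarray(self.base_correlation, dtype=float)
        C = self.base_correlation
        if np.abs(C - C.T).max() > 1e-10 or np.abs(np.diag(C) - 1).max() > 1e-10:
            raise ValueError("base_correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("base_correlation must be positive definite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        if len(self.planted_edges) != self.weights.size:
            raise ValueError("one weight per planted edge required")
        R = C.shape[0]
        seen = set()
        for e in self.planted_edges:
            if not (0 <= e.i < e.j < R):
                raise ValueError(f"planted edge ({e.i}, {e.j}) invalid for R={R}")
            if e.pool not in ("LOFC", "HOFC"):
                raise ValueError(f"unknown pool {e.pool!r}")
            if (e.i, e.j) in seen:
                raise ValueError(f"duplicate planted edge ({e.i}, {e.j})")
            seen.add((e.i, e.j))

    @property
    def n_regions(self) -> int:
        return self.base_correlation.shape[0]


@dataclass
class SyntheticCohort:
    subjects: list[RegionTimeSeries]
    scores: np.ndarray
    truth: GroundTruth
    master_seed: int

    def __iter__(self):
        return iter((self.subjects, self.scores))


@dataclass
class ConnectomeCohort:
    """Noise-free fast path: subject target correlation matrices directly."""

    matrices: list[ConnectivityMatrix]
    scores: np.ndarray
    truth: GroundTruth
    master_seed: int
    latents: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __iter__(self):
        return iter((self.matrices, self.scores))


def factor_base_correlation(n_regions: int, n_factors: int = 5, seed: int = 0) -> np.ndarray:
    """Unit-diagonal correlation matrix from a random loading factor model."""
    rng = np.random.default_rng(seed)
    lam = rng.normal(0.0, 0.6, size=(n_regions, n_factors))
    psi = 1.0
    C = lam @ lam.T + psi * np.eye(n_regions)
    d = np.sqrt(np.diag(C))
    C = C / np.outer(d, d)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return C


def nearest_pd_correlation(M: np.ndarray, eig_floor: float = _EIG_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite unit-diagonal one.

    Eigenvalues are clipped at ``eig_floor``, then the matrix is re-scaled
    to unit diagonal.  Cheap, deterministic, and adequate for the small
    perturbations used here (not an alternating-projections solver).
    """
    M = (M + M.T) / 2.0
    w, V = np.linalg.eigh(M)
    if w.min() < eig_floor:
        w = np.clip(w, eig_floor, None)
        M = (V * w) @ V.T
    d = np.sqrt(np.diag(M))
    M = M / np.outer(d, d)
    M = (M + M.T) / 2.0
    np.fill_diagonal(M, 1.0)
    return M


def _hofc_patterns(truth: GroundTruth) -> dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]:
    """Fixed loading patterns driving the HOFC-planted edges.

    For each HOFC edge (i, j) a set of partner regions and loadings is drawn
    once from ``pattern_seed``; subjects then scale the pattern by δ_s on
    both endpoint rows.
    """
    rng = np.random.default_rng(np.random.SeedSequence((truth.pattern_seed, 0x480FC)))
    R = truth.n_regions
    patterns = {}
    for e in truth.planted_edges:
        if e.pool != "HOFC":
            continue
        candidates = np.array([k for k in range(R) if k not in (e.i, e.j)])
        m = min(_HOFC_PARTNERS, candidates.size)
        partners = rng.choice(candidates, size=m, replace=False)
        loadings = rng.normal(0.0, 1.0, size=m)
        patterns[(e.i, e.j)] = (partners, loadings)
    return patterns


def _subject_target(
    truth: GroundTruth, patterns, deltas: np.ndarray, background: np.ndarray | None
) -> np.ndarray:
    """Perturb the base correlation at planted edges (plus background) and re-project."""
    M = truth.base_correlation.copy()
    if background is not None:
        M += background
    for delta, e in zip(deltas, truth.planted_edges):
        if e.pool == "LOFC":
            M[e.i, e.j] += delta
            M[e.j, e.i] = M[e.i, e.j]
        else:
            partners, loadings = patterns[(e.i, e.j)]
            for k, u in zip(partners, loadings):
                M[e.i, k] += delta * u
                M[k, e.i] = M[e.i, k]
                M[e.j, k] += delta * u
                M[k, e.j] = M[e.j, k]
    off = ~np.eye(truth.n_regions, dtype=bool)
    M[off] = np.clip(M[off], -_ENTRY_CLIP, _ENTRY_CLIP)
    return nearest_pd_correlation(M)


def _edge_values(M: np.ndarray, truth: GroundTruth) -> np.ndarray:
    """True feature values of the planted edges for one subject target."""
    needs_hofc = any(e.pool == "HOFC" for e in truth.planted_edges)
    H = None
    if needs_hofc:
        H = compute_hofc(ConnectivityMatrix(M, Kind.LOFC)).values
    vals = np.empty(len(truth.planted_edges))
    for k, e in enumerate(truth.planted_edges):
        vals[k] = M[e.i, e.j] if e.pool == "LOFC" else H[e.i, e.j]
    return vals


def _subject_rng(master_seed: int, s: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(s,)))


def _draw_subject(truth: GroundTruth, patterns, rng: np.random.Generator, n_regions: int):
    """Draw one subject's (target matrix, latent score, score noise).

    Draw order (deltas, background, noise) is fixed: both cohort modes call
    this first, so a time-series cohort has the same subject targets and
    scores as the connectome-level cohort at the same master seed.
    """
    deltas = rng.uniform(-DELTA_RANGE, DELTA_RANGE, size=len(truth.planted_edges))
    background = None
    if truth.background_sd > 0:
        E = rng.normal(0.0, truth.background_sd, size=(n_regions, n_regions))
        background = np.triu(E, 1)
        background = background + background.T
    eps = rng.normal(0.0, truth.noise_sd) if truth.noise_sd > 0 else 0.0
    M = _subject_target(truth, patterns, deltas, background)
    latent = float(truth.weights @ _edge_values(M, truth)) if truth.weights.size else 0.0
    return M, latent, eps


def _generate_targets(n_subjects, n_regions, truth, master_seed):
    if truth.n_regions != n_regions:
        raise ValueError(
            f"truth describes R={truth.n_regions} regions, requested {n_regions}"
        )
    if n_subjects < 3 or n_regions < 3:
        raise ValueError("need n_subjects >= 3 and n_regions >= 3")
    patterns = _hofc_patterns(truth)
    targets, latents, noises = [], [], []
    for s in range(n_subjects):
        rng = _subject_rng(master_seed, s)
        M, latent, eps = _draw_subject(truth, patterns, rng, n_regions)
        targets.append(M)
        latents.append(latent)
        noises.append(eps)
    latents = np.array(latents)
    scores = np.clip(
        truth.score_offset + truth.score_scale * (latents + np.array(noises)), 0.0, 100.0
    )
    return targets, latents, scores


def generate_connectome_cohort(
    n_subjects: int, n_regions: int, truth: GroundTruth, master_seed: int
) -> ConnectomeCohort:
    """Subject-level target correlation matrices and scores (no sampling noise).

    Fast path skipping time-series simulation: the returned matrices are the
    exact per-subject correlation targets, so the planted linear signal is
    noiseless apart from ``truth.noise_sd``.
    """
    targets, latents, scores = _generate_targets(n_subjects, n_regions, truth, master_seed)
    mats = [ConnectivityMatrix(M, Kind.LOFC) for M in targets]
    return ConnectomeCohort(mats, scores, truth, master_seed, latents)


def generate_cohort(
    n_subjects: int,
    n_regions: int,
    n_timepoints: int,
    truth: GroundTruth,
    master_seed: int,
) -> SyntheticCohort:
    """Full cohort: per-subject multivariate-normal time series plus scores.

    Each subject's T x R series is zero-mean Gaussian with covariance equal
    to the subject's target correlation matrix, so the empirical LOFC
    converges to the target as T grows.
    """
    import logging

    if n_timepoints < n_regions:
        logging.getLogger(__name__).info(
            "n_timepoints (%d) < n_regions (%d): empirical correlation "
            "matrices will be rank-deficient", n_timepoints, n_regions,
        )
    if truth.n_regions != n_regions:
        raise ValueError(
            f"truth describes R={truth.n_regions} regions, requested {n_regions}"
        )
    if n_subjects < 3 or n_regions < 3:
        raise ValueError("need n_subjects >= 3 and n_regions >= 3")
    patterns = _hofc_patterns(truth)
    subjects, latents, noises = [], [], []
    for s in range(n_subjects):
        rng = _subject_rng(master_seed, s)
        M, latent, eps = _draw_subject(truth, patterns, rng, n_regions)
        latents.append(latent)
        noises.append(eps)
        L = np.linalg.cholesky(M)
        series = rng.standard_normal((n_timepoints, n_regions)) @ L.T
        subjects.append(RegionTimeSeries(series, subject_id=f"sub-{s + 1:03d}"))
    scores = np.clip(
        truth.score_offset
        + truth.score_scale * (np.array(latents) + np.array(noises)),
        0.0,
        100.0,
    )
    return SyntheticCohort(subjects, scores, truth, master_seed)


def true_edge_values(cohort: ConnectomeCohort) -> np.ndarray:
    """(n_subjects x n_planted) matrix of true planted-edge feature values.

    The oracle design matrix: OLS of scores on these columns recovers the
    planted weights (up to the affine score mapping) when noise permits.
    """
    return np.vstack([_edge_values(m.values, cohort.truth) for m in cohort.matrices])


def make_default_truth(
    n_regions: int = 90,
    n_lofc_edges: int = 3,
    n_hofc_edges: int = 2,
    target_r2: float = 0.9,
    score_mean: float = 55.0,
    score_sd: float = 15.0,
    seed: int = 0,
    n_factors: int = 5,
) -> GroundTruth:
    """Construct a calibrated ground truth.

    Planted edges are drawn at random; each edge's weight is scaled so every
    edge contributes equal variance to the latent score (HOFC values vary
    less across subjects than LOFC values, so raw equal weights would let
    the LOFC edges dominate).  ``noise_sd`` is set so the oracle linear
    model on the true edge values attains R² = ``target_r2``, and the
    affine score map targets a TDT-like scale (mean ~55, SD ~15 on 0-100).
    Calibration uses an internal 300-subject cohort with a fixed seed.
    """
    if not (0 < target_r2 <= 1):
        raise ValueError("target_r2 must be in (0, 1]")
    rng = np.random.default_rng(seed)
    base = factor_base_correlation(n_regions, n_factors=n_factors, seed=seed)
    n_edges = n_lofc_edges + n_hofc_edges
    if 2 * n_edges <= n_regions:
        # disjoint endpoints keep the planted features cleanly attributable
        regs = rng.choice(n_regions, size=2 * n_edges, replace=False)
        pairs = sorted(
            tuple(sorted((int(regs[2 * k]), int(regs[2 * k + 1]))))
            for k in range(n_edges)
        )
    else:
        pairs = set()
        while len(pairs) < n_edges:
            i, j = sorted(rng.choice(n_regions, size=2, replace=False))
            pairs.add((int(i), int(j)))
        pairs = sorted(pairs)
    pools = ["LOFC"] * n_lofc_edges + ["HOFC"] * n_hofc_edges
    edges = [PlantedEdge(i, j, pool) for (i, j), pool in zip(pairs, pools)]
    signs = rng.choice([-1.0, 1.0], size=n_edges)

    probe = GroundTruth(
        planted_edges=edges,
        weights=np.ones(n_edges),
        noise_sd=0.0,
        base_correlation=base,
        pattern_seed=seed,
    )
    cal = generate_connectome_cohort(300, n_regions, probe, master_seed=seed + 1_000_003)
    vals = true_edge_values(cal)
    sds = vals.std(axis=0)
    sds = np.where(sds < 1e-6, 1e-6, sds)
    weights = signs / sds  # unit variance contribution per edge
    latent = vals @ weights
    var_latent = float(latent.var())
    noise_sd = (
        np.sqrt(var_latent * (1.0 / target_r2 - 1.0)) if target_r2 < 1 else 0.0
    )
    total_sd = np.sqrt(var_latent + noise_sd**2)
    scale = score_sd / total_sd if total_sd > 0 else 1.0
    offset = score_mean - scale * float(latent.mean())
    return replace(
        probe,
        weights=weights,
        noise_sd=noise_sd,
        score_offset=offset,
        score_scale=scale,
    )
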