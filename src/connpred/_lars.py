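"""Piecewise-linear LASSO path via least-angle regression (with drops).

Solves, over a decreasing range of penalties ``lam``,

    min_beta  (1/(2n)) * ||y - X beta||^2  +  lam * ||beta||_1

and returns the knots of the piecewise-linear coefficient path.  The solver
is specialised for the n << p regime of subsampled connectome features: each
step costs one (n x p) BLAS product plus a small dense solve on the active
set, which keeps per-path overhead far below a generic implementation.

`X` is used as given; callers are responsible for centering/standardising.
"""

from __future__ import annotations

import numpy as np

__all__ = ["lasso_lars_path", "coefs_at", "active_at"]

_EPS = 1e-12


def lasso_lars_path(
    X: np.ndarray,
    y: np.ndarray,
    lam_min: float = 0.0,
    max_steps: int | None = None,
    max_active: int | None = None,
):
    """Compute the LASSO coefficient path down to penalty ``lam_min``.

    Parameters
    ----------
    X : (n, p) array
        Design matrix (already centred/standardised by the caller).
    y : (n,) array
        Response (already centred by the caller).
    lam_min : float
        Smallest penalty of interest; the path stops once it is reached.
    max_steps : int, optional
        Safety cap on the number of add/drop events.
    max_active : int, optional
        Stop admitting new features once this many are active (the
        stability-selection per-resample cap q); drops may still occur.

    Returns
    -------
    lams : (K,) array, strictly decreasing penalty knots (lams[0] = lam_max).
    coefs : (p, K) array, coefficients at each knot; linear in ``lam``
        between consecutive knots.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if max_steps is None:
        max_steps = 8 * min(n, p)
    active_limit = min(n - 1, p)
    if max_active is not None:
        active_limit = min(active_limit, max_active)

    beta = np.zeros(p)
    c = X.T @ y / n  # current correlations X^T r / n
    lam = float(np.max(np.abs(c))) if p else 0.0

    lams = [lam]
    coefs = [beta.copy()]
    if lam <= lam_min or lam <= _EPS:
        return np.array(lams), np.array(coefs).T

    active: list[int] = []
    signs: list[float] = []
    inactive = np.ones(p, dtype=bool)

    j0 = int(np.argmax(np.abs(c)))
    active.append(j0)
    signs.append(np.sign(c[j0]))
    inactive[j0] = False

    for _ in range(max_steps):
        A = np.array(active)
        s = np.array(signs)
        XA = X[:, A]
        G = XA.T @ XA / n
        try:
            d = np.linalg.solve(G, s)
        except np.linalg.LinAlgError:
            d = np.linalg.lstsq(G, s, rcond=None)[0]
        # correlation decay rates along the direction; a[A] == s by construction
        a = X.T @ (XA @ d) / n

        # entry events: lam - g == +/- (c_j - g a_j); no entries once the
        # active set reaches the interpolation limit (drops may still occur)
        gamma_entry = np.inf
        j_entry = -1
        if inactive.any() and len(active) < active_limit:
            cj = c[inactive]
            aj = a[inactive]
            idx = np.where(inactive)[0]
            for sign in (1.0, -1.0):
                denom = 1.0 - sign * aj
                with np.errstate(divide="ignore", invalid="ignore"):
                    g = (lam - sign * cj) / denom
                g[denom <= _EPS] = np.inf
                g[g <= _EPS] = np.inf
                k = int(np.argmin(g))
                if g[k] < gamma_entry:
                    gamma_entry = float(g[k])
                    j_entry = int(idx[k])

        # drop events: beta_i + g * s_i d_i... coefficient hits zero
        gamma_drop = np.inf
        i_drop = -1
        bA = beta[A]
        with np.errstate(divide="ignore", invalid="ignore"):
            gd = -bA / d
        gd[gd <= _EPS] = np.inf
        if np.isfinite(gd).any():
            k = int(np.argmin(gd))
            if gd[k] < gamma_drop:
                gamma_drop = float(gd[k])
                i_drop = k

        gamma_end = lam - lam_min
        gamma = min(gamma_entry, gamma_drop, gamma_end)
        if not np.isfinite(gamma) or gamma <= 0:
            break

        beta[A] = bA + gamma * d
        c = c - gamma * a
        lam = lam - gamma

        if gamma == gamma_end or lam <= lam_min + _EPS:
            lams.append(lam)
            coefs.append(beta.copy())
            break

        if gamma == gamma_drop and i_drop >= 0:
            jd = active[i_drop]
            beta[jd] = 0.0
            inactive[jd] = True
            del active[i_drop]
            del signs[i_drop]
        else:
            active.append(j_entry)
            signs.append(np.sign(c[j_entry]) if abs(c[j_entry]) > _EPS else 1.0)
            inactive[j_entry] = False

        lams.append(lam)
        coefs.append(beta.copy())

        if not active:
            # re-seed from the largest remaining correlation
            if lam <= lam_min + _EPS:
                break
            j0 = int(np.argmax(np.abs(c)))
            if abs(c[j0]) <= lam_min + _EPS:
                break
            lam = float(abs(c[j0]))
            active.append(j0)
            signs.append(np.sign(c[j0]))
            inactive[j0] = False

    return np.array(lams), np.array(coefs).T


def coefs_at(lams: np.ndarray, coefs: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Evaluate a knot path at arbitrary penalties (linear interpolation).

    Penalties above ``lams[0]`` give zero coefficients; below the final knot
    the last knot's coefficients are held (the path was truncated there).
    """
    grid = np.asarray(grid, dtype=float)
    out = np.zeros((coefs.shape[0], grid.size))
    # np.interp needs increasing x
    xs = lams[::-1]
    for t, g in enumerate(grid):
        if g >= lams[0]:
            continue
        if g <= lams[-1]:
            out[:, t] = coefs[:, -1]
            continue
        k = int(np.searchsorted(xs, g))  # xs[k-1] < g <= xs[k]
        hi = lams.size - 1 - k
        lo = hi + 1  # lams[lo] < g <= lams[hi]
        w = (g - lams[lo]) / (lams[hi] - lams[lo])
        out[:, t] = coefs[:, lo] + w * (coefs[:, hi] - coefs[:, lo])
    return out


def active_at(lams: np.ndarray, coefs: np.ndarray, grid: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Boolean (p,) mask: features with a nonzero coefficient at any grid point."""
    return (np.abs(coefs_at(lams, coefs, grid)) > tol).any(axis=1)
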