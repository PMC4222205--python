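"""Distance matrices and Mantel / partial Mantel permutation inference.

The Mantel statistic is the Pearson (or Spearman, via midrank transform of
the triangle entries) correlation between the n(n-1)/2 lower-triangle
entries of two aligned symmetric matrices.  Its permutation null keeps one
matrix fixed and applies the same random relabelling to the rows and
columns of the other, which preserves the within-matrix dependence
structure that makes naive correlation tests on distance pairs invalid.

The partial Mantel statistic controls a third matrix Z through the
first-order partial correlation r_XY.Z; permutations relabel X only, with
r_XZ recomputed per permutation.  One-sided (greater) p-values with +1
smoothing are the default, matching the directional hypothesis that
between-region divergence exceeds within-region divergence; exhaustive
enumeration of all n! relabellings replaces sampling automatically for
small matrices (n! <= 5040).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sstats
from sklearn.metrics.pairwise import haversine_distances
from statsmodels.stats.multitest import multipletests

from .containers import PairwiseMatrix

__all__ = [
    "MantelResult",
    "EARTH_RADIUS_KM",
    "haversine_matrix",
    "region_indicator_matrix",
    "mantel",
    "partial_mantel",
    "fdr_bh",
]

EARTH_RADIUS_KM = 6371.0

EXHAUSTIVE_LIMIT = 5040  # 7!


@dataclass
class MantelResult:
    """Matrix correlation with its permutation p-value."""

    r: float
    p: float
    n_permutations: int
    method: str
    tail: str
    partial: bool = False
    exhaustive: bool = False
    seed: int | None = None


# ---------------------------------------------------------------------------
# distance matrix construction
# ---------------------------------------------------------------------------

def haversine_matrix(metadata: pd.DataFrame) -> PairwiseMatrix:
    """Great-circle distances between populations in km (Earth radius 6371)."""
    lat = metadata["latitude"].to_numpy(dtype=float)
    lon = metadata["longitude"].to_numpy(dtype=float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range (|lat|<=90, |lon|<=180)")
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("non-finite coordinates")
    rad = np.deg2rad(np.column_stack([lat, lon]))
    km = haversine_distances(rad) * EARTH_RADIUS_KM
    return PairwiseMatrix(
        metadata["population"].tolist(), km, kind="geographic-km"
    )


def region_indicator_matrix(metadata: pd.DataFrame) -> PairwiseMatrix:
    """0/1 matrix: 1 for population pairs spanning the two regions."""
    regions = metadata["region"].to_numpy(dtype=object)
    levels = pd.unique(regions)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 region levels, got {len(levels)}")
    ind = (regions[:, None] != regions[None, :]).astype(float)
    return PairwiseMatrix(
        metadata["population"].tolist(), ind, kind="region-indicator"
    )


# ---------------------------------------------------------------------------
# Mantel machinery
# ---------------------------------------------------------------------------

def _aligned(X: PairwiseMatrix, *others: PairwiseMatrix) -> list[PairwiseMatrix]:
    out = [X]
    for M in others:
        if set(M.labels) != set(X.labels):
            raise ValueError("matrices have different population labels")
        out.append(M if M.labels == X.labels else M.reorder(X.labels))
    return out

def _pearson_rows(xp: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of ``xp`` with the vector ``y``."""
    xc = xp - xp.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (xc @ yc) / denom


def _perm_indices(n: int, n_perm: int, rng) -> tuple[np.ndarray, bool]:
    """Permutations as an index array; exhaustive when n! is small."""
    if math.factorial(n) <= EXHAUSTIVE_LIMIT:
        perms = np.array(list(itertools.permutations(range(n))), dtype=int)
        return perms, True
    perms = np.tile(np.arange(n), (n_perm, 1))
    return rng.permuted(perms, axis=1), False


def _triangle_rows(M: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Triangle vectors of M after each row/column relabelling."""
    n = M.shape[0]
    i, j = np.tril_indices(n, -1)
    return M[perms[:, i], perms[:, j]]


def _tail_p(r_obs: float, r_perm: np.ndarray, tail: str, exhaustive: bool) -> float:
    eps = 1e-12
    if tail == "greater":
        hits = np.sum(r_perm >= r_obs - eps)
    elif tail == "less":
        hits = np.sum(r_perm <= r_obs + eps)
    elif tail == "two-sided":
        hits = np.sum(np.abs(r_perm) >= abs(r_obs) - eps)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    if exhaustive:
        # identity permutation is among the enumerated relabellings
        return float(hits) / r_perm.size
    return float(hits + 1) / (r_perm.size + 1)


def mantel(
    X: PairwiseMatrix,
    Y: PairwiseMatrix,
    method: str = "pearson",
    n_perm: int = 10000,
    seed: int | None = None,
    tail: str = "greater",
) -> MantelResult:
    """Mantel permutation test of association between two matrices.

    The correlation is computed on lower-triangle vectors (midranked first
    for ``method="spearman"``); the null distribution applies the same
    relabelling to X's rows and columns.  Pairs missing (NaN) in either
    matrix are removed pairwise from every correlation.  For n <= 7
    populations all n! relabellings are enumerated and the p-value is
    exact; otherwise ``n_perm`` relabellings are sampled and the p-value is
    (hits + 1)/(n_perm + 1).
    """
    X, Y = _aligned(X, Y)
    n = X.n
    if n < 4:
        raise ValueError("need >= 4 populations for a meaningful Mantel test")
    xm, ym = X.values, Y.values
    missing = ~(np.isfinite(xm) & np.isfinite(ym))
    np.fill_diagonal(missing, False)
    if missing.any():
        # drop pairs missing in either matrix from both triangles
        xm = np.where(missing, np.nan, xm)
        ym = np.where(missing, np.nan, ym)
    if method == "spearman":
        xm = _rank_matrix_nan(xm)
        ym = _rank_matrix_nan(ym)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    i, j = np.tril_indices(n, -1)
    valid = np.isfinite(xm[i, j]) & np.isfinite(ym[i, j])
    x_tri, y_tri = xm[i, j][valid], ym[i, j][valid]
    for name, v in (("X", x_tri), ("Y", y_tri)):
        if v.size < 3 or np.ptp(v) == 0:
            raise ValueError(f"{name} triangle has zero variance; r undefined")
    r_obs = float(_pearson_rows(x_tri[None, :], y_tri)[0])

    rng = np.random.default_rng(seed)
    perms, exhaustive = _perm_indices(n, n_perm, rng)
    xp = _triangle_rows(xm, perms)
    if missing.any():
        r_perm = _pearson_rows_nan(xp, ym[i, j])
    else:
        r_perm = _pearson_rows(xp[:, valid], y_tri)
    p = _tail_p(r_obs, r_perm[np.isfinite(r_perm)], tail, exhaustive)
    return MantelResult(
        r=r_obs,
        p=p,
        n_permutations=perms.shape[0],
        method=method,
        tail=tail,
        partial=False,
        exhaustive=exhaustive,
        seed=seed,
    )


def _rank_matrix_nan(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    i, j = np.tril_indices(n, -1)
    tri = M[i, j]
    ok = np.isfinite(tri)
    ranks = np.full(tri.shape, np.nan)
    ranks[ok] = sstats.rankdata(tri[ok])
    R = np.full_like(M, np.nan, dtype=float)
    R[i, j] = ranks
    R[j, i] = ranks
    np.fill_diagonal(R, 0.0)
    return R


def _pearson_rows_nan(xp: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson with pairwise removal of NaN entries."""
    out = np.empty(xp.shape[0])
    for k in range(xp.shape[0]):
        ok = np.isfinite(xp[k]) & np.isfinite(y)
        if ok.sum() < 3 or np.ptp(xp[k][ok]) == 0 or np.ptp(y[ok]) == 0:
            out[k] = np.nan
        else:
            out[k] = float(_pearson_rows(xp[k][ok][None, :], y[ok])[0])
    return out


def _partial_r(rxy, rxz, ryz) -> float:
    denom = (1.0 - rxz**2) * (1.0 - ryz**2)
    if denom <= 0:
        return np.nan
    return (rxy - rxz * ryz) / math.sqrt(denom)


def partial_mantel(
    X: PairwiseMatrix,
    Y: PairwiseMatrix,
    Z: PairwiseMatrix,
    method: str = "spearman",
    n_perm: int = 10000,
    seed: int | None = None,
    tail: str = "greater",
    permutation: str = "raw",
) -> MantelResult:
    """Partial Mantel test of X ~ Y controlling for Z.

    The statistic is the first-order partial correlation
    r_XY.Z = (r_XY - r_XZ r_YZ) / sqrt((1 - r_XZ²)(1 - r_YZ²)) on triangle
    vectors (midranked for Spearman).  The null relabels X's rows and
    columns, recomputing r_XY and r_XZ per permutation; Y and Z stay
    fixed.  Pairs missing in any matrix are removed from all three
    triangles.

    ``permutation="raw"`` (default) permutes X itself; this is close to
    nominal for moderate X-Z correlation but grows liberal as |r_XZ|
    approaches 1.  ``permutation="residual"`` permutes the matrix of
    triangle-wise residuals of X on Z with the fit added back
    (Freedman-Lane style), which is better calibrated under strong
    confounding.
    """
    X, Y, Z = _aligned(X, Y, Z)
    n = X.n
    if n < 4:
        raise ValueError("need >= 4 populations for a meaningful Mantel test")
    mats = [X.values, Y.values, Z.values]
    missing = ~np.all([np.isfinite(m) for m in mats], axis=0)
    np.fill_diagonal(missing, False)
    mats = [np.where(missing, np.nan, m) for m in mats]
    if method == "spearman":
        mats = [_rank_matrix_nan(m) for m in mats]
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    xm, ym, zm = mats

    i, j = np.tril_indices(n, -1)
    valid = np.isfinite(xm[i, j]) & np.isfinite(ym[i, j]) & np.isfinite(zm[i, j])
    x_tri, y_tri, z_tri = (m[i, j][valid] for m in mats)
    for name, v in (("X", x_tri), ("Y", y_tri), ("Z", z_tri)):
        if v.size < 3 or np.ptp(v) == 0:
            raise ValueError(f"{name} triangle has zero variance")
    r_xy = float(_pearson_rows(x_tri[None, :], y_tri)[0])
    r_xz = float(_pearson_rows(x_tri[None, :], z_tri)[0])
    r_yz = float(_pearson_rows(y_tri[None, :], z_tri)[0])
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise ValueError("|r_XZ| or |r_YZ| is 1: partial correlation undefined")
    r_obs = _partial_r(r_xy, r_xz, r_yz)

    if permutation == "residual":
        # replace X by fitted + residuals of the triangle regression on Z,
        # so relabelling shuffles only the part of X orthogonal to Z
        z_full = zm[i, j]
        ok = np.isfinite(xm[i, j]) & np.isfinite(z_full)
        beta, alpha = np.polyfit(z_full[ok], xm[i, j][ok], 1)
        resid = np.where(ok, xm[i, j] - (alpha + beta * z_full), np.nan)
        xm = np.zeros_like(xm)
        xm[i, j] = resid
        xm[j, i] = resid
        fitted_tri = alpha + beta * z_full
    elif permutation != "raw":
        raise ValueError(f"unknown permutation scheme {permutation!r}")

    rng = np.random.default_rng(seed)
    perms, exhaustive = _perm_indices(n, n_perm, rng)
    xp = _triangle_rows(xm, perms)
    if permutation == "residual":
        xp = xp + fitted_tri
    if missing.any():
        rp_xy = _pearson_rows_nan(xp, ym[i, j])
        rp_xz = _pearson_rows_nan(xp, zm[i, j])
    else:
        rp_xy = _pearson_rows(xp[:, valid], y_tri)
        rp_xz = _pearson_rows(xp[:, valid], z_tri)
    with np.errstate(invalid="ignore"):
        denom = (1.0 - rp_xz**2) * (1.0 - r_yz**2)
        r_perm = np.where(denom > 0, (rp_xy - rp_xz * r_yz) / np.sqrt(denom), np.nan)
    p = _tail_p(r_obs, r_perm[np.isfinite(r_perm)], tail, exhaustive)
    return MantelResult(
        r=float(r_obs),
        p=p,
        n_permutations=perms.shape[0],
        method=method,
        tail=tail,
        partial=True,
        exhaustive=exhaustive,
        seed=seed,
    )


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
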