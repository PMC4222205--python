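"""Environmental standardization, PCA and environmental distances.

Environmental variables arrive in wildly different units (metres, degrees
Celsius x10, mm of rain, index values), so each variable is shifted so its
minimum equals one, log-transformed, and z-scored before any multivariate
step.  PCA is an eigendecomposition of the correlation matrix (the same
operation serves the trait PCA), with a deterministic sign convention so
repeated runs agree.  Environmental distance between two populations is
the equal-weight Euclidean distance on the standardized variables, or the
absolute score difference on one principal axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import PairwiseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "standardize_env",
    "pca",
    "env_distance",
    "pc_axis_distance",
]


@dataclass
class PCAResult:
    """Loadings, scores and variance fractions of a correlation-matrix PCA.

    Components with numerically null eigenvalues (rank-deficient input,
    e.g. 26 variables on 10 populations) are dropped; variance fractions
    stay relative to the total variance of all variables, so they sum to
    one only for full-rank input.
    """

    loadings: pd.DataFrame  # variables x components, unit-norm columns
    scores: pd.DataFrame  # observations x components
    variance_fractions: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def standardize_env(
    raw: pd.DataFrame, population: str = "population"
) -> pd.DataFrame:
    """Shift each variable so its minimum is 1, log, then z-score.

    The shift makes every value positive (the observed minimum maps to
    log 1 = 0) so the log is always defined; the final z-score gives each
    variable mean 0 and unit variance so all 26 variables weigh equally in
    distances and PCA.  Constant variables carry no information and are
    dropped with a warning.
    """
    if len(raw) < 2:
        raise ValueError("need >= 2 populations to standardize")
    out = pd.DataFrame(index=raw.index)
    if population in raw.columns:
        out[population] = raw[population]
    for col in raw.columns:
        if col == population:
            continue
        x = raw[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"variable {col!r} has non-finite values")
        shifted = x + (1.0 - x.min())
        logged = np.log(shifted)
        sd = logged.std(ddof=1)
        if sd == 0.0:
            logger.warning("dropping constant environmental variable %r", col)
            continue
        out[col] = (logged - logged.mean()) / sd
    if out.shape[1] - int(population in out.columns) < 2:
        raise ValueError("fewer than 2 non-constant variables remain")
    return out


def pca(
    table: pd.DataFrame,
    mode: str = "correlation",
    population: str = "population",
) -> PCAResult:
    """PCA of a numeric table via the correlation (or covariance) matrix.

    Rows are observations; a ``population`` column, if present, becomes
    the score index.  Components are ordered by decreasing eigenvalue;
    each loading column is unit norm with its largest-magnitude entry
    positive; eigenvalues below 1e-10 are treated as null and dropped.
    Missing cells raise (impute or drop rows first).
    """
    idx = table[population] if population in table.columns else table.index
    X = table.drop(columns=[population], errors="ignore")
    cols = list(X.columns)
    M = X.to_numpy(dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need >= 2 rows")
    if not np.all(np.isfinite(M)):
        raise ValueError("missing or non-finite cells; impute or drop first")
    if mode == "correlation":
        sd = M.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = [c for c, s in zip(cols, sd) if s == 0]
            raise ValueError(f"constant columns {bad}; drop or standardize first")
        Xs = (M - M.mean(axis=0)) / sd
        S = np.corrcoef(M, rowvar=False)
        S = np.atleast_2d(S)
    elif mode == "covariance":
        Xs = M - M.mean(axis=0)
        S = np.cov(M, rowvar=False)
        S = np.atleast_2d(S)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    eigval, eigvec = np.linalg.eigh(S)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    total = eigval.sum()
    keep = eigval > 1e-10
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(eigvec.shape[1]):
        imax = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[imax, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    names = [f"PC{k + 1}" for k in range(eigvec.shape[1])]
    scores = Xs @ eigvec
    return PCAResult(
        loadings=pd.DataFrame(eigvec, index=cols, columns=names),
        scores=pd.DataFrame(scores, index=pd.Index(idx), columns=names),
        variance_fractions=eigval / total,
        eigenvalues=eigval,
    )


def env_distance(env: pd.DataFrame, population: str = "population") -> PairwiseMatrix:
    """Equal-weight Euclidean distance between populations.

    Expects a standardized table (one row per population) so that every
    variable contributes on the same scale.
    """
    if population not in env.columns:
        raise ValueError(f"column {population!r} required")
    labels = env[population].tolist()
    M = env.drop(columns=[population]).to_numpy(dtype=float)
    d = squareform(pdist(M, metric="euclidean"))
    return PairwiseMatrix(labels, d, kind="environmental")


def pc_axis_distance(result: PCAResult, component: int = 2) -> PairwiseMatrix:
    """|score_i - score_j| on one principal axis (1-based component index)."""
    if not (1 <= component <= result.n_components):
        raise ValueError(
            f"component {component} out of range 1..{result.n_components}"
        )
    s = result.scores[f"PC{component}"].to_numpy(dtype=float)
    d = np.abs(s[:, None] - s[None, :])
    return PairwiseMatrix(
        [str(x) for x in result.scores.index], d, kind=f"env-PC{component}"
    )
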