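"""Nested variance components, heritability and evolvability.

The quantitative-genetic model is a purely nested Gaussian random-effects
ANOVA: replicates within selfed-seed families, families within populations,
populations within (optionally) regions,

    y = mu + region + population + family + residual,

with every factor random and independent.  Two estimators are provided:

* REML, maximising the restricted likelihood of the nested model directly
  (components bounded at zero, so boundary estimates come out clamped); and
* the closed-form expected-mean-squares (EMS, Henderson method-of-moments)
  solution of the unbalanced nested ANOVA, used as a cross-check, as the
  fast path inside the family bootstrap, and as the REML starting point.

On balanced designs with interior estimates the two coincide.

Broad-sense heritability is H² = V_F / (V_F + V_E): with selfed seed
families the among-family variance captures the total genetic variance
within populations, so only broad-sense estimates are meaningful.  The
coefficient of genetic variation CV_G = 100 * sqrt(V_F) / mean (Houle's
evolvability measure) gives a scale-free alternative.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt
import scipy.stats as sstats

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceComponents",
    "HeritabilityEstimate",
    "RegionTestResult",
    "derive_traits",
    "fit_nested_varcomp",
    "heritability",
    "cv_g",
    "bootstrap_heritability_ci",
    "region_f_test",
    "percent_contributions",
]

RESIDUAL = "residual"


@dataclass
class VarianceComponents:
    """Estimated variance components of a nested random-effects model.

    ``components`` maps each grouping level (outermost first) plus
    ``"residual"`` to its estimate, clamped at zero; ``raw`` keeps the
    unclamped values (EMS solutions can be negative).
    """

    levels: tuple[str, ...]
    components: dict[str, float]
    raw: dict[str, float]
    method: str
    converged: bool
    n_obs: int

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.levels) + (RESIDUAL,)

    def __getitem__(self, name: str) -> float:
        return self.components[name]

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))

    def percent(self) -> dict[str, float]:
        return percent_contributions(self.components)


@dataclass
class HeritabilityEstimate:
    """Broad-sense heritability with a family-bootstrap percentile CI."""

    h2: float
    ci: tuple[float, float]
    level: float
    n_boot: int
    cv_g: float
    trait_mean: float
    seed: int | None = None
    boot_values: np.ndarray | None = field(default=None, repr=False)


@dataclass
class RegionTestResult:
    """F-test of regional trait differences against the population stratum."""

    f: float
    df_num: int
    df_den: int
    p: float


# ---------------------------------------------------------------------------
# derived traits
# ---------------------------------------------------------------------------

def derive_traits(
    raw: pd.DataFrame,
    diameter: str = "RosD",
    height: str = "RosH",
    volume: str = "RosV",
    log_volume: str = "logRosV",
    wue: str = "WUE",
) -> pd.DataFrame:
    """Add rosette volume, its log10, and water-use efficiency columns.

    Rosette volume is the cone volume ``pi * (RosD/2)**2 * RosH / 3`` (cm³)
    from the rosette diameter and height in cm.  WUE is the mean over the
    available per-measurement ratios A_i / E_i (carbon fixation over
    transpiration); measurement pairs are taken from columns named
    ``A``/``E`` or ``A1``/``E1`` etc.  Non-positive volumes yield a missing
    log entry with a warning; a measurement with E = 0 is dropped, and a
    plant with no valid measurement gets a missing WUE.
    """
    out = raw.copy()
    # already-derived columns are authoritative; derive only what is absent
    if (
        volume not in out.columns
        and diameter in out.columns
        and height in out.columns
    ):
        r = out[diameter].astype(float) / 2.0
        h = out[height].astype(float)
        vol = math.pi * r**2 * h / 3.0
        out[volume] = vol
        with np.errstate(divide="ignore", invalid="ignore"):
            logv = np.where(vol > 0, np.log10(np.where(vol > 0, vol, 1.0)), np.nan)
        n_bad = int(((vol <= 0) & vol.notna()).sum())
        if n_bad:
            logger.warning(
                "%d non-positive rosette volumes: log volume set to missing", n_bad
            )
        out[log_volume] = logv

    pairs = _wue_pairs(out.columns)
    if wue not in out.columns and pairs:
        ratios = []
        for a_col, e_col in pairs:
            a = out[a_col].astype(float)
            e = out[e_col].astype(float)
            ratios.append(np.where(e != 0, a / np.where(e != 0, e, 1.0), np.nan))
        out[wue] = np.nanmean(np.column_stack(ratios), axis=1)
    return out


def _wue_pairs(columns) -> list[tuple[str, str]]:
    cols = set(columns)
    pairs = []
    for c in columns:
        m = re.fullmatch(r"A(\d*)", str(c))
        if m and f"E{m.group(1)}" in cols:
            pairs.append((c, f"E{m.group(1)}"))
    return pairs


# ---------------------------------------------------------------------------
# nested codes and the EMS (method-of-moments) estimator
# ---------------------------------------------------------------------------

def _nested_codes(data: pd.DataFrame, levels: tuple[str, ...]) -> list[np.ndarray]:
    """Integer group codes per level, nested by construction (full label path)."""
    codes = []
    path = None
    for lev in levels:
        if lev not in data.columns:
            raise ValueError(f"grouping column {lev!r} not in table")
        col = data[lev].astype(str)
        path = col if path is None else path + "\x1f" + col
        codes.append(pd.factorize(path)[0])
    return codes


def _ems_components(y: np.ndarray, codes: list[np.ndarray]) -> np.ndarray:
    """Unbalanced nested ANOVA components by expected mean squares.

    Solves the triangular moment equations E[SS_k] = sum_{j>=k} C_kj V_j +
    df_k V_E for the fully nested classification, outermost level first.
    Returns the raw (possibly negative) estimates, residual last.
    """
    N = y.size
    L = len(codes)
    tot = y.sum()
    counts = [np.bincount(c) for c in codes]
    sums = [np.bincount(c, weights=y) for c in codes]
    T = [tot**2 / N] + [float((s**2 / n).sum()) for s, n in zip(sums, counts)]
    m = [1] + [len(n) for n in counts]
    ss = [T[k] - T[k - 1] for k in range(1, L + 1)]
    ss_e = float((y**2).sum() - T[L])
    df = [m[k] - m[k - 1] for k in range(1, L + 1)]
    df_e = N - m[L]

    # K[k][j]: sum over level-k groups g of sum_{level-j cells c in g} n_c^2 / n_g
    # (k = 0 is the grand stratum); j indexes levels 1..L.
    K = np.zeros((L + 1, L + 1))
    for j in range(1, L + 1):
        n_j = counts[j - 1]
        K[0, j] = float((n_j.astype(float) ** 2).sum() / N)
        for k in range(1, j + 1):
            # ancestor level-k code of each level-j cell, via first occurrence
            _, first_idx = np.unique(codes[j - 1], return_index=True)
            anc = codes[k - 1][first_idx]
            numer = np.bincount(anc, weights=n_j.astype(float) ** 2, minlength=m[k])
            K[k, j] = float((numer / counts[k - 1]).sum())

    V = np.zeros(L + 1)
    V[L] = ss_e / df_e if df_e > 0 else 0.0  # residual, stored last
    out = np.zeros(L + 1)
    out[L] = V[L]
    comp = np.zeros(L)  # V_1..V_L
    for k in range(L, 0, -1):
        rhs = ss[k - 1] - out[L] * df[k - 1]
        for j in range(k + 1, L + 1):
            rhs -= (K[k, j] - K[k - 1, j]) * comp[j - 1]
        c_kk = N - K[k - 1, k]
        comp[k - 1] = rhs / c_kk if c_kk > 0 else 0.0
    out[:L] = comp
    return out


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------

def _reml_neg2loglik_grad(theta: np.ndarray, y: np.ndarray, Zs: list[np.ndarray]):
    """-2 restricted log-likelihood (up to a constant) and its gradient.

    theta = (V_1 .. V_L, V_E); the fixed design is an intercept only, so the
    projection P = Vinv - Vinv 1 1' Vinv / (1' Vinv 1) has rank-one structure
    that keeps every term a Cholesky solve.
    """
    n = y.size
    L = len(Zs)
    V = np.eye(n) * theta[-1]
    for j, Z in enumerate(Zs):
        V += theta[j] * (Z @ Z.T)
    c, low = sla.cho_factor(V, lower=True, check_finite=False)
    logdet = 2.0 * np.log(np.diag(c)).sum()
    ones = np.ones(n)
    Vi1 = sla.cho_solve((c, low), ones, check_finite=False)
    Viy = sla.cho_solve((c, low), y, check_finite=False)
    s = float(ones @ Vi1)
    mu = float(ones @ Viy) / s
    Py = Viy - mu * Vi1
    f = logdet + np.log(s) + float(y @ Py)

    grad = np.empty(L + 1)
    for j, Z in enumerate(Zs):
        A = sla.cho_solve((c, low), Z, check_finite=False)  # Vinv Z
        tr_ViG = float((Z * A).sum())
        u = Z.T @ Vi1
        tr_PG = tr_ViG - float(u @ u) / s
        w = Z.T @ Py
        grad[j] = tr_PG - float(w @ w)
    ViVi = sla.cho_solve((c, low), np.eye(n), check_finite=False)
    tr_Vi = float(np.trace(ViVi))
    tr_P = tr_Vi - float(Vi1 @ Vi1) / s
    grad[-1] = tr_P - float(Py @ Py)
    return f, grad


def _reml_components(
    y: np.ndarray, codes: list[np.ndarray], start: np.ndarray
) -> tuple[np.ndarray, bool]:
    n = y.size
    Zs = []
    for c in codes:
        Z = np.zeros((n, c.max() + 1))
        Z[np.arange(n), c] = 1.0
        Zs.append(Z)
    vary = float(np.var(y))
    if vary == 0.0:
        return np.zeros(len(codes) + 1), True
    scale = vary
    x0 = np.maximum(start / scale, 1e-6)
    ys = (y - y.mean()) / math.sqrt(scale)
    bounds = [(0.0, None)] * len(codes) + [(1e-9, None)]
    opts = {"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500}
    res = sopt.minimize(
        _reml_neg2loglik_grad, x0, args=(ys, Zs), jac=True,
        method="L-BFGS-B", bounds=bounds, options=opts,
    )
    if not res.success:
        # boundary line searches occasionally abort; retry from a flat start
        res2 = sopt.minimize(
            _reml_neg2loglik_grad,
            np.full_like(x0, 1.0 / (len(x0))),
            args=(ys, Zs), jac=True, method="L-BFGS-B",
            bounds=bounds, options=opts,
        )
        if res2.success or res2.fun < res.fun:
            res = res2
    return res.x * scale, bool(res.success)


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------

def fit_nested_varcomp(
    data: pd.DataFrame,
    trait: str,
    levels: tuple[str, ...] = ("region", "population", "family"),
    method: str = "reml",
) -> VarianceComponents:
    """Estimate nested variance components for one trait.

    Parameters
    ----------
    data
        Table with one row per observation, containing the grouping label
        columns in ``levels`` (outermost first) and the trait column.
        Missing trait values are dropped.
    trait
        Trait column name.
    levels
        Nesting, outermost first, e.g. ``("region", "population",
        "family")`` or ``("population", "family")``; the residual stratum
        is implicit.
    method
        ``"reml"`` (default) or ``"ems"`` (closed-form expected mean
        squares).  REML falls back to the clamped EMS solution, flagged
        not-converged, if the optimiser fails.
    """
    levels = tuple(levels)
    keep = data[trait].notna()
    sub = data.loc[keep]
    if len(sub) == 0:
        raise ValueError(f"trait {trait!r} has no non-missing observations")
    codes = _nested_codes(sub, levels)
    for lev, c in zip(levels, codes):
        if c.max() + 1 < 2:
            raise ValueError(f"level {lev!r} has a single group; need >= 2")
    y = sub[trait].to_numpy(dtype=float)

    ems_raw = _ems_components(y, codes)
    if method == "ems":
        raw, converged = ems_raw, True
    elif method == "reml":
        raw, converged = _reml_components(y, codes, np.maximum(ems_raw, 0.0))
        if not converged:
            logger.warning(
                "REML did not converge for %s; using EMS estimates", trait
            )
            raw = ems_raw
    else:
        raise ValueError(f"unknown method {method!r}")

    names = levels + (RESIDUAL,)
    clamped = np.maximum(raw, 0.0)
    return VarianceComponents(
        levels=levels,
        components={n: float(v) for n, v in zip(names, clamped)},
        raw={n: float(v) for n, v in zip(names, raw)},
        method=method,
        converged=converged,
        n_obs=int(len(y)),
    )


def percent_contributions(components: dict[str, float]) -> dict[str, float]:
    """Each component as a percentage of the component total."""
    vals = {k: float(v) for k, v in components.items()}
    total = sum(vals.values())
    if total <= 0:
        raise ValueError("component total is zero; percentages undefined")
    return {k: 100.0 * v / total for k, v in vals.items()}


def heritability(vc, v_e: float | None = None) -> float:
    """Broad-sense heritability H² = V_F / (V_F + V_E).

    Accepts either a :class:`VarianceComponents` (using its family and
    residual entries) or the two components as plain numbers.
    """
    if isinstance(vc, VarianceComponents):
        v_f = vc.components[vc.levels[-1]]
        v_e = vc.components[RESIDUAL]
    else:
        v_f = float(vc)
        if v_e is None:
            raise ValueError("supply v_e when passing V_F as a number")
    if v_f < 0 or v_e < 0:
        raise ValueError("variance components must be non-negative")
    denom = v_f + v_e
    if denom == 0:
        raise ValueError("V_F + V_E = 0: heritability undefined")
    return v_f / denom


def cv_g(v_f: float, trait_mean: float) -> float:
    """Coefficient of genetic variation, 100 * sqrt(V_F) / mean (percent)."""
    if trait_mean <= 0:
        raise ValueError("CV_G requires a positive trait mean")
    if v_f < 0:
        raise ValueError("V_F must be non-negative")
    return 100.0 * math.sqrt(v_f) / trait_mean


def bootstrap_heritability_ci(
    data: pd.DataFrame,
    trait: str,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    levels: tuple[str, ...] = ("region", "population", "family"),
    point_method: str = "reml",
) -> HeritabilityEstimate:
    """Heritability with a family-resampling percentile bootstrap CI.

    Families are resampled with replacement within their population, each
    carrying all its replicates; the variance components are refit per
    resample (closed-form EMS, so a thousand resamples stay cheap) and the
    percentile interval of H² is returned.  The point estimate uses
    ``point_method``.
    """
    levels = tuple(levels)
    if levels[-1] != "family" and "family" not in levels:
        raise ValueError("deepest level must be the family stratum")
    keep = data[trait].notna()
    sub = data.loc[keep].reset_index(drop=True)
    codes = _nested_codes(sub, levels)
    y = sub[trait].to_numpy(dtype=float)
    point_vc = fit_nested_varcomp(sub, trait, levels=levels, method=point_method)
    h2_point = heritability(point_vc)

    fam = codes[-1]
    pop = codes[-2] if len(codes) >= 2 else np.zeros_like(fam)
    n_fam = fam.max() + 1
    fam_rows = [np.flatnonzero(fam == f) for f in range(n_fam)]
    fam_sizes = np.array([r.size for r in fam_rows])
    # population (and higher-level) code of each family
    _, first_idx = np.unique(fam, return_index=True)
    fam_pop = pop[first_idx]
    fam_upper = [c[first_idx] for c in codes[:-1]]
    pops = np.unique(fam_pop)
    fams_by_pop = [np.flatnonzero(fam_pop == p) for p in pops]
    if any(len(f) < 2 for f in fams_by_pop):
        raise ValueError("every population needs >= 2 families to bootstrap")

    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    L = len(levels)
    for b in range(n_boot):
        chosen = np.concatenate(
            [rng.choice(f, size=f.size, replace=True) for f in fams_by_pop]
        )
        sizes = fam_sizes[chosen]
        rows = np.concatenate([fam_rows[f] for f in chosen])
        yb = y[rows]
        cb = [np.repeat(fu[chosen], sizes) for fu in fam_upper]
        cb.append(np.repeat(np.arange(chosen.size), sizes))
        # upper-level codes keep their original (dense) values: resampling
        # within populations cannot drop a population or region
        comps = np.maximum(_ems_components(yb, cb), 0.0)
        denom = comps[-2] + comps[-1]
        boot[b] = comps[-2] / denom if denom > 0 else np.nan
    valid = boot[~np.isnan(boot)]
    if valid.size == 0:
        raise ValueError("all bootstrap resamples degenerate")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(valid, [alpha, 1.0 - alpha])
    mean = float(sub[trait].mean())
    return HeritabilityEstimate(
        h2=float(h2_point),
        ci=(float(lo), float(hi)),
        level=level,
        n_boot=n_boot,
        cv_g=cv_g(point_vc.components[levels[-1]], mean) if mean > 0 else float("nan"),
        trait_mean=mean,
        seed=seed,
        boot_values=boot,
    )


def region_f_test(
    data: pd.DataFrame,
    trait: str,
    region: str = "region",
    population: str = "population",
) -> RegionTestResult:
    """F-test of region means against the population-within-region stratum.

    In the nested design the populations, not the plants, are the
    replicates for a regional contrast, so F = MS(region) / MS(population
    within region) with (n_regions - 1, n_pops - n_regions) degrees of
    freedom -- (1, 8) for ten populations in two regions.
    """
    keep = data[trait].notna()
    sub = data.loc[keep]
    codes = _nested_codes(sub, (region, population))
    y = sub[trait].to_numpy(dtype=float)
    n_reg = codes[0].max() + 1
    n_pop = codes[1].max() + 1
    if n_reg < 2:
        raise ValueError("need >= 2 regions")
    per_region_pops = pd.Series(codes[1]).groupby(pd.Series(codes[0])).nunique()
    if (per_region_pops < 2).any():
        raise ValueError("each region needs >= 2 populations for the F denominator")
    N = y.size
    tot = y.sum()
    T0 = tot**2 / N
    T1 = float(
        (np.bincount(codes[0], weights=y) ** 2 / np.bincount(codes[0])).sum()
    )
    T2 = float(
        (np.bincount(codes[1], weights=y) ** 2 / np.bincount(codes[1])).sum()
    )
    ss_r, ss_p = T1 - T0, T2 - T1
    df_num, df_den = n_reg - 1, n_pop - n_reg
    ms_r, ms_p = ss_r / df_num, ss_p / df_den
    if ms_p == 0:
        f = math.inf if ms_r > 0 else 0.0
    else:
        f = ms_r / ms_p
    p = float(sstats.f.sf(f, df_num, df_den))
    return RegionTestResult(f=float(f), df_num=df_num, df_den=df_den, p=p)
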