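"""Pairwise quantitative (Q_ST) and neutral (F_ST, R_ST) divergence.

Q_ST for a pair of populations is V_P / (V_P + 2 V_F), with V_P and V_F the
population and family-within-population components of a two-level nested
ANOVA restricted to that pair; under selfed seed families the among-family
variance stands in for the additive variance of the classical formula.

F_ST is Weir & Cockerham's (1984) theta for multiallelic codominant data:
per-locus, per-allele variance components a (among populations), b (among
individuals within populations) and c (within individuals), combined over
alleles and loci as a ratio of sums.  R_ST is the allele-size analogue
(Slatkin 1995): the among-population variance component of allele sizes
over the total, suited to stepwise-mutating microsatellites.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .containers import MISSING_ALLELE, GenotypeTable, PairwiseMatrix
from .quantgen import _ems_components, fit_nested_varcomp

logger = logging.getLogger(__name__)

__all__ = [
    "pairwise_qst",
    "weir_cockerham_fst",
    "slatkin_rst",
    "build_divergence_matrix",
]


def pairwise_qst(
    traits: pd.DataFrame,
    trait: str,
    pop_a: str,
    pop_b: str,
    method: str = "ems",
    population: str = "population",
    family: str = "family",
) -> float:
    """Q_ST = V_P / (V_P + 2 V_F) for one pair of populations.

    Components are estimated from a nested ANOVA (population,
    family-within-population, residual) on the two populations' data and
    clamped at zero before forming the ratio, so a pair with no estimated
    population variance has Q_ST = 0; if both V_P and V_F vanish Q_ST is
    defined as 0.

    ``method`` selects the component estimator (``"ems"``: closed-form
    nested-ANOVA moments, the default; ``"reml"``).
    """
    sub = traits[traits[population].isin([pop_a, pop_b])]
    sub = sub[sub[trait].notna()]
    for p in (pop_a, pop_b):
        rows = sub[sub[population] == p]
        if len(rows) == 0:
            raise ValueError(f"trait {trait!r} entirely missing in population {p!r}")
        if rows[family].nunique() < 2:
            raise ValueError(f"population {p!r} has fewer than 2 families")
    vc = fit_nested_varcomp(sub, trait, levels=(population, family), method=method)
    v_p = vc.components[population]
    v_f = vc.components[family]
    denom = v_p + 2.0 * v_f
    if denom == 0.0:
        return 0.0
    return v_p / denom


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(genos: GenotypeTable, pops: list[str]):
    """Per-locus, per-allele W&C (a, b, c) sums for the given populations.

    Yields (sum_a, sum_abc) accumulated over all alleles of all loci; loci
    with fewer than two populations called, or monomorphic, contribute
    nothing (their components are identically zero).
    """
    r = len(pops)
    masks = [genos.populations == p for p in pops]
    sum_a = 0.0
    sum_abc = 0.0
    for locus in range(len(genos.loci)):
        calls = genos.alleles[:, locus, :]
        called = calls[:, 0] != MISSING_ALLELE
        n_i = np.array([int((m & called).sum()) for m in masks], dtype=float)
        if (n_i < 1).any() or n_i.sum() < 2:
            continue
        pair_called = np.logical_or.reduce(masks) & called
        alleles = np.unique(calls[pair_called])
        alleles = alleles[alleles != MISSING_ALLELE]
        if alleles.size < 2:
            continue  # monomorphic within the pair
        n_bar = n_i.mean()
        if n_bar <= 1:
            continue
        n_c = (r * n_bar - (n_i**2).sum() / (r * n_bar)) / (r - 1)
        for u in alleles:
            p_i = np.empty(r)
            h_i = np.empty(r)
            for k, m in enumerate(masks):
                g = calls[m & called]
                count_u = (g == u).sum()
                p_i[k] = count_u / (2.0 * n_i[k])
                h_i[k] = ((g == u).sum(axis=1) == 1).mean()
            p_bar = (n_i * p_i).sum() / (r * n_bar)
            s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (n_i * h_i).sum() / (r * n_bar)
            a = (n_bar / n_c) * (
                s2
                - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
                / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - s2 * (r - 1) / r
                - h_bar * (2 * n_bar - 1) / (4 * n_bar)
            )
            c = h_bar / 2.0
            sum_a += a
            sum_abc += a + b + c
    return sum_a, sum_abc


def weir_cockerham_fst(
    genos: GenotypeTable, pop_a: str, pop_b: str
) -> float:
    """Weir & Cockerham's theta for one pair of populations.

    Components are summed over all alleles of all polymorphic loci
    (ratio-of-sums weighting); missing calls drop out of that locus's
    counts only.  Raises if every locus is monomorphic across the pair.
    """
    sum_a, sum_abc = _wc_components(genos, [pop_a, pop_b])
    if sum_abc == 0.0:
        raise ValueError(
            f"theta undefined: no polymorphic locus for pair ({pop_a}, {pop_b})"
        )
    return sum_a / sum_abc


# ---------------------------------------------------------------------------
# Slatkin R_ST
# ---------------------------------------------------------------------------

def slatkin_rst(genos: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Allele-size variance analogue of F_ST for one population pair.

    Per locus, allele sizes are decomposed by a one-way ANOVA over
    populations (each allele copy one observation): S_w is the
    within-population mean square and the among-population component is
    (MS_among - S_w) / n0 with the usual unbalanced-design coefficient.
    Components are pooled over loci by summing, and
    R_ST = S_among / (S_among + S_w) = (S_bar - S_w) / S_bar.
    """
    pops = [pop_a, pop_b]
    masks = [genos.populations == p for p in pops]
    among = 0.0
    within_ms = 0.0
    for locus in range(len(genos.loci)):
        calls = genos.alleles[:, locus, :]
        called = calls[:, 0] != MISSING_ALLELE
        groups = []
        for m in masks:
            g = calls[m & called].ravel().astype(float)
            if g.size:
                groups.append(g)
        if len(groups) < 2:
            continue
        n_i = np.array([g.size for g in groups], dtype=float)
        N = n_i.sum()
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        ss_among = sum(n * (g.mean() - grand) ** 2 for n, g in zip(n_i, groups))
        df_w = N - len(groups)
        df_a = len(groups) - 1
        if df_w <= 0:
            continue
        ms_w = ss_within / df_w
        ms_a = ss_among / df_a
        n0 = (N - (n_i**2).sum() / N) / df_a
        among += (ms_a - ms_w) / n0
        within_ms += ms_w
    total = among + within_ms
    if total == 0.0:
        raise ValueError(
            f"R_ST undefined: no allele-size variance for pair ({pop_a}, {pop_b})"
        )
    return among / total


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def _qst_matrix_ems(
    traits: pd.DataFrame,
    trait: str,
    pops: list[str],
    population: str = "population",
    family: str = "family",
) -> PairwiseMatrix:
    """All-pairs Q_ST with the closed-form nested-ANOVA estimator.

    Equivalent to calling :func:`pairwise_qst` per pair (same moment
    equations) but with the per-population data extracted once.
    """
    sub = traits[traits[trait].notna()]
    per_pop: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for p in pops:
        rows = sub[sub[population] == p]
        y = rows[trait].to_numpy(dtype=float)
        fam = pd.factorize(rows[family])[0]
        per_pop[p] = (y, fam)
    n = len(pops)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        (y1, f1), (y2, f2) = per_pop[pops[i]], per_pop[pops[j]]
        if (
            y1.size == 0
            or y2.size == 0
            or (f1.max() + 1 if f1.size else 0) < 2
            or (f2.max() + 1 if f2.size else 0) < 2
        ):
            logger.warning(
                "QST undefined for (%s, %s): missing data or single family",
                pops[i],
                pops[j],
            )
            values[i, j] = values[j, i] = np.nan
            continue
        y = np.concatenate([y1, y2])
        pop_codes = np.concatenate(
            [np.zeros(y1.size, dtype=int), np.ones(y2.size, dtype=int)]
        )
        fam_codes = np.concatenate([f1, f2 + f1.max() + 1])
        comps = np.maximum(_ems_components(y, [pop_codes, fam_codes]), 0.0)
        v_p, v_f = comps[0], comps[1]
        denom = v_p + 2.0 * v_f
        values[i, j] = values[j, i] = v_p / denom if denom > 0 else 0.0
    return PairwiseMatrix(list(pops), values, kind="QST")


def build_divergence_matrix(
    source,
    statistic: str,
    trait: str | None = None,
    populations: list[str] | None = None,
    **kwargs,
) -> PairwiseMatrix:
    """Evaluate a pairwise divergence statistic over all population pairs.

    ``source`` is a trait table (DataFrame) for ``statistic="QST"`` (with
    ``trait`` naming the column) or a :class:`GenotypeTable` for ``"FST"``
    / ``"RST"``.  Pairs where the statistic is undefined are stored as NaN
    and logged.  Extra keyword arguments pass through to the element-wise
    operation.
    """
    statistic = statistic.upper()
    if statistic == "QST":
        if trait is None:
            raise ValueError("QST requires a trait name")
        pops = populations or list(pd.unique(source["population"]))
        if len(pops) < 2:
            raise ValueError("need >= 2 populations")
        if kwargs.get("method", "ems") == "ems":
            return _qst_matrix_ems(source, trait, list(pops))

        def element(a, b):
            return pairwise_qst(source, trait, a, b, **kwargs)

    elif statistic in ("FST", "RST"):
        pops = populations or source.population_labels
        fn = weir_cockerham_fst if statistic == "FST" else slatkin_rst

        def element(a, b):
            return fn(source, a, b, **kwargs)

    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    n = len(pops)
    if n < 2:
        raise ValueError("need >= 2 populations")
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        try:
            v = element(pops[i], pops[j])
        except ValueError as exc:
            logger.warning("%s undefined for (%s, %s): %s", statistic, pops[i], pops[j], exc)
            v = np.nan
        values[i, j] = values[j, i] = v
    return PairwiseMatrix(list(pops), values, kind=statistic)
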