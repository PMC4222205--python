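"""End-to-end regional-divergence analysis.

Sequences the whole study: descriptive statistics and regional F-tests per
trait, nested variance components with heritabilities and CV_G, pairwise
Q_ST matrices for every trait, a microsatellite F_ST matrix, geographic
and environmental distance matrices, and the Mantel / partial-Mantel test
battery with Benjamini-Hochberg FDR control within each test family
(regional F-tests; partial Mantel Q_ST-region tests; Q_ST-environment
Mantel tests).

Default synthetic inputs reproduce the study design: two regions holding
3 + 7 populations of a highly selfing plant, selfed seed families with
uneven family and replicate counts, five traits (leaf width, rosette
diameter/height, log rosette volume, water-use efficiency) with regional
mean shifts, 13 microsatellite loci at strong neutral differentiation, and
26 block-correlated environmental variables with a regional offset on the
precipitation block.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io, env_pca, matrix_stats, quantgen
from .containers import GenotypeTable, PairwiseMatrix
from .divergence import build_divergence_matrix
from .synthetic_data import (
    SimEnvConfig,
    SimGenotypeConfig,
    SimTraitConfig,
    simulate_environment,
    simulate_metadata,
    simulate_microsatellites,
    simulate_trait_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "AnalysisReport",
    "default_trait_configs",
    "default_synthetic_inputs",
    "run_full_analysis",
    "medians_within_between",
    "write_report",
]

#: Per-trait (V_R, V_P, V_F, V_E), grand mean and WEST-vs-EAST mean shift
#: for the default synthetic study.  Variance components follow the
#: study's published nested ANOVA estimates; regional shifts equal the
#: difference of the published regional trait means, with the region
#: effect carried by the fixed shift (V_R = 0 in the generator).
DEFAULT_TRAITS: dict[str, dict] = {
    "Leaf": {"vc": (0.0, 0.002, 0.017, 0.011), "mean": 0.62, "shift": 0.15},
    "RosD": {"vc": (0.0, 0.409, 1.879, 0.899), "mean": 5.24, "shift": 1.59},
    "RosH": {"vc": (0.0, 0.378, 0.575, 0.420), "mean": 3.05, "shift": 1.13},
    "RosV": {"vc": (0.0, 0.007, 0.050, 0.021), "mean": 0.82, "shift": 0.23},
    "WUE": {"vc": (0.0, 0.001, 0.029, 0.283), "mean": 0.89, "shift": 0.45},
}


@dataclass
class PipelineConfig:
    """Settings for one full analysis run."""

    trait_names: list[str] = field(default_factory=lambda: list(DEFAULT_TRAITS))
    n_perm: int = 10000
    n_boot: int = 1000
    seed: int = 0
    qst_method: str = "ems"
    varcomp_method: str = "reml"
    mantel_method: str = "spearman"
    fdr_alpha: float = 0.05
    compute_rst: bool = True
    per_region_varcomp: bool = True


@dataclass
class AnalysisReport:
    """All tables and matrices produced by one run."""

    region_tests: pd.DataFrame
    varcomp: pd.DataFrame
    trait_pca_loadings: pd.DataFrame
    trait_pca_fractions: pd.Series
    qst: dict[str, PairwiseMatrix]
    fst: PairwiseMatrix
    rst: PairwiseMatrix | None
    geographic: PairwiseMatrix
    region_indicator: PairwiseMatrix
    ibd: matrix_stats.MantelResult
    partial_mantel: pd.DataFrame
    env_standardized: pd.DataFrame
    env_pca_loadings: pd.DataFrame
    env_pca_fractions: pd.Series
    mantel_env: pd.DataFrame
    medians: pd.DataFrame
    scatter: pd.DataFrame
    summary: dict


def default_trait_configs(
    seed: int,
    families_per_pop=(8, 14),
    reps_per_family=(3, 6),
    trait_overrides: dict | None = None,
) -> list[SimTraitConfig]:
    """The default five-trait synthetic design (3 + 7 populations)."""
    specs = dict(DEFAULT_TRAITS)
    if trait_overrides:
        specs = {k: {**v, **trait_overrides.get(k, {})} for k, v in specs.items()}
    configs = []
    for t, (name, spec) in enumerate(specs.items()):
        configs.append(
            SimTraitConfig(
                trait_name=name,
                n_regions=2,
                pops_per_region=(3, 7),
                families_per_pop=families_per_pop,
                reps_per_family=reps_per_family,
                variance_components=tuple(spec["vc"]),
                grand_mean=spec["mean"],
                region_mean_shifts=(spec["shift"], 0.0),
                seed=seed * 1000 + t,
            )
        )
    return configs


def default_synthetic_inputs(seed: int, **trait_kwargs):
    """Synthetic traits, genotypes, metadata and environment for one seed."""
    # R1 is the WEST analogue (3 populations), R2 the EAST (7)
    metadata = simulate_metadata(
        (3, 7), region_names=("R1", "R2"), seed=seed * 1000 + 90
    )
    traits = simulate_trait_table(default_trait_configs(seed, **trait_kwargs))
    genos = simulate_microsatellites(
        SimGenotypeConfig(
            n_pops=10,
            inds_per_pop=15,
            n_loci=13,
            alleles_per_locus=6,
            target_fst=0.4,
            selfing_rate=0.9,
            seed=seed * 1000 + 91,
        )
    )
    # relabel simulated POPxx populations with the metadata labels, and
    # rename individuals to match so GenePop round-trips stay consistent
    new_pops = np.asarray(
        [metadata["population"].iloc[int(p[3:5]) - 1] for p in genos.populations],
        dtype=object,
    )
    genos = GenotypeTable(
        [f"{p}_{ind.rsplit('_', 1)[1]}" for p, ind in zip(new_pops, genos.individuals)],
        new_pops,
        genos.loci,
        genos.alleles,
    )
    env = simulate_environment(
        SimEnvConfig(
            shift_magnitude=2.0,
            region_shift_block="precipitation",
            shift_region="R1",  # the WEST analogue
            seed=seed * 1000 + 92,
        ),
        metadata,
    )
    return traits, genos, metadata, env


def medians_within_between(
    matrix: PairwiseMatrix, indicator: PairwiseMatrix
) -> tuple[float, float]:
    """Medians of the pairwise values within (0) and between (1) regions."""
    if indicator.labels != matrix.labels:
        indicator = indicator.reorder(matrix.labels)
    vals = matrix.triangle()
    ind = indicator.triangle()
    within = vals[(ind == 0) & np.isfinite(vals)]
    between = vals[(ind == 1) & np.isfinite(vals)]
    med_w = float(np.median(within)) if within.size else float("nan")
    med_b = float(np.median(between)) if between.size else float("nan")
    return med_w, med_b


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-18s %.2fs", name, t1 - t0)
    return t1


def run_full_analysis(
    traits: pd.DataFrame,
    genotypes: GenotypeTable,
    metadata: pd.DataFrame,
    environment: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> AnalysisReport:
    """Run the full divergence analysis on the given inputs.

    Deterministic for a fixed config seed: every permutation test and
    bootstrap derives its seed from ``config.seed``.
    """
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    t0 = time.perf_counter()

    traits = quantgen.derive_traits(traits)
    trait_names = [t for t in cfg.trait_names if t in traits.columns]
    if not trait_names:
        raise ValueError("none of the configured traits are present")
    pops = metadata["population"].tolist()

    # --- regional descriptive tests -------------------------------------
    rows = []
    for t in trait_names:
        res = quantgen.region_f_test(traits, t)
        by_region = traits.groupby("region")[t].agg(["count", "mean", "std"])
        rows.append(
            {
                "trait": t,
                "F": res.f,
                "df_num": res.df_num,
                "df_den": res.df_den,
                "p": res.p,
                **{
                    f"{stat}_{reg}": by_region.loc[reg, stat]
                    for reg in by_region.index
                    for stat in ("count", "mean", "std")
                },
            }
        )
    region_tests = pd.DataFrame(rows)
    region_tests["p_fdr"] = matrix_stats.fdr_bh(region_tests["p"])
    region_tests["significant_fdr"] = region_tests["p_fdr"] < cfg.fdr_alpha
    t0 = _stage("region-tests", t0)

    # --- variance components, heritability, CV_G ------------------------
    vc_rows = []
    scopes = [("BOTH", traits, ("region", "population", "family"))]
    if cfg.per_region_varcomp:
        for reg, sub in traits.groupby("region"):
            scopes.append((reg, sub, ("population", "family")))
    for scope, data, levels in scopes:
        for t in trait_names:
            vc = quantgen.fit_nested_varcomp(
                data, t, levels=levels, method=cfg.varcomp_method
            )
            pct = vc.percent()
            est = quantgen.bootstrap_heritability_ci(
                data,
                t,
                n_boot=cfg.n_boot,
                seed=int(rng.integers(2**31 - 1)),
                levels=levels,
                point_method=cfg.varcomp_method,
            )
            row = {"scope": scope, "trait": t, "method": vc.method}
            for name in vc.names:
                row[f"V_{name}"] = vc.components[name]
                row[f"pct_{name}"] = pct[name]
            row.update(
                {
                    "H2": est.h2,
                    "H2_ci_low": est.ci[0],
                    "H2_ci_high": est.ci[1],
                    "n_boot": est.n_boot,
                    "CV_G": est.cv_g,
                    "trait_mean": est.trait_mean,
                    "converged": vc.converged,
                }
            )
            vc_rows.append(row)
    varcomp = pd.DataFrame(vc_rows)
    t0 = _stage("varcomp", t0)

    # --- trait PCA -------------------------------------------------------
    complete = traits[trait_names].dropna()
    trait_pca = env_pca.pca(complete, mode="correlation")
    t0 = _stage("trait-pca", t0)

    # --- divergence matrices ---------------------------------------------
    qst = {
        t: build_divergence_matrix(
            traits, "QST", trait=t, populations=pops, method=cfg.qst_method
        )
        for t in trait_names
    }
    fst = build_divergence_matrix(genotypes, "FST", populations=pops)
    rst = (
        build_divergence_matrix(genotypes, "RST", populations=pops)
        if cfg.compute_rst
        else None
    )
    t0 = _stage("divergence", t0)

    # --- geographic structure --------------------------------------------
    geo = matrix_stats.haversine_matrix(metadata)
    indicator = matrix_stats.region_indicator_matrix(metadata)
    ibd = matrix_stats.mantel(
        fst,
        geo,
        method=cfg.mantel_method,
        n_perm=cfg.n_perm,
        seed=int(rng.integers(2**31 - 1)),
    )
    t0 = _stage("geography", t0)

    # --- partial Mantel: Q_ST ~ region | F_ST ----------------------------
    pm_rows = []
    for t in trait_names:
        res = matrix_stats.partial_mantel(
            qst[t],
            indicator,
            fst,
            method=cfg.mantel_method,
            n_perm=cfg.n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        pm_rows.append(
            {
                "trait": t,
                "r": res.r,
                "p": res.p,
                "n_perm": res.n_permutations,
                "tail": res.tail,
                "method": res.method,
            }
        )
    partial = pd.DataFrame(pm_rows)
    partial["p_fdr"] = matrix_stats.fdr_bh(partial["p"])
    partial["significant_fdr"] = partial["p_fdr"] < cfg.fdr_alpha
    t0 = _stage("partial-mantel", t0)

    # --- environment ------------------------------------------------------
    env_order = (
        environment.set_index("population").loc[pops].reset_index()
    )
    env_std = env_pca.standardize_env(env_order)
    epca = env_pca.pca(env_std, mode="correlation")
    env_dist = env_pca.env_distance(env_std)
    pc2_dist = env_pca.pc_axis_distance(epca, component=2)
    env_rows = []
    env_tests = [
        ("Distance", geo, "Environment", env_dist),
        ("Distance", geo, "EnvironmentPC2", pc2_dist),
        ("Region", indicator, "Environment", env_dist),
        ("Region", indicator, "EnvironmentPC2", pc2_dist),
    ]
    for t in trait_names:
        env_tests.append((f"QST-{t}", qst[t], "Environment", env_dist))
    for t in trait_names:
        env_tests.append((f"QST-{t}", qst[t], "EnvironmentPC2", pc2_dist))
    for name_a, mat_a, name_b, mat_b in env_tests:
        res = matrix_stats.mantel(
            mat_a,
            mat_b,
            method=cfg.mantel_method,
            n_perm=cfg.n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        env_rows.append(
            {
                "first": name_a,
                "second": name_b,
                "r": res.r,
                "p": res.p,
                "n_perm": res.n_permutations,
                "family": "structure" if name_a in ("Distance", "Region") else "qst_env",
            }
        )
    mantel_env = pd.DataFrame(env_rows)
    mantel_env["p_fdr"] = np.nan
    for fam, idx in mantel_env.groupby("family").groups.items():
        mantel_env.loc[idx, "p_fdr"] = matrix_stats.fdr_bh(mantel_env.loc[idx, "p"])
    mantel_env["significant_fdr"] = mantel_env["p_fdr"] < cfg.fdr_alpha
    t0 = _stage("environment", t0)

    # --- medians and scatter data ----------------------------------------
    med_rows = []
    for name, mat in [("FST", fst)] + [(f"QST-{t}", qst[t]) for t in trait_names]:
        w, b = medians_within_between(mat, indicator)
        med_rows.append({"statistic": name, "median_within": w, "median_between": b})
    medians = pd.DataFrame(med_rows)

    fst_tri = fst.triangle()
    ind_tri = indicator.reorder(fst.labels).triangle()
    pair_idx = fst.pair_index()
    scatter = pd.DataFrame(
        {
            "pop_i": pair_idx.get_level_values(0),
            "pop_j": pair_idx.get_level_values(1),
            "FST": fst_tri,
            "between_region": ind_tri.astype(int),
            **{t: qst[t].reorder(fst.labels).triangle() for t in trait_names},
        }
    )

    summary = {
        "n_populations": len(pops),
        "n_pairs": fst.n_pairs,
        "traits": trait_names,
        "seed": cfg.seed,
        "n_perm": cfg.n_perm,
        "n_boot": cfg.n_boot,
        "ibd": {"r": ibd.r, "p": ibd.p},
        "significant_partial_mantel": partial.loc[
            partial["significant_fdr"], "trait"
        ].tolist(),
        "fst_median_within": medians.loc[0, "median_within"],
        "fst_median_between": medians.loc[0, "median_between"],
    }
    return AnalysisReport(
        region_tests=region_tests,
        varcomp=varcomp,
        trait_pca_loadings=trait_pca.loadings,
        trait_pca_fractions=pd.Series(
            trait_pca.variance_fractions,
            index=trait_pca.loadings.columns,
            name="variance_fraction",
        ),
        qst=qst,
        fst=fst,
        rst=rst,
        geographic=geo,
        region_indicator=indicator,
        ibd=ibd,
        partial_mantel=partial,
        env_standardized=env_std,
        env_pca_loadings=epca.loadings,
        env_pca_fractions=pd.Series(
            epca.variance_fractions, index=epca.loadings.columns, name="variance_fraction"
        ),
        mantel_env=mantel_env,
        medians=medians,
        scatter=scatter,
        summary=summary,
    )


def write_report(report: AnalysisReport, outdir) -> None:
    """Write the report as a directory of delimited tables plus JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.region_tests.to_csv(out / "region_tests.tsv", sep="\t", index=False)
    report.varcomp.to_csv(out / "varcomp.tsv", sep="\t", index=False)
    report.trait_pca_loadings.to_csv(out / "trait_pca_loadings.tsv", sep="\t")
    report.trait_pca_fractions.to_csv(out / "trait_pca_fractions.tsv", sep="\t")
    for t, mat in report.qst.items():
        data_io.write_matrix(mat, out / f"qst_{t}.txt")
    data_io.write_matrix(report.fst, out / "fst.txt")
    if report.rst is not None:
        data_io.write_matrix(report.rst, out / "rst.txt")
    data_io.write_matrix(report.geographic, out / "geographic_km.txt")
    data_io.write_matrix(report.region_indicator, out / "region_indicator.txt")
    report.partial_mantel.to_csv(out / "partial_mantel.tsv", sep="\t", index=False)
    report.env_standardized.to_csv(out / "env_standardized.tsv", sep="\t", index=False)
    report.env_pca_loadings.to_csv(out / "env_pca_loadings.tsv", sep="\t")
    report.env_pca_fractions.to_csv(out / "env_pca_fractions.tsv", sep="\t")
    report.mantel_env.to_csv(out / "mantel_env.tsv", sep="\t", index=False)
    report.medians.to_csv(out / "medians.tsv", sep="\t", index=False)
    report.scatter.to_csv(out / "qst_fst_scatter.tsv", sep="\t", index=False)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(report.summary, fh, indent=2, default=float)
        fh.write("\n")
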