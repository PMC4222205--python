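"""Synthetic trait, genotype, environment and coordinate generators.

The generators emulate the structure of a two-region common-garden study of
a highly selfing perennial plant: ten natural populations (three in a WEST
region, seven in an EAST region), selfed seed families within populations,
and replicate plants within families.

* Traits follow the purely nested Gaussian model
  ``y = mu + shift_region + r + p + f + e`` with independent zero-mean
  effects of variances (V_R, V_P, V_F, V_E); regional mean shifts may be
  fixed offsets on top of the random region effects.
* Microsatellite genotypes use a Balding-Nichols model: per-population
  allele frequencies are Dirichlet-distributed around an ancestral
  frequency vector with concentration (1 - F)/F, which gives expected
  differentiation F_ST = F, and individuals are drawn with the equilibrium
  inbreeding F_IS = s/(2 - s) implied by a selfing rate s.
* Environmental variables are block-correlated Gaussians (temperature-like,
  precipitation-like and topographic-like blocks mirroring the bioclim
  suite) with an optional regional mean shift on one block, exponentiated
  so every value is strictly positive and the downstream log transform is
  exercised.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeTable

__all__ = [
    "SimTraitConfig",
    "SimGenotypeConfig",
    "SimEnvConfig",
    "DEFAULT_ENV_BLOCKS",
    "simulate_traits",
    "simulate_trait_table",
    "simulate_microsatellites",
    "simulate_environment",
    "simulate_metadata",
]


@dataclass
class SimTraitConfig:
    """Design and variance parameters for one simulated trait.

    ``pops_per_region`` gives the number of populations in each region
    (default the study design: 3 WEST + 7 EAST).  ``families_per_pop`` and
    ``reps_per_family`` may be single counts or (low, high) ranges from
    which per-population / per-family counts are drawn uniformly, to mimic
    uneven germination.
    """

    trait_name: str = "trait"
    n_regions: int = 2
    pops_per_region: tuple[int, ...] = (3, 7)
    families_per_pop: int | tuple[int, int] = 10
    reps_per_family: int | tuple[int, int] = 5
    variance_components: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)
    grand_mean: float = 0.0
    region_mean_shifts: tuple[float, ...] | None = None
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.pops_per_region) != self.n_regions:
            raise ValueError("pops_per_region must have one entry per region")
        if any(v < 0 for v in self.variance_components):
            raise ValueError("variance components must be non-negative")
        if len(self.variance_components) != 4:
            raise ValueError("expected (V_R, V_P, V_F, V_E)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if min(self.pops_per_region) < 1:
            raise ValueError("each region needs at least one population")
        if self.region_mean_shifts is not None and len(
            self.region_mean_shifts
        ) != self.n_regions:
            raise ValueError("region_mean_shifts must have one entry per region")


@dataclass
class SimGenotypeConfig:
    """Balding-Nichols microsatellite simulation parameters.

    ``target_fst`` is the drift parameter F of the Balding-Nichols model:
    either a single value shared by all populations or one value per
    population (heterogeneous drift, giving a genuine spread of pairwise
    divergence like the wide range seen in real microsatellite surveys).
    """

    n_pops: int = 10
    inds_per_pop: int = 15
    n_loci: int = 13
    alleles_per_locus: int = 6
    target_fst: float | tuple[float, ...] = 0.2
    selfing_rate: float = 0.9
    allele_size_step: int = 2
    base_allele_size: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        fsts = self.per_pop_fst
        if len(fsts) != self.n_pops:
            raise ValueError("target_fst must be scalar or one value per population")
        if any(not (0.0 <= f < 1.0) for f in fsts):
            raise ValueError("target_fst must be in [0, 1)")
        if self.alleles_per_locus < 2:
            raise ValueError("need >= 2 alleles per locus")
        if not (0.0 <= self.selfing_rate <= 1.0):
            raise ValueError("selfing_rate must be in [0, 1]")

    @property
    def per_pop_fst(self) -> tuple[float, ...]:
        if isinstance(self.target_fst, (tuple, list)):
            return tuple(float(f) for f in self.target_fst)
        return (float(self.target_fst),) * self.n_pops

    @property
    def f_is(self) -> float:
        """Equilibrium inbreeding coefficient under partial selfing."""
        s = self.selfing_rate
        return s / (2.0 - s)


#: Default 26-variable block structure: altitude, 19 bioclim variables
#: (BIO1-11 temperature, BIO12-19 precipitation), five topographic
#: variables and distance to the nearest stream.
DEFAULT_ENV_BLOCKS: dict[str, str] = {
    "ALT": "topographic",
    **{f"BIO{i}": "temperature" for i in range(1, 12)},
    **{f"BIO{i}": "precipitation" for i in range(12, 20)},
    "ASPECT": "topographic",
    "SLOPE": "topographic",
    "FLOWDIR": "topographic",
    "FLOWACC": "topographic",
    "CTI": "topographic",
    "STREAM": "topographic",
}


@dataclass
class SimEnvConfig:
    """Block-correlated environmental-variable simulation parameters."""

    blocks: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ENV_BLOCKS))
    within_block_correlation: float = 0.6
    region_shift_block: str = "precipitation"
    shift_magnitude: float = 0.0
    shift_region: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.blocks) < 2:
            raise ValueError("need >= 2 environmental variables")
        if not (0.0 <= self.within_block_correlation < 1.0):
            raise ValueError(
                "within_block_correlation must be in [0, 1) for a valid covariance"
            )

    @property
    def n_vars(self) -> int:
        return len(self.blocks)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def _counts(spec: int | tuple[int, int], size: int, rng) -> np.ndarray:
    if isinstance(spec, (tuple, list)):
        lo, hi = spec
        return rng.integers(lo, hi + 1, size=size)
    return np.full(size, int(spec))


def _sub_seed(seed: int | None, k: int):
    """Derived stream: independent sub-seeds for design vs trait values."""
    return None if seed is None else [int(seed), k]


def _design(config: SimTraitConfig, rng) -> pd.DataFrame:
    """Draw the nested plant design: region/population/family/replicate."""
    rows_region, rows_pop, rows_fam, rows_rep = [], [], [], []
    fam_id = 0
    region_names = [f"R{r + 1}" for r in range(config.n_regions)]
    for r, region in enumerate(region_names):
        n_pops = config.pops_per_region[r]
        fams_per_pop = _counts(config.families_per_pop, n_pops, rng)
        for p in range(n_pops):
            pop = f"{region}P{p + 1}"
            n_fams = int(fams_per_pop[p])
            reps_per_fam = _counts(config.reps_per_family, n_fams, rng)
            for f in range(n_fams):
                fam_id += 1
                fam = f"F{fam_id:04d}"
                n_rep = int(reps_per_fam[f])
                rows_region += [region] * n_rep
                rows_pop += [pop] * n_rep
                rows_fam += [fam] * n_rep
                rows_rep += list(range(1, n_rep + 1))
    return pd.DataFrame(
        {
            "region": rows_region,
            "population": rows_pop,
            "family": rows_fam,
            "replicate": rows_rep,
        }
    )


def _draw_values(design: pd.DataFrame, config: SimTraitConfig, rng) -> np.ndarray:
    """Draw one trait's values on an existing design."""
    v_r, v_p, v_f, v_e = config.variance_components
    shifts = config.region_mean_shifts or (0.0,) * config.n_regions
    regions = pd.factorize(design["region"])[0]
    pops = pd.factorize(design["population"])[0]
    fams = pd.factorize(design["family"])[0]
    e_r = rng.normal(0.0, np.sqrt(v_r), size=regions.max() + 1)
    e_p = rng.normal(0.0, np.sqrt(v_p), size=pops.max() + 1)
    e_f = rng.normal(0.0, np.sqrt(v_f), size=fams.max() + 1)
    shift = np.asarray(shifts, dtype=float)[regions]
    n = len(design)
    y = (
        config.grand_mean
        + shift
        + e_r[regions]
        + e_p[pops]
        + e_f[fams]
        + rng.normal(0.0, np.sqrt(v_e), size=n)
    )
    if config.missing_rate > 0:
        y = np.where(rng.random(n) < config.missing_rate, np.nan, y)
    return y


def simulate_traits(config: SimTraitConfig) -> pd.DataFrame:
    """Simulate one trait under the nested random-effects model.

    Returns a table with columns region, population, family, replicate and
    the trait, with strictly nested labels; trait cells are knocked out
    uniformly at random at ``missing_rate``.
    """
    design = _design(config, np.random.default_rng(_sub_seed(config.seed, 0)))
    out = design.copy()
    out[config.trait_name] = _draw_values(
        design, config, np.random.default_rng(_sub_seed(config.seed, 1))
    )
    return out


def simulate_trait_table(configs: list[SimTraitConfig]) -> pd.DataFrame:
    """Simulate several traits on one shared nested design.

    The first config fixes the design (region/population/family/replicate
    labels, including any randomly drawn family and replicate counts, from
    its own seed); each trait's values are then drawn independently with
    that trait's seed, so traits share plants but not effects.
    """
    if not configs:
        raise ValueError("need at least one trait config")
    base = configs[0]
    names = [cfg.trait_name for cfg in configs]
    if len(set(names)) != len(names):
        raise ValueError("trait names must be distinct")
    for cfg in configs[1:]:
        for fld in (
            "n_regions",
            "pops_per_region",
            "families_per_pop",
            "reps_per_family",
        ):
            if getattr(cfg, fld) != getattr(base, fld):
                raise ValueError(f"trait configs disagree on design field {fld!r}")
    design = _design(base, np.random.default_rng(_sub_seed(base.seed, 0)))
    out = design.copy()
    for cfg in configs:
        out[cfg.trait_name] = _draw_values(
            design, cfg, np.random.default_rng(_sub_seed(cfg.seed, 1))
        )
    return out


# ---------------------------------------------------------------------------
# microsatellites
# ---------------------------------------------------------------------------

def simulate_microsatellites(config: SimGenotypeConfig) -> GenotypeTable:
    """Simulate multiallelic codominant genotypes under Balding-Nichols.

    For each locus an ancestral frequency vector is drawn (rejecting
    degenerate near-fixed vectors); population frequencies are
    Dirichlet(p_anc * (1 - F)/F) for F = ``target_fst`` (F = 0 reuses the
    ancestral frequencies exactly).  Within populations, an individual is
    autozygous with probability F_IS = s/(2 - s), receiving two copies of
    one drawn allele, otherwise two independent draws.  Allele labels are
    fragment sizes ``base + k * allele_size_step``.
    """
    rng = np.random.default_rng(config.seed)
    P, n, L, A = (
        config.n_pops,
        config.inds_per_pop,
        config.n_loci,
        config.alleles_per_locus,
    )
    sizes = config.base_allele_size + config.allele_size_step * np.arange(A)
    fsts = config.per_pop_fst
    f_is = config.f_is

    pop_labels = [f"POP{p + 1:02d}" for p in range(P)]
    populations = np.repeat(pop_labels, n)
    individuals = [f"{pop}_{i + 1:03d}" for pop in pop_labels for i in range(n)]
    alleles = np.zeros((P * n, L, 2), dtype=int)

    for locus in range(L):
        for _ in range(1000):
            anc = rng.dirichlet(np.ones(A))
            if anc.max() < 0.95:  # reject near-fixed ancestral loci
                break
        else:
            raise RuntimeError("could not draw a polymorphic ancestral locus")
        freqs = np.empty((P, A))
        for p, f in enumerate(fsts):
            if f == 0.0:
                freqs[p] = anc
            else:
                freqs[p] = rng.dirichlet(anc * (1.0 - f) / f)
        for p in range(P):
            auto = rng.random(n) < f_is
            first = rng.choice(A, size=n, p=freqs[p])
            second = np.where(auto, first, rng.choice(A, size=n, p=freqs[p]))
            block = slice(p * n, (p + 1) * n)
            alleles[block, locus, 0] = sizes[first]
            alleles[block, locus, 1] = sizes[second]

    return GenotypeTable(
        individuals=individuals,
        populations=populations,
        loci=[f"Locus{j + 1}" for j in range(L)],
        alleles=alleles,
    )


# ---------------------------------------------------------------------------
# environment and coordinates
# ---------------------------------------------------------------------------

def simulate_environment(
    config: SimEnvConfig, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Simulate block-correlated environmental variables per population.

    ``metadata`` must carry ``population`` and ``region`` columns.  Latent
    values are multivariate Gaussian with correlation
    ``within_block_correlation`` inside each variable block and zero
    across blocks; populations in the shifted region get
    ``shift_magnitude`` (in SD units) added on the ``region_shift_block``
    variables; the result is exponentiated so every value is positive.
    """
    rng = np.random.default_rng(config.seed)
    pops = metadata["population"].tolist()
    regions = metadata["region"].tolist()
    var_names = list(config.blocks)
    block_of = np.asarray([config.blocks[v] for v in var_names], dtype=object)
    k = len(var_names)
    rho = config.within_block_correlation
    cov = np.where(block_of[:, None] == block_of[None, :], rho, 0.0)
    np.fill_diagonal(cov, 1.0)
    # validity check: block-diagonal equicorrelation, PSD iff rho in [0, 1)
    if np.linalg.eigvalsh(cov).min() < -1e-10:
        raise ValueError("block covariance is not positive semi-definite")

    z = rng.multivariate_normal(np.zeros(k), cov, size=len(pops), method="cholesky")
    shift_region = config.shift_region or regions[0]
    in_block = block_of == config.region_shift_block
    for i, reg in enumerate(regions):
        if reg == shift_region:
            z[i, in_block] += config.shift_magnitude
    values = np.exp(z)
    out = pd.DataFrame(values, columns=var_names)
    out.insert(0, "population", pops)
    return out


def simulate_metadata(
    pops_per_region: tuple[int, ...] = (3, 7),
    region_names: tuple[str, ...] | None = None,
    center: tuple[float, float] = (45.7, -112.8),
    region_separation_km: float = 100.0,
    scatter_km: float = 15.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Population metadata: labels, regions and scattered coordinates.

    Regions are placed ``region_separation_km`` apart east-west around the
    ``center`` (default southwestern Montana), populations scattered
    within regions with SD ``scatter_km``.
    """
    rng = np.random.default_rng(seed)
    n_regions = len(pops_per_region)
    if region_names is None:
        region_names = tuple(f"R{r + 1}" for r in range(n_regions))
    km_per_deg_lat = 111.32
    km_per_deg_lon = 111.32 * np.cos(np.deg2rad(center[0]))
    rows = []
    for r, (region, n_pops) in enumerate(zip(region_names, pops_per_region)):
        lon0 = center[1] + (r - (n_regions - 1) / 2) * (
            region_separation_km / km_per_deg_lon
        )
        for p in range(n_pops):
            rows.append(
                {
                    "population": f"{region}P{p + 1}",
                    "region": region,
                    "latitude": center[0]
                    + rng.normal(0, scatter_km / km_per_deg_lat),
                    "longitude": lon0 + rng.normal(0, scatter_km / km_per_deg_lon),
                }
            )
    return pd.DataFrame(rows)
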