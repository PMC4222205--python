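import numpy as np
import pandas as pd
import pytest

from qstdiv.containers import GenotypeTable, PairwiseMatrix
from qstdiv.synthetic_data import (
    SimGenotypeConfig,
    SimTraitConfig,
    simulate_microsatellites,
    simulate_traits,
)


@pytest.fixture
def balanced_traits():
    """Balanced 2 regions x 5 pops x 10 families x 4 reps, known components."""
    cfg = SimTraitConfig(
        trait_name="y",
        n_regions=2,
        pops_per_region=(5, 5),
        families_per_pop=10,
        reps_per_family=4,
        variance_components=(0.01, 0.004, 0.017, 0.011),
        grand_mean=10.0,
        seed=42,
    )
    return simulate_traits(cfg)


@pytest.fixture
def small_genotypes():
    """10 populations x 15 individuals x 13 loci at strong differentiation."""
    return simulate_microsatellites(
        SimGenotypeConfig(
            n_pops=10, inds_per_pop=15, n_loci=13, target_fst=0.4,
            selfing_rate=0.9, seed=11,
        )
    )


@pytest.fixture
def toy_genotypes():
    """Hand-written 2 pops x 6 individuals x 2 loci with a missing call."""
    alleles = np.array(
        [
            # pop A: locus1, locus2
            [[100, 100], [150, 152]],
            [[100, 102], [150, 150]],
            [[102, 102], [152, 152]],
            [[100, 100], [150, 152]],
            [[100, 102], [0, 0]],
            [[102, 102], [152, 154]],
            # pop B
            [[102, 102], [154, 154]],
            [[102, 104], [154, 154]],
            [[104, 104], [152, 154]],
            [[102, 102], [154, 154]],
            [[104, 104], [154, 154]],
            [[102, 104], [152, 152]],
        ]
    )
    return GenotypeTable(
        individuals=[f"A_{i}" for i in range(6)] + [f"B_{i}" for i in range(6)],
        populations=np.array(["A"] * 6 + ["B"] * 6, dtype=object),
        loci=["L1", "L2"],
        alleles=alleles,
    )


@pytest.fixture
def metadata_3_7():
    rng = np.random.default_rng(5)
    rows = []
    for r, (region, npop) in enumerate([("WEST", 3), ("EAST", 7)]):
        for p in range(npop):
            rows.append(
                {
                    "population": f"{region}{p + 1}",
                    "region": region,
                    "latitude": 45.0 + r + 0.1 * p,
                    "longitude": -113.0 + r + 0.05 * p + rng.normal(0, 0.01),
                }
            )
    return pd.DataFrame(rows)


def random_symmetric(rng, n=10, scale=1.0, labels=None):
    a = rng.uniform(0, 1, (n, n)) * scale
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return PairwiseMatrix(labels or [f"P{i}" for i in range(n)], a)
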