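"""Q_ST, Weir-Cockerham theta and R_ST against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qstdiv.containers import GenotypeTable
from qstdiv.divergence import (
    build_divergence_matrix,
    pairwise_qst,
    slatkin_rst,
    weir_cockerham_fst,
)
from qstdiv.synthetic_data import SimGenotypeConfig, simulate_microsatellites


def wc_theta_oracle(genos, pop_a, pop_b):
    """Direct transliteration of the published theta estimator equations.

    Loops over loci and alleles computing a, b, c from sample sizes,
    allele frequencies and heterozygote frequencies; kept deliberately
    separate from the package implementation.
    """
    num = den = 0.0
    r = 2
    for locus in range(len(genos.loci)):
        samples = {}
        for pop in (pop_a, pop_b):
            rows = [
                genos.alleles[k, locus, :]
                for k in range(len(genos.individuals))
                if genos.populations[k] == pop and genos.alleles[k, locus, 0] != 0
            ]
            samples[pop] = rows
        n1, n2 = len(samples[pop_a]), len(samples[pop_b])
        if n1 == 0 or n2 == 0:
            continue
        observed = sorted(
            {int(a) for rows in samples.values() for g in rows for a in g}
        )
        if len(observed) < 2:
            continue
        n_bar = (n1 + n2) / 2
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        for u in observed:
            p1 = sum((g == u).sum() for g in samples[pop_a]) / (2 * n1)
            p2 = sum((g == u).sum() for g in samples[pop_b]) / (2 * n2)
            h1 = sum((g == u).sum() == 1 for g in samples[pop_a]) / n1
            h2 = sum((g == u).sum() == 1 for g in samples[pop_b]) / n2
            p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
            s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / (
                (r - 1) * n_bar
            )
            h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
            a = (n_bar / n_c) * (
                s2
                - 1 / (n_bar - 1)
                * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar)
                - (r - 1) / r * s2
                - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2
            num += a
            den += a + b + c
    return num / den


def two_pop_traits(rows):
    return pd.DataFrame(rows, columns=["population", "family", "y"])


class TestWeirCockerham:
    def test_matches_hand_coded_oracle_on_toy_table(self, toy_genotypes):
        got = weir_cockerham_fst(toy_genotypes, "A", "B")
        expected = wc_theta_oracle(toy_genotypes, "A", "B")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_complete_fixation_gives_one(self):
        alleles = np.zeros((8, 3, 2), dtype=int)
        alleles[:4] = 100
        alleles[4:] = 120
        g = GenotypeTable(
            [f"i{k}" for k in range(8)],
            np.array(["A"] * 4 + ["B"] * 4, dtype=object),
            ["L1", "L2", "L3"],
            alleles,
        )
        assert weir_cockerham_fst(g, "A", "B") == pytest.approx(1.0)

    def test_monomorphic_pair_rejected(self):
        alleles = np.full((6, 2, 2), 100, dtype=int)
        g = GenotypeTable(
            [f"i{k}" for k in range(6)],
            np.array(["A"] * 3 + ["B"] * 3, dtype=object),
            ["L1", "L2"],
            alleles,
        )
        with pytest.raises(ValueError, match="undefined"):
            weir_cockerham_fst(g, "A", "B")

    def test_invariant_under_allele_relabelling(self, toy_genotypes):
        base = weir_cockerham_fst(toy_genotypes, "A", "B")
        relabel = {100: 7, 102: 3, 104: 11, 150: 2, 152: 9, 154: 5, 0: 0}
        mapped = np.vectorize(relabel.get)(toy_genotypes.alleles)
        g2 = GenotypeTable(
            list(toy_genotypes.individuals),
            toy_genotypes.populations.copy(),
            list(toy_genotypes.loci),
            mapped,
        )
        assert weir_cockerham_fst(g2, "A", "B") == pytest.approx(base, abs=1e-12)


class TestSlatkinRst:
    def test_identical_size_distributions_near_zero(self):
        block = np.array([[100, 104], [104, 104], [100, 100], [104, 100]] * 3)
        alleles = np.stack([block, block + 50], axis=1)  # 2 loci
        g = GenotypeTable(
            [f"i{k}" for k in range(24)],
            np.array(["A"] * 12 + ["B"] * 12, dtype=object),
            ["L1", "L2"],
            np.concatenate([alleles, alleles]),
        )
        assert abs(slatkin_rst(g, "A", "B")) < 0.05

    def test_fixation_on_different_sizes_gives_one(self):
        alleles = np.zeros((8, 1, 2), dtype=int)
        alleles[:4] = 100
        alleles[4:] = 120
        g = GenotypeTable(
            [f"i{k}" for k in range(8)],
            np.array(["A"] * 4 + ["B"] * 4, dtype=object),
            ["L1"],
            alleles,
        )
        assert slatkin_rst(g, "A", "B") == pytest.approx(1.0)

    def test_matches_direct_variance_decomposition(self, toy_genotypes):
        got = slatkin_rst(toy_genotypes, "A", "B")
        # independent one-way ANOVA of allele sizes per locus
        among = within = 0.0
        for locus in range(2):
            groups = []
            for pop in ("A", "B"):
                mask = (toy_genotypes.populations == pop) & (
                    toy_genotypes.alleles[:, locus, 0] != 0
                )
                groups.append(
                    toy_genotypes.alleles[mask, locus, :].ravel().astype(float)
                )
            n1, n2 = len(groups[0]), len(groups[1])
            allv = np.concatenate(groups)
            ss_a = sum(
                len(g) * (g.mean() - allv.mean()) ** 2 for g in groups
            )
            ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
            ms_w = ss_w / (n1 + n2 - 2)
            ms_a = ss_a / 1
            n0 = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / 1
            among += (ms_a - ms_w) / n0
            within += ms_w
        assert got == pytest.approx(among / (among + within), abs=1e-12)

    def test_affine_invariance_of_allele_sizes(self, toy_genotypes):
        base = slatkin_rst(toy_genotypes, "A", "B")
        scaled = toy_genotypes.alleles.copy()
        called = scaled != 0
        scaled[called] = 3 * scaled[called] + 17
        g2 = GenotypeTable(
            list(toy_genotypes.individuals),
            toy_genotypes.populations.copy(),
            list(toy_genotypes.loci),
            scaled,
        )
        assert slatkin_rst(g2, "A", "B") == pytest.approx(base, abs=1e-10)


class TestPairwiseQst:
    def test_equal_population_means_give_zero(self):
        rows = []
        rng = np.random.default_rng(0)
        for pop in ("A", "B"):
            for fam in range(5):
                for _ in range(4):
                    rows.append((pop, f"{pop}F{fam}", fam + rng.normal(0, 0.1)))
        # population effect absent by construction; V_P clamps to ~0
        df = two_pop_traits(rows)
        assert pairwise_qst(df, "y", "A", "B") <= 0.05

    def test_no_family_variance_gives_one(self):
        rows = [("A", f"AF{f}", 0.0) for f in range(3) for _ in range(3)]
        rows += [("B", f"BF{f}", 1.0) for f in range(3) for _ in range(3)]
        assert pairwise_qst(two_pop_traits(rows), "y", "A", "B") == 1.0

    def test_single_family_population_rejected(self):
        rows = [("A", "AF0", 1.0)] * 4 + [("B", f"BF{f}", 2.0) for f in range(4)]
        with pytest.raises(ValueError, match="fewer than 2 families"):
            pairwise_qst(two_pop_traits(rows), "y", "A", "B")

    def test_monotone_in_population_variance(self):
        # Q_ST = V_P/(V_P + 2 V_F) rises with the population separation
        rng = np.random.default_rng(1)
        vals = []
        for sep in (0.0, 0.5, 1.5):
            rows = []
            for j, pop in enumerate(("A", "B")):
                for fam in range(10):
                    fam_eff = rng.normal(0, 0.3)
                    for _ in range(5):
                        rows.append(
                            (pop, f"{pop}F{fam}",
                             j * sep + fam_eff + rng.normal(0, 0.3))
                        )
            vals.append(pairwise_qst(two_pop_traits(rows), "y", "A", "B"))
        assert vals[0] <= vals[1] <= vals[2]


class TestDivergenceMatrix:
    def test_pair_counts(self, small_genotypes):
        m = build_divergence_matrix(small_genotypes, "FST")
        assert m.n_pairs == 45
        assert np.isfinite(m.triangle()).all()
        two = build_divergence_matrix(
            small_genotypes.subset_populations(["POP01", "POP02"]), "FST"
        )
        assert two.n_pairs == 1

    def test_label_order_invariance(self, small_genotypes):
        pops = small_genotypes.population_labels
        m1 = build_divergence_matrix(small_genotypes, "FST", populations=pops)
        m2 = build_divergence_matrix(
            small_genotypes, "FST", populations=pops[::-1]
        )
        assert np.allclose(m2.reorder(pops).values, m1.values)

    def test_fst_rst_concordant_under_heterogeneous_drift(self):
        # pairwise divergence must genuinely differ between pairs for the
        # two statistics to have an ordering to agree on, so populations
        # get per-population drift parameters spanning 0.1-0.7
        from scipy.stats import spearmanr

        fs = tuple(np.linspace(0.1, 0.7, 10))
        rhos = []
        for s in range(5):
            g = simulate_microsatellites(
                SimGenotypeConfig(
                    n_pops=10, inds_per_pop=20, n_loci=26, target_fst=fs,
                    selfing_rate=0.9, seed=300 + s,
                )
            )
            fst = build_divergence_matrix(g, "FST")
            rst = build_divergence_matrix(g, "RST")
            rhos.append(spearmanr(fst.triangle(), rst.triangle()).statistic)
        assert np.mean(rhos) > 0.8

    def test_reml_and_ems_qst_paths_agree(self):
        rng = np.random.default_rng(3)
        rows = []
        for pop in ("A", "B"):
            for fam in range(8):
                eff = rng.normal(0, 0.2)
                for _ in range(4):
                    rows.append((pop, f"{pop}F{fam}", eff + rng.normal(0, 0.2)))
        df = two_pop_traits(rows)
        df["population"] = df["population"].astype(str)
        ems = build_divergence_matrix(df, "QST", trait="y")
        reml = build_divergence_matrix(df, "QST", trait="y", method="reml")
        assert ems.values[0, 1] == pytest.approx(reml.values[0, 1], abs=0.02)
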