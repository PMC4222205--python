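"""Shared in-memory containers for the divergence pipeline.

Trait, environment and metadata tables are plain :class:`pandas.DataFrame`
objects (validated by :mod:`qstdiv.data_io`); this module holds the two
containers that need more structure than a flat table: labelled symmetric
matrices (distances and pairwise divergence statistics) and codominant
genotype tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairwiseMatrix",
    "GenotypeTable",
    "MISSING_ALLELE",
]

#: Allele code used for a missing call (GenePop's "000").
MISSING_ALLELE = 0


@dataclass
class PairwiseMatrix:
    """A labelled symmetric population-by-population matrix.

    Used both for distance matrices (geographic km, environmental,
    PC-axis, 0/1 region indicator) and for pairwise divergence statistics
    (Q_ST, F_ST, R_ST).  Missing pairs are NaN.

    Parameters
    ----------
    labels
        Population labels, in a fixed order shared by rows and columns.
    values
        Square symmetric array with zero diagonal.
    kind
        Free-form tag describing what the entries are, e.g. ``"QST"``,
        ``"FST"``, ``"geographic-km"``, ``"region-indicator"``.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate population labels")
        with np.errstate(invalid="ignore"):
            asym = np.nanmax(np.abs(self.values - self.values.T)) if n else 0.0
        if n and asym > 1e-9:
            raise ValueError(f"matrix is asymmetric (max |A - A.T| = {asym:g})")
        # symmetrize exactly so triangle extraction is unambiguous
        self.values = (self.values + self.values.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_pairs(self) -> int:
        return self.n * (self.n - 1) // 2

    def triangle(self) -> np.ndarray:
        """Lower-triangle entries as a vector, pairs in label order (i > j)."""
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]

    def pair_index(self) -> pd.MultiIndex:
        """(row, column) labels aligned with :meth:`triangle`."""
        i, j = np.tril_indices(self.n, k=-1)
        arr = np.asarray(self.labels, dtype=object)
        return pd.MultiIndex.from_arrays([arr[i], arr[j]], names=["pop_i", "pop_j"])

    def reorder(self, labels: list[str]) -> "PairwiseMatrix":
        """Return a copy with rows/columns in the given label order."""
        idx = [self.labels.index(l) for l in labels]
        return PairwiseMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class GenotypeTable:
    """Codominant multiallelic genotypes for individuals in populations.

    ``alleles`` has shape (n_individuals, n_loci, 2) with positive integer
    allele labels (microsatellite fragment sizes); ``MISSING_ALLELE`` (0)
    marks a missing call, and a call is either fully present or fully
    missing at a locus.
    """

    individuals: list[str]
    populations: np.ndarray  # population label per individual
    loci: list[str]
    alleles: np.ndarray  # (n_ind, n_loci, 2) int

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=int)
        n, L = len(self.individuals), len(self.loci)
        if self.populations.shape != (n,):
            raise ValueError("one population label per individual required")
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"alleles shape {self.alleles.shape} != ({n}, {L}, 2)"
            )
        if (self.alleles < 0).any():
            raise ValueError("allele labels must be non-negative integers")
        half = self.alleles == MISSING_ALLELE
        if (half[..., 0] != half[..., 1]).any():
            raise ValueError("half-missing genotype call (one allele coded 0)")

    @property
    def population_labels(self) -> list[str]:
        """Distinct populations in first-appearance order."""
        return list(pd.unique(self.populations))

    def subset_populations(self, pops: list[str]) -> "GenotypeTable":
        mask = np.isin(self.populations, pops)
        return GenotypeTable(
            [ind for ind, m in zip(self.individuals, mask) if m],
            self.populations[mask],
            list(self.loci),
            self.alleles[mask],
        )
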