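"""Readers and writers for the pipeline's text formats.

Tables (traits, environment, metadata) are tab-delimited UTF-8 text with a
header row and '.' decimals.  Genotypes use the GenePop exchange format
(2- or 3-digit allele codes, "Pop" separators, comma after the individual
id).  Labelled symmetric matrices are serialized as a lower-triangle
block.  Every reader validates structure and is total on the matching
writer's output.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING_ALLELE, GenotypeTable, PairwiseMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_trait_table",
    "write_trait_table",
    "read_genepop",
    "write_genepop",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_env_table",
    "write_env_table",
]

LEVEL_COLUMNS = ("region", "population", "family", "replicate")


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

def _validate_nesting(df: pd.DataFrame, levels=LEVEL_COLUMNS) -> None:
    present = [c for c in levels if c in df.columns]
    for parent, child in zip(present, present[1:]):
        if child == "replicate":
            continue
        parents_per_child = df.groupby(child, sort=False)[parent].nunique()
        bad = parents_per_child[parents_per_child > 1]
        if len(bad):
            raise ValueError(
                f"{child} label(s) {list(bad.index)} appear under multiple "
                f"{parent} groups: nesting violated"
            )
    key = [c for c in ("population", "family", "replicate") if c in df.columns]
    if len(key) == 3:
        dup = df.duplicated(subset=key)
        if dup.any():
            rows = df.index[dup].tolist()[:5]
            raise ValueError(
                f"duplicate (population, family, replicate) keys at rows {rows}"
            )


def read_trait_table(
    path, required=("population", "family"), sep: str = "\t"
) -> pd.DataFrame:
    """Read and validate a per-plant trait table.

    Checks that the required label columns are present, that labels nest
    strictly (a family under one population, a population under one
    region) and that (population, family, replicate) keys are unique.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for c in LEVEL_COLUMNS:
        if c in df.columns and df[c].isna().any():
            rows = df.index[df[c].isna()].tolist()[:5]
            raise ValueError(f"{path}: malformed {c} labels at rows {rows}")
    _validate_nesting(df)
    trait_cols = [c for c in df.columns if c not in LEVEL_COLUMNS]
    for c in trait_cols:
        vals = df[c].to_numpy()
        if np.issubdtype(vals.dtype, np.number) and np.isinf(vals.astype(float)).any():
            raise ValueError(f"{path}: non-finite values in trait {c!r}")
    return df


def write_trait_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# GenePop
# ---------------------------------------------------------------------------

def write_genepop(
    genos: GenotypeTable, path, title: str = "qstdiv genotypes", digits: int = 3
) -> None:
    """Write genotypes as GenePop with fixed-width allele codes.

    Three-digit codes are the default (microsatellite fragment sizes
    exceed 99); missing calls are written as zeros.
    """
    if genos.alleles.max() >= 10**digits:
        raise ValueError(f"allele labels too large for {digits}-digit codes")
    lines = [title]
    lines += list(genos.loci)
    last_pop = None
    for ind, pop, row in zip(genos.individuals, genos.populations, genos.alleles):
        if pop != last_pop:
            lines.append("Pop")
            last_pop = pop
        codes = " ".join(f"{a:0{digits}d}{b:0{digits}d}" for a, b in row)
        lines.append(f"{ind}, {codes}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_genepop(path) -> GenotypeTable:
    """Parse a GenePop file (2- or 3-digit codes autodetected per token).

    Zero codes decode as missing.  Population labels are recovered from a
    shared ``LABEL_`` prefix of the individual ids when one exists,
    otherwise populations are named Pop1, Pop2, ... in file order.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln.rstrip() for ln in text.splitlines()]
    if len(lines) < 3:
        raise ValueError(f"{path}: not a GenePop file (too short)")
    # header: title then locus names until first "Pop"
    loci: list[str] = []
    body_start = None
    for k, ln in enumerate(lines[1:], start=2):
        if ln.strip().lower() == "pop":
            body_start = k
            break
        # loci may be one per line or comma-separated
        loci += [t.strip() for t in ln.split(",") if t.strip()]
    if body_start is None:
        raise ValueError(f"{path}: no 'Pop' separator found")
    if not loci:
        raise ValueError(f"{path}: no locus names before first 'Pop'")

    pop_members: list[list[tuple[str, list[int], int]]] = []
    current: list[tuple[str, list[int], int]] | None = None
    for lineno, ln in enumerate(lines[body_start - 1 :], start=body_start):
        s = ln.strip()
        if not s:
            continue
        if s.lower() == "pop":
            current = []
            pop_members.append(current)
            continue
        if current is None:
            raise ValueError(f"{path}:{lineno}: genotype line before 'Pop'")
        if "," not in s:
            raise ValueError(f"{path}:{lineno}: missing comma after individual id")
        ind, rest = s.split(",", 1)
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"{path}:{lineno}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        alleles: list[int] = []
        for t in tokens:
            if len(t) == 4:
                w = 2
            elif len(t) == 6:
                w = 3
            else:
                raise ValueError(
                    f"{path}:{lineno}: genotype code {t!r} is not 4 or 6 digits"
                )
            a, b = int(t[:w]), int(t[w:])
            if (a == 0) != (b == 0):
                raise ValueError(f"{path}:{lineno}: half-missing code {t!r}")
            alleles += [a, b]
        current.append((ind.strip(), alleles, lineno))

    individuals: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    for k, members in enumerate(pop_members):
        if not members:
            continue
        ids = [m[0] for m in members]
        prefixes = {i.rsplit("_", 1)[0] for i in ids if "_" in i}
        label = prefixes.pop() if len(prefixes) == 1 else f"Pop{k + 1}"
        for ind, alleles, _ in members:
            individuals.append(ind)
            pops.append(label)
            rows.append(alleles)
    arr = np.asarray(rows, dtype=int).reshape(len(individuals), len(loci), 2)
    return GenotypeTable(individuals, np.asarray(pops, dtype=object), loci, arr)


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix(matrix: PairwiseMatrix, path) -> None:
    """Serialize a labelled symmetric matrix as a lower-triangle block."""
    lines = [f"# kind: {matrix.kind}"]
    for i, lab in enumerate(matrix.labels):
        vals = [
            "NA" if not np.isfinite(matrix.values[i, j]) else repr(float(matrix.values[i, j]))
            for j in range(i)
        ]
        lines.append("\t".join([lab] + vals))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_matrix(path) -> PairwiseMatrix:
    """Read a lower-triangle matrix file back into a PairwiseMatrix."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    kind = ""
    rows = []
    for ln in lines:
        if ln.startswith("#"):
            if "kind:" in ln:
                kind = ln.split("kind:", 1)[1].strip()
            continue
        if ln.strip():
            rows.append(ln.split("\t"))
    labels = [r[0] for r in rows]
    n = len(labels)
    vals = np.zeros((n, n))
    for i, r in enumerate(rows):
        if len(r) != i + 1:
            raise ValueError(
                f"{path}: row {labels[i]!r} has {len(r) - 1} entries, expected {i}"
            )
        for j, tok in enumerate(r[1:]):
            v = np.nan if tok == "NA" else float(tok)
            vals[i, j] = vals[j, i] = v
    return PairwiseMatrix(labels, vals, kind=kind)


# ---------------------------------------------------------------------------
# metadata and environment
# ---------------------------------------------------------------------------

def read_metadata(path, sep: str = "\t") -> pd.DataFrame:
    """Population metadata: population, region, latitude, longitude."""
    df = pd.read_csv(path, sep=sep)
    need = {"population", "region", "latitude", "longitude"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if len(df) < 2:
        raise ValueError(f"{path}: need >= 2 populations")
    if df["population"].duplicated().any():
        raise ValueError(f"{path}: duplicate population labels")
    lat, lon = df["latitude"], df["longitude"]
    if (lat.abs() > 90).any() or (lon.abs() > 180).any():
        raise ValueError(f"{path}: coordinates out of range")
    return df


def write_metadata(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_env_table(path, sep: str = "\t") -> pd.DataFrame:
    """Environmental table: one row per population, numeric variables."""
    df = pd.read_csv(path, sep=sep)
    if "population" not in df.columns:
        raise ValueError(f"{path}: 'population' column required")
    if df["population"].duplicated().any():
        raise ValueError(f"{path}: more than one row per population")
    vals = df.drop(columns=["population"]).to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"{path}: non-finite environmental values")
    return df


def write_env_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)
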