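"""Count-matrix I/O, log-CPM, MAD gene selection and DEG filtering.

Expression data travel as a pandas DataFrame of non-negative integer
counts with genes as rows (index ``gene_id``) and samples as columns;
sample metadata as a DataFrame indexed by ``sample_id`` with a ``stage``
column.  Differential-expression tables are consumed, not produced: the
filtering contract here is the conventional
``|log2FC| > 1 and p.adj < 0.05`` rule (both strict), applied to tables
an external DE engine (e.g. DESeq2) emitted.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """Raised when an input table does not match its expected schema."""


DEG_COLUMNS = ("gene_id", "log2FoldChange", "pvalue", "padj")


def read_count_matrix(path) -> pd.DataFrame:
    """Read a TSV count matrix (first column ``gene_id``, then samples)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: need a gene_id column plus >= 1 sample")
    gene_col = df.columns[0]
    dupes = df[gene_col][df[gene_col].duplicated()]
    if len(dupes):
        raise SchemaError(f"{path}: duplicate gene ids: {sorted(set(dupes))[:5]}")
    df = df.set_index(gene_col)
    df.index.name = "gene_id"
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise SchemaError(
                f"{path}: non-numeric value in sample {col!r} "
                f"at gene {bad.index[0]!r}"
            )
    if (df.values < 0).any():
        raise SchemaError(f"{path}: negative counts present")
    return df


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "stage" not in df.columns:
        raise SchemaError(f"{path}: expected columns sample_id and stage")
    return df.set_index("sample_id")


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def log_cpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(pseudocount + counts-per-million), per sample.

    CPM divides each column by its library size (column sum) and scales by
    1e6, making values comparable across sequencing depths; the log tames
    the mean–variance relationship of counts before correlation analysis.
    """
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size in samples {bad}")
    cpm = counts.astype(float) / lib * 1e6
    return np.log2(pseudocount + cpm)


def mad_select_top_k(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Rows with the k largest median absolute deviations.

    MAD(g) = median(|x_g - median(x_g)|) across samples — the robust
    variability score used to pick the most variable genes (classically the
    top 5000) before network construction.  Ties break lexicographically on
    gene id so selection is reproducible.
    """
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds the {matrix.shape[0]} available genes")
    med = matrix.median(axis=1)
    mad = (matrix.sub(med, axis=0)).abs().median(axis=1)
    order = sorted(matrix.index, key=lambda g: (-mad[g], str(g)))
    return matrix.loc[order[:k]]


def read_deg_table(path, contrast: str | None = None) -> pd.DataFrame:
    """Read a DE result TSV with columns gene_id, log2FoldChange, pvalue, padj."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing DE columns {missing}")
    if contrast is not None:
        df = df.assign(contrast=contrast)
    return df


def filter_deg_table(
    table: pd.DataFrame, lfc_cut: float = 1.0, padj_cut: float = 0.05
) -> pd.DataFrame:
    """Retain differentially expressed rows: |log2FC| > lfc_cut AND padj < padj_cut.

    Both inequalities are strict, so a gene at exactly the fold-change or
    adjusted-p boundary is *not* called differential.  Rows with missing
    padj (independent-filtering NAs) never pass.
    """
    missing = [c for c in ("log2FoldChange", "padj") if c not in table.columns]
    if missing:
        raise SchemaError(f"DEG table missing columns {missing}")
    mask = (table["log2FoldChange"].abs() > lfc_cut) & (table["padj"] < padj_cut)
    return table[mask.fillna(False)].copy()


def contrast_overlap(
    deg_sets: Dict[str, Iterable[str]] | Sequence[Iterable[str]],
) -> Dict[FrozenSet[str], int]:
    """Exclusive Venn-region sizes over >= 2 DEG sets.

    Accepts a mapping contrast → gene set (or a sequence, auto-named
    ``set0``…).  Returns, for every non-empty combination of contrasts,
    the number of genes in exactly those contrasts and no others — the
    counts a Venn diagram prints.
    """
    if not isinstance(deg_sets, dict):
        deg_sets = {f"set{i}": s for i, s in enumerate(deg_sets)}
    if len(deg_sets) < 2:
        raise ValueError("contrast_overlap needs at least two DEG sets")
    sets: Dict[str, Set[str]] = {k: set(v) for k, v in deg_sets.items()}
    names = list(sets)
    regions: Dict[FrozenSet[str], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside: Set[str] = set()
            for other in names:
                if other not in combo:
                    outside |= sets[other]
            regions[frozenset(combo)] = len(inside - outside)
    return regions


def overlap_report(regions: Dict[FrozenSet[str], int]) -> Dict[str, int]:
    """JSON-serializable form of a Venn-region table (keys joined by ``&``)."""
    return {"&".join(sorted(k)): v for k, v in sorted(
        regions.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
    )}
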