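"""Weighted co-expression networks: soft threshold, TOM, modules, eigengenes.

The pipeline mirrors weighted gene co-expression network analysis (WGCNA):

1. Pearson correlation ``r`` between gene expression profiles.
2. Unsigned soft-thresholded adjacency ``a_ij = |r_ij|^beta``, with ``beta``
   chosen as the smallest power whose connectivity distribution fits a
   scale-free topology (signed R^2 >= 0.85 by default).
3. Topological overlap (TOM) similarity, rewarding genes that share
   neighbours; ``1 - TOM`` is the clustering dissimilarity.
4. Average-linkage hierarchical clustering with a static tree cut; clusters
   below the minimum size fall into the reserved ``grey`` label.  Modules
   are named by the WGCNA colour convention, largest first (``turquoise``,
   ``blue``, ...).
5. Module eigengenes (first principal component of the z-scored module
   submatrix) and their Pearson correlation with one-hot stage indicators.

Deviations from the reference R implementation are deliberate and
documented in the methods note: the tree cut is a static height cut
(default 0.8 on 1 - TOM) rather than the dynamic hybrid cut, and the
network is unsigned by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

GREY = "grey"

# WGCNA's standard module colour order (grey is reserved for unassigned).
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white",
]


class ConstantGeneError(ValueError):
    """Raised when constant genes make correlations undefined."""

    def __init__(self, genes: List[str]):
        self.genes = genes
        super().__init__(f"constant expression in genes: {genes[:10]}")


def correlation_matrix(
    expr: pd.DataFrame, on_constant: str = "error"
) -> pd.DataFrame:
    """Gene × gene Pearson correlations of a gene × sample matrix.

    ``on_constant`` is ``"error"`` (default: raise naming the offending
    genes) or ``"drop"`` (exclude them with a warning).
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlations")
    values = expr.to_numpy(dtype=float)
    constant = expr.index[np.ptp(values, axis=1) == 0].tolist()
    if constant:
        if on_constant == "drop":
            warnings.warn(
                f"dropping {len(constant)} constant genes", stacklevel=2
            )
            expr = expr.drop(index=constant)
            values = expr.to_numpy(dtype=float)
        else:
            raise ConstantGeneError(constant)
    corr = np.corrcoef(values)
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=expr.index, columns=expr.index)


def adjacency(corr: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |r_ij|^beta, unit diagonal."""
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    adj = np.abs(corr.to_numpy(dtype=float)) ** beta
    np.fill_diagonal(adj, 1.0)
    return pd.DataFrame(adj, index=corr.index, columns=corr.columns)


@dataclass
class SoftThresholdReport:
    """Scale-free fit diagnostics per candidate power."""

    candidates: List[float]
    r_squared: List[float]          # signed: R^2 * sign(slope); NaN if undefined
    mean_connectivity: List[float]
    chosen: float
    reached_cut: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.candidates,
                "signed_r2": self.r_squared,
                "mean_connectivity": self.mean_connectivity,
                "chosen": [b == self.chosen for b in self.candidates],
            }
        )


def _scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10 p(k) vs log10 k over equal-width k bins."""
    k = connectivity[connectivity > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_p.append(np.log10(members.size / k.size))
    if len(log_k) < 2:
        return float("nan")
    x = np.asarray(log_k)
    y = np.asarray(log_p)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    r2 = 1.0 - ss_res / ss_tot
    return r2 * np.sign(slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidates: Sequence[float] = tuple(range(1, 21)),
    r2_cut: float = 0.85,
    on_constant: str = "error",
) -> SoftThresholdReport:
    """Choose the soft-threshold power by the scale-free topology criterion.

    For each candidate power the unsigned adjacency is built, per-gene
    connectivity ``k_i = sum_{j != i} a_ij`` computed, and the fit of
    ``log10 p(k)`` against ``log10 k`` scored as R^2 signed by the slope
    (a scale-free network has a negative slope).  The chosen power is the
    smallest candidate reaching ``r2_cut``; if none does, the power with
    maximal signed R^2 is returned with a warning.
    """
    corr = correlation_matrix(expr, on_constant=on_constant)
    abs_r = np.abs(corr.to_numpy())
    np.fill_diagonal(abs_r, 0.0)
    r2s: List[float] = []
    mean_k: List[float] = []
    for beta in candidates:
        k = (abs_r**beta).sum(axis=1)
        mean_k.append(float(k.mean()))
        r2s.append(_scale_free_fit(k))
    chosen = None
    for beta, r2 in zip(candidates, r2s):
        if not np.isnan(r2) and r2 >= r2_cut:
            chosen = beta
            break
    reached = chosen is not None
    if not reached:
        finite = [(r2, b) for b, r2 in zip(candidates, r2s) if not np.isnan(r2)]
        if not finite:
            warnings.warn(
                "scale-free fit undefined for every power; defaulting to the "
                "smallest candidate",
                stacklevel=2,
            )
            chosen = candidates[0]
        else:
            chosen = max(finite)[1]
            warnings.warn(
                f"no power reached signed R^2 >= {r2_cut}; "
                f"using beta={chosen} (max R^2 {max(finite)[0]:.3f})",
                stacklevel=2,
            )
    return SoftThresholdReport(
        candidates=list(candidates),
        r_squared=r2s,
        mean_connectivity=mean_k,
        chosen=chosen,
        reached_cut=reached,
    )


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{j != i} a_ij``;
    the diagonal is 1.  Two genes overlap strongly when they are directly
    connected *and* share neighbours.
    """
    a = adj.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a                       # diagonal of a is 0, so u != i,j handled
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.8,
) -> pd.Series:
    """Cluster genes on 1 − TOM and name modules by the colour convention.

    Average-linkage hierarchical clustering with a static cut at
    ``cut_height``; clusters smaller than ``min_module_size`` are assigned
    the reserved ``grey`` label.  Real modules are named ``turquoise``,
    ``blue``, ... in order of decreasing size (ties broken by smallest
    member gene id).  Returns a gene-indexed Series of labels.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    genes = tom.index
    # Order-invariance: cluster in a canonical gene order.
    order = sorted(genes, key=str)
    tom_sorted = tom.loc[order, order]
    dissim = 1.0 - tom_sorted.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    dissim = (dissim + dissim.T) / 2.0
    np.clip(dissim, 0.0, None, out=dissim)
    if len(order) == 1:
        return pd.Series([GREY], index=genes, name="module")
    z = linkage(squareform(dissim, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    clusters: Dict[int, List[str]] = {}
    for gene, c in zip(order, raw):
        clusters.setdefault(int(c), []).append(gene)
    real = [
        members for members in clusters.values() if len(members) >= min_module_size
    ]
    real.sort(key=lambda ms: (-len(ms), str(min(ms, key=str))))
    labels = {g: GREY for g in genes}
    for rank, members in enumerate(real):
        name = (
            MODULE_COLORS[rank]
            if rank < len(MODULE_COLORS)
            else f"module_{rank}"
        )
        for g in members:
            labels[g] = name
    return pd.Series([labels[g] for g in genes], index=genes, name="module")


@dataclass
class EigengeneMatrix:
    """Module eigengenes (module × sample) with variance explained."""

    values: pd.DataFrame
    variance_explained: Dict[str, float] = field(default_factory=dict)


def module_eigengenes(
    expr: pd.DataFrame, modules: pd.Series
) -> EigengeneMatrix:
    """First principal component of each module's z-scored submatrix.

    Each eigengene is scaled to unit variance across samples and
    sign-flipped so its mean correlation with the module's member genes is
    non-negative.  Grey (unassigned) genes are skipped.
    """
    me_rows: Dict[str, np.ndarray] = {}
    var_expl: Dict[str, float] = {}
    n_samples = expr.shape[1]
    for module in sorted(set(modules) - {GREY}):
        members = modules.index[modules == module]
        if len(members) < 2:
            raise ValueError(f"module {module!r} has fewer than 2 genes")
        sub = expr.loc[members].to_numpy(dtype=float)
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        if (sd == 0).any():
            raise ConstantGeneError(
                [str(g) for g, s in zip(members, sd.ravel()) if s == 0]
            )
        z = (sub - mu) / sd
        # PC across samples: right singular vector of the gene x sample z.
        _, s, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        var_expl[module] = float(s[0] ** 2 / np.sum(s**2))
        me = me / me.std(ddof=1)
        mean_corr = np.mean([np.corrcoef(row, me)[0, 1] for row in z])
        if mean_corr < 0:
            me = -me
        me_rows[module] = me
    values = pd.DataFrame(
        me_rows, index=expr.columns
    ).T  # module x sample
    values.index.name = "module"
    return EigengeneMatrix(values=values, variance_explained=var_expl)


def module_trait_correlation(
    me: EigengeneMatrix | pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r (and two-sided p) of each eigengene with each stage indicator.

    Stages are one-hot encoded — one indicator column per developmental
    stage — and each (module, stage) cell carries the correlation between
    the module eigengene and that indicator, with the p-value from
    ``t = r * sqrt((n-2)/(1-r^2))`` on n−2 degrees of freedom.  Constant
    indicators yield NaN.  Returns a long-form DataFrame
    (module, stage, r, p).
    """
    values = me.values if isinstance(me, EigengeneMatrix) else me
    n = values.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")
    stage = samples.loc[values.columns, "stage"]
    rows = []
    for st in pd.unique(stage):
        indicator = (stage == st).to_numpy(dtype=float)
        const = indicator.std() == 0
        for module in values.index:
            x = values.loc[module].to_numpy(dtype=float)
            if const or x.std() == 0:
                rows.append((module, st, np.nan, np.nan))
                continue
            r = float(np.corrcoef(x, indicator)[0, 1])
            r = max(-1.0, min(1.0, r))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t_stat = r * np.sqrt((n - 2) / (1.0 - r**2))
                p = float(2.0 * t_dist.sf(abs(t_stat), df=n - 2))
            rows.append((module, st, r, min(p, 1.0)))
    return pd.DataFrame(rows, columns=["module", "stage", "r", "p"])
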