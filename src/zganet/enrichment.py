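"""Over-representation analysis of gene groups against GMT term sets.

For a group of *n* genes from a universe of *N*, a term annotating *K*
universe genes, and an observed overlap of *k*, the enrichment p-value is
the hypergeometric upper tail ``P(X >= k)`` — the classical one-sided ORA
test.  Benjamini–Hochberg step-up correction is applied within each
group's family of terms by default (matching per-community reporting),
with an optional global family.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` overlap, ``n`` query size, ``K`` term size, ``N`` universe size.
    Evaluated through the survival function (log-space internally), so
    extreme overlaps do not underflow to spurious zeros at these scales.
    """
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"need n, K <= N; got n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich_groups(
    groups: Dict[str, Iterable[str]],
    terms: Dict[str, List[str]],
    universe: Iterable[str],
    family: str = "per_group",
) -> pd.DataFrame:
    """One hypergeometric test per (group, term) pair.

    Genes outside the universe are dropped (count logged in the result's
    ``attrs``); term memberships are intersected with the universe.  BH
    correction runs within each group's term family (``family="per_group"``,
    the default) or over all tests at once (``family="global"``).  Rows are
    sorted by group then adjusted p.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    if family not in ("per_group", "global"):
        raise ValueError("family must be 'per_group' or 'global'")
    N = len(universe_set)
    term_members = {t: set(g) & universe_set for t, g in terms.items()}
    dropped: Dict[str, int] = {}
    rows = []
    for group, genes in groups.items():
        gene_set = set(genes)
        inside = gene_set & universe_set
        dropped[group] = len(gene_set) - len(inside)
        n = len(inside)
        for term, members in term_members.items():
            K = len(members)
            overlap = sorted(inside & members)
            k = len(overlap)
            p = hypergeometric_p(k, n, K, N)
            rows.append(
                {
                    "group": group,
                    "term_id": term,
                    "k": k,
                    "n": n,
                    "K": K,
                    "N": N,
                    "p": p,
                    "genes": ",".join(overlap),
                }
            )
    result = pd.DataFrame(rows)
    if len(result):
        if family == "per_group":
            result["p_adj"] = (
                result.groupby("group")["p"].transform(lambda s: bh_adjust(s.values))
            )
        else:
            result["p_adj"] = bh_adjust(result["p"].values)
        result = result.sort_values(
            ["group", "p_adj", "p", "term_id"], kind="stable"
        ).reset_index(drop=True)
        result = result[
            ["group", "term_id", "k", "n", "K", "N", "p", "p_adj", "genes"]
        ]
    result.attrs["dropped_outside_universe"] = dropped
    return result
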