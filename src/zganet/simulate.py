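"""Synthetic data with planted ground truth for every pipeline stage.

Three generators cover the inputs the analysis consumes:

* :func:`simulate_expression` — staged single-embryo count matrices.
  Each planted co-expression module *m* has a latent eigengene
  ``e_{m,s} = trend_m(stage(s)) + N(0, jitter)`` per sample; a member gene
  *g* with loading ``w_g`` has negative-binomial counts with mean
  ``baseline * exp(w_g * e_{m,s})`` and variance ``mu + mu^2/dispersion``.
  Background genes have loading 0.  This emulates the strong stage-tracking
  modules of an embryonic zygotic-genome-activation time course without
  modelling reads, transcript length or GC content.
* :func:`simulate_ppi` — a stochastic block model with planted
  communities, Uniform(0.4, 1.0) edge weights (mimicking normalized
  STRING confidence) and optional injected hubs that receive extra
  within-block edges, so both weighted and unweighted degree filters have
  something to find.
* :func:`simulate_annotations` — GMT-style term → gene sets, a fraction of
  which are planted to draw >= 80% of their members from one community.

Every generator is a pure function of its config, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .graph import WeightedGraph


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


DEFAULT_STAGES = ("8cell", "16cell", "32cell")
# One rising, one falling, one mid-peaked eigengene trend across the three
# cleavage stages.  The three trend vectors sit at pairwise correlation
# -0.5 rather than being exact mirror images: under an unsigned
# co-expression network |r| erases sign, so perfectly anti-correlated
# trends would define a single module by construction.
DEFAULT_TRENDS = (
    (-1.5, 0.0, 1.5),
    (1.5, -1.5, 0.0),
    (0.0, 1.5, -1.5),
)


@dataclass
class ExpressionSimConfig:
    """Parameters of the staged negative-binomial expression simulator."""

    n_modules: int = 3
    genes_per_module: int = 50
    n_background_genes: int = 350
    samples_per_stage: int = 8
    stages: Sequence[str] = DEFAULT_STAGES
    stage_trend: Sequence[Sequence[float]] = DEFAULT_TRENDS
    loading_range: Tuple[float, float] = (0.6, 1.0)
    eigengene_jitter: float = 1.0
    nb_dispersion: float = 10.0
    baseline_mean: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_modules < 1 or self.genes_per_module < 1:
            raise ConfigError("n_modules and genes_per_module must be >= 1")
        if self.n_background_genes < 0 or self.samples_per_stage < 1:
            raise ConfigError("negative background or empty stages")
        if not self.stages:
            raise ConfigError("stages must be non-empty")
        if not self.nb_dispersion > 0:
            raise ConfigError("nb_dispersion must be > 0")
        lo, hi = self.loading_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigError("loading_range must lie in [0, 1] with lo <= hi")
        if len(self.stage_trend) < self.n_modules:
            raise ConfigError("stage_trend needs one row per module")
        for row in self.stage_trend:
            if len(row) != len(self.stages):
                raise ConfigError("stage_trend rows must match the stage count")


@dataclass
class PPISimConfig:
    """Stochastic-block-model PPI simulator parameters."""

    block_sizes: Sequence[int] = (60, 60)
    p_in: float = 0.3
    p_out: float = 0.01
    weight_low: float = 0.4
    weight_high: float = 1.0
    n_hubs_per_block: int = 1
    hub_extra_degree: int = 15
    node_names: Sequence[str] | None = None
    seed: int = 0

    def validate(self) -> None:
        if any(b < 2 for b in self.block_sizes):
            raise ConfigError("block sizes must all be >= 2")
        if not (0 <= self.p_out <= 1 and 0 <= self.p_in <= 1):
            raise ConfigError("edge probabilities must lie in [0, 1]")
        if not (0 < self.weight_low <= self.weight_high <= 1):
            raise ConfigError("edge weights must lie in (0, 1]")
        if self.n_hubs_per_block < 0 or self.hub_extra_degree < 0:
            raise ConfigError("hub parameters must be non-negative")
        n = sum(self.block_sizes)
        if self.node_names is not None and len(self.node_names) != n:
            raise ConfigError("node_names must match the total block size")


@dataclass
class GroundTruth:
    """Planted structure underlying a simulated dataset."""

    gene_module: Dict[str, str] = field(default_factory=dict)
    node_community: Dict[str, int] = field(default_factory=dict)
    gene_loading: Dict[str, float] = field(default_factory=dict)
    eigengenes: pd.DataFrame | None = None      # module x sample latent values
    planted_terms: Dict[str, int] = field(default_factory=dict)  # term -> community


def simulate_expression(
    config: ExpressionSimConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a planted-module count matrix.

    Returns ``(counts, samples, truth)``: a gene × sample integer
    DataFrame, a sample table with stage labels, and the ground truth
    (gene → module, loadings, realized per-sample eigengenes).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    stages = list(config.stages)
    sample_ids, sample_stage = [], []
    for stage in stages:
        for i in range(config.samples_per_stage):
            sample_ids.append(f"{stage}_s{i + 1}")
            sample_stage.append(stage)
    n_samples = len(sample_ids)

    module_names = [f"M{i + 1}" for i in range(config.n_modules)]
    # Realized eigengene per (module, sample): stage trend + sample jitter.
    eig = np.empty((config.n_modules, n_samples))
    for mi in range(config.n_modules):
        trend = dict(zip(stages, config.stage_trend[mi]))
        eig[mi] = [trend[s] for s in sample_stage]
    eig += rng.normal(0.0, config.eigengene_jitter, size=eig.shape)

    genes: List[str] = []
    gene_module: Dict[str, str] = {}
    loadings: Dict[str, float] = {}
    log_mean_rows = []
    lo, hi = config.loading_range
    gidx = 0
    for mi, mod in enumerate(module_names):
        for _ in range(config.genes_per_module):
            gidx += 1
            g = f"gene{gidx:05d}"
            genes.append(g)
            gene_module[g] = mod
            w = float(rng.uniform(lo, hi))
            loadings[g] = w
            log_mean_rows.append(w * eig[mi])
    for _ in range(config.n_background_genes):
        gidx += 1
        g = f"gene{gidx:05d}"
        genes.append(g)
        gene_module[g] = "background"
        loadings[g] = 0.0
        log_mean_rows.append(np.zeros(n_samples))

    mu = config.baseline_mean * np.exp(np.asarray(log_mean_rows))
    # NB with variance mu + mu^2/dispersion: shape n = dispersion,
    # success prob p = n / (n + mu).
    n_param = config.nb_dispersion
    counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    counts_df.index.name = "gene_id"
    samples_df = pd.DataFrame(
        {"stage": sample_stage}, index=pd.Index(sample_ids, name="sample_id")
    )
    truth = GroundTruth(
        gene_module=gene_module,
        gene_loading=loadings,
        eigengenes=pd.DataFrame(eig, index=module_names, columns=sample_ids),
    )
    return counts_df, samples_df, truth


def simulate_ppi(config: PPISimConfig) -> Tuple[WeightedGraph, GroundTruth]:
    """Draw a weighted SBM graph with planted blocks and injected hubs."""
    import warnings

    config.validate()
    if config.p_in <= config.p_out and config.p_in < 1:
        warnings.warn(
            "p_in <= p_out: planted block structure is unrecoverable",
            stacklevel=2,
        )
    rng = np.random.default_rng(config.seed)
    n = sum(config.block_sizes)
    names = (
        list(config.node_names)
        if config.node_names is not None
        else [f"node{i + 1:04d}" for i in range(n)]
    )
    blocks: List[List[str]] = []
    community: Dict[str, int] = {}
    pos = 0
    for bi, size in enumerate(config.block_sizes):
        block = names[pos:pos + size]
        blocks.append(block)
        for nd in block:
            community[nd] = bi
        pos += size

    graph = WeightedGraph()
    for nd in names:
        graph.add_node(nd)

    def draw_weight() -> float:
        return float(rng.uniform(config.weight_low, config.weight_high))

    for i in range(n):
        for j in range(i + 1, n):
            p = config.p_in if community[names[i]] == community[names[j]] else config.p_out
            if rng.random() < p:
                graph.add_edge(names[i], names[j], draw_weight())

    # Hub injection: extra within-block edges to random non-neighbours,
    # capped by block size.
    for block in blocks:
        for hub in block[: config.n_hubs_per_block]:
            candidates = [
                nd for nd in block
                if nd != hub and graph.edge_weight(hub, nd) == 0.0
            ]
            extra = min(config.hub_extra_degree, len(candidates))
            if extra == 0:
                continue
            chosen = rng.choice(len(candidates), size=extra, replace=False)
            for ci in sorted(chosen):
                graph.add_edge(hub, candidates[ci], draw_weight())

    return graph, GroundTruth(node_community=community)


def simulate_annotations(
    truth: GroundTruth,
    n_terms: int = 100,
    planted_fraction: float = 0.1,
    term_size_range: Tuple[int, int] = (10, 40),
    planted_purity: float = 0.9,
    seed: int = 0,
) -> Tuple[Dict[str, List[str]], GroundTruth]:
    """Draw GMT-style term → gene sets over a community-labelled universe.

    ``round(n_terms * planted_fraction)`` planted terms draw a
    ``planted_purity`` fraction (>= 0.8) of their members from a single
    planted community, cycling over communities; the rest draw uniformly
    from the universe.  Returns the term map and the truth object updated
    with the planted term → community mapping.
    """
    if not truth.node_community:
        raise ConfigError("ground truth has no community labels")
    if not 0 <= planted_fraction <= 1:
        raise ConfigError("planted_fraction must lie in [0, 1]")
    if planted_purity < 0.8:
        raise ConfigError("planted terms must draw >= 80% from one community")
    universe = sorted(truth.node_community)
    lo, hi = term_size_range
    if lo < 1 or hi > len(universe) or lo > hi:
        raise ConfigError(
            f"term_size_range {term_size_range} invalid for a universe of "
            f"{len(universe)} genes"
        )
    rng = np.random.default_rng(seed)
    communities = sorted(set(truth.node_community.values()))
    members_of = {
        c: sorted(g for g, cc in truth.node_community.items() if cc == c)
        for c in communities
    }
    n_planted = int(round(n_terms * planted_fraction))
    terms: Dict[str, List[str]] = {}
    planted: Dict[str, int] = {}
    for ti in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        name = f"TERM{ti + 1:04d}"
        if ti < n_planted:
            comm = communities[ti % len(communities)]
            pool = members_of[comm]
            n_core = min(max(int(np.ceil(planted_purity * size)), 1), len(pool))
            core = [pool[i] for i in rng.choice(len(pool), n_core, replace=False)]
            rest_pool = [g for g in universe if g not in set(core)]
            n_rest = min(size - n_core, len(rest_pool))
            rest = (
                [rest_pool[i] for i in rng.choice(len(rest_pool), n_rest, replace=False)]
                if n_rest > 0
                else []
            )
            terms[name] = sorted(core + rest)
            planted[name] = comm
        else:
            idx = rng.choice(len(universe), min(size, len(universe)), replace=False)
            terms[name] = sorted(universe[i] for i in idx)
    new_truth = GroundTruth(
        gene_module=truth.gene_module,
        node_community=truth.node_community,
        gene_loading=truth.gene_loading,
        eigengenes=truth.eigengenes,
        planted_terms=planted,
    )
    return terms, new_truth


# -- text-format writers -------------------------------------------------

def write_gmt(terms: Dict[str, List[str]], path) -> None:
    """Write term → gene sets in GMT format (term, description, genes...)."""
    with Path(path).open("w") as fh:
        for term in terms:
            fh.write("\t".join([term, term] + list(terms[term])) + "\n")


def read_gmt(path) -> Dict[str, List[str]]:
    terms: Dict[str, List[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ConfigError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            if fields[0] in terms:
                raise ConfigError(f"{path}:{lineno}: duplicate term {fields[0]!r}")
            terms[fields[0]] = fields[2:]
    return terms


def write_ground_truth(truth: GroundTruth, path) -> None:
    import json

    payload = {
        "gene_module": truth.gene_module,
        "node_community": truth.node_community,
        "gene_loading": truth.gene_loading,
        "planted_terms": truth.planted_terms,
        "eigengenes": (
            None
            if truth.eigengenes is None
            else {
                "modules": list(truth.eigengenes.index),
                "samples": list(truth.eigengenes.columns),
                "values": truth.eigengenes.to_numpy().tolist(),
            }
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
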