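"""Generate the three synthetic inputs: counts, PPI graph, annotations.

Every generator carries planted ground truth so downstream stages can be
scored.  The expression simulator draws negative-binomial counts whose
log-means follow per-module stage trends; the PPI simulator is a weighted
stochastic block model with injected hubs; the annotation simulator
plants community-concentrated terms among uniform null terms.
"""

from zganet import (
    ExpressionSimConfig,
    PPISimConfig,
    simulate_annotations,
    simulate_expression,
    simulate_ppi,
)

counts, samples, truth = simulate_expression(ExpressionSimConfig(seed=1))
print(f"count matrix: {counts.shape[0]} genes x {counts.shape[1]} samples")
print(f"stages: {samples['stage'].value_counts().to_dict()}")
n_module = sum(m != "background" for m in truth.gene_module.values())
print(f"planted module genes: {n_module}, background: "
      f"{len(truth.gene_module) - n_module}")

ppi, ppi_truth = simulate_ppi(PPISimConfig(seed=2))
degs = [ppi.degree(n) for n in ppi.nodes]
print(f"\nPPI graph: {ppi.n_nodes} nodes, {ppi.n_edges} edges, "
      f"max weighted degree {max(degs):.1f}")

terms, ann_truth = simulate_annotations(ppi_truth, n_terms=100,
                                        planted_fraction=0.1, seed=3)
print(f"annotations: {len(terms)} terms, "
      f"{len(ann_truth.planted_terms)} planted")
# The planted terms draw >= 90% of their member genes from one planted
# community; the rest are uniform draws and should never enrich.
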