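"""Attention-guided gene selection and recovery of the planted signal.

Trains on synthetic data, finds the most attentive cross-omics module per
layer, scores per-gene contributions (inner product of gene vector and
module vector, averaged over samples), selects genes above per-omics
Z-score percentiles, and checks the overlap with the planted signal genes
against the hypergeometric chance expectation.
"""

from scipy.stats import hypergeom

from mtamo import (
    HyperParams,
    SyntheticSpec,
    gene_importance,
    generate,
    select_attentive_modules,
    standardize,
    train,
    union_genes,
    zscore_threshold,
)

spec = SyntheticSpec(seed=1)  # 500 samples, 3 x 1000 genes, 50 signal genes
dataset, truth = generate(spec)
for label in dataset.labels:
    dataset.layers[label] = standardize(dataset.layers[label])
params, _ = train(dataset, HyperParams(N=8, D=8, seed=2))

pairs, top_module = select_attentive_modules(params, dataset)
print("most attentive cross-omics module pairs (batch-mean cosine):")
for p in pairs:
    print(
        f"  {p.omics_label_a}[{p.module_index_a}] ~ "
        f"{p.omics_label_b}[{p.module_index_b}]  cos={p.mean_cosine:.3f}"
    )

percentiles = {"mRNA": 98.0, "meth": 98.9, "SNV": 97.0}
selections = {}
for label in dataset.labels:
    table = gene_importance(params, dataset, label, top_module[label])
    genes, _ = zscore_threshold(table, percentiles[label])
    selections[label] = genes
    hits = len(set(genes) & truth.signal_genes[label])
    chance = hypergeom.mean(
        dataset.layers[label].n_genes, len(truth.signal_genes[label]), len(genes)
    )
    print(
        f"{label}: {len(genes)} genes above the {percentiles[label]}th "
        f"percentile, {hits} planted ({hits / chance:.0f}x chance)"
    )

union = union_genes(selections)
shared = (union["n_layers"] > 1).sum()
print(f"union across omics: {len(union)} unique genes, {shared} in >1 layer")
print(
    "Enrichment far above 1x chance shows the attentive modules concentrate "
    "the genes that carry the shared cross-omics signal."
)
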