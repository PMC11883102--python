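# mtamo

Attention-aware multi-task integration of gene-level multi-omics data for
continuous phenotype prediction and gene prioritization.

## The problem

Cohort studies of complex traits such as sarcopenia measure several omics
layers — mRNA expression, DNA methylation and SNV burden, each summarized
per gene — on partially overlapping sample sets, together with continuous
body-composition phenotypes like appendicular lean mass (ALM). Integrating
the layers *during* modelling (rather than concatenating inputs early or
merging predictions late) preserves each layer's distribution while still
letting shared biology couple them. `mtamo` implements such an
intermediate-integration model and the downstream gene-prioritization steps
that turn it into a candidate-gene screen, for bioinformaticians working
from Python.

## The model

For omics layer *m* with standardized gene values `x_m ∈ R^G`, a bias-free
dense layer with weights `W_m ∈ R^{G×N×D}` builds one *module vector* per
latent module `i = 1..N`:

    u_i = Σ_j x_j · W_m[j, i, :]        (sum of per-gene "gene vectors")
    V_m[i, :] = u_i / ‖u_i‖₂            (unit normalization)

Cross-omics *module attention* between a source layer *n* and target layer
*m* is a softmax over the target's modules of cosine similarities,

    S_{n→m}[l, k] = exp(cos(v^n_l, v^m_k)) / Σ_k' exp(cos(v^n_l, v^m_k')),

and each layer's module vectors are updated per sample by the other layers'
attention, `U_m = mean_n S_{n→m}ᵀ V_m`. One affine head per layer maps the
flattened `U_m` to the phenotype task(s); the multi-task objective is the
unweighted mean of per-layer MSEs, minimized with mini-batch Adam, a seeded
80/20 validation split and early stopping.

After training:

* the most *attentive* cross-omics module pairs (highest batch-mean cosine)
  mark modules carrying shared signal;
* a gene's contribution to such a module is the inner product of its gene
  vector with the unit module vector (contributions sum exactly to `‖u_i‖₂`
  per sample);
* per layer, contribution Z-scores above an empirical percentile (defaults
  98 / 98.9 / 97 for mRNA / meth / SNV) define the selected genes, combined
  across layers by set union;
* selected genes can be screened on a protein–protein interaction edge list
  by node degree (hub genes) and intersected with a curated aging-gene
  reference list.

A seeded linear-Gaussian simulator (`mtamo.synthetic`) plants latent
modules shared across layers that drive both a subset of genes and the
phenotype, providing ground truth for recovery tests.

## Worked example

`examples/simulate_train_evaluate.py` simulates 300 samples × three
500-gene layers with 30 signal genes over 3 shared latent modules, trains
with N=8 modules and D=8 embedding dimensions, and prints:

```
samples: 300, layers: ['SNV', 'mRNA', 'meth']
phenotype variance (the mean-predictor MSE floor): 2.936
epochs run: 74, best epoch: 52
best validation MSE (mean over omics): 1.348
    SNV: MSE 1.299  RMSE 1.140  MAE 0.898
   mRNA: MSE 1.200  RMSE 1.095  MAE 0.866
   meth: MSE 1.544  RMSE 1.243  MAE 1.046
```

The validation MSE of ~1.35 against a variance floor of ~2.94 means the
model recovers roughly half of the phenotype variance from the planted
cross-omics signal. `examples/gene_importance_selection.py` continues to
gene selection (on the default 500-sample benchmark it recovers planted
genes at ~20× the hypergeometric chance expectation in every layer), and
`examples/hub_gene_screen.py` shows the PPI degree screen. The same flow is
available from the shell:

```bash
mtamo run --config config.yaml --seed 1 --out results/
```

with a YAML config naming either TSV layer/phenotype files or a synthetic
spec, the model hyperparameters, per-omics selection percentiles and an
optional edge list + reference list (see `examples/full_pipeline.py` for
the schema).

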