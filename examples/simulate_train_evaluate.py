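"""Simulate a multi-omics cohort, train the attention model, evaluate it.

Generates three gene-level omics layers (mRNA, meth, SNV) in which 50 genes
share latent-module structure that drives a continuous lean-mass-like
phenotype, then fits the module-encoder + cross-omics-attention +
multi-task-heads model and reports per-omics prediction error on the
held-out validation split.
"""

import numpy as np

from mtamo import HyperParams, SyntheticSpec, generate, standardize, train

spec = SyntheticSpec(
    n_samples=300,
    genes_per_layer={"mRNA": 500, "meth": 500, "SNV": 500},
    n_signal_genes=30,
    n_signal_modules=3,
    effect_size=1.0,
    noise_sd=0.5,
    cross_omics_correlation=0.6,
    seed=1,
)
dataset, truth = generate(spec)
for label in dataset.labels:
    dataset.layers[label] = standardize(dataset.layers[label])

params, report = train(dataset, HyperParams(N=8, D=8, epochs=120, seed=2))

var_z = dataset.phenotype.var()
print(f"samples: {dataset.n_samples}, layers: {dataset.labels}")
print(f"phenotype variance (the mean-predictor MSE floor): {var_z:.3f}")
print(f"epochs run: {report.n_epochs_run}, best epoch: {report.best_epoch}")
print(f"best validation MSE (mean over omics): {min(report.val_mse):.3f}")
for omics, metrics in sorted(report.val_metrics.items()):
    print(
        f"  {omics:>5}: MSE {metrics['MSE']:.3f}  RMSE {metrics['RMSE']:.3f}"
        f"  MAE {metrics['MAE']:.3f}"
    )
print(
    "A validation MSE well below the phenotype variance means the model "
    "explains part of the planted cross-omics signal."
)
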