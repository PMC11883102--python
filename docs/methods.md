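# Methods

## Model

Each omics layer `m` (gene-level real values, samples × genes) is encoded
by a bias-free dense map `W_m ∈ R^{G_m×N×D}`: the unnormalized module
vector is `u_i = Σ_j x_j W_m[j,i,:]` and the module vector is
`V_m[i] = u_i/‖u_i‖₂`. Bias-freeness is deliberate: it makes the module
vector an exact sum of per-gene *gene vectors* `x_j·W_m[j,i,:]`, which in
turn makes the importance attribution conservative — the inner products of
gene vectors with the unit module vector sum exactly to `‖u_i‖₂` per
sample. Normalization is per (sample, module); an all-zero input yields a
zero module vector with a degeneracy flag rather than NaN, and flagged
vectors contribute cosine 0 to attention.

Attention between distinct layers is a per-sample softmax over the target
layer's modules of the cosine similarities,
`S_{n→m}[l,k] = softmax_k cos(v^n_l, v^m_k)`; because module vectors are
unit vectors the cosine is the inner product, and every row of `S` sums
to 1. The target layer's vectors are updated as
`U_m = (1/(L−1)) Σ_{n≠m} S_{n→m}ᵀ V_m`, i.e. each of `m`'s module vectors
is reweighted by the attention it receives from the other layers, averaged
so the scale does not depend on the layer count. This update requires equal
module counts `N` across layers, which the trainer enforces (`N` is a
single hyperparameter). A known algebraic quirk of this conformable update
is that it contracts the *source* module index against the target layer's
vectors, so reordering another layer's modules can change `U_m`; the order
of layers in the average does not. The attention itself has no learned
parameters.

One affine head per layer maps the flattened `U_m` (length `N·D`) to the
phenotype task(s). The objective is the unweighted mean over layers of
per-layer MSE (a symmetric multi-task choice) plus an optional L2 penalty
on encoder and head weights.

## Training

The forward pass and its analytic gradients are implemented directly in
numpy (the network is three small tensor contractions, a softmax and a
normalization per layer); the gradients are verified against central
finite differences in the test-suite at relative tolerance 1e-5.
Optimization is mini-batch Adam (defaults: learning rate 1e-3, batch 32,
up to 200 epochs), with a seeded 80/20 train/validation split, early
stopping after 20 non-improving epochs on validation MSE, and restoration
of the best-epoch parameters. Encoders use Glorot-style uniform
initialization; heads start at zero, so the untrained model is exactly the
zero predictor — a clean reference for null checks and for the
zero-learning-rate row of a hyperparameter grid. All randomness (init,
split, shuffling) derives from one integer seed; identical seeds give
bit-identical loss traces. Hyperparameter selection is a seeded k-fold CV
grid search ranked by mean validation MSE, ties broken toward smaller N
then smaller D (parsimony).

## Preprocessing and data handling

Layers are aligned by sample-ID intersection in lexicographic order (the
layers of a real cohort are measured on unequal sample sets; no imputation
is attempted, and per-layer dropped counts are logged). Each gene column is
z-scored (ddof=1); zero-variance genes become all-zeros and are flagged.
Unit-scale inputs matter because the attention is cosine-based. Duplicate
gene symbols in input files collapse by mean (logged); missing or
non-numeric cells are rejected with their coordinates rather than imputed.
The per-gene numeric encoding of SNV data is accepted as given — any
sample × gene burden summary works.

## Gene selection

After training, for every ordered pair of layers the module pair with the
highest batch-mean cosine is reported, and each layer's member of its best
pair becomes that layer's *attentive module*. Gene contributions to that
module (`c_{s,j} = ⟨x_{s,j}W[j,i,:], V[s,i,:]⟩`) are averaged over samples
— a signed mean by default; an absolute-value variant is available where
the sign of the contribution is not of interest. Raw scores are
standardized to Z-scores over the layer's genes (population SD), and genes
strictly above the linear-interpolation empirical percentile (defaults
98 / 98.9 / 97 for mRNA / meth / SNV) are selected; with distinct scores
this yields ≈ `n_genes·(1−p/100)` genes. Selections are combined by set
union with per-layer provenance. Hub screening ranks the nodes of a
user-supplied PPI edge list (STRING-export style; reversed duplicates
collapse, self-loops drop, optional score filter) by raw degree with
alphabetical tie-break, and intersects hubs with a reference list
case-insensitively. The PPI network is an input, not fetched: interaction
databases are versioned web resources and a query snapshot is not
reproducible.

## Synthetic benchmark

The generator is a linear-Gaussian factor model: `K` latent factors
(standard normal per sample) are shared by all layers; each of the
`n_signal_genes` signal genes (the same symbols in every layer, assigned to
factors round-robin) is `√ρ·F_k + √(1−ρ)·ε` with `ρ` the cross-omics
correlation; all other genes are independent standard normal; the
phenotype is `z = β·Σ_k F_k + N(0, σ²)`. Defaults — 500 samples, three
1000-gene layers, 50 signal genes, `K = 4`, `β = 1`, `σ = 0.5`, `ρ = 0.6`
— are the package's standard benchmark condition; `K = 4` splits the 50
signal genes into realistically sized co-regulated groups while keeping
the signal variance (`K·β² = 4`) clearly above the noise floor
(`σ² = 0.25`). Phenotype variance is `K·β² + σ²` and same-gene cross-layer
correlation is `ρ`, both verified empirically in tests. An optional
per-layer sample dropout emulates partially overlapping sample sets.

What the simulator does *not* emulate: methylation beta-value
distributions, genotype dosage discreteness, heavy-tailed expression,
batch effects, linkage/co-expression among noise genes, or gene sets
differing across layers. Passing recovery tests therefore show the method
works when its structural assumption (linear shared latent modules) holds,
not that it works on real cohort data.

## Behaviour under the phenotype-null

With `β = 0` the phenotype is pure noise and the trained model's
validation MSE matches the phenotype variance of the validation samples
(within ~1%, as the zero-initialized heads make the initial model the
mean/zero predictor and early stopping never accepts a worse epoch).
Gene *selection*, however, still enriches the planted genes several-fold
over chance: the cross-omics correlation `ρ` remains, and cosine-based
module attention detects shared cross-layer structure without any
phenotype supervision — freshly initialized and trained models enrich
about equally. Attention-guided importance is thus a detector of shared
cross-omics structure, not of phenotype association alone; on real data a
phenotype-permutation control is the appropriate null for the selection
step. This property is exercised honestly in the test-suite.

## Numerical choices

Softmax is computed with max-subtraction; module-vector norms below 1e-12
are treated as degenerate; attention rows are asserted row-stochastic to
1e-6; the contribution-conservation identity holds to 1e-9; vectorized
operators match naive scalar-loop oracles to 1e-10 on randomized small
instances. Argmax tie-breaks (attentive pairs, degree ranking, grid
ranking) are deterministic: lowest module indices, alphabetical node
order, smaller model first. Output tables are written with fixed float
formatting so that identical config + seed reproduce byte-identical files.

## Problem sizes

The test-suite trains on datasets from 40×(2×20 genes) up to the full
benchmark 500×(3×1000 genes) with N=D=8, which takes a few seconds per
fit on one CPU; the acceptance script runs two benchmark fits (signal and
null) plus the oracle and determinism checks in well under a minute.

## Known limitations

* The attention update is sensitive to the module order of *other* layers
  (see above); module order is itself learned, so this does not affect a
  fixed trained model, but it is an asymmetry of the formulation.
* Equal module count across layers is required.
* Importance uses the signed mean contribution by default; genes whose
  contributions cancel across samples score near zero.
* The trainer is CPU-only and dense; layers beyond ~10⁵ genes per module
  count would need minibatched einsum paths or sparsity.
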