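"""Module encoder: gene vectors, module vectors, unit normalization.

Each omics layer owns a dense bias-free linear map from genes to N_m latent
modules, each represented by a D-dimensional vector.  A gene's *gene vector*
for module i is its input value times its weight vector W[j, i, :]; the
module's unnormalized vector is the sum of its gene vectors,
u_i = sum_j x_j * W[j, i, :], and the *module vector* is u_i scaled to unit
Euclidean norm.  Bias-freeness makes the gene-vector decomposition of a
module vector exact, which the importance attribution relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EncoderWeights", "ModuleVectors", "init_encoder", "gene_vectors", "encode_modules"]

#: module vectors with unnormalized norm below this are treated as zero
ZERO_NORM_TOL = 1e-12


@dataclass
class EncoderWeights:
    """Per-omics weight tensor W of shape [n_genes, N_m, D]."""

    omics_label: str
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 3:
            raise ValueError("W must have shape [n_genes, N_m, D]")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("encoder weights must be finite")
        if self.N_m < 2 or self.D < 2:
            raise ValueError("need N_m >= 2 and D >= 2")

    @property
    def n_genes(self) -> int:
        return self.W.shape[0]

    @property
    def N_m(self) -> int:
        return self.W.shape[1]

    @property
    def D(self) -> int:
        return self.W.shape[2]


@dataclass
class ModuleVectors:
    """Unit module vectors V [batch, N_m, D] plus pre-normalization norms.

    ``norms[s, i]`` is the Euclidean norm of the unnormalized module vector
    u_i for sample s (used by the importance attribution); ``zero_flags``
    marks degenerate (all-zero-input) module vectors, which are returned as
    zero rather than NaN.
    """

    omics_label: str
    V: np.ndarray
    norms: np.ndarray
    zero_flags: np.ndarray

    @property
    def batch_size(self) -> int:
        return self.V.shape[0]

    @property
    def N_m(self) -> int:
        return self.V.shape[1]

    @property
    def D(self) -> int:
        return self.V.shape[2]


def init_encoder(
    n_genes: int, N_m: int, D: int, seed: int, omics_label: str = ""
) -> EncoderWeights:
    """Glorot-style uniform initialization on [-a, a], a = sqrt(6/(n_genes + N_m*D))."""
    if n_genes <= 0 or N_m <= 0 or D <= 0:
        raise ValueError("n_genes, N_m and D must all be positive")
    rng = np.random.default_rng(seed)
    a = np.sqrt(6.0 / (n_genes + N_m * D))
    W = rng.uniform(-a, a, size=(n_genes, N_m, D))
    return EncoderWeights(omics_label=omics_label, W=W)


def gene_vectors(
    x: np.ndarray, w: EncoderWeights, module_index: int
) -> np.ndarray:
    """Gene vectors for one module: row j is x_j * W[j, module_index, :]."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != w.n_genes:
        raise ValueError(f"expected {w.n_genes} gene values, got {x.shape[0]}")
    if not 0 <= module_index < w.N_m:
        raise IndexError(f"module_index {module_index} out of range [0, {w.N_m})")
    return x[:, None] * w.W[:, module_index, :]


def encode_modules(x_batch: np.ndarray, w: EncoderWeights) -> ModuleVectors:
    """Encode a batch of samples into unit module vectors.

    Accepts [batch, n_genes] (or a single [n_genes] vector).  The
    unnormalized module vector is u[s, i, :] = sum_j x[s, j] * W[j, i, :];
    V is u normalized per (sample, module) pair.
    """
    x_batch = np.asarray(x_batch, dtype=float)
    if x_batch.ndim == 1:
        x_batch = x_batch[None, :]
    if x_batch.ndim != 2 or x_batch.shape[1] != w.n_genes:
        raise ValueError(
            f"x_batch must be [batch, {w.n_genes}], got {x_batch.shape}"
        )
    u = np.einsum("sg,gid->sid", x_batch, w.W)
    norms = np.linalg.norm(u, axis=2)
    zero = norms <= ZERO_NORM_TOL
    safe = np.where(zero, 1.0, norms)
    V = u / safe[:, :, None]
    V[zero, :] = 0.0
    return ModuleVectors(
        omics_label=w.omics_label, V=V, norms=norms, zero_flags=zero
    )
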