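"""Cross-omics module attention.

For an ordered pair of omics layers (source n, target m) the attention
matrix S holds, per sample, a softmax over the *target* layer's modules of
the cosine similarities between source and target module vectors:

    S[l, k] = exp(cos(v^n_l, v^m_k)) / sum_k' exp(cos(v^n_l, v^m_k'))

Since module vectors are unit-normalized the cosine is a plain inner
product; degenerate (zero-flagged) module vectors contribute cosine 0.
A target layer's module vectors are then updated by each other layer's
attention and the results averaged:

    U_V_m = mean over other layers n of  S_{n->m}^T  @  V_m   (per sample)

so each target module vector is reweighted by how much the other layers'
modules attend to it.  Equal module counts across layers are required for
this product to be conformable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import ModuleVectors

__all__ = ["SimilarityMatrix", "UpdatedModuleVectors", "cosine_matrix", "similarity_matrix", "update_module_vectors"]


@dataclass
class SimilarityMatrix:
    """Batched row-stochastic attention S [batch, N_source, N_target]."""

    source_label: str
    target_label: str
    S: np.ndarray

    def __post_init__(self) -> None:
        if self.source_label == self.target_label:
            raise ValueError("attention is defined only across distinct layers")
        if self.S.ndim != 3:
            raise ValueError("S must be [batch, N_source, N_target]")


@dataclass
class UpdatedModuleVectors:
    """Attention-updated module vectors U [batch, N_m, D]."""

    omics_label: str
    U: np.ndarray


def cosine_matrix(V_n: ModuleVectors, V_m: ModuleVectors) -> np.ndarray:
    """Batched cosine similarities C [batch, N_n, N_m] of unit module vectors.

    Zero-flagged (degenerate) module vectors have cosine 0 with everything.
    """
    if V_n.batch_size != V_m.batch_size:
        raise ValueError("batch size mismatch between layers")
    # unit vectors: cosine == inner product; zero-flag rows are all-zero, so
    # their cosines come out 0 automatically
    return np.einsum("sld,skd->slk", V_n.V, V_m.V)


def similarity_matrix(V_n: ModuleVectors, V_m: ModuleVectors) -> SimilarityMatrix:
    """Attention of source layer n onto target layer m (softmax over m's modules)."""
    if V_n.omics_label == V_m.omics_label:
        raise ValueError("attention requires two distinct omics layers")
    C = cosine_matrix(V_n, V_m)
    E = np.exp(C - C.max(axis=2, keepdims=True))  # stabilized softmax
    S = E / E.sum(axis=2, keepdims=True)
    return SimilarityMatrix(
        source_label=V_n.omics_label, target_label=V_m.omics_label, S=S
    )


def update_module_vectors(
    V_m: ModuleVectors, S_from_others: list[SimilarityMatrix]
) -> UpdatedModuleVectors:
    """Average of S^T @ V_m over the other layers' attention matrices."""
    if not S_from_others:
        raise ValueError("need at least one similarity matrix")
    N = V_m.N_m
    acc = np.zeros_like(V_m.V)
    for sim in S_from_others:
        if sim.target_label != V_m.omics_label:
            raise ValueError(
                f"similarity targets {sim.target_label!r}, not {V_m.omics_label!r}"
            )
        if sim.S.shape[1] != N or sim.S.shape[2] != N:
            raise ValueError(
                "module counts must be equal across layers for the update"
            )
        if sim.S.shape[0] != V_m.batch_size:
            raise ValueError("batch size mismatch")
        # per sample: U[k] = sum_l S[l, k] * V_m[l]  ==  S^T @ V_m
        acc += np.einsum("slk,sld->skd", sim.S, V_m.V)
    U = acc / len(S_from_others)
    return UpdatedModuleVectors(omics_label=V_m.omics_label, U=U)
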