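"""Attention-guided gene importance and per-omics selection.

After training, the most attentive cross-omics module pairs (highest
batch-mean cosine similarity between module vectors of different layers)
mark the modules that carry shared signal.  A gene's contribution to such a
module is the inner product of its gene vector with the unit module vector,

    c[s, j] = < x[s, j] * W[j, i, :],  V[s, i, :] >,

averaged over samples; contributions are exactly conservative: their sum
over genes equals the unnormalized module-vector norm ||u_i|| for each
sample.  Per layer, raw scores are standardized to Z-scores over genes and
genes above a stated empirical percentile of the Z-score distribution are
selected; selections from all layers are combined by set union.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .encoder import encode_modules
from .io_data import MultiOmicsDataset
from .model import MTAMOParams

__all__ = [
    "AttentiveModulePair",
    "ImportanceTable",
    "select_attentive_modules",
    "gene_importance",
    "zscore_threshold",
    "union_genes",
]


@dataclass(frozen=True)
class AttentiveModulePair:
    """The most similar module pair for one ordered pair of omics layers."""

    omics_label_a: str
    module_index_a: int
    omics_label_b: str
    module_index_b: int
    mean_cosine: float


@dataclass
class ImportanceTable:
    """Per-gene contribution scores of one layer's attentive module."""

    omics_label: str
    module_index: int
    table: pd.DataFrame  # columns: gene, raw_score, z_score, selected
    threshold_percentile: float | None = None
    signed: bool = True


def select_attentive_modules(
    params: MTAMOParams, dataset: MultiOmicsDataset
) -> tuple[list[AttentiveModulePair], dict[str, int]]:
    """Top batch-mean-cosine module pair per ordered omics pair.

    Returns the pairs plus, per omics layer, the index of its module in the
    best pair it participates in.  Ties break toward the lowest
    (module_index_a, module_index_b); degenerate (all module vectors zero)
    layers raise.
    """
    labels = params.labels
    mv = {
        m: encode_modules(dataset.layers[m].values, params.encoders[m])
        for m in labels
    }
    for m in labels:
        if mv[m].zero_flags.all():
            raise ValueError(f"layer {m!r}: all module vectors are degenerate")

    pairs: list[AttentiveModulePair] = []
    best_for: dict[str, tuple[float, int, int]] = {}
    for a in labels:
        for b in labels:
            if a == b:
                continue
            C = np.einsum("sld,skd->slk", mv[a].V, mv[b].V).mean(axis=0)
            flat = int(np.argmax(C))  # row-major => lowest (i, j) on ties
            i, j = divmod(flat, C.shape[1])
            pair = AttentiveModulePair(a, i, b, j, float(C[i, j]))
            pairs.append(pair)
            for label, idx in ((a, i), (b, j)):
                cur = best_for.get(label)
                cand = (pair.mean_cosine, -idx)
                if cur is None or cand > (cur[0], -cur[1]):
                    best_for[label] = (pair.mean_cosine, idx)
    top_module = {m: best_for[m][1] for m in labels}
    return pairs, top_module


def gene_importance(
    params: MTAMOParams,
    dataset: MultiOmicsDataset,
    omics_label: str,
    module_index: int,
    signed: bool = True,
) -> ImportanceTable:
    """Per-gene contribution scores for one module of one layer.

    ``raw_score`` is the mean over samples of the gene-vector / module-vector
    inner product (or of its absolute value if ``signed=False``);
    ``z_score`` standardizes raw scores over the layer's genes.
    """
    layer = dataset.layers[omics_label]
    enc = params.encoders[omics_label]
    if not 0 <= module_index < enc.N_m:
        raise IndexError(f"module_index {module_index} out of range")
    X = layer.values  # [n, G]
    mv = encode_modules(X, enc)
    V = mv.V[:, module_index, :]  # [n, D]
    # c[s, j] = x[s, j] * <W[j, i, :], V[s, :]>
    contrib = X * (V @ enc.W[:, module_index, :].T)
    if not signed:
        contrib = np.abs(contrib)
    raw = contrib.mean(axis=0)
    sd = raw.std(ddof=0)
    if sd == 0.0:
        raise ValueError("degenerate importance: all raw scores identical")
    zs = (raw - raw.mean()) / sd
    table = pd.DataFrame(
        {
            "gene": layer.gene_symbols,
            "raw_score": raw,
            "z_score": zs,
            "selected": False,
        }
    )
    return ImportanceTable(
        omics_label=omics_label,
        module_index=module_index,
        table=table,
        signed=signed,
    )


def zscore_threshold(
    table: ImportanceTable, percentile: float
) -> tuple[list[str], ImportanceTable]:
    """Select genes with Z-score strictly above the empirical percentile.

    The cutoff is the linear-interpolation quantile of the layer's Z-score
    distribution, so with distinct scores roughly n_genes * (1 - p/100)
    genes are selected.  Returns the selected genes (descending Z-score)
    and an updated table with selection flags.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    if len(table.table) < 10:
        raise ValueError("need at least 10 genes for percentile selection")
    zs = table.table["z_score"].to_numpy()
    cutoff = float(np.percentile(zs, percentile))
    selected_mask = zs > cutoff
    new = replace(
        table,
        table=table.table.assign(selected=selected_mask),
        threshold_percentile=percentile,
    )
    chosen = new.table.loc[selected_mask].sort_values(
        "z_score", ascending=False, kind="stable"
    )
    return list(chosen["gene"]), new


def union_genes(selections: dict[str, list[str]]) -> pd.DataFrame:
    """Sorted set union of per-layer selections with layer provenance.

    Returns a table with one row per unique gene, the contributing layers
    (comma-joined, layer-sorted) and their count.
    """
    if not selections or all(len(v) == 0 for v in selections.values()):
        raise ValueError("need at least one nonempty selection")
    members: dict[str, set[str]] = {}
    for label in sorted(selections):
        for gene in selections[label]:
            members.setdefault(gene, set()).add(label)
    rows = [
        {
            "gene": g,
            "layers": ",".join(sorted(members[g])),
            "n_layers": len(members[g]),
        }
        for g in sorted(members)
    ]
    return pd.DataFrame(rows)
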