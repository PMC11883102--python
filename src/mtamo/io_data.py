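"""Reading, validation and alignment of gene-level omics matrices.

Every omics layer (mRNA expression, DNA methylation beta/M values summarized
per gene, per-gene SNV burden, ...) is handled as a real matrix of samples x
genes with string sample IDs and gene symbols.  Layers measured on partially
overlapping sample sets are combined by intersection into a
:class:`MultiOmicsDataset` carrying one or more continuous phenotype tasks
(e.g. appendicular lean mass).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsMatrix",
    "MultiOmicsDataset",
    "read_omics_matrix",
    "read_phenotype_table",
    "read_gene_list",
    "align_dataset",
    "standardize",
    "write_omics_matrix",
]


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class OmicsMatrix:
    """One omics layer: real values for ``n_samples x n_genes``.

    Parameters
    ----------
    omics_label
        Layer name, conventionally one of ``mRNA``, ``meth``, ``SNV``.
    sample_ids, gene_symbols
        Ordered, unique identifiers for rows and columns of ``values``.
    values
        Real matrix, samples as rows.
    zero_variance_genes
        Gene symbols flagged by :func:`standardize` as having no variance.
    """

    omics_label: str
    sample_ids: list[str]
    gene_symbols: list[str]
    values: np.ndarray
    zero_variance_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_symbols = [str(g) for g in self.gene_symbols]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.values.shape != (len(self.sample_ids), len(self.gene_symbols)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_symbols)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"duplicate sample IDs in layer {self.omics_label!r}")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValueError(f"duplicate gene symbols in layer {self.omics_label!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in layer {self.omics_label!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.gene_symbols
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        """Return a copy restricted to ``sample_ids``, in the given order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return replace(
            self, sample_ids=list(sample_ids), values=self.values[idx, :].copy()
        )


@dataclass
class MultiOmicsDataset:
    """Sample-aligned omics layers plus continuous phenotype task(s)."""

    layers: dict[str, OmicsMatrix]
    phenotype: np.ndarray  # [n_samples, n_tasks]
    task_names: list[str]
    sample_ids: list[str]
    dropped_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phenotype = np.atleast_2d(np.asarray(self.phenotype, dtype=float))
        if self.phenotype.shape[0] == 1 and len(self.sample_ids) != 1:
            self.phenotype = self.phenotype.T
        if self.phenotype.shape[0] != len(self.sample_ids):
            raise ValueError("phenotype rows must match sample_ids")
        if self.phenotype.shape[1] != len(self.task_names):
            raise ValueError("phenotype columns must match task_names")
        if self.phenotype.shape[1] < 1:
            raise ValueError("at least one phenotype task required")
        if not np.all(np.isfinite(self.phenotype)):
            raise ValueError("phenotype contains non-finite values")
        for label, layer in self.layers.items():
            if layer.sample_ids != self.sample_ids:
                raise ValueError(
                    f"layer {label!r} sample order does not match dataset"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_tasks(self) -> int:
        return self.phenotype.shape[1]

    @property
    def labels(self) -> list[str]:
        return sorted(self.layers)

    def subset_samples(self, indices: Sequence[int]) -> "MultiOmicsDataset":
        ids = [self.sample_ids[i] for i in indices]
        return MultiOmicsDataset(
            layers={k: v.subset_samples(ids) for k, v in self.layers.items()},
            phenotype=self.phenotype[list(indices), :].copy(),
            task_names=list(self.task_names),
            sample_ids=ids,
        )


def _read_table(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    """Read a delimited table with one header row and one ID column.

    Non-numeric cells raise with the offending row/column labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sep = _delimiter_for(path, delimiter)
    # header=None keeps duplicate labels intact (pandas would mangle them)
    raw = pd.read_csv(path, sep=sep, header=None, dtype=str)
    columns = [str(c) for c in raw.iloc[0, 1:]]
    index = [str(r) for r in raw.iloc[1:, 0]]
    cells = raw.iloc[1:, 1:].to_numpy(dtype=object)
    numeric = np.empty(cells.shape, dtype=float)
    for j in range(cells.shape[1]):
        col = pd.to_numeric(cells[:, j], errors="coerce")
        numeric[:, j] = col
    bad = ~np.isfinite(numeric)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric or missing cell at row {index[r]!r}, "
            f"column {columns[c]!r} in {path}"
        )
    return pd.DataFrame(numeric, index=index, columns=columns)


def read_omics_matrix(
    path: str | Path,
    omics_label: str,
    orientation: str = "samples_as_rows",
    delimiter: str | None = None,
) -> OmicsMatrix:
    """Read a delimited omics matrix into samples x genes orientation.

    ``orientation`` names what the file's *rows* are.  Duplicate gene symbols
    are collapsed by their mean (logged); duplicate sample IDs are an error.
    """
    if orientation not in ("samples_as_rows", "genes_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    frame = _read_table(path, delimiter)
    if orientation == "genes_as_rows":
        frame = frame.T
    # rows are samples now
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID {dup!r} in {path}")
    if frame.columns.duplicated().any():
        n_dup = int(frame.columns.duplicated().sum())
        logger.info(
            "layer %s: collapsing %d duplicate gene symbol(s) by mean",
            omics_label,
            n_dup,
        )
        frame = frame.T.groupby(level=0, sort=False).mean().T
    return OmicsMatrix(
        omics_label=omics_label,
        sample_ids=list(frame.index),
        gene_symbols=list(frame.columns),
        values=frame.to_numpy(dtype=float),
    )


def read_phenotype_table(
    path: str | Path, delimiter: str | None = None
) -> pd.DataFrame:
    """Read a phenotype table (sample ID column + one column per task)."""
    frame = _read_table(path, delimiter)
    if frame.index.duplicated().any():
        dup = frame.index[frame.index.duplicated()][0]
        raise ValueError(f"duplicate sample ID {dup!r} in phenotype table")
    return frame


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list, skipping blank lines."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]


def align_dataset(
    layers: Sequence[OmicsMatrix],
    phenotype_table: pd.DataFrame | Mapping[str, Sequence[float]],
) -> MultiOmicsDataset:
    """Intersect samples across all layers and the phenotype table.

    Only samples present in every layer *and* the phenotype table are kept,
    in deterministic lexicographic order; per-layer dropped counts are
    recorded on the returned dataset and logged.
    """
    if len(layers) < 2:
        raise ValueError("at least two omics layers required")
    if not isinstance(phenotype_table, pd.DataFrame):
        phenotype_table = pd.DataFrame.from_dict(
            {k: np.atleast_1d(v) for k, v in phenotype_table.items()},
            orient="index",
        )
        phenotype_table.columns = [
            f"task{i}" for i in range(phenotype_table.shape[1])
        ]
    if phenotype_table.shape[1] < 1:
        raise ValueError("phenotype table must have at least one task column")

    common = set(phenotype_table.index.astype(str))
    for layer in layers:
        common &= set(layer.sample_ids)
    if not common:
        raise ValueError("no samples shared by all layers and the phenotype")
    order = sorted(common)

    dropped = {
        layer.omics_label: layer.n_samples - len(order) for layer in layers
    }
    dropped["phenotype"] = phenotype_table.shape[0] - len(order)
    for name, n in dropped.items():
        if n:
            logger.info("alignment dropped %d sample(s) from %s", n, name)

    pheno = phenotype_table.loc[order]
    return MultiOmicsDataset(
        layers={m.omics_label: m.subset_samples(order) for m in layers},
        phenotype=pheno.to_numpy(dtype=float),
        task_names=[str(c) for c in pheno.columns],
        sample_ids=order,
        dropped_counts=dropped,
    )


def standardize(m: OmicsMatrix) -> OmicsMatrix:
    """Z-score each gene column (mean 0, unit sample SD, ddof=1).

    Zero-variance columns become all-zeros and are flagged in
    ``zero_variance_genes``.  Idempotent.
    """
    if m.n_samples < 2:
        raise ValueError("standardize requires at least two samples")
    mu = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=1)
    flat = sd == 0.0
    sd_safe = np.where(flat, 1.0, sd)
    vals = (m.values - mu) / sd_safe
    vals[:, flat] = 0.0
    flagged = tuple(g for g, f in zip(m.gene_symbols, flat) if f)
    if flagged:
        logger.info(
            "layer %s: %d zero-variance gene(s) set to 0", m.omics_label, len(flagged)
        )
    return replace(m, values=vals, zero_variance_genes=flagged)


def write_omics_matrix(
    m: OmicsMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a layer as delimited text (samples as rows, 10 significant digits)."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    m.to_frame().to_csv(path, sep=sep, float_format="%.10g", index_label="sample_id")
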