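"""Synthetic multi-omics benchmark with planted cross-omics signal.

A linear-Gaussian factor model: a small number of latent "signal modules"
(standard-normal factor scores per sample) drive (a) a subset of genes in
*every* omics layer, with loading sqrt(cross_omics_correlation), and (b) a
continuous phenotype, z = effect_size * sum of factor scores + noise.  All
remaining genes are independent standard normal.  This is the minimal
structure the attention model assumes — latent modules shared across omics
layers predicting a continuous trait — and gives analytically transparent
ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_data import (
    MultiOmicsDataset,
    OmicsMatrix,
    align_dataset,
    write_omics_matrix,
)

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate", "write_fixture"]


def _default_genes() -> dict[str, int]:
    return {"mRNA": 1000, "meth": 1000, "SNV": 1000}


@dataclass
class SyntheticSpec:
    """Parameters fully determining a synthetic dataset's distribution.

    Defaults describe the standard benchmark condition used throughout the
    test-suite: 500 samples, three 1000-gene layers, 50 signal genes spread
    over 4 latent modules, per-module phenotype effect 1.0, residual SD 0.5,
    and cross-omics correlation 0.6 for signal genes.
    """

    n_samples: int = 500
    genes_per_layer: dict[str, int] = field(default_factory=_default_genes)
    n_signal_genes: int = 50
    n_signal_modules: int = 4
    effect_size: float = 1.0
    noise_sd: float = 0.5
    cross_omics_correlation: float = 0.6
    n_tasks: int = 1
    sample_dropout: float = 0.0  # fraction of samples missing per layer
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not self.genes_per_layer or len(self.genes_per_layer) < 2:
            raise ValueError("need at least two omics layers")
        if any(g < 1 for g in self.genes_per_layer.values()):
            raise ValueError("genes_per_layer entries must be positive")
        if self.n_signal_genes < 1:
            raise ValueError("n_signal_genes must be positive")
        if self.n_signal_genes > min(self.genes_per_layer.values()):
            raise ValueError("n_signal_genes exceeds smallest layer")
        if self.n_signal_modules < 1:
            raise ValueError("n_signal_modules must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.cross_omics_correlation <= 1.0:
            raise ValueError("cross_omics_correlation must be in [0, 1]")
        if self.n_tasks < 1:
            raise ValueError("n_tasks must be positive")
        if not 0.0 <= self.sample_dropout < 1.0:
            raise ValueError("sample_dropout must be in [0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated dataset."""

    signal_genes: dict[str, set[str]]  # omics_label -> symbols
    module_assignment: dict[str, int]  # gene -> latent factor index
    true_coefficients: dict[str, float]  # gene -> phenotype effect of its factor
    factor_scores: np.ndarray  # [n_samples, n_signal_modules], aligned order


def generate(spec: SyntheticSpec) -> tuple[MultiOmicsDataset, SyntheticTruth]:
    """Draw one dataset from ``spec``; same seed gives bit-identical output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n = spec.n_samples
    k = spec.n_signal_modules
    rho = spec.cross_omics_correlation
    sample_ids = [f"S{i:05d}" for i in range(n)]
    n_genes_min = min(spec.genes_per_layer.values())

    # shared gene universe; signal genes common to all layers
    signal_idx = rng.choice(n_genes_min, size=spec.n_signal_genes, replace=False)
    signal_idx.sort()
    signal_genes = [f"G{j:05d}" for j in signal_idx]
    module_of = {g: i % k for i, g in enumerate(signal_genes)}

    factors = rng.standard_normal((n, k))  # latent module scores

    layers = []
    for label in sorted(spec.genes_per_layer):
        n_genes = spec.genes_per_layer[label]
        symbols = [f"G{j:05d}" for j in range(n_genes)]
        values = rng.standard_normal((n, n_genes))
        for g, j in zip(signal_genes, signal_idx):
            fac = factors[:, module_of[g]]
            values[:, j] = np.sqrt(rho) * fac + np.sqrt(1.0 - rho) * values[:, j]
        layers.append(
            OmicsMatrix(
                omics_label=label,
                sample_ids=sample_ids,
                gene_symbols=symbols,
                values=values,
            )
        )

    signal = spec.effect_size * factors.sum(axis=1)
    pheno = signal[:, None] + rng.normal(0.0, spec.noise_sd, size=(n, spec.n_tasks))
    pheno_table = pd.DataFrame(
        pheno,
        index=sample_ids,
        columns=[f"lean_mass_{t}" for t in range(spec.n_tasks)],
    )

    if spec.sample_dropout > 0.0:
        # emulate layers measured on partially overlapping sample sets
        kept_layers = []
        for layer in layers:
            keep = rng.random(n) >= spec.sample_dropout
            kept_layers.append(
                layer.subset_samples([s for s, k_ in zip(sample_ids, keep) if k_])
            )
        layers = kept_layers

    dataset = align_dataset(layers, pheno_table)
    order_idx = [sample_ids.index(s) for s in dataset.sample_ids]

    truth = SyntheticTruth(
        signal_genes={m.omics_label: set(signal_genes) for m in layers},
        module_assignment=dict(module_of),
        true_coefficients={g: spec.effect_size for g in signal_genes},
        factor_scores=factors[order_idx, :],
    )
    return dataset, truth


def write_fixture(
    dataset: MultiOmicsDataset,
    truth: SyntheticTruth,
    out_dir: str | Path,
    spec: SyntheticSpec | None = None,
) -> dict[str, Path]:
    """Write layers, phenotype and truth tables as TSV readable by io_data.

    Values round-trip at 10 significant digits.  Returns the emitted paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for label, layer in dataset.layers.items():
        p = out / f"layer_{label}.tsv"
        write_omics_matrix(layer, p)
        paths[f"layer_{label}"] = p

    p = out / "phenotype.tsv"
    pd.DataFrame(
        dataset.phenotype, index=dataset.sample_ids, columns=dataset.task_names
    ).to_csv(p, sep="\t", float_format="%.10g", index_label="sample_id")
    paths["phenotype"] = p

    rows = []
    for label in sorted(truth.signal_genes):
        for g in sorted(truth.signal_genes[label]):
            rows.append(
                {
                    "omics_label": label,
                    "gene": g,
                    "module": truth.module_assignment[g],
                    "coefficient": truth.true_coefficients[g],
                }
            )
    p = out / "truth_signal_genes.tsv"
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    paths["truth"] = p

    if spec is not None:
        p = out / "spec.yaml"
        spec.to_yaml(p)
        paths["spec"] = p
    return paths
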