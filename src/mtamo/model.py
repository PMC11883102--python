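"""Multi-task training of the attention model.

Architecture, per omics layer m (all layers share module count N and
embedding dimension D):

    x_m --encoder--> V_m --cross-omics attention--> U_m --affine head--> z_hat_m

Each layer has its own prediction head for the same continuous phenotype
task(s); the training objective is the unweighted mean over layers of the
per-layer mean-squared error, optionally with an L2 penalty on encoder and
head weights.  The whole network is small and purely tensor-algebraic, so
the forward pass and its analytic gradients are written directly in numpy
(verified against finite differences in the test-suite) and optimized with
Adam on mini-batches, with an internal seeded 80/20 train/validation split
and early stopping on validation MSE.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .attention import similarity_matrix, update_module_vectors
from .encoder import EncoderWeights, ModuleVectors, encode_modules, init_encoder
from .io_data import MultiOmicsDataset

__all__ = [
    "HyperParams",
    "Head",
    "MTAMOParams",
    "FitReport",
    "DivergenceError",
    "init_params",
    "forward",
    "loss",
    "train",
    "evaluate",
    "grid_search_cv",
    "save_model",
    "load_model",
]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass
class HyperParams:
    """Training hyperparameters.  N and D are shared by all layers."""

    N: int = 8
    D: int = 8
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 32
    l2_penalty: float = 0.0
    seed: int = 0
    patience: int = 20
    val_fraction: float = 0.2

    def validate(self) -> None:
        if self.N < 2 or self.D < 2:
            raise ValueError("N and D must be >= 2")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.l2_penalty < 0:
            raise ValueError("l2_penalty must be nonnegative")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class Head:
    """Affine prediction head: flattened [N*D] module vectors -> n_tasks."""

    W: np.ndarray  # [N*D, n_tasks]
    b: np.ndarray  # [n_tasks]


@dataclass
class MTAMOParams:
    """All learnable parameters plus the hyperparameters that shaped them."""

    encoders: dict[str, EncoderWeights]
    heads: dict[str, Head]
    hyper: HyperParams
    gene_symbols: dict[str, list[str]] = field(default_factory=dict)
    task_names: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return sorted(self.encoders)


@dataclass
class FitReport:
    """Per-epoch traces and best-epoch validation metrics."""

    train_loss: list[float]
    val_mse: list[float]
    best_epoch: int
    val_metrics: dict[str, dict[str, float]]  # omics -> {MSE, RMSE, MAE}
    n_epochs_run: int
    val_sample_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.train_loss)),
                "train_loss": self.train_loss,
                "val_mse": self.val_mse,
            }
        )


def init_params(dataset: MultiOmicsDataset, hyper: HyperParams) -> MTAMOParams:
    """Seeded initialization: Glorot encoders, zero heads.

    Zero head weights make the untrained network the zero predictor, a clean
    reference point for null-signal checks.
    """
    hyper.validate()
    n_tasks = dataset.n_tasks
    encoders, heads, symbols = {}, {}, {}
    for i, label in enumerate(dataset.labels):
        layer = dataset.layers[label]
        encoders[label] = init_encoder(
            layer.n_genes, hyper.N, hyper.D, seed=hyper.seed + i, omics_label=label
        )
        heads[label] = Head(
            W=np.zeros((hyper.N * hyper.D, n_tasks)), b=np.zeros(n_tasks)
        )
        symbols[label] = list(layer.gene_symbols)
    return MTAMOParams(
        encoders=encoders,
        heads=heads,
        hyper=hyper,
        gene_symbols=symbols,
        task_names=list(dataset.task_names),
    )


def _forward_cached(
    X: dict[str, np.ndarray], params: MTAMOParams
) -> tuple[dict[str, np.ndarray], dict]:
    """Full forward pass keeping every intermediate for backprop."""
    labels = params.labels
    mv: dict[str, ModuleVectors] = {
        m: encode_modules(X[m], params.encoders[m]) for m in labels
    }
    sims = {
        (n, m): similarity_matrix(mv[n], mv[m])
        for m in labels
        for n in labels
        if n != m
    }
    U, preds = {}, {}
    for m in labels:
        upd = update_module_vectors(
            mv[m], [sims[(n, m)] for n in labels if n != m]
        )
        U[m] = upd.U
        flat = upd.U.reshape(upd.U.shape[0], -1)
        head = params.heads[m]
        preds[m] = flat @ head.W + head.b
    cache = {"mv": mv, "sims": sims, "U": U, "preds": preds, "X": X}
    return preds, cache


def forward(
    batch: MultiOmicsDataset | dict[str, np.ndarray], params: MTAMOParams
) -> dict[str, np.ndarray]:
    """Per-omics phenotype predictions for a batch of aligned samples."""
    X = batch if isinstance(batch, dict) else {
        m: batch.layers[m].values for m in batch.labels
    }
    if sorted(X) != params.labels:
        raise ValueError(
            f"layers {sorted(X)} do not match model layers {params.labels}"
        )
    for m, enc in params.encoders.items():
        if np.asarray(X[m]).shape[-1] != enc.n_genes:
            raise ValueError(f"layer {m!r}: expected {enc.n_genes} genes")
    preds, _ = _forward_cached({m: np.atleast_2d(X[m]) for m in X}, params)
    return preds


def loss(
    preds: dict[str, np.ndarray], z: np.ndarray, params: MTAMOParams
) -> float:
    """Mean over layers of per-layer MSE plus L2 penalty on weights."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    total = 0.0
    for m in params.labels:
        p = preds[m]
        if p.shape != z.shape:
            raise ValueError(f"layer {m!r}: prediction shape {p.shape} != {z.shape}")
        if not (np.all(np.isfinite(p)) and np.all(np.isfinite(z))):
            raise ValueError("NaN or inf in predictions or targets")
        total += float(np.mean((p - z) ** 2))
    value = total / len(params.labels)
    lam = params.hyper.l2_penalty
    if lam > 0:
        value += lam * sum(
            float(np.sum(e.W**2)) for e in params.encoders.values()
        )
        value += lam * sum(float(np.sum(h.W**2)) for h in params.heads.values())
    return value


def _backward(
    z: np.ndarray, params: MTAMOParams, cache: dict
) -> dict[tuple[str, str], np.ndarray]:
    """Analytic gradients of :func:`loss` w.r.t. every parameter tensor."""
    labels = params.labels
    L = len(labels)
    B, T = z.shape
    lam = params.hyper.l2_penalty
    mv, sims, preds, X = cache["mv"], cache["sims"], cache["preds"], cache["X"]

    dV = {m: np.zeros_like(mv[m].V) for m in labels}
    grads: dict[tuple[str, str], np.ndarray] = {}

    for m in labels:
        head = params.heads[m]
        dpred = 2.0 * (preds[m] - z) / (B * T * L)
        Um = cache["U"][m]
        flat = Um.reshape(B, -1)
        grads[("head_W", m)] = flat.T @ dpred + 2.0 * lam * head.W
        grads[("head_b", m)] = dpred.sum(axis=0)
        dU = (dpred @ head.W.T).reshape(Um.shape)

        others = [n for n in labels if n != m]
        coef = 1.0 / len(others)
        Vm = mv[m].V
        for n in others:
            S = sims[(n, m)].S
            # U contribution: U += coef * S^T V_m
            dS = coef * np.einsum("skd,sld->slk", dU, Vm)
            dV[m] += coef * np.einsum("slk,skd->sld", S, dU)
            # softmax (over k) backprop to cosine logits
            dC = S * (dS - (dS * S).sum(axis=2, keepdims=True))
            # cosine C[l,k] = <V_n[l], V_m[k]>
            dV[n] += np.einsum("slk,skd->sld", dC, Vm)
            dV[m] += np.einsum("slk,sld->skd", dC, mv[n].V)

    for m in labels:
        v = mv[m]
        dot = (dV[m] * v.V).sum(axis=2, keepdims=True)
        safe = np.where(v.zero_flags, 1.0, v.norms)
        du = (dV[m] - dot * v.V) / safe[:, :, None]
        du[v.zero_flags, :] = 0.0
        grads[("enc_W", m)] = (
            np.einsum("sg,sid->gid", X[m], du) + 2.0 * lam * params.encoders[m].W
        )
    return grads


class _Adam:
    """Plain Adam on a dict of named parameter arrays (updated in place)."""

    def __init__(self, arrays: dict, lr: float, b1: float = 0.9,
                 b2: float = 0.999, eps: float = 1e-8) -> None:
        self.arrays = arrays
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.arrays[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _param_arrays(params: MTAMOParams) -> dict:
    out = {}
    for m in params.labels:
        out[("enc_W", m)] = params.encoders[m].W
        out[("head_W", m)] = params.heads[m].W
        out[("head_b", m)] = params.heads[m].b
    return out


def _mean_layer_mse(
    X: dict[str, np.ndarray], z: np.ndarray, params: MTAMOParams
) -> float:
    preds, _ = _forward_cached(X, params)
    return float(
        np.mean([np.mean((preds[m] - z) ** 2) for m in params.labels])
    )


def train(
    dataset: MultiOmicsDataset, hyper: HyperParams
) -> tuple[MTAMOParams, FitReport]:
    """Mini-batch Adam training with early stopping on a held-out split.

    The split, initialization and shuffling are all driven by
    ``hyper.seed``; two runs with the same seed produce identical traces.
    Returns the parameters of the best validation epoch.
    """
    hyper.validate()
    rng = np.random.default_rng(hyper.seed)
    n = dataset.n_samples
    perm = rng.permutation(n)
    n_val = max(1, int(round(hyper.val_fraction * n)))
    if n - n_val < 1:
        raise ValueError("too few samples for the train/validation split")
    val_idx, train_idx = perm[:n_val], perm[n_val:]

    X_full = {m: dataset.layers[m].values for m in dataset.labels}
    z_full = dataset.phenotype
    X_tr = {m: X_full[m][train_idx] for m in X_full}
    z_tr = z_full[train_idx]
    X_va = {m: X_full[m][val_idx] for m in X_full}
    z_va = z_full[val_idx]

    params = init_params(dataset, hyper)
    opt = _Adam(_param_arrays(params), lr=hyper.learning_rate)

    train_trace: list[float] = []
    val_trace: list[float] = []
    best_val = np.inf
    best_state: dict | None = None
    best_epoch = 0
    stale = 0
    n_tr = len(train_idx)

    for epoch in range(hyper.epochs):
        order = rng.permutation(n_tr)
        batch_losses = []
        for start in range(0, n_tr, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            Xb = {m: X_tr[m][idx] for m in X_tr}
            zb = z_tr[idx]
            preds, cache = _forward_cached(Xb, params)
            value = loss(preds, zb, params)
            if not np.isfinite(value):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            batch_losses.append(value)
            opt.step(_backward(zb, params, cache))
        train_trace.append(float(np.mean(batch_losses)))

        val_mse = _mean_layer_mse(X_va, z_va, params)
        if not np.isfinite(val_mse):
            raise DivergenceError(f"non-finite validation MSE at epoch {epoch}")
        val_trace.append(val_mse)

        if val_mse < best_val:
            best_val = val_mse
            best_epoch = epoch
            best_state = copy.deepcopy(_param_arrays(params))
            stale = 0
        else:
            stale += 1
            if stale > hyper.patience:
                break

    if best_state is not None:
        for k, v in _param_arrays(params).items():
            v[...] = best_state[k]

    val_ds = dataset.subset_samples([int(i) for i in val_idx])
    report = FitReport(
        train_loss=train_trace,
        val_mse=val_trace,
        best_epoch=best_epoch,
        val_metrics=evaluate(params, val_ds),
        n_epochs_run=len(train_trace),
        val_sample_ids=list(val_ds.sample_ids),
    )
    return params, report


def evaluate(
    params: MTAMOParams, dataset: MultiOmicsDataset
) -> dict[str, dict[str, float]]:
    """Per-omics MSE, RMSE (= sqrt MSE) and MAE against the phenotype."""
    preds = forward(dataset, params)
    z = dataset.phenotype
    out = {}
    for m in params.labels:
        resid = preds[m] - z
        mse = float(np.mean(resid**2))
        out[m] = {
            "MSE": mse,
            "RMSE": float(np.sqrt(mse)),
            "MAE": float(np.mean(np.abs(resid))),
        }
    return out


def grid_search_cv(
    dataset: MultiOmicsDataset,
    grid: list[HyperParams],
    k: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded k-fold CV over a hyperparameter grid.

    Each cell trains :func:`train` on the fold-train portion and records the
    held-out fold's mean-over-layers MSE.  The returned table is ranked by
    ascending mean CV MSE with ties broken by smaller N, then smaller D.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not grid:
        raise ValueError("empty hyperparameter grid")
    n = dataset.n_samples
    folds = np.array_split(np.random.default_rng(seed).permutation(n), k)
    for f in folds:
        if len(f) < 2:
            raise ValueError("every fold needs at least 2 samples")

    rows = []
    for hyper in grid:
        fold_mse, fold_rmse, fold_mae = [], [], []
        for f in folds:
            test_idx = [int(i) for i in f]
            train_idx = [i for i in range(n) if i not in set(test_idx)]
            params, _ = train(dataset.subset_samples(train_idx), hyper)
            metrics = evaluate(params, dataset.subset_samples(test_idx))
            fold_mse.append(np.mean([metrics[m]["MSE"] for m in metrics]))
            fold_rmse.append(np.mean([metrics[m]["RMSE"] for m in metrics]))
            fold_mae.append(np.mean([metrics[m]["MAE"] for m in metrics]))
        row = asdict(hyper)
        row["hyper"] = hyper
        row["cv_mse"] = float(np.mean(fold_mse))
        row["cv_rmse"] = float(np.mean(fold_rmse))
        row["cv_mae"] = float(np.mean(fold_mae))
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["cv_mse", "N", "D"], kind="stable", ignore_index=True
    )
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


def save_model(params: MTAMOParams, path: str | Path) -> None:
    """Archive weights, hyperparameters and symbol lists in one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["task_names"] = [str(t) for t in params.task_names]
        for key, val in asdict(params.hyper).items():
            f.attrs[f"hyper_{key}"] = val
        for m in params.labels:
            grp = f.create_group(m)
            grp.create_dataset("enc_W", data=params.encoders[m].W)
            grp.create_dataset("head_W", data=params.heads[m].W)
            grp.create_dataset("head_b", data=params.heads[m].b)
            grp.create_dataset(
                "gene_symbols",
                data=np.array(params.gene_symbols[m], dtype="S"),
            )


def load_model(path: str | Path) -> MTAMOParams:
    with h5py.File(path, "r") as f:
        hyper = HyperParams(
            **{
                key[len("hyper_"):]: val.item() if hasattr(val, "item") else val
                for key, val in f.attrs.items()
                if key.startswith("hyper_")
            }
        )
        encoders, heads, symbols = {}, {}, {}
        for m in f.keys():
            grp = f[m]
            encoders[m] = EncoderWeights(omics_label=m, W=grp["enc_W"][...])
            heads[m] = Head(W=grp["head_W"][...], b=grp["head_b"][...])
            symbols[m] = [s.decode() for s in grp["gene_symbols"][...]]
        task_names = [str(t) for t in f.attrs["task_names"]]
    return MTAMOParams(
        encoders=encoders,
        heads=heads,
        hyper=hyper,
        gene_symbols=symbols,
        task_names=task_names,
    )
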