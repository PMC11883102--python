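import numpy as np
import pytest

from mtamo.model import (
    HyperParams,
    evaluate,
    forward,
    grid_search_cv,
    init_params,
    load_model,
    loss,
    save_model,
    train,
    _backward,
    _forward_cached,
)
from mtamo.synthetic import SyntheticSpec, generate
from conftest import standardized


def naive_forward(X, params):
    """End-to-end composition of the three stages via explicit loops."""
    labels = params.labels
    B = next(iter(X.values())).shape[0]
    N, D = params.hyper.N, params.hyper.D
    V = {}
    for m in labels:
        W = params.encoders[m].W
        V[m] = np.zeros((B, N, D))
        for s in range(B):
            for i in range(N):
                u = np.zeros(D)
                for j in range(W.shape[0]):
                    u += X[m][s, j] * W[j, i]
                n = np.linalg.norm(u)
                V[m][s, i] = u / n if n > 0 else 0.0
    preds = {}
    for m in labels:
        others = [n for n in labels if n != m]
        U = np.zeros((B, N, D))
        for s in range(B):
            for n_lab in others:
                logits = np.exp(V[n_lab][s] @ V[m][s].T)  # [N_src, N_tgt]
                S = logits / logits.sum(axis=1, keepdims=True)
                U[s] += S.T @ V[m][s] / len(others)
        head = params.heads[m]
        preds[m] = U.reshape(B, -1) @ head.W + head.b
    return preds


def _tiny(seed=0, n=10):
    spec = SyntheticSpec(
        n_samples=n,
        genes_per_layer={"mRNA": 3, "meth": 3},
        n_signal_genes=2,
        n_signal_modules=1,
        seed=seed,
    )
    ds, _ = generate(spec)
    return standardized(ds)


def _random_heads(params, rng):
    for m in params.labels:
        params.heads[m].W[...] = rng.normal(0, 0.5, params.heads[m].W.shape)
        params.heads[m].b[...] = rng.normal(0, 0.5, params.heads[m].b.shape)


class TestForward:
    def test_zero_head_predicts_bias(self, rng):
        ds = _tiny()
        params = init_params(ds, HyperParams(N=2, D=2, seed=1))
        for m in params.labels:
            params.heads[m].b[...] = 3.25
        preds = forward(ds, params)
        for m in params.labels:
            np.testing.assert_allclose(preds[m], 3.25)

    def test_identical_samples_identical_predictions(self, rng):
        ds = _tiny()
        params = init_params(ds, HyperParams(N=2, D=2, seed=1))
        _random_heads(params, rng)
        X = {m: ds.layers[m].values[[0, 0], :] for m in ds.labels}
        preds = forward(X, params)
        for m in preds:
            np.testing.assert_array_equal(preds[m][0], preds[m][1])

    def test_matches_hand_rolled_composition(self, rng):
        """2 layers, N=2, D=2, 3 genes: forward == loop composition to 1e-10."""
        ds = _tiny(seed=4, n=6)
        params = init_params(ds, HyperParams(N=2, D=2, seed=2))
        _random_heads(params, rng)
        X = {m: ds.layers[m].values for m in ds.labels}
        got = forward(X, params)
        want = naive_forward(X, params)
        for m in got:
            np.testing.assert_allclose(got[m], want[m], atol=1e-10)

    def test_layer_mismatch_rejected(self):
        ds = _tiny()
        params = init_params(ds, HyperParams(N=2, D=2, seed=1))
        with pytest.raises(ValueError):
            forward({"mRNA": ds.layers["mRNA"].values}, params)


class TestLoss:
    def test_perfect_predictions_zero(self):
        ds = _tiny()
        params = init_params(ds, HyperParams(N=2, D=2, seed=0))
        z = ds.phenotype
        preds = {m: z.copy() for m in params.labels}
        assert loss(preds, z, params) == 0.0

    def test_constant_offset_one(self):
        ds = _tiny()
        params = init_params(ds, HyperParams(N=2, D=2, seed=0))
        z = ds.phenotype
        preds = {m: z + 1.0 for m in params.labels}
        assert loss(preds, z, params) == pytest.approx(1.0, abs=1e-12)

    def test_matches_scalar_loop(self, rng):
        ds = _tiny(n=3)
        params = init_params(ds, HyperParams(N=2, D=2, l2_penalty=0.01, seed=0))
        _random_heads(params, rng)
        z = ds.phenotype
        preds = {m: rng.normal(size=z.shape) for m in params.labels}
        total = 0.0
        for m in params.labels:
            acc = 0.0
            for s in range(z.shape[0]):
                for t in range(z.shape[1]):
                    acc += (preds[m][s, t] - z[s, t]) ** 2
            total += acc / z.size
        total /= len(params.labels)
        for m in params.labels:
            total += 0.01 * np.sum(params.encoders[m].W ** 2)
            total += 0.01 * np.sum(params.heads[m].W ** 2)
        assert loss(preds, z, params) == pytest.approx(total, abs=1e-12)

    def test_nan_rejected(self):
        ds = _tiny()
        params = init_params(ds, HyperParams(N=2, D=2, seed=0))
        z = ds.phenotype
        preds = {m: np.full_like(z, np.nan) for m in params.labels}
        with pytest.raises(ValueError):
            loss(preds, z, params)


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        """Analytic gradients of the full network vs. central differences."""
        spec = SyntheticSpec(
            n_samples=5,
            genes_per_layer={"a": 4, "b": 3, "c": 5},
            n_signal_genes=2,
            n_signal_modules=2,
            seed=9,
        )
        ds, _ = generate(spec)
        ds = standardized(ds)
        params = init_params(ds, HyperParams(N=3, D=2, l2_penalty=0.005, seed=3))
        _random_heads(params, rng)
        X = {m: ds.layers[m].values for m in ds.labels}
        z = ds.phenotype
        _, cache = _forward_cached(X, params)
        grads = _backward(z, params, cache)

        eps = 1e-6
        for m in params.labels:
            for key, arr in (
                ("enc_W", params.encoders[m].W),
                ("head_W", params.heads[m].W),
                ("head_b", params.heads[m].b),
            ):
                flat = arr.ravel()
                idx = rng.choice(flat.size, size=min(10, flat.size), replace=False)
                for i in idx:
                    orig = flat[i]
                    flat[i] = orig + eps
                    p, _ = _forward_cached(X, params)
                    lp = loss(p, z, params)
                    flat[i] = orig - eps
                    p, _ = _forward_cached(X, params)
                    lm = loss(p, z, params)
                    flat[i] = orig
                    num = (lp - lm) / (2 * eps)
                    assert grads[(key, m)].ravel()[i] == pytest.approx(
                        num, rel=1e-5, abs=1e-8
                    )


class TestTrain:
    def test_strong_signal_beats_mean_predictor(self):
        spec = SyntheticSpec(
            n_samples=200,
            genes_per_layer={"mRNA": 100, "meth": 100, "SNV": 100},
            n_signal_genes=20,
            n_signal_modules=2,
            effect_size=1.0,
            noise_sd=0.5,
            seed=21,
        )
        ds, _ = generate(spec)
        ds = standardized(ds)
        params, report = train(ds, HyperParams(N=4, D=4, epochs=80, seed=22))
        assert min(report.val_mse) < ds.phenotype.var()

    def test_null_signal_val_mse_near_variance(self):
        spec = SyntheticSpec(
            n_samples=200,
            genes_per_layer={"mRNA": 80, "meth": 80},
            n_signal_genes=10,
            n_signal_modules=2,
            effect_size=0.0,
            noise_sd=0.5,
            seed=31,
        )
        ds, _ = generate(spec)
        ds = standardized(ds)
        params, report = train(ds, HyperParams(N=4, D=4, epochs=60, seed=32))
        ids = set(report.val_sample_ids)
        mask = np.array([s in ids for s in ds.sample_ids])
        var_val = ds.phenotype[mask].var()
        assert min(report.val_mse) == pytest.approx(var_val, rel=0.10)

    def test_same_seed_identical_traces(self):
        ds = standardized(
            generate(
                SyntheticSpec(
                    n_samples=40,
                    genes_per_layer={"mRNA": 20, "meth": 20},
                    n_signal_genes=5,
                    n_signal_modules=1,
                    seed=8,
                )
            )[0]
        )
        hyper = HyperParams(N=3, D=3, epochs=10, seed=5)
        _, r1 = train(ds, hyper)
        _, r2 = train(ds, HyperParams(N=3, D=3, epochs=10, seed=5))
        assert r1.train_loss == r2.train_loss
        assert r1.val_mse == r2.val_mse

    def test_training_trace_finite(self, small_trained):
        _, report, _, _ = small_trained
        assert np.all(np.isfinite(report.train_loss))
        assert np.all(np.isfinite(report.val_mse))


class TestEvaluate:
    def test_perfect_and_symmetric_residuals(self):
        ds = _tiny()
        params = init_params(ds, HyperParams(N=2, D=2, seed=0))
        # zero-head predictions are identically 0; craft a target to match
        ds.phenotype[...] = 0.0
        metrics = evaluate(params, ds)
        for m in metrics:
            assert metrics[m] == {"MSE": 0.0, "RMSE": 0.0, "MAE": 0.0}
        # residuals (+1, -1): MSE = RMSE = MAE = 1
        ds.phenotype[...] = 0.0
        ds.phenotype[0::2] = 1.0
        ds.phenotype[1::2] = -1.0
        metrics = evaluate(params, ds)
        for m in metrics:
            assert metrics[m]["MSE"] == pytest.approx(1.0)
            assert metrics[m]["RMSE"] == pytest.approx(1.0)
            assert metrics[m]["MAE"] == pytest.approx(1.0)

    def test_matches_scalar_loop_and_rmse_consistency(self, small_trained):
        params, _, ds, _ = small_trained
        metrics = evaluate(params, ds)
        preds = forward(ds, params)
        for m in metrics:
            resid = preds[m] - ds.phenotype
            acc_sq, acc_abs, count = 0.0, 0.0, 0
            for s in range(resid.shape[0]):
                for t in range(resid.shape[1]):
                    acc_sq += resid[s, t] ** 2
                    acc_abs += abs(resid[s, t])
                    count += 1
            assert metrics[m]["MSE"] == pytest.approx(acc_sq / count, abs=1e-12)
            assert metrics[m]["MAE"] == pytest.approx(acc_abs / count, abs=1e-12)
            assert metrics[m]["RMSE"] == pytest.approx(
                np.sqrt(metrics[m]["MSE"]), abs=1e-9
            )


class TestGridSearch:
    def _data(self):
        spec = SyntheticSpec(
            n_samples=60,
            genes_per_layer={"mRNA": 30, "meth": 30},
            n_signal_genes=8,
            n_signal_modules=1,
            effect_size=1.0,
            noise_sd=0.3,
            seed=13,
        )
        return standardized(generate(spec)[0])

    def test_singleton_grid(self):
        ds = self._data()
        hyper = HyperParams(N=2, D=2, epochs=5, seed=1)
        table = grid_search_cv(ds, [hyper], k=2, seed=3)
        assert len(table) == 1
        assert np.isfinite(table.loc[0, "cv_mse"])

    def test_duplicate_config_identical_metrics(self):
        ds = self._data()
        g = [HyperParams(N=2, D=2, epochs=4, seed=1)] * 2
        table = grid_search_cv(ds, g, k=2, seed=3)
        assert table.loc[0, "cv_mse"] == table.loc[1, "cv_mse"]

    def test_zero_learning_rate_ranks_last(self):
        ds = self._data()
        trainable = HyperParams(N=3, D=3, epochs=40, seed=1)
        frozen = HyperParams(N=3, D=3, epochs=40, learning_rate=0.0, seed=1)
        table = grid_search_cv(ds, [trainable, frozen], k=2, seed=3)
        assert table.loc[0, "learning_rate"] > 0.0

    def test_invalid_inputs(self):
        ds = self._data()
        with pytest.raises(ValueError):
            grid_search_cv(ds, [], k=2)
        with pytest.raises(ValueError):
            grid_search_cv(ds, [HyperParams()], k=1)


def test_model_archive_round_trip(tmp_path, small_trained):
    params, _, ds, _ = small_trained
    path = tmp_path / "model.h5"
    save_model(params, path)
    back = load_model(path)
    assert back.labels == params.labels
    assert back.hyper == params.hyper
    assert back.task_names == params.task_names
    for m in params.labels:
        np.testing.assert_array_equal(back.encoders[m].W, params.encoders[m].W)
        np.testing.assert_array_equal(back.heads[m].W, params.heads[m].W)
        assert back.gene_symbols[m] == params.gene_symbols[m]
    p1 = forward(ds, params)
    p2 = forward(ds, back)
    for m in p1:
        np.testing.assert_array_equal(p1[m], p2[m])
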