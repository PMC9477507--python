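"""1D-CNN denoiser: architecture, training mechanics, persistence."""

import numpy as np
import pytest

from dwicnn import (
    DenoiserConfig,
    DWIDataset,
    DWIProtocol,
    build_model,
    denoise,
    grid_search,
    load_model,
    save_model,
    to_voxel_matrix,
    train,
)
from dwicnn.cnn import _forward, _backward
from dwicnn.io import VoxelMatrix


def _toy_matrix(rng, V=200, T=32, scale=100.0):
    values = scale * np.abs(rng.normal(size=(V, T))) + 0.1 * scale
    index = np.array([(i, 0, 0) for i in range(V)])
    return VoxelMatrix(values=values, index=index)


class TestArchitecture:
    @pytest.mark.parametrize(
        "T,flat", [(184, 32 * 46), (80, 32 * 20), (26, 32 * 6)]
    )
    def test_dense_layer_sizes(self, T, flat):
        m = build_model(T, seed=0)
        assert m.weights["Wd"].shape == (flat, T)
        assert m.weights["W1"].shape == (16, 16)
        assert m.weights["W2"].shape == (8 * 16, 32)

    def test_short_time_course_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            build_model(15)

    def test_zero_network_maps_to_zero(self, rng):
        m = build_model(32, seed=0)
        for k in m.weights:
            m.weights[k][:] = 0.0
        X = rng.normal(size=(7, 32)).astype(np.float32)
        np.testing.assert_array_equal(_forward(m.weights, X), 0.0)

    def test_init_deterministic(self):
        a, b = build_model(40, seed=3), build_model(40, seed=3)
        for k in a.weights:
            np.testing.assert_array_equal(a.weights[k], b.weights[k])

    def test_gradients_match_finite_differences(self, rng):
        """Analytic backward pass against central finite differences."""
        T = 22  # odd pooled lengths exercise the truncated tail
        m = build_model(T, seed=1)
        w = {k: v.astype(np.float64) for k, v in m.weights.items()}
        X = rng.normal(size=(4, T))
        R = rng.normal(size=(4, T))
        Y, cache = _forward(w, X, want_cache=True)
        grads = _backward(w, cache, 2 * (Y - R) / Y.size)

        def loss():
            return np.mean((_forward(w, X) - R) ** 2)

        for k in w:
            flat = w[k].ravel()
            for i in rng.choice(flat.size, size=min(4, flat.size),
                                replace=False):
                eps, orig = 1e-6, flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - grads[k].ravel()[i]) < 1e-5 * max(1, abs(num))


class TestTraining:
    def test_identity_task_converges(self, rng):
        """Mapping clean data to itself: the network should become a near
        identity on the data manifold within a few hundred epochs.

        Rows are realistic mono-exponential decay curves (random amplitude
        and diffusivity), the manifold the denoiser operates on.
        """
        T, V = 32, 1000
        bvals = np.linspace(0.0, 2000.0, T)
        amp = rng.uniform(500.0, 1500.0, size=V)
        adc = rng.uniform(0.3e-3, 3.0e-3, size=V)
        values = amp[:, None] * np.exp(-bvals[None, :] * adc[:, None])
        vm = VoxelMatrix(values=values,
                         index=np.array([(i, 0, 0) for i in range(V)]))
        cfg = DenoiserConfig(epochs=200, learning_rate=0.05, batch_size=125,
                             seed=0)
        model = train(vm, vm, cfg)
        ns = model.norm_scale
        X = (vm.values / ns).astype(np.float32)
        out = _forward(model.weights, X)
        rmse = np.sqrt(np.mean((out - X) ** 2))
        input_rms = np.sqrt(np.mean(X**2))
        assert rmse < 0.10 * input_rms
        assert model.loss_history[-1] < model.loss_history[0]

    def test_adam_converges_and_is_reproducible(self, rng):
        vm = _toy_matrix(rng, V=200, T=32)
        cfg = DenoiserConfig(epochs=30, learning_rate=0.001, batch_size=100,
                             optimizer="adam", seed=3)
        m1 = train(vm, vm, cfg)
        m2 = train(vm, vm, cfg)
        assert m1.loss_history[-1] < m1.loss_history[0]
        np.testing.assert_array_equal(m1.loss_history, m2.loss_history)

    def test_unknown_optimizer_rejected(self):
        with pytest.raises(ValueError, match="optimizer"):
            DenoiserConfig(optimizer="lbfgs")

    def test_zero_learning_rate_is_a_no_op(self, rng):
        vm = _toy_matrix(rng, V=50, T=32)
        cfg = DenoiserConfig(epochs=5, learning_rate=0.0, batch_size=50,
                             seed=2)
        model = train(vm, vm, cfg)
        init = build_model(32, seed=2)
        for k in model.weights:
            np.testing.assert_array_equal(model.weights[k], init.weights[k])
        assert np.ptp(model.loss_history) == 0.0

    def test_divergence_reports_learning_rate(self, rng):
        vm = _toy_matrix(rng, V=100, T=32)
        cfg = DenoiserConfig(epochs=200, learning_rate=1e4, batch_size=100,
                             seed=0)
        with pytest.raises(FloatingPointError, match="learning rate"):
            train(vm, vm, cfg)

    def test_shape_mismatch_rejected(self, rng):
        a, b = _toy_matrix(rng, V=20, T=32), _toy_matrix(rng, V=21, T=32)
        with pytest.raises(ValueError, match="shapes differ"):
            train(a, b, DenoiserConfig(epochs=1))

    def test_seeded_training_reproducible(self, rng):
        vm = _toy_matrix(rng, V=100, T=32)
        cfg = DenoiserConfig(epochs=10, learning_rate=0.01, batch_size=25,
                             seed=7)
        m1 = train(vm, vm, cfg)
        m2 = train(vm, vm, cfg)
        np.testing.assert_array_equal(m1.loss_history, m2.loss_history)
        for k in m1.weights:
            np.testing.assert_array_equal(m1.weights[k], m2.weights[k])


def _dataset_from_matrix(vm, protocol):
    nx = vm.V
    data = np.zeros((nx, 1, 1, vm.T))
    data[:, 0, 0, :] = vm.values
    mask = np.ones((nx, 1, 1), bool)
    return DWIDataset(data=data, protocol=protocol, mask=mask)


@pytest.fixture()
def toy_protocol():
    rng = np.random.default_rng(0)
    dirs = rng.normal(size=(30, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return DWIProtocol(
        bvals=np.r_[0.0, 0.0, np.full(30, 1000.0)],
        bvecs=np.vstack([np.zeros((2, 3)), dirs]),
    )


class TestDenoise:
    def test_deterministic_application(self, rng, toy_protocol):
        vm = _toy_matrix(rng, V=50, T=toy_protocol.T)
        ds = _dataset_from_matrix(vm, toy_protocol)
        cfg = DenoiserConfig(epochs=5, learning_rate=0.01, batch_size=50,
                             seed=0)
        model = train(vm, vm, cfg, protocol=toy_protocol)
        out1 = denoise(model, ds)
        out2 = denoise(model, ds)
        np.testing.assert_array_equal(out1.data, out2.data)
        assert (out1.data >= 0).all()

    def test_scale_covariance(self, rng, toy_protocol):
        """Scaling the training pair and the input by the same constant
        scales the output by that constant (normalization correctness)."""
        vm = _toy_matrix(rng, V=80, T=toy_protocol.T)
        cfg = DenoiserConfig(epochs=20, learning_rate=0.01, batch_size=40,
                             seed=1)
        ds = _dataset_from_matrix(vm, toy_protocol)
        m1 = train(vm, vm, cfg, protocol=toy_protocol)
        out1 = denoise(m1, ds)
        c = 37.5
        vm_s = VoxelMatrix(values=vm.values * c, index=vm.index)
        ds_s = _dataset_from_matrix(vm_s, toy_protocol)
        m2 = train(vm_s, vm_s, cfg, protocol=toy_protocol)
        out2 = denoise(m2, ds_s)
        np.testing.assert_allclose(out2.data, out1.data * c, rtol=1e-4,
                                   atol=1e-4)

    def test_t_mismatch_rejected(self, rng, toy_protocol):
        model = build_model(64, seed=0)
        ds = _dataset_from_matrix(_toy_matrix(rng, V=10, T=toy_protocol.T),
                                  toy_protocol)
        with pytest.raises(ValueError, match="expects"):
            denoise(model, ds)

    def test_protocol_signature_mismatch_warns(self, rng, toy_protocol):
        vm = _toy_matrix(rng, V=30, T=toy_protocol.T)
        cfg = DenoiserConfig(epochs=2, learning_rate=0.01, batch_size=30,
                             seed=0)
        model = train(vm, vm, cfg, protocol=toy_protocol)
        bvecs = toy_protocol.bvecs.copy()
        bvecs[2:] = np.roll(bvecs[2:], 1, axis=0)  # reorder the dw volumes
        other = DWIProtocol(bvals=toy_protocol.bvals, bvecs=bvecs)
        ds = _dataset_from_matrix(vm, other)
        with pytest.warns(UserWarning, match="signature"):
            denoise(model, ds)


class TestGridSearch:
    def test_single_cell_matches_manual_split(self, rng):
        vm = _toy_matrix(rng, V=120, T=32)
        tbl = grid_search(vm, vm, [0.01], [30], epochs=5, seed=3)
        assert len(tbl) == 1
        assert np.isfinite(tbl.rmse.iloc[0])

    def test_grid_shape(self, rng):
        vm = _toy_matrix(rng, V=60, T=32)
        tbl = grid_search(vm, vm, [0.001, 0.01], [20, 40], epochs=2, seed=0)
        assert len(tbl) == 4
        assert set(tbl.columns) == {"learning_rate", "batch_size", "rmse"}

    def test_absurd_learning_rate_is_worst(self, rng):
        vm = _toy_matrix(rng, V=200, T=32)
        tbl = grid_search(vm, vm, [1e-4, 1e-2, 1e4], [50], epochs=30, seed=0)
        worst = tbl.sort_values("rmse").iloc[-1]
        assert worst.learning_rate == 1e4

    def test_empty_grid_rejected(self, rng):
        vm = _toy_matrix(rng, V=20, T=32)
        with pytest.raises(ValueError, match="nonempty"):
            grid_search(vm, vm, [], [10], epochs=1)


class TestPersistence:
    def test_round_trip_bitwise(self, rng, tmp_path):
        vm = _toy_matrix(rng, V=40, T=32)
        cfg = DenoiserConfig(epochs=3, learning_rate=0.01, batch_size=40,
                             seed=5)
        model = train(vm, vm, cfg)
        path = tmp_path / "model.dwicnn.zip"
        save_model(model, path)
        back = load_model(path)
        X = rng.normal(size=(9, 32)).astype(np.float32)
        np.testing.assert_array_equal(
            _forward(model.weights, X), _forward(back.weights, X)
        )
        assert back.norm_scale == model.norm_scale
        assert back.config == cfg

    def test_missing_weights_rejected(self, tmp_path):
        import json
        import zipfile

        path = tmp_path / "broken.zip"
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps({"T": 32, "norm_scale": 1.0}))
            import io as _io

            buf = _io.BytesIO()
            np.savez(buf, weight_W1=np.zeros((16, 16)))
            zf.writestr("arrays.npz", buf.getvalue())
        with pytest.raises(ValueError, match="missing weights"):
            load_model(path)
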