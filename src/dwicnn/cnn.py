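"""Temporal-domain 1D-CNN denoiser for DWI voxel time courses.

The network maps one noisy voxel time course (length T) to its low-noise
reference.  Architecture (five weight/pool stages):

    input (T x 1)
    -> conv1d: 16 kernels of length 16, same padding, ReLU
    -> max pool, kernel 2, stride 2
    -> conv1d: 32 kernels of length 8, same padding, ReLU
    -> max pool, kernel 2, stride 2
    -> flatten (32 * floor(T/4))
    -> dense -> T outputs (linear)

Training minimizes the mean-squared error between network output and the
reference time courses with plain stochastic gradient descent (optional
momentum available but off by default), voxels shuffled each epoch.  Because
every masked voxel is a training sample, a single paired dataset suffices to
fit the model, and the trained model transfers to other datasets acquired
with the same protocol.

Intensities are normalized by a single global scale (99th percentile of the
reference b0 intensities at training; recomputed from the input dataset by
the same rule at inference) so arbitrary scanner units do not change network
behavior.

Everything is implemented in NumPy (float32) with explicit backward passes;
training and inference are deterministic given the seeds.
"""

from __future__ import annotations

import io as _io
import json
import logging
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numba
import numpy as np
import pandas as pd

from .io import DWIDataset, DWIProtocol, VoxelMatrix, from_voxel_matrix, to_voxel_matrix

log = logging.getLogger("dwicnn")

__all__ = [
    "DenoiserConfig",
    "TrainedDenoiser",
    "build_model",
    "train",
    "denoise",
    "grid_search",
    "save_model",
    "load_model",
]

K1, C1 = 16, 16  # first conv: kernel length, filters
K2, C2 = 8, 32   # second conv: kernel length, filters
NORM_PERCENTILE = 99.0


@dataclass
class DenoiserConfig:
    """Training hyper-parameters.

    The reference values for a full-scale run are 20000 epochs, learning
    rate 0.001, batch size 6000; the learning rate and batch size interact
    and should be re-tuned per protocol (see :func:`grid_search`).  The
    default epoch count here is a desk-scale setting — the training error
    typically stabilizes well before the full-scale epoch count.
    """

    epochs: int = 2000
    learning_rate: float = 0.001
    batch_size: int = 6000
    seed: int = 0
    loss: str = "mse"
    optimizer: str = "sgd"  # "sgd" (optional momentum) or "adam"
    momentum: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss != "mse":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class TrainedDenoiser:
    """Weights + normalization + protocol signature of a (possibly
    untrained) denoiser."""

    weights: dict[str, np.ndarray]
    T: int
    norm_scale: float = 1.0
    protocol_signature: str | None = None
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    config: DenoiserConfig | None = None

    @property
    def flat_features(self) -> int:
        return C2 * (self.T // 4)


def _feature_len(T: int) -> int:
    return C2 * (T // 4)


def build_model(T: int, seed: int = 0) -> TrainedDenoiser:
    """Initialize the network for time courses of length ``T``.

    He-normal initialization for the ReLU conv layers, Glorot for the linear
    dense layer; deterministic for a fixed seed.
    """
    if T < K1:
        raise ValueError(
            f"time-course length T={T} is shorter than the first kernel "
            f"length {K1}"
        )
    rng = np.random.default_rng(seed)
    F = _feature_len(T)
    weights = {
        "W1": rng.normal(0.0, np.sqrt(2.0 / K1), size=(K1, C1)),
        "b1": np.zeros(C1),
        "W2": rng.normal(0.0, np.sqrt(2.0 / (K2 * C1)), size=(K2 * C1, C2)),
        "b2": np.zeros(C2),
        "Wd": rng.normal(0.0, np.sqrt(2.0 / (F + T)), size=(F, T)),
        "bd": np.zeros(T),
    }
    weights = {k: v.astype(np.float32) for k, v in weights.items()}
    return TrainedDenoiser(weights=weights, T=T)


# ---------------------------------------------------------------------------
# forward / backward


@numba.njit(cache=False)
def _im2col_kernel(xp, L, k, out):  # pragma: no cover - exercised via _forward
    B, _, C = xp.shape
    for b in range(B):
        for t in range(L):
            for j in range(k):
                for c in range(C):
                    out[b, t, j * C + c] = xp[b, t + j, c]


@numba.njit(cache=False)
def _col2im_add_kernel(dwin, L, k, out):  # pragma: no cover
    B, _, C = out.shape
    for b in range(B):
        for t in range(L):
            for j in range(k):
                for c in range(C):
                    out[b, t + j, c] += dwin[b, t, j * C + c]


@numba.njit(cache=False)
def _pool_kernel(A, P, take0):  # pragma: no cover
    """Max pool (kernel 2, stride 2) along axis 1; records the winner
    (ties go to the earlier sample)."""
    B, L2, C = P.shape
    for b in range(B):
        for t in range(L2):
            for c in range(C):
                a0 = A[b, 2 * t, c]
                a1 = A[b, 2 * t + 1, c]
                if a0 >= a1:
                    P[b, t, c] = a0
                    take0[b, t, c] = 1
                else:
                    P[b, t, c] = a1
                    take0[b, t, c] = 0


@numba.njit(cache=False)
def _unpool_mask_kernel(dP, take0, Z, out):  # pragma: no cover
    """Adjoint of pool+ReLU: route gradients to the winning position and
    zero them where the pre-activation was nonpositive."""
    B, L, C = out.shape
    L2 = dP.shape[1]
    for b in range(B):
        for t in range(L2):
            for c in range(C):
                if take0[b, t, c]:
                    g0, g1 = dP[b, t, c], 0.0
                else:
                    g0, g1 = 0.0, dP[b, t, c]
                out[b, 2 * t, c] = g0 if Z[b, 2 * t, c] > 0 else 0.0
                out[b, 2 * t + 1, c] = g1 if Z[b, 2 * t + 1, c] > 0 else 0.0
        for t in range(2 * L2, L):  # odd tail never pooled
            for c in range(C):
                out[b, t, c] = 0.0


def _ws_get(ws: dict | None, name: str, shape, dtype):
    """Reusable workspace buffer (fresh allocation when ws is None)."""
    if ws is None:
        return np.empty(shape, dtype=dtype)
    buf = ws.get(name)
    if buf is None or buf.shape != tuple(shape) or buf.dtype != dtype:
        buf = np.empty(shape, dtype=dtype)
        ws[name] = buf
    return buf


def _conv_windows(x: np.ndarray, k: int, ws: dict | None = None,
                  tag: str = "") -> np.ndarray:
    """im2col with 'same' padding.

    (B, L) -> contiguous (B, L, k); (B, L, C) -> contiguous (B, L, k*C)
    with taps as the slower axis (tap-major), matching the weight layouts.
    """
    pad_l = (k - 1) // 2
    if x.ndim == 2:
        x = x[:, :, None]
    B, L, C = x.shape
    xp = _ws_get(ws, f"xp{tag}", (B, L + k - 1, C), x.dtype)
    xp[:, :pad_l] = 0
    xp[:, pad_l : pad_l + L] = x
    xp[:, pad_l + L :] = 0
    win = _ws_get(ws, f"win{tag}", (B, L, k * C), x.dtype)
    _im2col_kernel(xp, L, k, win)
    return win


def _forward(weights: dict[str, np.ndarray], X: np.ndarray,
             want_cache: bool = False, ws: dict | None = None):
    """Forward pass on a batch of normalized time courses X (B, T).

    Each convolution is im2col + one large GEMM; ``ws`` is an optional
    buffer workspace reused across batches to avoid reallocation.
    """
    B, T = X.shape
    T2, T4 = T // 2, T // 4
    dt = X.dtype
    win1 = _conv_windows(X, K1, ws, "1")             # (B, T, K1)
    Z1 = _ws_get(ws, "Z1", (B * T, C1), dt)
    np.dot(win1.reshape(B * T, K1), weights["W1"], out=Z1)
    Z1 += weights["b1"]
    A1 = np.maximum(Z1, 0.0, out=_ws_get(ws, "A1", Z1.shape, dt))
    P1 = _ws_get(ws, "P1", (B, T2, C1), dt)
    take1 = _ws_get(ws, "take1", (B, T2, C1), np.uint8)
    _pool_kernel(A1.reshape(B, T, C1), P1, take1)
    win2 = _conv_windows(P1, K2, ws, "2")            # (B, T2, K2*C1)
    Z2 = _ws_get(ws, "Z2", (B * T2, C2), dt)
    np.dot(win2.reshape(B * T2, K2 * C1), weights["W2"], out=Z2)
    Z2 += weights["b2"]
    A2 = np.maximum(Z2, 0.0, out=_ws_get(ws, "A2", Z2.shape, dt))
    P2 = _ws_get(ws, "P2", (B, T4, C2), dt)
    take2 = _ws_get(ws, "take2", (B, T4, C2), np.uint8)
    _pool_kernel(A2.reshape(B, T2, C2), P2, take2)
    flat = P2.reshape(B, T4 * C2)
    Y = _ws_get(ws, "Y", (B, T), dt)
    np.dot(flat, weights["Wd"], out=Y)
    Y += weights["bd"]
    if not want_cache:
        return Y
    cache = dict(X=X, win1=win1, Z1=Z1, take1=take1, win2=win2, Z2=Z2,
                 take2=take2, flat=flat, T2=T2, T4=T4)
    return Y, cache


def _backward(weights, cache, dY, ws: dict | None = None):
    """Gradients of the batch loss w.r.t. all weights, given dL/dY."""
    B, T = cache["X"].shape
    T2, T4 = cache["T2"], cache["T4"]
    dt = dY.dtype
    grads = {}
    grads["Wd"] = cache["flat"].T @ dY
    grads["bd"] = dY.sum(axis=0)
    dP2 = _ws_get(ws, "dP2", (B, T4 * C2), dt)
    np.dot(dY, weights["Wd"].T, out=dP2)
    dZ2 = _ws_get(ws, "dZ2", (B, T2, C2), dt)
    _unpool_mask_kernel(dP2.reshape(B, T4, C2), cache["take2"],
                        cache["Z2"].reshape(B, T2, C2), dZ2)
    dZ2 = dZ2.reshape(B * T2, C2)
    grads["W2"] = cache["win2"].reshape(B * T2, K2 * C1).T @ dZ2
    grads["b2"] = dZ2.sum(axis=0)
    # conv2 input gradient: scatter-add each tap of the window
    dwin2 = _ws_get(ws, "dwin2", (B * T2, K2 * C1), dt)
    np.dot(dZ2, weights["W2"].T, out=dwin2)
    pad_l = (K2 - 1) // 2
    dP1p = _ws_get(ws, "dP1p", (B, T2 + K2 - 1, C1), dt)
    dP1p[:] = 0
    _col2im_add_kernel(dwin2.reshape(B, T2, K2 * C1), T2, K2, dP1p)
    dP1 = np.ascontiguousarray(dP1p[:, pad_l : pad_l + T2])
    dZ1 = _ws_get(ws, "dZ1", (B, T, C1), dt)
    _unpool_mask_kernel(dP1, cache["take1"],
                        cache["Z1"].reshape(B, T, C1), dZ1)
    dZ1 = dZ1.reshape(B * T, C1)
    grads["W1"] = cache["win1"].reshape(B * T, K1).T @ dZ1
    grads["b1"] = dZ1.sum(axis=0)
    return grads


def _predict(weights: dict[str, np.ndarray], X: np.ndarray,
             batch: int = 16384) -> np.ndarray:
    out = np.empty_like(X, dtype=np.float32)
    for i in range(0, X.shape[0], batch):
        out[i : i + batch] = _forward(weights, X[i : i + batch])
    return out


def _norm_scale_from(values: np.ndarray, b0_columns: np.ndarray | None) -> float:
    cols = values if b0_columns is None else values[:, b0_columns]
    scale = float(np.percentile(cols, NORM_PERCENTILE))
    if scale <= 0:
        raise ValueError("normalization scale is nonpositive; check intensities")
    return scale


# ---------------------------------------------------------------------------
# training


def train(
    noisy: VoxelMatrix,
    reference: VoxelMatrix,
    cfg: DenoiserConfig,
    protocol: DWIProtocol | None = None,
) -> TrainedDenoiser:
    """Fit the denoiser on paired noisy/reference voxel time courses.

    Rows of ``noisy`` and ``reference`` must correspond voxel-for-voxel.
    Both are divided by a single scale — the 99th percentile of the
    reference b0 intensities (all volumes if no protocol is given) — before
    fitting.  Per-epoch mean training loss is recorded in ``loss_history``.
    """
    if noisy.values.shape != reference.values.shape:
        raise ValueError(
            f"noisy {noisy.values.shape} and reference "
            f"{reference.values.shape} shapes differ"
        )
    V, T = noisy.values.shape
    model = build_model(T, seed=cfg.seed)
    b0_cols = None
    if protocol is not None:
        if protocol.T != T:
            raise ValueError(f"protocol T={protocol.T} != data T={T}")
        b0_cols = np.flatnonzero(protocol.b0_mask)
        model.protocol_signature = protocol.signature()
    ns = _norm_scale_from(reference.values, b0_cols)
    model.norm_scale = ns
    X = (noisy.values / ns).astype(np.float32)
    R = (reference.values / ns).astype(np.float32)

    weights = model.weights
    velocity = {k: np.zeros_like(v) for k, v in weights.items()}
    adam_v = {k: np.zeros_like(v) for k, v in weights.items()}
    rng = np.random.default_rng(cfg.seed)
    lr = np.float32(cfg.learning_rate)
    mom = np.float32(cfg.momentum)
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    step = 0
    history = np.empty(cfg.epochs, dtype=np.float64)
    ws: dict = {}
    for epoch in range(cfg.epochs):
        perm = rng.permutation(V)
        total, count = 0.0, 0
        for start in range(0, V, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            Xb, Rb = X[idx], R[idx]
            Y, cache = _forward(weights, Xb, want_cache=True, ws=ws)
            err = Y - Rb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}; "
                    f"reduce the learning rate (currently {cfg.learning_rate})"
                )
            dY = (2.0 / err.size) * err
            grads = _backward(weights, cache, dY, ws=ws)
            if cfg.optimizer == "adam":
                step += 1
                corr1 = 1.0 - b1**step
                corr2 = 1.0 - b2**step
                for k in weights:
                    velocity[k] = b1 * velocity[k] + (1 - b1) * grads[k]
                    adam_v[k] = b2 * adam_v[k] + (1 - b2) * grads[k] ** 2
                    weights[k] -= lr * (velocity[k] / corr1) / (
                        np.sqrt(adam_v[k] / corr2) + eps_adam
                    )
            else:
                for k in weights:
                    if mom > 0:
                        velocity[k] = mom * velocity[k] - lr * grads[k]
                        weights[k] += velocity[k]
                    else:
                        weights[k] -= lr * grads[k]
            total += loss * len(idx)
            count += len(idx)
        history[epoch] = total / count
        if (epoch + 1) % 100 == 0 or epoch == 0:
            log.debug("epoch %d/%d: training loss %.4e",
                      epoch + 1, cfg.epochs, history[epoch])
    model.loss_history = history
    model.config = cfg
    return model


def denoise(model: TrainedDenoiser, ds: DWIDataset) -> DWIDataset:
    """Apply a trained denoiser to every masked voxel time course.

    The normalization scale is recomputed from the input dataset with the
    same percentile rule used at training, so the model is covariant to a
    global intensity rescaling (arbitrary scanner units).  Negative network
    outputs are clipped to zero (magnitude data); unmasked voxels pass
    through unchanged.
    """
    if ds.protocol.T != model.T:
        raise ValueError(
            f"dataset has T={ds.protocol.T} volumes but the model expects "
            f"T={model.T}"
        )
    if (
        model.protocol_signature is not None
        and ds.protocol.signature() != model.protocol_signature
    ):
        import warnings

        warnings.warn(
            "gradient-table signature differs from the one the model was "
            "trained with; proceeding (tables may be reordered copies)",
            stacklevel=2,
        )
    vm = to_voxel_matrix(ds)
    b0_cols = np.flatnonzero(ds.protocol.b0_mask)
    ns = _norm_scale_from(vm.values, b0_cols if b0_cols.size else None)
    X = (vm.values / ns).astype(np.float32)
    Y = np.maximum(_predict(model.weights, X), 0.0) * ns
    out = from_voxel_matrix(VoxelMatrix(values=Y, index=vm.index), ds)
    out.meta.update(denoised="1dcnn", denoise_norm_scale=ns)
    return out


def grid_search(
    noisy: VoxelMatrix,
    reference: VoxelMatrix,
    learning_rates,
    batch_sizes,
    split_fraction: float = 0.75,
    epochs: int = 200,
    seed: int = 0,
    protocol: DWIProtocol | None = None,
) -> pd.DataFrame:
    """Hyper-parameter search over (learning rate, batch size) pairs.

    Trains on a seeded random ``split_fraction`` of the voxels and reports
    the RMSE between the denoised held-out voxels and their reference time
    courses (original intensity units).  Divergent runs report infinite
    RMSE.
    """
    learning_rates = list(learning_rates)
    batch_sizes = list(batch_sizes)
    if not learning_rates or not batch_sizes:
        raise ValueError("learning-rate and batch-size grids must be nonempty")
    V = noisy.V
    rng = np.random.default_rng(seed)
    perm = rng.permutation(V)
    n_train = int(round(split_fraction * V))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    if test_idx.size == 0 or train_idx.size == 0:
        raise ValueError(
            f"split_fraction={split_fraction} leaves an empty train or test set"
        )
    sub = lambda vm, idx: VoxelMatrix(values=vm.values[idx], index=vm.index[idx])
    noisy_tr, ref_tr = sub(noisy, train_idx), sub(reference, train_idx)
    noisy_te, ref_te = sub(noisy, test_idx), sub(reference, test_idx)
    rows = []
    for lr in learning_rates:
        for bs in batch_sizes:
            cfg = DenoiserConfig(
                epochs=epochs, learning_rate=lr, batch_size=bs, seed=seed
            )
            try:
                model = train(noisy_tr, ref_tr, cfg, protocol=protocol)
                ns = model.norm_scale
                pred = np.maximum(
                    _predict(model.weights, (noisy_te.values / ns).astype(np.float32)),
                    0.0,
                ) * ns
                err = float(np.sqrt(np.mean((pred - ref_te.values) ** 2)))
            except FloatingPointError:
                err = np.inf
            rows.append(
                {"learning_rate": lr, "batch_size": bs, "rmse": err}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence


FORMAT_VERSION = 1


def save_model(model: TrainedDenoiser, path: str | Path) -> Path:
    """Serialize a denoiser to a self-describing ``.npz``-style archive."""
    path = Path(path)
    meta = {
        "format_version": FORMAT_VERSION,
        "T": model.T,
        "norm_scale": model.norm_scale,
        "protocol_signature": model.protocol_signature,
        "config": asdict(model.config) if model.config else None,
    }
    arrays = {f"weight_{k}": v for k, v in model.weights.items()}
    arrays["loss_history"] = np.asarray(model.loss_history)
    buf = _io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        zf.writestr("arrays.npz", buf.getvalue())
    return path


def load_model(path: str | Path) -> TrainedDenoiser:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with zf.open("arrays.npz") as f:
            arrays = dict(np.load(_io.BytesIO(f.read())))
    weights = {
        k[len("weight_"):]: v for k, v in arrays.items()
        if k.startswith("weight_")
    }
    expected = {"W1", "b1", "W2", "b2", "Wd", "bd"}
    if set(weights) != expected:
        raise ValueError(
            f"model archive is missing weights: {sorted(expected - set(weights))}"
        )
    cfg = DenoiserConfig(**meta["config"]) if meta.get("config") else None
    return TrainedDenoiser(
        weights=weights,
        T=int(meta["T"]),
        norm_scale=float(meta["norm_scale"]),
        protocol_signature=meta.get("protocol_signature"),
        loss_history=arrays.get("loss_history", np.empty(0)),
        config=cfg,
    )
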