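"""Weighted-least-squares diffusion-tensor fitting and FA/MD maps.

The single-tensor model ``ln S = ln S0 - b g^T D g`` is linear in the seven
parameters ``(ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)``.  Fitting follows the
standard two-pass WLS scheme: an ordinary least-squares pass on the
log-signal, then one reweighted pass with weights equal to the squared
fitted signals (the variance-stabilizing weights for log-transformed
magnitude data).  Negative eigenvalues are clipped to zero before computing
the scalar maps, so FA stays in [0, 1].

The module also provides a high-b "noise-floor index": the mean normalized
signal bias on the highest shell within a tissue, a direct readout of the
rectified noise floor that inflates apparent high-b signal at low SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DWIDataset

__all__ = ["TensorFit", "fit_dti_wls", "metric_maps", "fa_from_eigenvalues",
           "high_b_floor_index"]

LOG_FLOOR_FRACTION = 1e-6  # of the dataset's 99th percentile


@dataclass
class TensorFit:
    """Per-voxel diffusion tensors (mm^2/s) with derived scalar maps."""

    tensors: np.ndarray      # (x, y, z, 3, 3) symmetric
    ln_s0: np.ndarray        # (x, y, z)
    mask: np.ndarray
    eigenvalues: np.ndarray = field(init=False)  # (x, y, z, 3) descending >= 0

    def __post_init__(self) -> None:
        evals = np.linalg.eigvalsh(self.tensors[self.mask])  # ascending
        evals = np.clip(evals[:, ::-1], 0.0, None)
        full = np.zeros((*self.mask.shape, 3))
        full[self.mask] = evals
        self.eigenvalues = full

    @property
    def fa(self) -> np.ndarray:
        out = np.zeros(self.mask.shape)
        out[self.mask] = fa_from_eigenvalues(self.eigenvalues[self.mask])
        return out

    @property
    def md(self) -> np.ndarray:
        out = np.zeros(self.mask.shape)
        out[self.mask] = self.eigenvalues[self.mask].mean(axis=1)
        return out


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean||_2 / ||lambda||_2 (0 for zero tensors)."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = ((evals - mean) ** 2).sum(axis=-1)
    den = (evals**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    return np.where(den > 0, np.clip(fa, 0.0, 1.0), 0.0)


def _design_matrix(protocol) -> np.ndarray:
    b = protocol.bvals
    g = protocol.bvecs
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_dti_wls(ds: DWIDataset, shells: list[float] | None = None) -> TensorFit:
    """Two-pass weighted-least-squares tensor fit on the masked voxels.

    ``shells`` restricts the fit to the b0 volumes plus the listed shells
    (default: all volumes).  Requires at least 7 volumes spanning >= 6
    non-collinear diffusion directions.
    """
    proto = ds.protocol
    if shells is not None:
        keep = proto.b0_mask.copy()
        for s in shells:
            keep |= np.isclose(proto.bvals, s)
        idx = np.flatnonzero(keep)
    else:
        idx = np.arange(proto.T)
    bvals = proto.bvals[idx]
    bvecs = proto.bvecs[idx]
    dw = bvals > 0
    n_unique = np.linalg.matrix_rank(
        np.column_stack(
            [
                bvecs[dw, 0] ** 2, bvecs[dw, 1] ** 2, bvecs[dw, 2] ** 2,
                bvecs[dw, 0] * bvecs[dw, 1],
                bvecs[dw, 0] * bvecs[dw, 2],
                bvecs[dw, 1] * bvecs[dw, 2],
            ]
        )
    ) if dw.any() else 0
    if len(idx) < 7 or n_unique < 6:
        raise ValueError(
            "tensor fit needs >= 7 volumes spanning >= 6 independent "
            f"directions; got {len(idx)} volumes, direction rank {n_unique}"
        )

    from .io import DWIProtocol

    sub_proto = DWIProtocol(bvals=bvals, bvecs=bvecs)
    B = _design_matrix(sub_proto)                    # (Tn, 7)
    S = ds.data[ds.mask][:, idx].astype(np.float64)  # (V, Tn)
    eps = LOG_FLOOR_FRACTION * float(np.percentile(ds.data, 99))
    y = np.log(np.maximum(S, eps))
    # OLS pass
    beta = np.linalg.lstsq(B, y.T, rcond=None)[0].T  # (V, 7)
    # one reweighted pass, weights = squared fitted signals
    w = np.exp(2.0 * (beta @ B.T))                   # (V, Tn)
    Bw = w[:, :, None] * B[None, :, :]               # (V, Tn, 7)
    A = np.einsum("vti,tj->vij", Bw, B)
    rhs = np.einsum("vti,vt->vi", Bw, y)
    try:
        beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        beta = np.stack(
            [np.linalg.lstsq(a, r, rcond=None)[0] for a, r in zip(A, rhs)]
        )
    tensors = np.zeros((*ds.spatial_shape, 3, 3))
    ln_s0 = np.zeros(ds.spatial_shape)
    d = np.zeros((len(beta), 3, 3))
    d[:, 0, 0] = beta[:, 1]
    d[:, 1, 1] = beta[:, 2]
    d[:, 2, 2] = beta[:, 3]
    d[:, 0, 1] = d[:, 1, 0] = beta[:, 4]
    d[:, 0, 2] = d[:, 2, 0] = beta[:, 5]
    d[:, 1, 2] = d[:, 2, 1] = beta[:, 6]
    tensors[ds.mask] = d
    ln_s0[ds.mask] = beta[:, 0]
    return TensorFit(tensors=tensors, ln_s0=ln_s0, mask=ds.mask.copy())


def metric_maps(fit: TensorFit) -> dict[str, np.ndarray]:
    """Scalar maps {FA, MD} (zeros outside the mask, NaN-free within)."""
    return {"FA": fit.fa, "MD": fit.md}


def high_b_floor_index(
    ds: DWIDataset,
    gt: DWIDataset,
    labels: np.ndarray,
    tissue: int = 1,
    shell: float | None = None,
) -> float:
    """Mean normalized signal bias on the highest shell within a tissue.

    ``mean(S/S0_b0) - mean(S_gt/S0_b0_gt)`` over the tissue voxels; positive
    values indicate the rectified noise floor inflating the high-b signal
    (most visible in CSF, where the true high-b signal is near zero).
    """
    proto = ds.protocol
    if shell is None:
        shell = float(proto.shells()[-1])
    vol = proto.volume_indices(shell)
    b0 = np.flatnonzero(proto.b0_mask)
    vox = (labels == tissue) & ds.mask
    if not vox.any():
        raise ValueError(f"no masked voxels with label {tissue}")

    def norm_mean(d: DWIDataset) -> float:
        s0 = d.data[vox][:, b0].mean()
        return float(d.data[vox][:, vol].mean() / s0)

    return norm_mean(ds) - norm_mean(gt)
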