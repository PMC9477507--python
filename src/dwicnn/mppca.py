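"""Marchenko-Pastur PCA denoising (patchwise, sliding window).

For each masked voxel, the time courses of the voxels in a centered patch
form an M x T matrix X.  Its covariance spectrum is split into a
Marchenko-Pastur noise bulk and signal components: pure-noise eigenvalues of
an M x P Gaussian matrix occupy an interval of width ``4 sigma^2 sqrt(P/M)``
around their mean ``sigma^2``, so the largest trailing set of eigenvalues
whose spread is consistent with that width is classified as noise.  The
center voxel is reconstructed from the retained (signal) components, and the
per-voxel noise estimate ``sigma_hat`` is emitted as a map.

This is the standard comparator for the temporal-domain CNN denoiser: it
removes Gaussian noise effectively but, operating on magnitude data, cannot
remove the rectified noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DWIDataset

__all__ = ["PatchSpec", "mp_noise_sigma", "mppca_denoise"]


@dataclass(frozen=True)
class PatchSpec:
    """Odd patch extents per axis (clipped to the volume at call time)."""

    extent: tuple[int, int, int] = (5, 5, 5)

    def __post_init__(self) -> None:
        if len(self.extent) != 3:
            raise ValueError("extent must have 3 entries")
        if any(e < 1 or e % 2 == 0 for e in self.extent):
            raise ValueError(f"extents must be odd and >= 1; got {self.extent}")
        if int(np.prod(self.extent)) < 2:
            raise ValueError("patch must contain at least 2 voxels")


def mp_noise_sigma(eigenvalues: np.ndarray, M: int, T: int) -> tuple[float, int]:
    """Split a covariance spectrum into MP noise bulk and signal components.

    ``eigenvalues`` are the ``min(M, T)`` eigenvalues (descending) of the
    patch Gram matrix scaled by ``max(M, T)`` — i.e. of ``X^T X / M`` when
    the patch has more voxels than volumes.  Returns
    ``(sigma_hat, n_signal_components)``.

    The criterion scans candidate noise sets (the p+1 smallest eigenvalues):
    the set is MP-consistent when its spread ``lam[p] - lam[0]`` is smaller
    than the MP bulk width ``4 sigma^2 sqrt((p+1)/max(M,T))`` evaluated at
    ``sigma^2`` = mean of the set.  The largest consistent set wins.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.ndim != 1 or lam.size < 4:
        raise ValueError("need at least 4 eigenvalues for an MP fit")
    if np.any(np.diff(lam) > 1e-12 * max(lam[0], 1.0)):
        raise ValueError("eigenvalues must be sorted descending")
    q = max(M, T)
    R = lam.size
    asc = np.clip(lam[::-1], 0.0, None)
    if asc[-1] <= 0:
        return 0.0, 0
    p1 = np.arange(1, R + 1)             # candidate noise-set sizes
    sig1 = np.cumsum(asc) / p1           # mean of the p1 smallest
    spread = asc - asc[0]
    sig2 = spread / (4.0 * np.sqrt(p1 / q))
    ok = np.flatnonzero(sig2 < sig1)
    if ok.size == 0:
        return 0.0, R
    p_star = int(ok[-1])
    return float(np.sqrt(sig1[p_star])), R - (p_star + 1)


def _patch_bounds(center: int, extent: int, size: int) -> slice:
    """Window of ``extent`` voxels containing ``center``, shifted inward at
    the borders so the patch size stays constant."""
    e = min(extent, size)
    lo = center - e // 2
    lo = max(0, min(lo, size - e))
    return slice(lo, lo + e)


def mppca_denoise(
    ds: DWIDataset, patch: PatchSpec = PatchSpec()
) -> tuple[DWIDataset, np.ndarray]:
    """Denoise every masked voxel from its local patch; return the denoised
    dataset and the ``sigma_hat`` map."""
    T = ds.protocol.T
    if T < 8:
        raise ValueError(f"need at least 8 volumes for an MP fit; got {T}")
    nx, ny, nz = ds.spatial_shape
    ext = tuple(min(e, s) for e, s in zip(patch.extent, (nx, ny, nz)))
    M = int(np.prod(ext))
    data = ds.data.astype(np.float64)
    out = data.copy()
    sigma_map = np.zeros(ds.spatial_shape)
    coords = np.argwhere(ds.mask)
    for x, y, z in coords:
        sx = _patch_bounds(x, ext[0], nx)
        sy = _patch_bounds(y, ext[1], ny)
        sz = _patch_bounds(z, ext[2], nz)
        X = data[sx, sy, sz].reshape(M, T)
        row = int((x - sx.start) * ext[1] * ext[2]
                  + (y - sy.start) * ext[2] + (z - sz.start))
        q = max(M, T)
        if M >= T:
            C = (X.T @ X) / q            # T x T, time-space eigenvectors
        else:
            C = (X @ X.T) / q            # M x M, voxel-space eigenvectors
        lam, vecs = np.linalg.eigh(C)    # ascending
        sigma_hat, n_sig = mp_noise_sigma(lam[::-1], M, T)
        if n_sig >= min(M, T):
            rec = X[row]
        elif n_sig == 0:
            rec = np.zeros(T)
        elif M >= T:
            V = vecs[:, -n_sig:]          # top components
            rec = (X[row] @ V) @ V.T
        else:
            U = vecs[:, -n_sig:]
            rec = U[row] @ (U.T @ X)
        out[x, y, z] = rec
        sigma_map[x, y, z] = sigma_hat
    denoised = ds.copy_with(
        out, denoised="mppca", patch_extent=ext
    )
    return denoised, sigma_map
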