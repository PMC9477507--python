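"""Reading, writing, and reshaping diffusion-weighted MRI datasets.

Volumes are NIfTI-1 (via :mod:`nibabel`); gradient tables are FSL-style
``.bval``/``.bvec`` whitespace-separated text.  All computations downstream
are voxelwise, so voxel indices are 0-based and follow the on-disk
``(x, y, z, t)`` axis order; the affine is carried along as provenance but
never interpreted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "DWIProtocol",
    "DWIDataset",
    "VoxelMatrix",
    "read_dwi",
    "write_dwi",
    "to_voxel_matrix",
    "from_voxel_matrix",
]

#: fraction of the robust (99th percentile) mean-b0 maximum used by the
#: automatic foreground mask when no mask file is supplied
AUTO_MASK_FRACTION = 0.10


@dataclass
class DWIProtocol:
    """Multi-shell gradient table: b-values (s/mm^2) and unit directions.

    Directions for ``b > 0`` volumes must be unit-norm; ``b = 0`` volumes may
    carry zero vectors (the scanner convention for non-diffusion-weighted
    acquisitions).
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (T, 3); got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise ValueError(
                f"gradient table mismatch: {len(self.bvals)} b-values vs "
                f"{len(self.bvecs)} directions"
            )
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be nonnegative")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dw = self.bvals > 0
        if np.any(np.abs(norms[dw] - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(norms[dw] - 1.0) > 1e-6))
            raise ValueError(
                f"non-unit direction for diffusion-weighted volume (norm "
                f"{norms[dw][bad]:.6g})"
            )

    @property
    def T(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def shells(self) -> np.ndarray:
        """Unique nonzero b-values, ascending."""
        return np.unique(self.bvals[self.bvals > 0])

    def volume_indices(self, shell: float | None) -> np.ndarray:
        """Indices of volumes on a shell (``None`` selects all volumes)."""
        if shell is None:
            return np.arange(self.T)
        return np.flatnonzero(np.isclose(self.bvals, shell))

    def signature(self) -> str:
        """Hash of the rounded gradient table, used to guard model transfer."""
        h = hashlib.sha256()
        h.update(np.round(self.bvals, 3).tobytes())
        h.update(np.round(self.bvecs, 6).tobytes())
        return h.hexdigest()[:16]


@dataclass
class DWIDataset:
    """4-D magnitude DWI data + gradient table + brain mask.

    ``data`` is indexed ``(x, y, z, t)``; intensities are arbitrary scanner
    units, finite, and nonnegative for magnitude data.  ``meta`` is a
    free-form provenance record (seeds, noise level, combine operator, ...).
    """

    data: np.ndarray
    protocol: DWIProtocol
    mask: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D; got shape {self.data.shape}")
        if self.data.shape[3] != self.protocol.T:
            raise ValueError(
                f"volume count mismatch: image has {self.data.shape[3]} "
                f"volumes but gradient table has {self.protocol.T}"
            )
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial shape "
                f"{self.data.shape[:3]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("dataset contains non-finite intensities")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def copy_with(self, data: np.ndarray, **meta) -> "DWIDataset":
        """New dataset sharing protocol/mask/geometry, with updated meta."""
        return DWIDataset(
            data=data,
            protocol=self.protocol,
            mask=self.mask,
            voxel_size=self.voxel_size,
            meta={**self.meta, **meta},
        )


@dataclass
class VoxelMatrix:
    """Masked voxel time courses as a V x T matrix.

    Row order is the lexicographic enumeration of the mask by ``(x, y, z)``,
    so volume -> matrix -> volume round-trips are exact on masked voxels.
    """

    values: np.ndarray
    index: np.ndarray  # (V, 3) int voxel coordinates

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.index = np.asarray(self.index)
        if self.values.shape[0] != self.index.shape[0]:
            raise ValueError("row count of values and index differ")

    @property
    def V(self) -> int:
        return self.values.shape[0]

    @property
    def T(self) -> int:
        return self.values.shape[1]


def _load_table(path: str | Path) -> np.ndarray:
    # tolerant of tabs/spaces/newlines, strict about counts (checked later)
    return np.loadtxt(str(path), ndmin=2)


def auto_mask(data: np.ndarray, b0_idx: np.ndarray,
              fraction: float = AUTO_MASK_FRACTION) -> np.ndarray:
    """Foreground mask: mean-b0 above ``fraction`` of its 99th percentile."""
    mean_b0 = data[..., b0_idx].mean(axis=3)
    robust_max = np.percentile(mean_b0, 99)
    return mean_b0 > fraction * robust_max


def read_dwi(
    nifti_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    mask_path: str | Path | None = None,
    auto_mask_fraction: float = AUTO_MASK_FRACTION,
) -> DWIDataset:
    """Load a 4-D NIfTI volume with its FSL gradient table.

    When ``mask_path`` is omitted, a foreground mask is derived from the mean
    b0 image (voxels above ``auto_mask_fraction`` of its 99th percentile).
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D NIfTI, got {data.ndim}-D")
    bvals = _load_table(bval_path).ravel()
    bvecs = _load_table(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T  # FSL layout: 3 rows x T columns
    if len(bvals) != data.shape[3] or bvecs.shape[0] != data.shape[3]:
        raise ValueError(
            f"gradient table/image mismatch: image has {data.shape[3]} "
            f"volumes, bval has {len(bvals)} entries, bvec has "
            f"{bvecs.shape[0]} directions"
        )
    protocol = DWIProtocol(bvals=bvals, bvecs=bvecs)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = auto_mask(data, np.flatnonzero(protocol.b0_mask),
                         auto_mask_fraction)
    zooms = img.header.get_zooms()[:3]
    return DWIDataset(
        data=data,
        protocol=protocol,
        mask=mask,
        voxel_size=tuple(float(z) for z in zooms),
        meta={"source": str(nifti_path), "affine": np.asarray(img.affine)},
    )


def write_dwi(
    ds: DWIDataset,
    nifti_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    mask_path: str | Path | None = None,
) -> tuple[Path, Path, Path]:
    """Write a dataset as NIfTI + FSL bval/bvec text (3 rows x T columns)."""
    affine = ds.meta.get("affine")
    if affine is None:
        affine = np.diag([*ds.voxel_size, 1.0])
    img = nib.Nifti1Image(ds.data.astype(np.float32), np.asarray(affine))
    img.header.set_zooms((*ds.voxel_size, 1.0))
    nib.save(img, str(nifti_path))
    with open(bval_path, "w") as f:
        f.write(" ".join(f"{b:g}" for b in ds.protocol.bvals) + "\n")
    with open(bvec_path, "w") as f:
        for row in ds.protocol.bvecs.T:  # 3 rows
            f.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    if mask_path is not None:
        nib.save(
            nib.Nifti1Image(ds.mask.astype(np.uint8), np.asarray(affine)),
            str(mask_path),
        )
    return Path(nifti_path), Path(bval_path), Path(bvec_path)


def to_voxel_matrix(ds: DWIDataset) -> VoxelMatrix:
    """Stack masked voxel time courses into a V x T matrix (lexicographic)."""
    if not ds.mask.any():
        raise ValueError("mask is empty; no voxel time courses to extract")
    index = np.argwhere(ds.mask)  # lexicographic by (x, y, z) in C order
    values = ds.data[ds.mask]     # same C-order enumeration
    return VoxelMatrix(values=values, index=index)


def from_voxel_matrix(vm: VoxelMatrix, template: DWIDataset) -> DWIDataset:
    """Scatter matrix rows back into a copy of ``template``.

    Unmasked voxels keep their template values.
    """
    if vm.T != template.protocol.T:
        raise ValueError(
            f"time-course length {vm.T} does not match protocol T="
            f"{template.protocol.T}"
        )
    data = template.data.copy()
    data[vm.index[:, 0], vm.index[:, 1], vm.index[:, 2], :] = vm.values
    return template.copy_with(data)
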