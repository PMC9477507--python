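"""Digital multi-shell diffusion phantom.

Generates noise-free ground-truth DWI data from a labeled tissue volume and
the single-tensor signal model ``S(b, g) = S0 * exp(-b g^T D g)``.  The
phantom geometry is a stack of slices, each holding a central CSF core, a
gray-matter band, and an outer white-matter annulus whose principal fiber
direction rotates with azimuthal angle, so that voxel time courses span a
range of orientations rather than a single decay curve.  Different seeds
jitter the region boundaries and the orientation-field phase — the mechanism
standing in for "different subjects" in transfer experiments.

Tissue diffusivities default to conventional literature values
(CSF isotropic 3.0e-3 mm^2/s; GM mildly anisotropic; WM prolate
1.7/0.3/0.3e-3 mm^2/s); they are configuration, not measured facts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DWIDataset, DWIProtocol

__all__ = [
    "TissueParams",
    "DigitalPhantom",
    "DEFAULT_TISSUE_PARAMS",
    "LABEL_NAMES",
    "make_protocol",
    "make_phantom",
    "simulate_noise_free",
]

LABEL_NAMES = {0: "background", 1: "CSF", 2: "GM", 3: "WM"}


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue b0 intensity and diffusion-tensor eigenvalues (mm^2/s)."""

    S0: float
    eigenvalues: tuple[float, float, float]  # lambda1 >= lambda2 >= lambda3

    def __post_init__(self) -> None:
        l1, l2, l3 = self.eigenvalues
        if not (l1 >= l2 >= l3 > 0):
            raise ValueError(
                f"eigenvalues must be positive and sorted descending; got "
                f"{self.eigenvalues}"
            )


DEFAULT_TISSUE_PARAMS: dict[int, TissueParams] = {
    1: TissueParams(S0=1000.0, eigenvalues=(3.0e-3, 3.0e-3, 3.0e-3)),  # CSF
    2: TissueParams(S0=800.0, eigenvalues=(0.9e-3, 0.7e-3, 0.7e-3)),   # GM
    3: TissueParams(S0=700.0, eigenvalues=(1.7e-3, 0.3e-3, 0.3e-3)),   # WM
}


@dataclass
class DigitalPhantom:
    labels: np.ndarray  # (x, y, z) int, 0=background 1=CSF 2=GM 3=WM
    tissue_params: dict[int, TissueParams]
    wm_orientation_field: np.ndarray  # (x, y, z, 3) unit vectors in WM voxels
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    meta: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


# ---------------------------------------------------------------------------
# gradient scheme


def _pair_energy(x: np.ndarray) -> float:
    """Electrostatic energy with antipodal symmetry: sum 1/|xi-xj| + 1/|xi+xj|."""
    d = x[:, None, :] - x[None, :, :]
    s = x[:, None, :] + x[None, :, :]
    dn = np.linalg.norm(d, axis=-1)
    sn = np.linalg.norm(s, axis=-1)
    iu = np.triu_indices(len(x), k=1)
    return float((1.0 / dn[iu]).sum() + (1.0 / sn[iu]).sum())


def _repulsion_directions(n: int, rng: np.random.Generator,
                          n_iter: int = 300, n_restarts: int = 3) -> np.ndarray:
    """Approximately uniform antipodally-symmetric directions on the sphere.

    Projected gradient descent on the electrostatic-repulsion energy of the
    n points and their antipodes, best of ``n_restarts`` random starts.
    """
    best, best_e = None, np.inf
    for _ in range(n_restarts):
        x = rng.normal(size=(n, 3))
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        step = 0.1
        for it in range(n_iter):
            d = x[:, None, :] - x[None, :, :]
            s = x[:, None, :] + x[None, :, :]
            dn = np.linalg.norm(d, axis=-1)
            sn = np.linalg.norm(s, axis=-1)
            np.fill_diagonal(dn, 1.0)
            np.fill_diagonal(sn, 1.0)  # self-antipode force is radial
            # guard exact collisions/antipodes during transient overshoots
            np.maximum(dn, 1e-6, out=dn)
            np.maximum(sn, 1e-6, out=sn)
            inv_d = dn**-3
            inv_s = sn**-3
            np.fill_diagonal(inv_d, 0.0)
            np.fill_diagonal(inv_s, 0.0)
            # force = sum over j of (xi-xj)/|xi-xj|^3 + (xi+xj)/|xi+xj|^3
            f = (d * inv_d[..., None]).sum(axis=1)
            f += (s * inv_s[..., None]).sum(axis=1)
            x = x + step * f / n
            x /= np.linalg.norm(x, axis=1, keepdims=True)
            if (it + 1) % 50 == 0:
                step *= 0.5
        e = _pair_energy(x)
        if e < best_e:
            best, best_e = x, e
    return best


def make_protocol(
    n_b0: int = 4,
    dirs_per_shell: tuple[int, ...] = (90, 90),
    shell_bvals: tuple[float, ...] = (1000.0, 2000.0),
    seed: int = 0,
) -> DWIProtocol:
    """Multi-shell protocol: b0 volumes first, then one block per shell.

    Defaults reproduce the simulation protocol: 4 b0 + 90 directions at
    b=1000 s/mm^2 + 90 at b=2000 s/mm^2, T=184.  Directions are placed by
    electrostatic repulsion (antipodally symmetric), independently per shell.
    """
    if len(dirs_per_shell) != len(shell_bvals):
        raise ValueError("dirs_per_shell and shell_bvals lengths differ")
    if any(n < 6 for n in dirs_per_shell):
        raise ValueError(
            "each shell needs at least 6 directions for tensor fitting"
        )
    rng = np.random.default_rng(seed)
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for n_dirs, b in zip(dirs_per_shell, shell_bvals):
        dirs = _repulsion_directions(n_dirs, rng)
        bvals.extend([float(b)] * n_dirs)
        bvecs.extend(dirs)
    return DWIProtocol(bvals=np.array(bvals), bvecs=np.array(bvecs))


# ---------------------------------------------------------------------------
# phantom geometry


def make_phantom(
    shape: tuple[int, int, int] = (64, 64, 4),
    seed: int = 0,
    tissue_params: dict[int, TissueParams] | None = None,
) -> DigitalPhantom:
    """Concentric-region slice phantom with a rotating WM orientation field.

    Per slice: CSF core, GM band, WM annulus, background outside.  The seed
    jitters the center, the region radii, and the orientation-field phase.
    """
    if any(s < m for s, m in zip(shape, (16, 16, 1))):
        raise ValueError(f"shape {shape} below minimum (16, 16, 1)")
    params = dict(tissue_params or DEFAULT_TISSUE_PARAMS)
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int8)
    orient = np.zeros((*shape, 3))
    base = 0.5 * min(nx, ny)
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    for z in range(nz):
        cx = (nx - 1) / 2 + rng.uniform(-0.04, 0.04) * nx
        cy = (ny - 1) / 2 + rng.uniform(-0.04, 0.04) * ny
        r_out = base * 0.84 * (1 + rng.uniform(-0.05, 0.05))
        r_gm = base * 0.60 * (1 + rng.uniform(-0.05, 0.05))
        r_csf = base * 0.30 * (1 + rng.uniform(-0.05, 0.05))
        phase = rng.uniform(0, 2 * np.pi)
        r = np.hypot(xs - cx, ys - cy)
        sl = np.zeros((nx, ny), dtype=np.int8)
        sl[r < r_out] = 3
        sl[r < r_gm] = 2
        sl[r < r_csf] = 1
        labels[:, :, z] = sl
        theta = np.arctan2(ys - cy, xs - cx)
        psi = theta + phase
        wm = sl == 3
        orient[:, :, z, 0][wm] = -np.sin(psi[wm])
        orient[:, :, z, 1][wm] = np.cos(psi[wm])
    return DigitalPhantom(
        labels=labels,
        tissue_params=params,
        wm_orientation_field=orient,
        meta={"seed": seed, "shape": shape},
    )


# ---------------------------------------------------------------------------
# signal synthesis


def simulate_noise_free(ph: DigitalPhantom, proto: DWIProtocol) -> DWIDataset:
    """Closed-form tensor-model signal for every tissue voxel.

    b0 volumes equal the tissue S0 exactly; diffusion-weighted volumes decay
    as ``exp(-b g^T D g)`` with D assembled from the tissue eigenvalues and,
    for WM, the local principal direction (axially symmetric tensor).
    """
    g = proto.bvecs  # (T, 3)
    b = proto.bvals  # (T,)
    data = np.zeros((*ph.labels.shape, proto.T), dtype=np.float64)
    for label, tp in ph.tissue_params.items():
        vox = ph.labels == label
        if not vox.any():
            continue
        l1, l2, l3 = tp.eigenvalues
        if label == 3 and abs(l2 - l3) < 1e-15:
            # axially symmetric WM tensor around the local orientation:
            # g^T D g = (l1 - l2) (g.e)^2 + l2 |g|^2
            e = ph.wm_orientation_field[vox]  # (V, 3)
            ge = e @ g.T  # (V, T)
            q = (l1 - l2) * ge**2 + l2 * (g**2).sum(axis=1)[None, :]
        else:
            # diagonal tensor with principal axis along z
            D = np.diag([l3, l2, l1])
            q = np.einsum("ti,ij,tj->t", g, D, g)[None, :]
        data[vox] = tp.S0 * np.exp(-b[None, :] * q)
    return DWIDataset(
        data=data,
        protocol=proto,
        mask=ph.mask,
        voxel_size=ph.voxel_size,
        meta={"phantom_seed": ph.meta.get("seed"), "noise_free": True},
    )
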