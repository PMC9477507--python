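"""Multi-coil complex Gaussian noise model and coil-combination operators.

Complex Gaussian noise is added independently to the real and imaginary
parts of each coil channel; the channels are then combined with either

* ``"sos"`` — root sum of squares ``sqrt(sum_c |s_c|^2)``.  With N channels
  of equal noise level the zero-signal magnitude follows a central chi
  distribution with 2N degrees of freedom, producing the *rectified noise
  floor* that biases high-b-value diffusion signal upward; or
* ``"sense1"`` — the phase-aware matched filter
  ``|sum_c conj(c_c) s_c| / sum_c |c_c|^2`` with known sensitivities
  (equivalently the adaptive combine with exact sensitivity estimates),
  whose magnitude is Rician with a much lower floor.

Both combines called with the same seed consume identical channel noise, so
an SoS/SENSE1 pair derives from the exact same underlying complex image.
The simulated object signal is real-valued with zero phase; all phase
structure lives in the coil sensitivity maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, special

from .io import DWIDataset

__all__ = [
    "CoilModel",
    "make_coil_model",
    "corrupt",
    "combine_noise_free",
    "sigma_for_snr",
    "noncentral_chi_mean",
    "noncentral_chi_sd",
    "empirical_snr",
]

COMBINES = ("sos", "sense1")


@dataclass
class CoilModel:
    """Per-channel complex sensitivity maps and channel noise level.

    ``sigma`` is the standard deviation of the Gaussian noise added to each
    of the real and imaginary parts of every channel sample.
    """

    sensitivities: np.ndarray  # (n_coils, x, y, z) complex
    sigma: float

    def __post_init__(self) -> None:
        self.sensitivities = np.asarray(self.sensitivities)
        if self.sensitivities.ndim != 4:
            raise ValueError("sensitivities must be (n_coils, x, y, z)")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive; got {self.sigma}")

    @property
    def n_coils(self) -> int:
        return self.sensitivities.shape[0]

    def sum_sq(self) -> np.ndarray:
        """``sum_c |c_c|^2`` per voxel (matched-filter normalization)."""
        return (np.abs(self.sensitivities) ** 2).sum(axis=0)

    def with_sigma(self, sigma: float) -> "CoilModel":
        return replace(self, sigma=sigma)


def make_coil_model(
    shape: tuple[int, int, int],
    n_coils: int = 8,
    sigma: float = 1.0,
    seed: int = 0,
) -> CoilModel:
    """Circular phased-array surrogate: Gaussian magnitude falloff from coil
    centers equally spaced on a circle around the FOV, smooth linear phase.

    Magnitudes are globally rescaled so the mean root-sum-of-squares
    sensitivity over the volume is 1, keeping combined intensities on the
    scale of the object signal.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive; got {sigma}")
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    xs, ys, zs = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    cx, cy = (nx - 1) / 2, (ny - 1) / 2
    radius = 0.65 * max(nx, ny)
    width = 0.55 * max(nx, ny)
    sens = np.empty((n_coils, nx, ny, nz), dtype=np.complex128)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.1, 0.1)
        px, py = cx + radius * np.cos(ang), cy + radius * np.sin(ang)
        d2 = (xs - px) ** 2 + (ys - py) ** 2
        mag = np.exp(-d2 / (2 * width**2))
        # smooth spatial phase: random linear ramp + per-coil offset
        kx, ky = rng.uniform(-np.pi / nx, np.pi / nx, size=2)
        phase = kx * (xs - cx) + ky * (ys - cy) + rng.uniform(0, 2 * np.pi)
        sens[c] = mag * np.exp(1j * phase)
    rss = np.sqrt((np.abs(sens) ** 2).sum(axis=0))
    sens /= rss.mean()
    return CoilModel(sensitivities=sens, sigma=float(sigma))


def _combine(channels: np.ndarray, coil: CoilModel, combine: str) -> np.ndarray:
    if combine == "sos":
        return np.sqrt((np.abs(channels) ** 2).sum(axis=0))
    if combine == "sense1":
        q = coil.sum_sq()[..., None]
        num = (np.conj(coil.sensitivities[..., None]) * channels).sum(axis=0)
        return np.abs(num) / q
    raise ValueError(f"unknown combine {combine!r}; expected one of {COMBINES}")


def combine_noise_free(gt: DWIDataset, coil: CoilModel, combine: str) -> DWIDataset:
    """sigma -> 0 limit of :func:`corrupt`: the combined noiseless image.

    For ``"sense1"`` this equals the object signal; for ``"sos"`` it is the
    signal scaled by the root-sum-of-squares sensitivity.  This is the
    reference/ground-truth image on the intensity scale of the corresponding
    noisy reconstruction.
    """
    if combine == "sense1":
        data = gt.data.astype(np.float64)
    elif combine == "sos":
        rss = np.sqrt(coil.sum_sq())
        data = gt.data * rss[..., None]
    else:
        raise ValueError(f"unknown combine {combine!r}; expected one of {COMBINES}")
    return gt.copy_with(data, combine=combine, sigma=0.0, noise_free=True)


def corrupt(
    gt: DWIDataset, coil: CoilModel, combine: str, seed: int = 0
) -> DWIDataset:
    """Add per-channel complex Gaussian noise and combine the channels.

    The channel noise is drawn from ``seed`` alone, so ``"sos"`` and
    ``"sense1"`` calls with the same seed see identical noise realizations.
    """
    if combine not in COMBINES:
        raise ValueError(f"unknown combine {combine!r}; expected one of {COMBINES}")
    if coil.sensitivities.shape[1:] != gt.spatial_shape:
        raise ValueError("coil model spatial shape does not match dataset")
    rng = np.random.default_rng(seed)
    shape = (coil.n_coils, *gt.data.shape)
    noise = rng.normal(scale=coil.sigma, size=shape).astype(np.float32) \
        + 1j * rng.normal(scale=coil.sigma, size=shape).astype(np.float32)
    channels = coil.sensitivities[:, ..., None] * gt.data[None] + noise
    data = _combine(channels, coil, combine)
    return gt.copy_with(
        np.ascontiguousarray(data, dtype=np.float32),
        combine=combine,
        sigma=float(coil.sigma),
        noise_seed=int(seed),
        noise_free=False,
    )


# ---------------------------------------------------------------------------
# noncentral chi magnitude statistics (N coils -> 2N degrees of freedom)


def noncentral_chi_mean(nu, sigma, n_coils: int) -> np.ndarray:
    """E[magnitude] for an N-channel magnitude signal.

    ``nu`` is the underlying noiseless magnitude, ``sigma`` the per-component
    Gaussian SD.  N=1 gives the Rician mean; nu=0 the central chi
    (Rayleigh for N=1) noise-floor mean
    ``sigma * sqrt(2) * Gamma(N + 1/2) / Gamma(N)``.
    """
    nu, sigma = np.broadcast_arrays(
        np.asarray(nu, dtype=float), np.asarray(sigma, dtype=float)
    )
    x = nu**2 / (2 * sigma**2)
    lead = sigma * np.sqrt(2) * np.exp(
        special.gammaln(n_coils + 0.5) - special.gammaln(n_coils)
    )
    small = x < 500
    out = np.empty_like(x)
    # exact: sigma*sqrt(2)*Gamma(N+1/2)/Gamma(N) * 1F1(-1/2; N; -x)
    out[small] = lead[small] * special.hyp1f1(-0.5, n_coils, -x[small])
    # large-argument asymptotics of 1F1 (second moment expansion)
    big = ~small
    out[big] = np.sqrt(nu[big] ** 2 + (2 * n_coils - 1) * sigma[big] ** 2)
    return out


def noncentral_chi_sd(nu, sigma, n_coils: int) -> np.ndarray:
    """SD of the N-channel magnitude: from E[M^2] = nu^2 + 2 N sigma^2."""
    nu, sigma = np.broadcast_arrays(
        np.asarray(nu, dtype=float), np.asarray(sigma, dtype=float)
    )
    m1 = noncentral_chi_mean(nu, sigma, n_coils)
    m2 = nu**2 + 2 * n_coils * sigma**2
    return np.sqrt(np.maximum(m2 - m1**2, 0.0))


def _predicted_snr(
    sigma: float,
    s0: np.ndarray,
    q: np.ndarray,
    combine: str,
    n_coils: int,
) -> float:
    """Analytic SNR of the combined b0 image over the reference voxels.

    SNR := mean(E[b0 magnitude]) / mean(SD[b0 magnitude]).
    """
    if combine == "sos":
        nu = s0 * np.sqrt(q)
        mean = noncentral_chi_mean(nu, sigma, n_coils)
        sd = noncentral_chi_sd(nu, sigma, n_coils)
    else:  # sense1: Rician with effective per-component SD sigma/sqrt(q)
        sig_eff = sigma / np.sqrt(q)
        mean = noncentral_chi_mean(s0, sig_eff, 1)
        sd = noncentral_chi_sd(s0, sig_eff, 1)
    return float(mean.mean() / sd.mean())


def sigma_for_snr(
    gt: DWIDataset,
    labels: np.ndarray,
    target_snr: float,
    combine: str,
    coil: CoilModel,
    reference_label: int = 3,
) -> float:
    """Channel noise SD giving the requested b0 SNR in the reference tissue.

    SNR is defined as the mean b0 intensity of the combined image in the
    reference tissue (default WM, label 3) divided by the analytic SD of the
    combined-image b0 intensity there.  Solved by bracketing the closed-form
    noncentral-chi moments, which remain accurate into the noise-floor
    regime.
    """
    if target_snr <= 0:
        raise ValueError(f"target_snr must be positive; got {target_snr}")
    if combine not in COMBINES:
        raise ValueError(f"unknown combine {combine!r}; expected one of {COMBINES}")
    ref = (labels == reference_label) & gt.mask
    if not ref.any():
        raise ValueError(f"no voxels with reference label {reference_label}")
    b0_idx = np.flatnonzero(gt.protocol.b0_mask)
    s0 = gt.data[ref][:, b0_idx].mean(axis=1)
    q = coil.sum_sq()[ref]
    scale = float(s0.mean())

    def gap(sigma: float) -> float:
        return _predicted_snr(sigma, s0, q, combine, coil.n_coils) - target_snr

    lo, hi = scale * 1e-6, scale * 10.0
    return float(optimize.brentq(gap, lo, hi, xtol=scale * 1e-9))


def empirical_snr(
    gt: DWIDataset,
    coil: CoilModel,
    combine: str,
    labels: np.ndarray,
    n_draws: int = 50,
    seed: int = 0,
    reference_label: int = 3,
) -> float:
    """Monte-Carlo SNR check: mean over draws / per-voxel SD across draws.

    Only the b0 volumes are simulated, mirroring the analytic definition.
    """
    b0_idx = np.flatnonzero(gt.protocol.b0_mask)
    from .io import DWIProtocol

    proto_b0 = DWIProtocol(
        bvals=gt.protocol.bvals[b0_idx], bvecs=gt.protocol.bvecs[b0_idx]
    )
    gt_b0 = DWIDataset(
        data=gt.data[..., b0_idx],
        protocol=proto_b0,
        mask=gt.mask,
        voxel_size=gt.voxel_size,
        meta=dict(gt.meta),
    )
    ref = (labels == reference_label) & gt.mask
    rng = np.random.default_rng(seed)
    draws = np.stack(
        [
            corrupt(gt_b0, coil, combine, seed=int(rng.integers(2**31))).data[ref]
            for _ in range(n_draws)
        ]
    )  # (n_draws, V, n_b0)
    return float(draws.mean() / draws.std(axis=0, ddof=1).mean())
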