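"""Coil model, noise-floor statistics, and SNR calibration."""

import numpy as np
import pytest
from scipy.special import gammaln

from dwicnn import (
    CoilModel,
    DWIDataset,
    DWIProtocol,
    combine_noise_free,
    corrupt,
    make_coil_model,
    sigma_for_snr,
)
from dwicnn.noise import empirical_snr, noncentral_chi_mean, noncentral_chi_sd


def _flat_dataset(value, shape=(6, 6, 1), T=40):
    proto = DWIProtocol(bvals=np.zeros(T), bvecs=np.zeros((T, 3)))
    data = np.full((*shape, T), float(value))
    mask = np.ones(shape, bool)
    return DWIDataset(data=data, protocol=proto, mask=mask)


def _unit_coil(shape, n_coils):
    sens = np.ones((n_coils, *shape), dtype=complex)
    return CoilModel(sensitivities=sens, sigma=1.0)


class TestCoilModel:
    def test_deterministic_for_seed(self):
        a = make_coil_model((12, 12, 2), seed=5)
        b = make_coil_model((12, 12, 2), seed=5)
        np.testing.assert_array_equal(a.sensitivities, b.sensitivities)

    def test_rss_profile_moderate(self, small_gt, small_coil):
        rss = np.sqrt(small_coil.sum_sq())
        inside = rss[small_gt.mask]
        assert inside.min() > 0.2 and inside.max() < 2.0

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError, match="sigma"):
            make_coil_model((16, 16, 1), sigma=0.0)

    def test_single_flat_coil_combines_agree(self):
        """With one unit-sensitivity coil, SoS and SENSE1 both reduce to the
        single-channel magnitude."""
        ds = _flat_dataset(50.0, T=20)
        coil = _unit_coil(ds.spatial_shape, 1).with_sigma(3.0)
        sos = corrupt(ds, coil, "sos", seed=4)
        s1 = corrupt(ds, coil, "sense1", seed=4)
        np.testing.assert_allclose(sos.data, s1.data, rtol=1e-6)


class TestNoiseFloorStatistics:
    """Zero-signal magnitudes follow Rayleigh / central chi closed forms."""

    def test_sense1_zero_signal_rayleigh_mean(self):
        sigma = 2.0
        ds = _flat_dataset(0.0, shape=(16, 16, 1), T=40)  # 10240 draws
        coil = _unit_coil(ds.spatial_shape, 8).with_sigma(sigma)
        vals = corrupt(ds, coil, "sense1", seed=1).data.ravel()
        expected = sigma / np.sqrt(8) * np.sqrt(np.pi / 2)  # sigma_eff = s/sqrt(N)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - expected) < 3 * se

    def test_sos_zero_signal_central_chi_mean(self):
        sigma = 2.0
        ds = _flat_dataset(0.0, shape=(16, 16, 1), T=40)
        coil = _unit_coil(ds.spatial_shape, 8).with_sigma(sigma)
        vals = corrupt(ds, coil, "sos", seed=1).data.ravel()
        expected = sigma * np.sqrt(2) * np.exp(gammaln(8.5) - gammaln(8))
        assert np.isclose(expected, 3.94 * sigma, rtol=2e-3)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - expected) < 3 * se

    def test_closed_form_moments_match_monte_carlo(self, rng):
        nu, sigma, N = 5.0, 2.0, 8
        noise = rng.normal(scale=sigma, size=(200_000, 2 * N))
        noise[:, 0] += nu
        mags = np.sqrt((noise**2).sum(axis=1))
        se = mags.std(ddof=1) / np.sqrt(len(mags))
        assert abs(mags.mean() - noncentral_chi_mean(nu, sigma, N)) < 4 * se
        assert np.isclose(mags.std(), noncentral_chi_sd(nu, sigma, N),
                          rtol=0.02)

    def test_asymptotic_branch_continuous(self):
        # the exact/asymptotic switch (x = 500) must not introduce a jump
        sigma, N = 1.0, 8
        nu_lo = np.sqrt(2 * 499.9)
        nu_hi = np.sqrt(2 * 500.1)
        lo = float(noncentral_chi_mean(nu_lo, sigma, N))
        hi = float(noncentral_chi_mean(nu_hi, sigma, N))
        assert abs(hi - lo) < 1e-2


class TestCorrupt:
    def test_noiseless_limit(self, small_gt, small_coil):
        tiny = small_coil.with_sigma(1e-9)
        sos = corrupt(small_gt, tiny, "sos", seed=0)
        ref = combine_noise_free(small_gt, small_coil, "sos")
        np.testing.assert_allclose(sos.data, ref.data, rtol=1e-4, atol=1e-4)
        s1 = corrupt(small_gt, tiny, "sense1", seed=0)
        np.testing.assert_allclose(s1.data, small_gt.data, rtol=1e-4,
                                   atol=1e-4)

    def test_same_seed_shares_channel_noise(self, small_gt, small_coil):
        """Cauchy-Schwarz on identical channel noise: the SoS magnitude
        bounds the normalized matched-filter magnitude at every voxel."""
        sos = corrupt(small_gt, small_coil, "sos", seed=9)
        s1 = corrupt(small_gt, small_coil, "sense1", seed=9)
        q = small_coil.sum_sq()
        lhs = s1.data * np.sqrt(q)[..., None]  # |matched sum| / sqrt(q)
        assert (lhs <= sos.data * (1 + 1e-5)).all()

    def test_high_snr_means_converge_to_signal(self, small_gt, small_coil):
        """At SNR >= 50 both combines are unbiased within 2%."""
        ph_labels = np.where(small_gt.mask, 3, 0)  # treat all tissue as ref
        reps = []
        for combine in ("sos", "sense1"):
            sigma = sigma_for_snr(small_gt, ph_labels, 50.0, combine,
                                  small_coil)
            coil = small_coil.with_sigma(sigma)
            ref = combine_noise_free(small_gt, coil, combine)
            acc = np.zeros_like(ref.data)
            for s in range(20):
                acc += corrupt(small_gt, coil, combine, seed=100 + s).data
            mean = acc / 20
            sel = small_gt.mask & (ref.data[..., 0] > 0)
            rel = np.abs(mean[sel] - ref.data[sel]) / ref.data[sel]
            # compare on the b0 volume where the relative SE is smallest
            reps.append(np.median(rel[:, 0]))
        assert max(reps) < 0.02

    def test_unknown_combine_rejected(self, small_gt, small_coil):
        with pytest.raises(ValueError, match="unknown combine"):
            corrupt(small_gt, small_coil, "grappa", seed=0)


class TestSNRCalibration:
    def test_empirical_snr_matches_target(self, small_gt, small_phantom,
                                          small_coil):
        labels = small_phantom.labels
        for combine in ("sos", "sense1"):
            sigma = sigma_for_snr(small_gt, labels, 30.0, combine, small_coil)
            snr = empirical_snr(small_gt, small_coil.with_sigma(sigma),
                                combine, labels, n_draws=50, seed=2)
            assert abs(snr - 30.0) / 30.0 < 0.02

    def test_sigma_scales_inversely_with_snr(self, small_gt, small_phantom,
                                             small_coil):
        """In the Gaussian regime sigma(SNR) is ~ inverse-linear, so
        sigma(10) is close to 3x sigma(30); the SoS floor makes the SNR-10
        value slightly larger than linear."""
        labels = small_phantom.labels
        s10 = sigma_for_snr(small_gt, labels, 10.0, "sense1", small_coil)
        s30 = sigma_for_snr(small_gt, labels, 30.0, "sense1", small_coil)
        assert 2.8 < s10 / s30 < 3.3
        s10_sos = sigma_for_snr(small_gt, labels, 10.0, "sos", small_coil)
        s30_sos = sigma_for_snr(small_gt, labels, 30.0, "sos", small_coil)
        assert s10_sos / s30_sos > 3.0

    def test_sos_needs_more_noise_than_sense1_at_same_snr(
        self, small_gt, small_phantom, small_coil
    ):
        """The SoS magnitude aggregates 2N noise channels, so reaching the
        same image SNR requires a larger per-channel sigma."""
        labels = small_phantom.labels
        s_sos = sigma_for_snr(small_gt, labels, 10.0, "sos", small_coil)
        s_s1 = sigma_for_snr(small_gt, labels, 10.0, "sense1", small_coil)
        assert s_sos > s_s1

    def test_invalid_target_rejected(self, small_gt, small_phantom, small_coil):
        with pytest.raises(ValueError, match="positive"):
            sigma_for_snr(small_gt, small_phantom.labels, -5.0, "sos",
                          small_coil)
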