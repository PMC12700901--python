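"""Phasor transform, IRF calibration, universal semicircle, clustering."""

import numpy as np
import pytest

from mitoflim import (
    DecayHistogram,
    TCSPCConfig,
    calibrate_phasor,
    cluster_phasor,
    expected_decay_curve,
    gaussian_irf,
    phasor_image,
    phasor_transform,
    simulate_decay,
)
from mitoflim.phasor import PhasorCloud, ideal_phasor


def irf_reference(cfg, irf):
    """Phasor of the IRF histogram itself (the calibration reference)."""
    return phasor_transform(DecayHistogram(irf.counts * 1e6, cfg.bin_width_ps))


class TestTransform:
    def test_delta_limit(self, cfg):
        counts = np.zeros(cfg.n_bins)
        counts[0] = 100
        p = phasor_transform(DecayHistogram(counts, cfg.bin_width_ps))
        assert p.g == pytest.approx(1.0, abs=0.02)
        assert p.s == pytest.approx(0.0, abs=0.02)

    def test_omega_tau_one_lands_at_half_half(self, cfg, irf):
        """omega*tau = 1 at 80 MHz for tau = 1/omega = 1.9894 ns."""
        tau = 1.0 / cfg.omega
        h = simulate_decay([(1.0, tau)], cfg, 1e6, noiseless=True)
        p = calibrate_phasor(phasor_transform(h), irf_reference(cfg, irf), 0.0)
        assert p.g == pytest.approx(0.5, abs=1e-3)
        assert p.s == pytest.approx(0.5, abs=1e-3)

    def test_mixture_lies_on_chord(self, cfg, irf):
        """The transform is linear in photons: a 50/50 photon mixture sits
        exactly on the segment between its component phasors."""
        ref = irf_reference(cfg, irf)
        c1 = expected_decay_curve([(1.0, 0.6)], cfg, 1000.0, irf=irf)
        c2 = expected_decay_curve([(1.0, 2.4)], cfg, 1000.0, irf=irf)
        dt = cfg.bin_width_ps
        p1 = calibrate_phasor(phasor_transform(DecayHistogram(c1, dt)), ref)
        p2 = calibrate_phasor(phasor_transform(DecayHistogram(c2, dt)), ref)
        pm = calibrate_phasor(phasor_transform(DecayHistogram(0.5 * c1 + 0.5 * c2, dt)), ref)
        assert pm.g == pytest.approx(0.5 * (p1.g + p2.g), abs=1e-9)
        assert pm.s == pytest.approx(0.5 * (p1.s + p2.s), abs=1e-9)
        # and strictly inside the semicircle
        assert pm.s**2 + (pm.g - 0.5) ** 2 < 0.25

    def test_empty_histogram_raises(self, cfg):
        with pytest.raises(ValueError):
            phasor_transform(DecayHistogram(np.zeros(cfg.n_bins), cfg.bin_width_ps))


class TestCalibration:
    def test_universal_semicircle_residual(self, cfg, irf):
        """Noiseless calibrated mono-exponentials sit on
        s^2 + (g-1/2)^2 = 1/4 to machine precision."""
        ref = irf_reference(cfg, irf)
        for tau in (0.2, 0.5, 1.0, 2.0, 5.0):
            h = simulate_decay([(1.0, tau)], cfg, 1e6, noiseless=True)
            p = calibrate_phasor(phasor_transform(h), ref, 0.0)
            assert abs(p.s**2 + (p.g - 0.5) ** 2 - 0.25) < 1e-6

    def test_delta_irf_reference_is_near_identity(self, cfg):
        counts = np.zeros(cfg.n_bins)
        counts[0] = 1e6
        ref = phasor_transform(DecayHistogram(counts, cfg.bin_width_ps))
        h = simulate_decay([(1.0, 1.5)], cfg, 1e5, noiseless=True)
        raw = phasor_transform(h)
        cal = calibrate_phasor(raw, ref, 0.0)
        assert cal.g == pytest.approx(raw.g, abs=2e-3)
        assert cal.s == pytest.approx(raw.s, abs=2e-3)

    def test_self_calibration_gives_origin_of_circle(self, cfg, irf):
        ref = irf_reference(cfg, irf)
        p = calibrate_phasor(ref, ref, 0.0)
        assert p.g == pytest.approx(1.0, abs=2e-3)
        assert p.s == pytest.approx(0.0, abs=0.02)

    def test_known_reference_lifetime(self, cfg, irf):
        """Calibrating against a mono decay of known lifetime (not the IRF)
        also lands samples on the semicircle."""
        ref_tau = 1.0
        ref_hist = simulate_decay([(1.0, ref_tau)], cfg, 1e6, noiseless=True)
        ref = phasor_transform(ref_hist)
        h = simulate_decay([(1.0, 2.5)], cfg, 1e6, noiseless=True)
        p = calibrate_phasor(phasor_transform(h), ref, reference_tau_ns=ref_tau)
        assert abs(p.s**2 + (p.g - 0.5) ** 2 - 0.25) < 1e-6
        assert p.phase_lifetime_ns == pytest.approx(2.5, rel=5e-3)

    def test_zero_reference_raises(self, cfg):
        from mitoflim.phasor import PhasorPoint

        zero = PhasorPoint(0.0, 0.0, cfg.omega)
        with pytest.raises(ValueError):
            calibrate_phasor(zero, zero)

    def test_phase_lifetime_matches_fit(self, cfg, irf):
        """tau_phi = s/(g*omega) agrees with the reconvolution fit within
        3% at the 500-photon operating point (averaged over pixels)."""
        from mitoflim import fit_decay

        ref = irf_reference(cfg, irf)
        tau_true = 1.2
        phis, fits = [], []
        for seed in range(10):
            h = simulate_decay([(1.0, tau_true)], cfg, 500, rng=seed)
            p = calibrate_phasor(phasor_transform(h), ref, 0.0)
            phis.append(p.phase_lifetime_ns)
            fits.append(fit_decay(h, irf).tau_av_int)
        assert np.mean(phis) == pytest.approx(np.mean(fits), rel=0.03)


class TestClustering:
    @staticmethod
    def two_population_cloud(cfg, irf, n_side=8, seed=0):
        rngl = np.random.default_rng(seed)
        cube = np.zeros((n_side, 2 * n_side, cfg.n_bins))
        truth = np.zeros((n_side, 2 * n_side), dtype=int)
        c_short = expected_decay_curve([(1.0, 0.6)], cfg, 500.0, irf=irf)
        c_long = expected_decay_curve([(1.0, 1.4)], cfg, 500.0, irf=irf)
        cube[:, :n_side] = rngl.poisson(c_short, size=(n_side, n_side, cfg.n_bins))
        cube[:, n_side:] = rngl.poisson(c_long, size=(n_side, n_side, cfg.n_bins))
        truth[:, n_side:] = 1
        return cube, truth

    def test_two_populations_separate(self, cfg, irf):
        cube, truth = self.two_population_cloud(cfg, irf)
        ref = irf_reference(cfg, irf)
        cloud = phasor_image(cube, cfg.bin_width_ns, reference=ref)
        labels, label_img = cluster_phasor(cloud, k=2, seed=0)
        got = label_img - 1
        agree = max((got == truth).mean(), (got == 1 - truth).mean())
        assert agree >= 0.99

    def test_auto_k_single_population(self, cfg, irf):
        rngl = np.random.default_rng(1)
        curve = expected_decay_curve([(1.0, 1.0)], cfg, 500.0, irf=irf)
        cube = rngl.poisson(curve, size=(10, 10, cfg.n_bins))
        cloud = phasor_image(cube, cfg.bin_width_ns)
        labels, _ = cluster_phasor(cloud, k="auto", seed=0)
        assert len(np.unique(labels)) == 1

    def test_auto_k_two_populations(self, cfg, irf):
        cube, _ = self.two_population_cloud(cfg, irf)
        cloud = phasor_image(cube, cfg.bin_width_ns)
        labels, _ = cluster_phasor(cloud, k="auto", seed=0)
        assert len(np.unique(labels)) == 2

    def test_every_pixel_with_photons_participates(self, cfg, irf):
        """No thresholding: a 1-photon pixel still gets a phasor point."""
        cube = np.zeros((3, 3, cfg.n_bins))
        cube[0, 0, 10] = 1
        cube[2, 2] = 500 * gaussian_irf(cfg).normalized
        cloud = phasor_image(cube, cfg.bin_width_ns)
        assert len(cloud) == 2

    def test_empty_cloud_raises(self, cfg):
        cloud = PhasorCloud(
            g=np.array([]), s=np.array([]), photons=np.array([]),
            pixel_index=np.zeros((0, 2), dtype=int), image_shape=(2, 2), omega=cfg.omega,
        )
        with pytest.raises(ValueError):
            cluster_phasor(cloud)

    def test_k_exceeding_pixels_raises(self, cfg, irf):
        cube = np.zeros((2, 2, cfg.n_bins))
        cube[0, 0, 5] = 10
        cloud = phasor_image(cube, cfg.bin_width_ns)
        with pytest.raises(ValueError):
            cluster_phasor(cloud, k=5)
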