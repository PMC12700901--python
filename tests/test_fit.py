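"""Reconvolution fitting: model curve, chi-square, recovery, model selection."""

import numpy as np
import pytest

from mitoflim import (
    DecayHistogram,
    TCSPCConfig,
    chi2_stat,
    fit_decay,
    fit_flim_image,
    intensity_weighted_lifetime,
    model_curve,
    select_model,
    simulate_decay,
)
from mitoflim.tcspc import IRFCurve

from test_tcspc import delta_irf


class TestModelCurve:
    def test_delta_irf_identity(self, cfg):
        """Convolution with a delta IRF returns the decay itself."""
        y = model_curve([1.0], [2.0], delta_irf(cfg), periodic=False)
        t = cfg.bin_centers_ns
        np.testing.assert_allclose(y / y[0], np.exp(-(t - t[0]) / 2.0), rtol=1e-6)

    def test_one_bin_shift_displaces_curve(self, cfg, irf):
        y0 = model_curve([1.0], [2.0], irf)
        y1 = model_curve([1.0], [2.0], irf, irf_shift=-1.0)
        np.testing.assert_allclose(y1[1:-1], y0[:-2], rtol=1e-9)

    def test_convolution_sum_identity(self, cfg, irf):
        """Total of the convolution = (sum IRF) x (sum decay kernel)."""
        y = model_curve([3.0], [1.5], irf)
        dt = cfg.bin_width_ns
        decay_total = 3.0 * 1.5 / dt  # A*tau/dt, unit-normalized IRF
        assert y.sum() == pytest.approx(decay_total, rel=1e-9)

    def test_mismatched_component_shapes_raise(self, irf):
        with pytest.raises(ValueError):
            model_curve([1.0, 2.0], [1.0], irf)


class TestChi2:
    def test_perfect_fit_is_zero(self):
        obs = np.full(32, 7.0)
        assert chi2_stat(obs, obs)[0] == 0.0

    def test_hand_evaluated_bin(self):
        """A bin with N=4, model 2 contributes (4-2)^2/4 = 1."""
        obs = np.zeros(32)
        exp = np.zeros(32)
        obs[5], exp[5] = 4.0, 2.0
        chi2, _ = chi2_stat(obs, exp)
        assert chi2 == pytest.approx(1.0)

    def test_zero_bins_excluded_from_dof(self):
        obs = np.zeros(32)
        obs[:8] = 5.0
        chi2, chi2_red = chi2_stat(obs, np.full(32, 5.0), n_free=2)
        assert chi2 == 0.0
        # 8 included bins - 2 free params = 6 dof
        obs[0] = 8.0
        chi2, chi2_red = chi2_stat(obs, np.full(32, 5.0), n_free=2)
        assert chi2_red == pytest.approx(chi2 / 6)

    def test_all_zero_histogram_raises(self):
        with pytest.raises(ValueError):
            chi2_stat(np.zeros(32), np.ones(32))

    def test_reduced_chi2_near_one_for_correct_model(self, cfg, irf):
        """Correctly specified fits under Poisson noise: chi2_red ~ 1."""
        vals = []
        for seed in range(40):
            h = simulate_decay([(1.0, 1.5)], cfg, 5000, rng=seed)
            vals.append(fit_decay(h, irf, n=1).chi2_reduced)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)


class TestIntensityWeightedLifetime:
    def test_single_component(self):
        assert intensity_weighted_lifetime([2.0], [1.5]) == 1.5

    def test_two_equal_amplitudes(self):
        # I = A*tau = [1, 3]; tau_av = (1*1 + 3*3)/(1+3) = 2.5
        assert intensity_weighted_lifetime([1.0, 1.0], [1.0, 3.0]) == pytest.approx(2.5)

    def test_zero_amplitude_component_ignored(self):
        assert intensity_weighted_lifetime([2.0, 0.0], [1.0, 5.0]) == pytest.approx(1.0)

    def test_all_zero_amplitudes_raise(self):
        with pytest.raises(ValueError):
            intensity_weighted_lifetime([0.0, 0.0], [1.0, 2.0])

    def test_lies_between_component_lifetimes(self, cfg, irf):
        for seed in range(5):
            h = simulate_decay([(1.0, 0.5), (0.3, 3.0)], cfg, 50000, rng=seed)
            fit = fit_decay(h, irf, n=2)
            assert fit.lifetimes.min() - 1e-9 <= fit.tau_av_int <= fit.lifetimes.max() + 1e-9


def grid_search_oracle(hist, irf, taus, group_target=10):
    """Independent 1-D exhaustive search: for each candidate tau solve the
    amplitude analytically under the same grouped Neyman weighting, return
    the tau minimizing chi2."""
    from mitoflim.fit import _group_edges

    obs = hist.counts.astype(float)
    edges = _group_edges(obs, group_target)
    obs_g = np.add.reduceat(obs, edges)
    nz = obs_g > 0
    w = 1.0 / obs_g[nz]
    best = (np.inf, None)
    for tau in taus:
        shape = np.add.reduceat(model_curve([1.0], [tau], irf), edges)[nz]
        a = (w * obs_g[nz] * shape).sum() / (w * shape**2).sum()
        chi2 = (w * (obs_g[nz] - a * shape) ** 2).sum()
        if chi2 < best[0]:
            best = (chi2, tau)
    return best[1]


class TestFitDecay:
    def test_noiseless_exact_recovery(self, cfg, irf):
        h = simulate_decay([(1.0, 2.0)], cfg, 1e6, noiseless=True)
        fit = fit_decay(h, irf, n=1, fit_window="full")
        assert fit.lifetimes[0] == pytest.approx(2.0, abs=1e-4)
        assert fit.tau_av_int == pytest.approx(2.0, abs=1e-4)

    def test_high_photon_recovery_and_grid_oracle(self, cfg):
        cfg2 = TCSPCConfig(irf_fwhm_ns=0.25)
        from mitoflim import gaussian_irf

        irf2 = gaussian_irf(cfg2)
        h = simulate_decay([(1.0, 1.0)], cfg2, 1e5, rng=11)
        fit = fit_decay(h, irf2, n=1, free_shift=False, free_irf_background=False)
        assert abs(fit.lifetimes[0] - 1.0) < 0.02
        taus = np.arange(0.8, 1.2, 0.005)
        oracle = grid_search_oracle(h, irf2, taus)
        assert abs(fit.lifetimes[0] - oracle) <= 0.005 + 1e-9

    def test_biexponential_recovery(self, cfg, irf):
        # equal component intensities: A1*tau1 = A2*tau2
        h = simulate_decay([(1.0, 0.5), (1 / 6, 3.0)], cfg, 1e6, rng=7)
        fit = fit_decay(h, irf, n=2)
        assert fit.lifetimes[0] == pytest.approx(0.5, rel=0.10)
        assert fit.lifetimes[1] == pytest.approx(3.0, rel=0.10)

    def test_low_photon_moment_fallback(self, cfg, irf):
        h = simulate_decay([(1.0, 1.5)], cfg, 50, rng=3)
        fit = fit_decay(h, irf, n=1)
        assert fit.n == 1
        assert not fit.converged
        assert not fit.accepted

    def test_variance_shrinks_with_photons(self, cfg, irf):
        sds = []
        for photons in (250, 500, 1000, 5000):
            taus = [
                fit_decay(simulate_decay([(1.0, 1.5)], cfg, photons, rng=s), irf).lifetimes[0]
                for s in range(30)
            ]
            sds.append(np.var(taus))
        assert sds == sorted(sds, reverse=True)

    def test_grid_mismatch_raises(self, cfg, irf):
        h = DecayHistogram(np.ones(cfg.n_bins // 2), cfg.bin_width_ps)
        with pytest.raises(ValueError):
            fit_decay(h, irf)


class TestSelectModel:
    def test_mono_data_selects_mono(self, cfg, irf):
        picks = [
            select_model(simulate_decay([(1.0, 1.5)], cfg, 5000, rng=s), irf).n
            for s in range(20)
        ]
        assert np.mean(np.array(picks) == 1) >= 0.9

    def test_biexp_data_selects_biexp(self, cfg, irf):
        picks = [
            select_model(simulate_decay([(1.0, 0.5), (1 / 6, 3.0)], cfg, 1e5, rng=s), irf).n
            for s in range(20)
        ]
        assert np.mean(np.array(picks) == 2) >= 0.9

    def test_fifty_photon_decay_contract(self, cfg, irf):
        fit = select_model(simulate_decay([(1.0, 1.5)], cfg, 50, rng=1), irf)
        assert fit.n == 1 and not fit.accepted


class TestFitImage:
    def test_uniform_image_mean_matches_truth(self, cfg, irf, rng):
        tau_true = 1.0
        from mitoflim.tcspc import expected_decay_curve

        curve = expected_decay_curve([(1.0, tau_true)], cfg, 800)
        cube = rng.poisson(curve, size=(6, 6, cfg.n_bins))
        maps = fit_flim_image(cube, irf)
        taus = maps["tau"][maps["valid"]]
        se = taus.std(ddof=1) / np.sqrt(taus.size)
        assert taus.mean() == pytest.approx(tau_true, abs=max(2 * se, 0.03))

    def test_noiseless_binning_identity(self, cfg, irf):
        """On a noiseless uniform image, binned and unbinned maps agree."""
        from mitoflim.tcspc import expected_decay_curve

        curve = expected_decay_curve([(1.0, 1.2)], cfg, 900)
        cube = np.tile(curve, (5, 5, 1))
        m0 = fit_flim_image(cube, irf, spatial_binning=0)
        m1 = fit_flim_image(cube, irf, spatial_binning=1)
        np.testing.assert_allclose(m0["tau"], m1["tau"], atol=1e-4)

    def test_empty_pixels_flagged_invalid(self, cfg, irf):
        cube = np.zeros((4, 4, cfg.n_bins), dtype=int)
        cube[0, 0] = simulate_decay([(1.0, 1.0)], cfg, 600, rng=0).counts
        maps = fit_flim_image(cube, irf)
        assert maps["valid"][0, 0]
        assert not maps["valid"][1:].any()
        assert np.isnan(maps["tau"][1, 1])
        assert np.isfinite(maps["tau"][0, 0])
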