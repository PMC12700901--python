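"""TCSPC decay containers and the forward photon-counting model.

A pulsed laser at repetition rate ``rep_rate`` (default 80 MHz, i.e. a
12.5 ns observation window) excites the sample; photon arrival times are
histogrammed into ``n_bins`` bins.  Because the window equals the pulse
period, a fluorophore whose decay does not complete within one period wraps
into the next ("incomplete decay"), so the forward model uses a *periodized*
exponential and circular convolution with the instrument response function
(IRF).  Observed counts are independent Poisson draws per bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class TCSPCConfig:
    """Acquisition settings for simulated TCSPC histograms.

    ``n_bins * bin_width`` always equals the pulse period ``1/rep_rate``
    (12.5 ns at 80 MHz); ``bin_width_ps`` is derived so the invariant holds
    by construction.
    """

    rep_rate_MHz: float = 80.0
    n_bins: int = 256
    irf_center_ns: float = 2.0
    irf_fwhm_ns: float = 0.25
    irf_background: float = 0.0  # uniform fraction of IRF counts
    target_photons: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 16:
            raise ValueError("n_bins must be >= 16")
        if self.rep_rate_MHz <= 0:
            raise ValueError("rep_rate must be positive")
        if self.irf_fwhm_ns <= 0:
            raise ValueError("irf_fwhm must be positive")
        if not 0 <= self.irf_background < 1:
            raise ValueError("irf_background is a fraction in [0, 1)")

    @property
    def window_ns(self) -> float:
        return 1e3 / self.rep_rate_MHz

    @property
    def bin_width_ns(self) -> float:
        return self.window_ns / self.n_bins

    @property
    def bin_width_ps(self) -> float:
        return 1e3 * self.bin_width_ns

    @property
    def bin_centers_ns(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns

    @property
    def omega(self) -> float:
        """First-harmonic angular frequency, rad/ns."""
        return 2.0 * np.pi / self.window_ns


@dataclass
class DecayHistogram:
    """Binned photon arrival counts for one pixel or ROI."""

    counts: np.ndarray
    bin_width_ps: float
    t0_ns: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 16:
            raise ValueError("counts must be a 1-D array of length >= 16")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bin_width_ns(self) -> float:
        return self.bin_width_ps * 1e-3

    @property
    def bin_centers_ns(self) -> np.ndarray:
        return self.t0_ns + (np.arange(self.n_bins) + 0.5) * self.bin_width_ns

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class IRFCurve:
    """Instrument response histogram on the same grid as the data it deconvolves."""

    counts: np.ndarray
    bin_width_ps: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("IRF counts must be 1-D")
        if np.any(self.counts < 0) or self.counts.sum() <= 0:
            raise ValueError("IRF counts must be non-negative with positive total")

    @property
    def normalized(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def centroid_ns(self) -> float:
        t = (np.arange(self.counts.size) + 0.5) * self.bin_width_ps * 1e-3
        return float((self.counts * t).sum() / self.counts.sum())


def wrapped_exp_bins(tau_ns: float, n_bins: int, bin_width_ns: float) -> np.ndarray:
    """Per-bin photon fractions of a periodized mono-exponential decay.

    Exact bin integrals of ``sum_m exp(-(t + m*T)/tau)`` on [0, T),
    normalized to unit sum; the geometric tail sum is closed-form.
    """
    if tau_ns <= 0:
        raise ValueError(f"lifetime must be positive, got {tau_ns}")
    rho = np.exp(-bin_width_ns / tau_ns)
    k = np.arange(n_bins)
    w = rho**k * (1.0 - rho)
    return w / w.sum()  # equals division by (1 - rho**n_bins)


def multi_exp_bins(
    components: Sequence[tuple[float, float]], n_bins: int, bin_width_ns: float
) -> np.ndarray:
    """Photon-fraction curve of ``sum_i A_i exp(-t/tau_i)`` (periodized).

    Component photon weights are proportional to ``A_i * tau_i`` (the
    integral of each exponential), matching the intensity weighting used by
    the intensity-weighted mean lifetime.
    """
    if not components:
        raise ValueError("at least one (amplitude, lifetime) component required")
    out = np.zeros(n_bins)
    wsum = 0.0
    for amp, tau in components:
        if amp < 0:
            raise ValueError("amplitudes must be >= 0")
        weight = amp * tau
        out += weight * wrapped_exp_bins(tau, n_bins, bin_width_ns)
        wsum += weight
    if wsum <= 0:
        raise ValueError("all component weights are zero")
    return out / wsum


def gaussian_irf(cfg: TCSPCConfig) -> IRFCurve:
    """Gaussian IRF (plus uniform background fraction), bin-integrated and wrapped."""
    from scipy.special import erf

    sigma = cfg.irf_fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    edges = np.arange(cfg.n_bins + 1) * cfg.bin_width_ns
    acc = np.zeros(cfg.n_bins)
    # wrap a few periods so the tail mass is conserved
    for m in (-1, 0, 1):
        mu = cfg.irf_center_ns + m * cfg.window_ns
        cdf = 0.5 * (1.0 + erf((edges - mu) / (sigma * np.sqrt(2.0))))
        acc += np.diff(cdf)
    acc /= acc.sum()
    curve = (1.0 - cfg.irf_background) * acc + cfg.irf_background / cfg.n_bins
    return IRFCurve(curve, cfg.bin_width_ps)


def circular_convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular (periodic) discrete convolution of equal-length sequences."""
    if a.shape != b.shape:
        raise ValueError("sequences must share length for circular convolution")
    out = np.fft.irfft(np.fft.rfft(a) * np.fft.rfft(b), n=a.size)
    return np.clip(out, 0.0, None)


def expected_decay_curve(
    components: Sequence[tuple[float, float]],
    cfg: TCSPCConfig,
    n_photons: float,
    irf: IRFCurve | None = None,
    background_fraction: float = 0.0,
) -> np.ndarray:
    """Noise-free expected counts per bin, normalized to ``n_photons`` total."""
    if n_photons < 0:
        raise ValueError("n_photons must be >= 0")
    if not 0 <= background_fraction <= 1:
        raise ValueError("background_fraction must lie in [0, 1]")
    if irf is None:
        irf = gaussian_irf(cfg)
    decay = multi_exp_bins(components, cfg.n_bins, cfg.bin_width_ns)
    curve = circular_convolve(irf.normalized, decay)
    curve = curve / curve.sum()
    curve = (1.0 - background_fraction) * curve + background_fraction / cfg.n_bins
    return n_photons * curve

def simulate_decay(
    components: Sequence[tuple[float, float]],
    cfg: TCSPCConfig,
    n_photons: float,
    rng: np.random.Generator | int | None = None,
    irf: IRFCurve | None = None,
    background_fraction: float = 0.0,
    noiseless: bool = False,
) -> DecayHistogram:
    """Simulate one TCSPC histogram for a multi-exponential emitter.

    Parameters
    ----------
    components : sequence of (amplitude, lifetime_ns)
        Pre-exponential factors and lifetimes; photon share of component i
        is proportional to ``A_i * tau_i``.
    cfg : TCSPCConfig
        Acquisition window, binning and IRF shape.
    n_photons : float
        Expected total photons (Poisson mean summed over bins).
    rng : numpy Generator, int seed, or None
        Randomness source; None falls back to ``cfg.seed``.  Identical
        (components, cfg, seed) give bit-identical histograms.
    noiseless : bool
        Return the expected (float) curve instead of Poisson counts.
    """
    curve = expected_decay_curve(components, cfg, n_photons, irf, background_fraction)
    if noiseless:
        return DecayHistogram(curve, cfg.bin_width_ps)
    if rng is None:
        rng = cfg.seed
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts = rng.poisson(curve)
    return DecayHistogram(counts, cfg.bin_width_ps)
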