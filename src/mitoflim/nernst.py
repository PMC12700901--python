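"""Nernstian probe accumulation and concentration-induced quenching.

Cationic mitochondrial probes partition across the inner membrane according
to the membrane potential: at equilibrium the internal/external concentration
ratio of a monovalent cation is exp(-zF*delta_psi/(RT)).  With the
matrix-negative convention (polarized mitochondria have delta_psi < 0) a
polarized mitochondrion concentrates the dye several-hundred-fold.  At high
local concentration the dye self-quenches, which shortens its fluorescence
lifetime; the lifetime therefore reads out membrane potential ordinally
(more polarized -> more accumulated -> shorter lifetime).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.constants import R as GAS_CONSTANT
from scipy.constants import physical_constants

FARADAY = physical_constants["Faraday constant"][0]  # C/mol


@dataclass(frozen=True)
class NernstParams:
    """Equilibrium partitioning parameters for a permeant cation.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.
    valence : int
        Ion charge; +1 for all probes in scope.
    c_out : float
        External (cytosolic) probe concentration in nM.
    delta_psi : float
        Membrane potential in mV, matrix-negative convention:
        polarized mitochondria have ``delta_psi < 0``.
    """

    temperature: float = 310.15
    valence: int = 1
    c_out: float = 250.0
    delta_psi: float = -150.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature) or self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.c_out < 0:
            raise ValueError(f"c_out must be >= 0, got {self.c_out}")
        if self.valence != 1:
            raise ValueError("only monovalent cations (valence=+1) are in scope")
        if not math.isfinite(self.delta_psi):
            raise ValueError("delta_psi must be finite")


def nernst_accumulation(p: NernstParams) -> float:
    """Internal probe concentration (µM) at Nernst equilibrium.

    ``c_in = c_out * exp(-z F dpsi / (R T))``; c_out is given in nM, the
    return value is in µM (factor 1e-3).  For z=+1 and dpsi<0 the ratio
    exceeds 1 and grows e-fold per ~26.7 mV of polarization at 37 °C.
    """
    ratio = accumulation_ratio(p.delta_psi, p.temperature, p.valence)
    return p.c_out * 1e-3 * ratio


def accumulation_ratio(delta_psi_mV: float, temperature_K: float, valence: int = 1) -> float:
    """Dimensionless c_in/c_out ratio; depends only on delta_psi/T (and z)."""
    if not np.all(np.isfinite(delta_psi_mV)):
        raise ValueError("delta_psi must be finite")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    rt_over_f_mV = GAS_CONSTANT * temperature_K / FARADAY * 1e3
    return np.exp(-valence * np.asarray(delta_psi_mV, dtype=float) / rt_over_f_mV)


@dataclass(frozen=True)
class ProbeModel:
    """Concentration–lifetime law and brightness of a potentiometric dye.

    The lifetime follows a decreasing Hill sigmoid in concentration,

        tau(c) = tau_min + (tau_unquenched - tau_min) / (1 + (c/c_half)**hill),

    the minimal monotone family matching the probe's observed dynamic range
    (defaults span 0.2–1.5 ns).  Emission assumes pure dynamic quenching:
    the quantum yield scales with tau, so

        emission = brightness * c * tau(c) / tau_unquenched

    which lets total intensity keep rising while the lifetime falls
    (for hill <= 1).

    Parameters
    ----------
    tau_unquenched, tau_min : float
        Lifetime plateau at infinite dilution / saturating quenching, ns.
    c_half : float
        Concentration of half-maximal lifetime drop, µM.
    hill : float
        Hill exponent (> 0) of the sigmoid.
    brightness : float
        Photons per µM per unit exposure at the unquenched lifetime.
    """

    tau_unquenched: float = 1.5
    tau_min: float = 0.2
    c_half: float = 20.0
    hill: float = 1.0
    brightness: float = 22.0

    def __post_init__(self) -> None:
        if not (0 < self.tau_min < self.tau_unquenched):
            raise ValueError("require 0 < tau_min < tau_unquenched")
        if self.c_half <= 0 or self.hill <= 0:
            raise ValueError("c_half and hill must be positive")
        if self.brightness < 0:
            raise ValueError("brightness must be >= 0")


def probe_response(c, probe: ProbeModel = ProbeModel()):
    """Lifetime (ns) and emission rate (photons/unit exposure) at concentration c (µM).

    Vectorized over ``c``.  Raises for negative concentrations.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError("concentration must be finite and >= 0")
    tau = probe.tau_min + (probe.tau_unquenched - probe.tau_min) / (
        1.0 + (c / probe.c_half) ** probe.hill
    )
    emission = probe.brightness * c * tau / probe.tau_unquenched
    if c.ndim == 0:
        return float(tau), float(emission)
    return tau, emission


def lifetime_for_potential(
    delta_psi_mV,
    probe: ProbeModel = ProbeModel(),
    temperature_K: float = 310.15,
    c_out_nM: float = 250.0,
):
    """Ground-truth lifetime (ns) and emission for a membrane potential (mV).

    Composition of Nernst accumulation with the quenching law; monotone:
    more-negative potentials never increase the lifetime and never decrease
    the expected emission over physiological ranges.
    """
    ratio = accumulation_ratio(delta_psi_mV, temperature_K)
    c_in = c_out_nM * 1e-3 * ratio
    return probe_response(c_in, probe)
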