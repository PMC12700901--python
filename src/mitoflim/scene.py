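"""Ground-truth scenes and FLIM stack rendering.

A scene is a set of mitochondria-shaped objects (ellipses, optionally
elongated and rotated) on a dark background, each carrying its own membrane
potential.  Rendering composes the physics chain per pixel:

    delta_psi --Nernst--> local dye concentration --quenching law-->
    (lifetime, emission rate) --TCSPC--> Poisson photon histogram

Polarized objects are therefore simultaneously *brighter* and
*shorter-lived* — the anticorrelation that makes the probe's lifetime an
ordinal membrane-potential readout.  Background pixels carry a dim
"unbound dye" component with a fixed long lifetime (1.7 ns default; the
true value in cells is unknown and the default is arbitrary).

Objects move with a per-frame drift plus diffusion jitter, and scheduled
transient depolarization events ("flashes") shift an object's potential for
a window of frames, elevating its lifetime and dimming it until recovery.
All randomness flows from a single seed; identical (scene, config, seed)
render bit-identical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .nernst import NernstParams, ProbeModel, accumulation_ratio, probe_response
from .tcspc import TCSPCConfig, expected_decay_curve, gaussian_irf


@dataclass
class Mitochondrion:
    """One elliptical object with its own membrane potential."""

    center: tuple[float, float]  # (row, col) px
    axes: tuple[float, float] = (4.0, 2.0)  # semi-axes, px
    angle: float = 0.0  # rad, counter-clockwise
    delta_psi: float = -150.0  # mV, matrix-negative
    velocity_um: tuple[float, float] = (0.0, 0.0)  # drift per frame
    diffusion_sd_um: float = 0.0


@dataclass
class TransientEvent:
    """Scheduled depolarization: potential shifted by ``delta_psi_shift``
    (positive = toward zero, i.e. depolarizing) on [onset, onset+duration)."""

    object_id: int
    onset_frame: int
    duration_frames: int
    delta_psi_shift: float  # mV


@dataclass
class SimScene:
    shape: tuple[int, int] = (48, 48)
    pixel_size_um: float = 0.1
    mitochondria: list[Mitochondrion] = field(default_factory=list)
    nucleus_centroid: tuple[float, float] | None = None  # (row, col) px
    background_rate: float = 2.0  # photons/pixel
    background_tau_ns: float = 1.7
    n_frames: int = 1
    events: list[TransientEvent] = field(default_factory=list)

    def validate(self) -> None:
        h, w = self.shape
        for i, m in enumerate(self.mitochondria):
            r, c = m.center
            rad = max(m.axes)
            if not (rad <= r <= h - 1 - rad and rad <= c <= w - 1 - rad):
                raise ValueError(f"object {i} extends outside image bounds")
        for ev in self.events:
            if ev.onset_frame < 0 or ev.onset_frame + ev.duration_frames > self.n_frames:
                raise ValueError(f"event on object {ev.object_id} outside [0, n_frames)")
            if not 0 <= ev.object_id < len(self.mitochondria):
                raise ValueError(f"event references unknown object {ev.object_id}")


@dataclass
class RenderedStack:
    """Simulated FLIM stack plus its ground truth."""

    counts: np.ndarray  # (n_frames, H, W, n_bins) uint32
    cfg: TCSPCConfig
    tau_map: np.ndarray  # (n_frames, H, W) ground-truth lifetime, ns
    intensity_map: np.ndarray  # expected photons/pixel
    label_mask: np.ndarray  # (n_frames, H, W) object_id+1, 0=background
    objects: pd.DataFrame  # frame, object_id, row, col, delta_psi_mV, c_in_uM, tau_ns
    events: list[TransientEvent]
    scene: SimScene


def _ellipse_mask(shape, center, axes, angle) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def render_scene(
    scene: SimScene,
    probe: ProbeModel | None = None,
    nernst: NernstParams | None = None,
    cfg: TCSPCConfig | None = None,
    seed: int | None = None,
) -> RenderedStack:
    """Render a scene into a TCSPC FLIM stack with known ground truth.

    ``nernst.delta_psi`` is ignored; each object supplies its own potential.
    The per-pixel expected photon count is the probe's emission rate at the
    object's internal concentration (brightness is calibrated so the default
    polarized object lands near the 500 photons/pixel operating point).
    """
    probe = probe or ProbeModel()
    nernst = nernst or NernstParams()
    cfg = cfg or TCSPCConfig()
    scene.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    h, w = scene.shape
    nf, nb = scene.n_frames, cfg.n_bins
    counts = np.zeros((nf, h, w, nb), dtype=np.uint32)
    tau_map = np.full((nf, h, w), scene.background_tau_ns)
    inten_map = np.full((nf, h, w), float(scene.background_rate))
    labels = np.zeros((nf, h, w), dtype=np.int32)
    rows = []

    # per-object diffusion random walks, drawn up front in a fixed order
    px = scene.pixel_size_um
    n_obj = len(scene.mitochondria)
    steps = np.zeros((n_obj, nf, 2))
    for i, m in enumerate(scene.mitochondria):
        if m.diffusion_sd_um > 0 and nf > 1:
            steps[i, 1:] = rng.normal(0.0, m.diffusion_sd_um / px, size=(nf - 1, 2))
    walks = steps.cumsum(axis=1)

    bg_curve = expected_decay_curve(
        [(1.0, scene.background_tau_ns)], cfg, max(scene.background_rate, 0.0)
    )

    for f in range(nf):
        shifts = {ev.object_id: ev.delta_psi_shift for ev in scene.events
                  if ev.onset_frame <= f < ev.onset_frame + ev.duration_frames}
        # background everywhere first; objects overwrite
        frame_counts = rng.poisson(bg_curve, size=(h, w, nb))
        for i, m in enumerate(scene.mitochondria):
            drift = (np.asarray(m.velocity_um) / px) * f
            center = np.asarray(m.center) + drift + walks[i, f]
            mask = _ellipse_mask((h, w), center, m.axes, m.angle)
            dpsi = m.delta_psi + shifts.get(i, 0.0)
            c_in = nernst.c_out * 1e-3 * accumulation_ratio(dpsi, nernst.temperature)
            tau, emission = probe_response(c_in, probe)
            curve = expected_decay_curve([(1.0, tau)], cfg, emission)
            npix = int(mask.sum())
            if npix:
                frame_counts[mask] = rng.poisson(curve, size=(npix, nb))
            tau_map[f][mask] = tau
            inten_map[f][mask] = emission
            labels[f][mask] = i + 1
            rows.append(
                dict(frame=f, object_id=i, row=center[0], col=center[1],
                     delta_psi_mV=dpsi, c_in_uM=c_in, tau_ns=tau,
                     emission=emission, area_px=npix)
            )
        counts[f] = frame_counts

    return RenderedStack(
        counts=counts,
        cfg=cfg,
        tau_map=tau_map,
        intensity_map=inten_map,
        label_mask=labels,
        objects=pd.DataFrame(rows),
        events=list(scene.events),
        scene=scene,
    )


# ---------------------------------------------------------------------------
# Canonical study scenes
# ---------------------------------------------------------------------------

def two_population_scene(
    seed: int = 0,
    shape: tuple[int, int] = (48, 48),
    n_per_group: int = 5,
    dpsi_polarized: float = -150.0,
    dpsi_depolarized: float = -60.0,
) -> SimScene:
    """Two spatially interleaved object populations at different potentials.

    Emulates a drug-treatment contrast: the depolarized population is dimmer
    and longer-lived.  Objects are laid out on a jittered grid with >= 3 px
    clearance so segmentation can recover them.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    cells = []
    grid = []
    nx = int(np.ceil(np.sqrt(2 * n_per_group)))
    for gy in range(nx):
        for gx in range(nx):
            grid.append((gy, gx))
    rng.shuffle(grid)
    pitch_r, pitch_c = (h - 12) / nx, (w - 12) / nx
    dps = [dpsi_polarized] * n_per_group + [dpsi_depolarized] * n_per_group
    for (gy, gx), dpsi in zip(grid, dps):
        r = 6 + (gy + 0.5) * pitch_r + rng.uniform(-1, 1)
        c = 6 + (gx + 0.5) * pitch_c + rng.uniform(-1, 1)
        cells.append(
            Mitochondrion(
                center=(r, c),
                axes=(rng.uniform(2.4, 3.0), rng.uniform(1.3, 1.8)),
                angle=rng.uniform(0, np.pi),
                delta_psi=dpsi,
            )
        )
    return SimScene(shape=shape, mitochondria=cells, nucleus_centroid=(h / 2, w / 2))


def gradient_scene(
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    n_objects: int = 12,
    dpsi_perinuclear: float = -80.0,
    dpsi_peripheral: float = -160.0,
) -> SimScene:
    """Radial membrane-potential gradient around a central nucleus.

    Peripheral mitochondria are more polarized (metabolically active) than
    perinuclear ones, so ground-truth lifetime *decreases* with distance
    from the nucleus: the distance-lifetime rank correlation is negative.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    nucleus = (h / 2, w / 2)
    rmin, rmax = 8.0, min(h, w) / 2 - 7.0
    cells = []
    for i in range(n_objects):
        radius = rmin + (rmax - rmin) * (i + rng.uniform(0, 0.6)) / n_objects
        theta = rng.uniform(0, 2 * np.pi)
        r = nucleus[0] + radius * np.sin(theta)
        c = nucleus[1] + radius * np.cos(theta)
        r = float(np.clip(r, 6, h - 7))
        c = float(np.clip(c, 6, w - 7))
        frac = (radius - rmin) / (rmax - rmin)
        dpsi = dpsi_perinuclear + frac * (dpsi_peripheral - dpsi_perinuclear)
        cells.append(
            Mitochondrion(
                center=(r, c),
                axes=(rng.uniform(2.5, 3.5), rng.uniform(1.5, 2.0)),
                angle=rng.uniform(0, np.pi),
                delta_psi=dpsi + rng.normal(0, 4.0),
            )
        )
    return SimScene(shape=shape, mitochondria=cells, nucleus_centroid=nucleus)


def event_scene(
    seed: int = 0,
    shape: tuple[int, int] = (36, 36),
    n_frames: int = 40,
    events: list[TransientEvent] | None = None,
) -> SimScene:
    """Time-lapse scene with scheduled transient depolarizations.

    Two slowly drifting polarized objects; the default schedule gives
    object 0 one +90 mV depolarization (frames 12-17) — a sudden potential
    drop followed by recovery, visible as a lifetime spike on its track.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    cells = [
        Mitochondrion(center=(h * 0.3, w * 0.3), axes=(3.5, 2.0),
                      angle=rng.uniform(0, np.pi), delta_psi=-150.0,
                      velocity_um=(0.02, 0.015), diffusion_sd_um=0.01),
        Mitochondrion(center=(h * 0.7, w * 0.65), axes=(3.5, 2.0),
                      angle=rng.uniform(0, np.pi), delta_psi=-150.0,
                      velocity_um=(-0.015, 0.02), diffusion_sd_um=0.01),
    ]
    if events is None:
        events = [TransientEvent(object_id=0, onset_frame=12, duration_frames=6,
                                 delta_psi_shift=90.0)]
    return SimScene(shape=shape, mitochondria=cells, nucleus_centroid=(h / 2, w / 2),
                    n_frames=n_frames, events=events)


def z_stack_decays(
    seed: int = 0,
    n_planes: int = 8,
    tau_ns: float = 0.8,
    surface_photons: float = 2000.0,
    attenuation_per_plane: float = 0.25,
    cfg: TCSPCConfig | None = None,
):
    """Depth series: constant true lifetime, exponentially attenuated intensity.

    Emulates focal drift / scattering through a thick specimen: the photon
    budget falls ~25%/plane while the underlying lifetime is depth-
    invariant.  Returns (histograms, expected_photons_per_plane).
    """
    from .tcspc import simulate_decay

    cfg = cfg or TCSPCConfig()
    rng = np.random.default_rng(seed)
    photons = surface_photons * (1.0 - attenuation_per_plane) ** np.arange(n_planes)
    hists = [simulate_decay([(1.0, tau_ns)], cfg, p, rng=rng) for p in photons]
    return hists, photons
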