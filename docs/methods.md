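# Methods

This note documents the models, numerical choices and limitations behind
`mitoflim`, in the order the data flows: physics → photon counting →
lifetime estimation → phasor → morphology → statistics.

## Probe physics

**Nernst partitioning.** A monovalent cationic probe equilibrates across
the inner membrane as `c_in = c_out · exp(−zFΔψ/RT)` (matrix-negative
convention: polarized mitochondria have Δψ < 0, z = +1 for all probes in
scope). Physical constants come from `scipy.constants`; at 310.15 K the
e-fold scale RT/F is 26.73 mV, so −61.5 mV concentrates the dye ~10-fold
and −150 mV ~274-fold. Defaults: T = 310.15 K, c_out = 250 nM (a typical
staining concentration).

**Concentration quenching.** The lifetime–concentration law is a
decreasing Hill sigmoid

    τ(c) = τ_min + (τ_0 − τ_min) / (1 + (c/c_half)^h),

the minimal monotone family matching the probe's observed behaviour: flat
at low concentration, then a monotone drop spanning a 1.5 → 0.2 ns dynamic
range (the defaults `τ_0 = 1.5 ns`, `τ_min = 0.2 ns`). `c_half = 20 µM`
places the onset of self-quenching where it is observed for this dye class
in solution; `h = 1` by default. Both are free, per-probe parameters.

**Emission.** Pure dynamic quenching is assumed: the quantum yield scales
with the lifetime, so `emission = brightness · c · τ(c)/τ_0`. With h ≤ 1
intensity keeps rising as lifetime falls — the characteristic
anticorrelation. The very-high-concentration intensity *decline* seen in
cuvettes is reproduced only for h > 1 and is not treated as an invariant.
`brightness = 22 photons/µM` is calibrated so a fully polarized object
(−150 mV at 250 nM external) lands at ≈500 photons/pixel, the standard
acquisition operating point. The simulator works in effective local
concentration; no two-dimensional membrane-partition model is attempted
(absolute membrane concentrations are not quantifiable anyway).

## TCSPC forward model

The excitation window equals the pulse period (12.5 ns at 80 MHz, 256 bins
by default), so decays that do not complete within one period wrap into
the next. The simulator therefore uses *periodized* exponentials with
exact per-bin integrals (closed-form geometric sums) and circular
convolution with the IRF. The Gaussian IRF is bin-integrated via the error
function and wrapped; a uniform IRF-background fraction is supported, as
are measured IRF histograms. Expected curves are normalized so the total
equals the requested photon count; observed counts are independent Poisson
draws per bin from a single seeded generator. Identical (scene, config,
seed) produce bit-identical stacks.

Multi-component decays weight each component's photon share by `A_i·τ_i`
(its integral), consistent with the intensity weighting used downstream.

**Scenes.** Objects are rotated ellipses with per-object Δψ; background
pixels carry a dim "unbound dye" component at 1.7 ns — an arbitrary,
documented default, since the unbound lifetime in cells is not known.
Motion is per-frame drift plus a diffusion random walk (µm units,
converted by the pixel size); scheduled events shift an object's Δψ for a
frame window and recover. Pixels take the single lifetime of their object
(no intra-pixel mixing by default). Canonical study scenes:
`two_population_scene` (−150 vs −60 mV, a drug-treatment-style contrast),
`gradient_scene` (radially increasing polarization, emulating
perinuclear-vs-peripheral heterogeneity), `event_scene` (transient
depolarizations on moving objects), `z_stack_decays` (depth-attenuated
intensity at constant lifetime).

## Reconvolution fitting

The model is `y(t) = {IRF(t + Shift) + Bkgr_IRF} ⊗ {Σ A_i e^(−t/τ_i) +
Bkgr}` with fractional-bin IRF shift by linear interpolation and the same
periodic convolution as the simulator (a linear mode exists for aperiodic
data). The IRF is normalized to unit sum inside the model; its physical
scale is absorbed by the amplitudes.

**The χ² statistic.** Goodness of fit is the Neyman form
`Σ (N − N_c)²/N` with observed-count denominators; zero-count groups are
excluded from both the sum and the degrees of freedom
(`points − free parameters`). Neyman weights are known to bias fits when
individual bins hold only a few photons (the 1/N weights over-reward
under-shooting the sparse tail: at 500 photons over 256 bins the lifetime
bias reaches tens of percent). The classical remedy — require a minimum
expected count per χ² cell — is applied by *adaptive grouping*: within the
fit window, consecutive bins are pooled until each group holds at least 10
photons, while the model stays on the fine grid and is summed over the
same groups. This keeps the printed statistic and restores accuracy
(median lifetime error ≈3% at 500 photons, ≈2% at 5,000). `group_target=0`
recovers raw per-bin weighting.

**Fit window.** By default from 10% of the rising edge (on lightly
smoothed data) to the end of the window; with the periodic model the
pre-rise bins contain the wrapped tail, so masking them loses a little
information but introduces no bias (model and data are masked
identically). A `full` window is available.

**Optimization.** Bounded trust-region least squares
(`scipy.optimize.least_squares`) over {A_i, τ_i, Bkgr, Shift_IRF,
Bkgr_IRF}, initialized from the fast-FLIM moment estimate (mean arrival
time minus IRF centroid; components spread geometrically around it for
n > 1), with up to 3 restarts from multiplicatively perturbed starts drawn
from a fixed seed. Shift bounds are ±3 bins. Decays under the 100-photon
floor return a moment estimate flagged `converged=False`; non-convergence
never raises. Model selection fits n = 1, 2, 3 in order and keeps the
first fit with reduced χ² < 1.3 (the conventional acceptance bound of
commercial FLIM software, read as *reduced* χ²); if none qualifies the
best is returned flagged `accepted=False`.

**Image fitting.** Per-pixel fits optionally sum (2b+1)² neighborhoods
before fitting (`spatial_binning=b`) and fix Shift_IRF and Bkgr_IRF at
zero: neither is identifiable at ~500 photons and both are instrument
properties, not pixel properties. Pixels under the photon floor are
flagged invalid (NaN) and excluded from every downstream mean.

## Phasor analysis

`g + is = Σ N_k e^(iωt_k) / Σ N_k` at the first harmonic (ω = 2π·rep
rate), bin centers, no apodization, no thresholding — every pixel with ≥1
photon participates. Because histograms record bin sums, the raw transform
of a mono-exponential is off the universal semicircle by a half-bin phase
and a `cos(ωΔ/2)` amplitude factor; when the window equals the pulse
period these corrections are exact closed forms (for a bin-integrated
wrapped exponential, `1/P = cos(ωΔ/2)·[1 − i·tan(ωΔ/2)·coth(Δ/2τ)]`).
Calibration divides the sample phasor by a reference phasor (the IRF, or
any mono decay of known lifetime) and multiplies by the discrete ideal
phasor of the reference lifetime, which lands noiseless mono-exponentials
on the semicircle to machine precision and makes mixtures exact convex
combinations. Clustering is photon-weighted k-means in (g, s) with a fixed
seed; `k="auto"` picks the silhouette-best k in 2..4 and falls back to one
cluster when the best split scores below 0.5 (an unsplit unimodal cloud).
The clustering algorithm itself is a documented stand-in — validated on
synthetic separability only.

## Segmentation and tracking

Segmentation runs on the photon-count map (intensity carries the
object/background contrast); the lifetime map is sampled afterwards.
Chain: median filter (disk radius 1) → rolling-ball background
subtraction (radius 20 px — larger than any object half-width) → Otsu
threshold on a 256-bin histogram → opening (disk radius 1) → removal of
objects under 4 px². The rolling-ball background is the classical
morphological form — grayscale opening with the ball height profile —
rather than the single-pass "apex" approximation some libraries use. The
full-pipeline driver thresholds on `log(1+I)`: with membrane potentials
differing by ~90 mV the two object populations differ ~10-fold in
brightness, and a linear-scale Otsu merges the dim population into the
background class. Components are 8-connected (thin curvilinear objects
fragment under 4-connectivity). Per object: centroid, area, total
photons, photon-weighted mean lifetime over valid pixels, and mean pixel
distance to the (manually supplied) nucleus centroid. None of the radii
are prescribed by the imaging protocol this mirrors; all are defaults
validated on synthetic scenes only.

Tracking is a Simple LAP tracker: squared centroid distance costs, links
beyond `max_link_dist` forbidden, birth/death at 1.05·max_link_dist²
(the standard alternative-cost convention), solved exactly by the
Hungarian algorithm on the augmented matrix; then gap closing reconnects
track ends to later starts within `max_gap` frames and `gap_dist`,
lowest-cost first. Deterministic throughout.

## Statistics

- Spearman ρ uses average (tie-corrected) ranks; two-sided p by exhaustive
  permutation for n ≤ 9, t-approximation otherwise.
- Condition contrasts: Welch's unequal-variance t-test by default (safer
  than Student's and identical in the equal-variance limit), paired t on
  request; Δτ is treated-minus-control with per-group SEM. No
  multiple-testing correction is applied — the readouts are single planned
  comparisons.
- Event detection: baseline is a 15-frame running median per track;
  frames exceeding baseline by ≥0.2 ns (≈ the fit noise floor at 500
  photons) for ≥2 consecutive frames form one event with onset, exclusive
  offset and peak excursion. Events lasting longer than about half the
  baseline window would contaminate the median and should be detected
  with a wider window.
- z-stability: coefficient of variation uses the sample standard
  deviation (ddof = 1).

## Problem sizes and what the tests show

Synthetic experiments run at desk scale: 48–64 px scenes with ~10 objects,
single frames for contrast/gradient readouts, 40-frame stacks for
time-lapse, 100-decay ensembles for recovery and χ² calibration. Passing
tests demonstrate internal consistency of the chain — the estimator
recovers what the generator wrote, ordinally and quantitatively — under
idealized conditions: single-lifetime objects, Gaussian IRF, Poisson-only
noise, no afterpulsing or dark counts, no photobleaching, no 3-D optics
(the PSF, scattering and depth attenuation are not modelled beyond a
schematic intensity decay), no absolute Δψ calibration. In particular the
lifetime→potential map is monotone by construction; on real data only
relative/ordinal Δψ contrasts are supported, and no absolute millivolt
inference is claimed anywhere.
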