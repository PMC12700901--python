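# mitoflim

Mitochondrial membrane potential (Δψ_m) imaging by fluorescence lifetime:
a simulation and analysis toolkit for concentration-quenched potentiometric
FLIM.

## The problem and the model

Cationic mitochondrial dyes accumulate across the inner membrane according
to the Nernst equation,

    c_in / c_out = exp(−zFΔψ / RT),

so a polarized mitochondrion (Δψ ≈ −150 mV) concentrates a monovalent
cation several-hundred-fold. At high local concentration such dyes
self-quench: the fluorescence lifetime drops monotonically with
concentration (modelled here as a Hill sigmoid spanning 1.5 → 0.2 ns) while
total emission can keep rising. The lifetime of the probe therefore reads
out membrane potential *ordinally* — more polarized → more dye → shorter
lifetime and brighter signal — without the intensity artifacts
(path length, focus, bleaching) that plague intensity-based Δψ_m probes.

`mitoflim` implements both sides of this experiment:

- **Forward simulation** (`nernst`, `tcspc`, `scene`): Δψ-annotated
  mitochondria-shaped scenes rendered into per-pixel TCSPC photon
  histograms (80 MHz excitation, 12.5 ns window, Gaussian IRF, Poisson
  statistics at the ~500 photons/pixel operating point), with full ground
  truth (lifetime maps, object masks, motion, scheduled transient
  depolarization events).
- **Lifetime fitting** (`fit`): n-exponential reconvolution
  `y(t) = {IRF(t + Shift) + Bkgr_IRF} ⊗ {Σ A_i e^(−t/τ_i) + Bkgr}`,
  minimizing the Neyman χ² `Σ [N(t_k) − N_c(t_k)]² / N(t_k)` on adaptively
  grouped bins, with model selection at the reduced χ² < 1.3 acceptance
  bound and the intensity-weighted mean lifetime
  `τ_AvInt = Σ I_k τ_k / Σ I_k`, `I_k = A_k τ_k`.
- **Phasor analysis** (`phasor`): first-harmonic (g, s) transform, IRF
  calibration with exact finite-bin corrections, and photon-weighted
  clustering of pixels with similar lifetimes.
- **Segmentation & tracking** (`segment`, `tracking`): median filter →
  rolling-ball background → Otsu → opening → labeling → per-object
  photon-weighted lifetime and nucleus distance → Simple-LAP tracking with
  gap closing.
- **Heterogeneity statistics** (`stats`): distance–lifetime Spearman
  correlation (exact permutation p for small n), Welch/paired t contrasts
  with SEM, transient-event detection on lifetime tracks, and z-stack
  coefficient-of-variation summaries.

## Worked example

Render a scene with two object populations (−150 mV vs −60 mV), fit every
pixel, segment, and compare the recovered per-object lifetimes:

```python
import mitoflim as mf
from mitoflim.pipeline import measure_stack

scene = mf.two_population_scene(seed=1)
stack = mf.render_scene(scene, seed=1)          # (1, 48, 48, 256) photon counts
objects, _, _ = measure_stack(stack)            # fit -> segment -> measure

truth = stack.objects.set_index("object_id")["delta_psi_mV"]
psi = objects.true_object_id.map(truth)
depol = objects.loc[psi > -100, "mean_tau_ns"]
polar = objects.loc[psi <= -100, "mean_tau_ns"]
print(mf.compare_conditions(depol, polar))
```

Output:

```
polarized (-150 mV):  n=5, tau = 0.484 +/- 0.002 ns
depolarized (-60 mV): n=5, tau = 1.297 +/- 0.028 ns
delta_tau = 0.813 ns, Welch t = 28.52, p = 7.96e-06
```

The depolarized population is read out ~0.8 ns longer-lived, matching the
generating physics (ground truth 0.494 ns at −150 mV vs 1.363 ns at
−60 mV): the polarized objects concentrate ~68 µM of dye and quench, the
depolarized ones hold ~2 µM and stay near the unquenched lifetime. Note the
anticorrelation — the short-lifetime objects are also the bright ones
(~500 vs ~50 photons/pixel).

A command-line interface mirrors the library
(`mitoflim simulate|fit-decay|fit-image|phasor|segment|track|report`);
see `mitoflim --help`.

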