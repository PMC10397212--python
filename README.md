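# endomat

Tools for studying how very early (APPL1-positive) endosomes mature into
early (EEA1-positive) endosomes from whole-cell, two-channel volumetric
live imaging — and for simulating the "trigger-and-convert" mechanism
that explains why inter-endosomal collisions accelerate that switch.

The package is aimed at quantitative cell biologists working with fast
volumetric two-colour movies (lattice light-sheet or similar) and
time-resolved (TCSPC/FLIM) data. It has four parts:

* **`endomat.syndata`** — a synthetic-data generator: endosomes with
  run-and-pause motility in a reflecting box, scripted collisions /
  fusions / APPL1→EEA1 conversions, Gaussian-blob volumetric rendering
  with Poisson + read noise, and two-exponential TCSPC photon
  histograms. The latent tracks and scripted event log are the ground
  truth the analysis stages are validated against.
* **`endomat.detect` / `endomat.track` / `endomat.events`** — the
  imaging pipeline: multiscale Laplacian-of-Gaussian over-detection with
  brightest/dimmest-template 2-means validation; Crocker–Grier-style
  linking on position *and* log-intensity; and event classification —
  collisions are sub-200-nm local minima of the pairwise surface
  separation, maturation events are cotracking episodes that end in
  APPL1 loss, split into fusion vs conversion (did the EEA1 track
  pre-exist?) and collision-induced vs unaided (any heterotypic
  collision within the preceding 30 s?), summarised as cohort heatmaps
  over (cotracking duration × preceding collisions).
* **`endomat.flim`** — fixed two-lifetime TCSPC unmixing
  (τ₁ = 1.006 ns FRET/N-terminal, τ₂ = 2.600 ns C-terminal) by Poisson
  maximum likelihood, yielding per-pixel NT-EEA1/CT-EEA1 channel images,
  N:C ratio traces, and fusion-pair categories (N/C/A).
* **`endomat.endosim`** — an agent-based simulator of one endosome
  surface: a bi-layered Fibonacci-sphere lattice where APPL1, N-/C-
  terminal EEA1 and the phosphatase INPP4A compete for Rab5 and
  phosphoinositide sites with clustering feedback; a collision injects a
  pulse of N-terminal EEA1; conversion is the first-passage time of the
  PI(3,4)P₂→PI(3)P fraction over 60%.

## The model in brief

On the surface lattice, node *i* carries a Rab5 site and a lipid site.
Attachment and detachment are Markovian with local feedback,

    p_attach = k_on · dt · (1 + α · n_same),
    p_detach = k_off · dt · (1 + β · n_recently_detached),

subject to each species' site requirements (APPL1 needs Rab5 + adjacent
PI(3,4)P₂; NT-EEA1 only Rab5; CT-EEA1 Rab5 + adjacent PI(3)P; INPP4A a
protein-free PI(3,4)P₂, which it converts irreversibly to PI(3)P with a
fixed per-step probability before jumping to a nearby free substrate).
A collision at time t_c adds up to M NT-EEA1 to free Rab5 sites during
[t_c, t_c + w]. The conversion time is

    T = inf{ t : N_PI3P(t) / N_nodes ≥ 0.60 },

and ensembles of runs under Poisson-random collisions are stratified by
the number of collisions experienced before T; each stratum is
summarised by its 10-s-bin histogram mode.

## Worked example

```python
import numpy as np
from endomat.endosim import DEFAULT_PARAMS, run, ensemble
from endomat.flim import DecayModel, fit_decay
from endomat.syndata import simulate_flim_photons

trace = run(DEFAULT_PARAMS, seed=7)
print(f"conversion time: {trace.conversion_time:.1f} s "
      f"after {trace.n_collisions_before_conversion} collision(s)")

res = ensemble(DEFAULT_PARAMS, n_reps=200, seed=7)
for k, mode in sorted(res.modes().items()):
    print(f"{k}-collision stratum: mode {mode:.0f} s "
          f"(n={len(res.stratum_times(k))})")

model = DecayModel()
_, counts = simulate_flim_photons(0.7, 10_000, model, seed=7)
fit = fit_decay(counts, model)
print(f"fitted N-terminal photon fraction: {fit.f_n:.3f} (true 0.700)")
```

prints

```
conversion time: 139.6 s after 2 collision(s)
0-collision stratum: mode 145 s (n=62)
1-collision stratum: mode 65 s (n=109)
2-collision stratum: mode 45 s (n=28)
fitted N-terminal photon fraction: 0.693 (true 0.700)
```

The single run converted 139.6 s into the simulation after two
collisions. In the ensemble, endosomes that never collided convert
slowest (mode 145 s), one collision roughly halves the conversion time,
and two collisions halve it again — the collision-as-trigger effect.
The FLIM fit recovers the N-terminal photon fraction of a 10⁴-photon
two-lifetime decay to within ~0.01.

A command-line interface mirrors the library (`endomat simulate-movie`,
`endomat detect`, `endomat track`, `endomat events`, `endomat evaluate`,
`endomat flim-unmix`, `endomat endosim run|ensemble|calibrate`); run
`endomat --help` for details.

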