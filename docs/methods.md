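# Methods

This note documents the models, the numerical choices, and the known
limitations of the package. It is written for users who want to know what
the computations assume, not just what the functions return.

## Synthetic ground truth (`endomat.syndata`)

The generator stands in for two-channel (APPL1 / EEA1) volumetric
live-cell movies of early endosomes. It produces a latent track table, a
scripted event log, and a rendered noisy movie; the latent state is the
oracle every downstream stage is scored against.

**Motility.** Each endosome follows a two-state run-and-pause process:
runs translate at `run_speed` (default 0.5 µm/s) along a direction that
persists for the duration of the run; pauses are isotropic diffusion with
coefficient `pause_diffusion` (default 0.01 µm²/s). Switching is
Markovian (default 0.2 s⁻¹ both ways) and the box walls reflect. Volumes
are sampled every 3 s, the whole-cell volumetric rate of the imaging this
emulates. The ensemble mean-squared displacement of this process has a
closed form (persistent-run cross terms decay with the run survival
probability per frame), which the test suite checks at 10³ tracks.

**Scripted events.** Collisions steer the EEA1 partner so the pair's
surface separation dips to 50 nm at the scripted frame and relaxes over
±3 frames. Conversions switch one endosome's channel identity with a
switch-like profile: EEA1 rises over the first ~30% of the cotracking
window while APPL1 holds, then APPL1 decays over the last ~30%. (A
symmetric linear crossfade leaves almost no window in which both markers
are simultaneously detectable, which no real conversion shows; converting
endosomes display an EEA1 jump while APPL1 is still present.) Fusions
walk the APPL1 endosome onto its EEA1 partner along a bounded-step
approach path (≤1.2 µm/frame, a directed-run displacement), merge the
positions, and decay the APPL1 signal over the cotracking window.

**Rendering.** Each endosome is an anisotropic Gaussian blob with
per-axis width `sqrt((r/√3)² + psf²)`, integrating to its channel
brightness in expected photons; Poisson shot noise and Gaussian read
noise are applied per voxel. The default geometry is a 96×96×16 volume
with 0.104×0.104×0.268 µm voxels (light-sheet-like anisotropy). SNR is
defined as peak blob amplitude over the background noise sd and is a
sweep parameter; the reference scene uses SNR 5 with per-track brightness
spread log-uniformly up to 2.5× above that floor, because brightness
heterogeneity is what makes intensity informative for linking.

**Reference scene.** Ten endosomes (five per channel) in a
9.98×9.98×4.29 µm box, 100 frames, with three scripted collisions, one
collision-induced conversion, one unaided conversion, and two fusions.
Radii are drawn in [0.18, 0.45] µm — inside the detector's configured
size range, since the scene validates tracking and event logic, not
sub-resolution detection limits. What passing tests on this scene do
*not* show: performance on real movies with autofluorescent background
structure, optical aberrations, depth-dependent SNR, or endosome
densities far above ten per field.

**TCSPC photons.** Photon arrival times are drawn from
`f_N·Exp(τ₁) + (1−f_N)·Exp(τ₂)` with τ₁ = 1.006 ns and τ₂ = 2.600 ns,
convolved with a Gaussian instrument response (σ = 0.1 ns, centred 2 ns
into a 12.5 ns window); out-of-window arrivals are redrawn so histograms
hold exactly the requested photon count.

## Detection (`endomat.detect`)

Each volume is contrast-limited adaptive-histogram equalised (8-voxel
lateral tiles, clip limit 0.01) and median filtered, then over-detected
with a multiscale Laplacian of Gaussian: six log-spaced scales across the
per-channel radius range, maxima above 5% of the frame's peak response.
Three numerical choices matter in anisotropic stacks:

* per-axis filter widths are floored at 0.8 voxels — sub-voxel Gaussian
  derivatives are dominated by discretisation error, which otherwise
  swamps scale selection along z;
* the scale-normalised Laplacian is taken in the lateral plane only,
  where the sampling actually resolves object size; z contributes
  smoothing but no second derivative (for an ideal solid sphere the
  response still peaks at σ = r/√3);
* overlapping maxima are suppressed (stronger response wins) and the
  candidate list is trimmed per frame to the 60 brightest.

Brightness ranking and template correlation use a median-filtered
min-max-normalised copy of the raw frame, *not* the equalised image:
CLAHE stretches every tile to full range, which makes "brightest object"
meaningless on it. The cap matters for the validation stage: at the
deliberately low LoG threshold, noise candidates outnumber true blobs
~100:1, and 2-means clustering on such imbalanced data splits the noise
bulk instead of isolating the signal; at ~10:1 the over-detection margin
is preserved and the split is clean.

Validation follows the brightest/dimmest-template design: the top and
bottom 100 candidates by peak brightness become "endosome" and
"background" templates; each candidate is described by (mean NCC against
bright templates, mean NCC against dim templates, peak brightness, LoG
response), features are z-scored per movie, and a seeded 2-means split
labels the cluster with higher bright-NCC as signal. Detected radii are
the LoG scale with the lateral PSF contribution removed
(`sqrt(scale² − 3·psf_lat²)`); centres are refined to sub-voxel precision
by a background-subtracted intensity centroid. Integrated intensity is
summed in a fixed 0.3 µm mask, which keeps the per-frame intensity
measurement independent of radius-estimate jitter.

## Linking (`endomat.track`)

Frame-to-frame assignment minimises
`|Δx|² + intensity_weight·(Δlog I)²` inside a search radius, solved
exactly (Hungarian algorithm on the gated cost matrix augmented with
birth/death alternatives priced at `search_range²`); a greedy best-first
fallback handles subnetworks above 10⁴ combinations and is logged when
triggered. Lost tracks persist up to 2 frames and re-acquire within a
radius grown by 50% per missed frame; tracks shorter than 5 frames are
dropped. Defaults: search radius 1.8 µm/frame — deliberately above the
1.5 µm per-frame run displacement, since a radius equal to the typical
step breaks tracks on localisation noise. Log-intensity (not raw) enters
the cost so the weight is scale-free.

## Event classification (`endomat.events`)

Surface separation of an APPL1/EEA1 pair is centre distance minus both
radii, clipped at zero, with linear interpolation across linking gaps.
Collisions are sub-200-nm local minima of that series, with three
practical rules: runs of equal values (clipped contact plateaus) count as
one minimum at their midpoint; minima of one pair closer than 10 s merge
to the deepest (one touch-and-go encounter, not several); and minima
inside sustained-contact episodes (≥2 consecutive colocalised frames) are
excluded as conversion-like.

A maturation event requires an APPL1/EEA1 pair colocalised (<200 nm
centre distance) for ≥2 consecutive frames, APPL1 track termination with
terminal intensity below `appl1_terminal_fraction` of its pre-event
median, EEA1 persistence ≥10 frames beyond APPL1 loss, and no APPL1
signal reappearing on the EEA1 track within 30 s (rejects reversions).
The terminal-intensity cut defaults to 1.2 — effectively permissive —
because a fading track drops out of detection while still at 60–100% of
its plateau brightness, so the measured terminal value cannot reach a
small fraction of the median; the persistence and no-reversion filters
carry the discrimination. When several pairs survive, each track keeps
the partner with the most colocalised frames (the true partner stays
close throughout); one EEA1 track may take part in several events but not
in two with overlapping windows.

Kind: fusion iff the EEA1 track pre-existed cotracking by ≥2 frames,
with an intensity cross-check — if the partner's intensity collapses
below 70% of its pre-onset median right at onset, the "pre-existing"
track absorbed a newly appearing signal through a linking artefact and
the event is a conversion. Induction: collision-induced iff the APPL1
endosome collided with *any* EEA1 endosome in the 30 s before onset.
Cohorts are summarised as the fraction of events per (10-s cotracking
bin × preceding-collision count) cell, globally normalised (row
normalisation available), plus the four category counts.

**Known limitation.** On the noisy reference scene the pipeline reports
events with precision ~1.0, recovers conversions reliably, but misses
roughly half of the scripted fusions and a fraction of chance
collisions. The dominant failure is a track-identity switch exactly at
an event: an endosome whose signal is vanishing, with another endosome
of similar brightness inside one search radius, is genuinely ambiguous
to any tracker. The classification rules themselves are exact on ideal
trajectories, which the suite verifies separately.

## FLIM unmixing (`endomat.flim`)

Decays are fitted as a fixed two-lifetime mixture (τ₁ = 1.006 ns,
τ₂ = 2.600 ns) plus a flat background, by Poisson maximum likelihood over
the binned histogram; each component's bin probabilities come from the
exponentially modified Gaussian closed form (exponential decay convolved
with the Gaussian IRF), renormalised over the window. Only the two
amplitudes and the background are free. The photon fraction of the short
component, `f_N = A₁τ₁/(A₁τ₁ + A₂τ₂)`, splits each pixel's photons into
NT-EEA1 and CT-EEA1 images (`nt + ct` equals the total exactly). Pixels
below a 50-photon floor are fitted on a pooled 3×3 neighbourhood; pixels
that still lack photons are masked. At 10⁴ photons the fitted fraction is
within 0.05 of truth in >95% of replicates across the whole fraction
grid. N:C ratio traces floor the C channel at one photon and smooth with
a centred 3-frame boxcar. Fusion-pair categories label an endosome A
(absent) below a presence threshold, otherwise N if `f_N ≥ 0.5` else C;
pair labels are unordered. Amplitude-fraction splitting (instead of
photon fraction) is available as an option.

## Surface simulator (`endomat.endosim`)

One endosome surface is a Fibonacci-sphere lattice (default 400 nodes,
6-nearest-neighbour lists symmetrised to a mutual relation) where each
node stacks a Rab5 protein site and a phosphoinositide site. Agents obey
the trigger-and-convert interaction map: APPL1 binds Rab5 plus an
adjacent free PI(3,4)P₂; N-terminal EEA1 binds Rab5 alone; C-terminal
EEA1 binds Rab5 plus adjacent PI(3)P; INPP4A binds protein-free
PI(3,4)P₂ and converts it irreversibly to PI(3)P, then jumps to a free
PI(3,4)P₂ within graph distance 2 or leaves. "Adjacent across layers"
means the same node or a lattice neighbour.

Dynamics are fixed-step kinetic Monte Carlo (dt = 0.05 s) with a fresh
random node order each sweep. Attachment probability is
`k_on·dt·(1 + α·n_same_neighbours)` (cluster attach) and detachment
`k_off·dt·(1 + β·n_recent_detached_neighbours)` with a 2 s recency
window (cluster detach); the constructor rejects any parameter set whose
largest per-step probability exceeds 0.1. A collision adds up to
`M = 320` N-terminal EEA1 onto free Rab5 sites, spread uniformly over a
10 s window and capped by availability. Runs start from an
APPL1-dominated surface (30 s APPL1-only burn-in on all-PI(3,4)P₂).
Conversion time is the first passage of the PI(3)P node fraction over
θ = 60%; runs censor at 500 s.

**Calibrated defaults.** The published account of this model does not
include its rate constants, so the defaults ship from a seeded
calibration (`endomat.endosim.calibrate`) against the stratified
conversion-time mode targets: 130–200 s for endosomes converting with no
collision, 60–100 s with one, 20–50 s with two. The calibration record
(seed, targets, achieved modes 145/75/35 s) is stored in
`CALIBRATION_INFO`. The package defines a default collision-frequency
sweep (0.008, 0.016, 0.032 s⁻¹); zero- and one-collision strata are read
from the lowest frequency, the two-collision stratum from the highest,
where it is well populated — mirroring ensembles run at several collision
frequencies.

Two structural findings from the calibration are worth recording. First,
the cluster-detach gain must exceed the cluster-attach gain (defaults
β = 1.4 vs α = 0.3) for clustering to *accelerate* conversion: attach
feedback alone stabilises the APPL1 carpet and slows maturation, whereas
detach cascades expand holes in it, exposing PI(3,4)P₂ to the
phosphatase. Second, the multi-modal conversion-time structure requires a
single collision to push the converted fraction close to (but not over)
the 60% threshold: the first collision leaves the endosome poised, so a
second collision completes conversion almost immediately, producing the
fast two-collision mode.

Ensembles run independent seeded replicates with Poisson collision
schedules, stratify completed runs by collisions experienced before
conversion, and report 10-s-bin histogram modes (earliest maximal bin on
ties) only for strata with ≥20 runs.

## Problem sizes

Default test and acceptance workloads: 500-replicate ensembles at 400
lattice nodes (~1 minute), a 100-frame 96×96×16 two-channel movie for the
pipeline checks (~1 minute of detection), and 200 fit replicates per
FLIM fraction (~15 s).
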