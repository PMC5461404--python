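# Methods

This note documents the models, conventions and numerical choices behind
`efptrack`, in the spirit of a methods section a maintainer can audit.

## The two-state kinetic-diffusion model

A molecule is either **bound** to a translating ribosome (diffusion
coefficient `D_slow`, µm²/s) or **free** (`D_fast`). Transitions are
first-order: the free→bound rate is 1/τ_free and the bound→free rate is
1/τ_bound (dwell times exponential, in ms). The stationary bound fraction
is therefore

    f_slow = τ_bound / (τ_bound + τ_free),

and `TwoStateModel` enforces this identity at construction — a model built
from lifetimes derives its fractions, and a static (non-exchanging) model
simply carries no lifetimes. State histories are sampled event-driven
(exact exponential dwells), never per-substep Bernoulli, so the kinetics
are exact for any substep size.

Default parameters mirror the wild-type condition: D_slow = 0.2,
D_fast = 4.3 µm²/s, τ_free = 16 ms, τ_bound = 7 ms (f_slow = 7/23 ≈ 0.30),
σ_slow = 50 nm, σ_fast = 75 nm. Alternate condition presets (ribosome,
chloramphenicol, rifampin, K34A) are in `fixtures.PRESETS`.

## Confined Brownian dynamics

Cells are spherocylinders (default diameter 0.9 µm, length 4 µm; study
bundles draw lengths over 3.2–8.4 µm). Each camera frame (Δt = 2 ms) is
divided into 20 substeps of 0.1 ms; per substep the walker takes an
isotropic 3D Gaussian step with per-axis variance 2·D·dt. Confinement is by
**rejection resampling of the whole substep**: the step is redrawn until the
endpoint lies inside the cell (boundary inclusive). Rejection preserves the
uniform equilibrium distribution exactly — verified against uniform volume
sampling — and is unambiguous at the cap/cylinder junction, unlike
specular reflection. A hard cap (1000 draws) turns geometrically impossible
step sizes into an explicit error. At the default substep the rms step for
D = 10 µm²/s is ~45 nm, far below the 450 nm cell radius, so the rejection
bias is negligible.

The frame interval is fixed at 2.0 ms even though the camera's 485.4 Hz
implies 2.06 ms; every published analysis quantity is quoted "per 2 ms" and
the interval is exposed in `SimConfig` for anyone who prefers the exact
cadence.

## Observation model and the meaning of σ

Only the (x, y) projection is observed; z is simulated but hidden. Each
frame contributes one localization with additive Gaussian noise of
per-coordinate standard deviation σ of the frame's **majority-occupancy
state** (the tie-break when a frame straddles a transition).

σ is treated as the *dynamic localization error*: the effective
per-localization uncertainty including both photon noise and motion blur
during the 2 ms exposure. That is the convention under which the
per-condition values (50–90 nm) are quoted, so by default the simulator
samples the instantaneous position at frame start (`motion_blur=False`)
and adds σ. This choice keeps the closed forms exact — unconfined
displacements are Rayleigh with scale √(2DΔt + 2σ²), and MSD(τ) = 4Dτ +
4σ² — and reproduces the clearly two-peaked static P(⟨r⟩₆). Applying
explicit exposure-averaging *and* the full quoted σ would double-count
blur and visibly wash out that structure. Explicit blur remains available
(`motion_blur=True`, observed position = mean of substep positions over the
exposure) and is always physical in the movie renderer, where the PSF is
accumulated over substep positions and σ is not added at all — photon noise
and blur arise from the image itself. σ is per-coordinate; if a source
quotes the 2D radial rms instead, divide by √2 before passing it in.

## Summary statistics

* Trajectories shorter than 7 localizations are discarded; 7 frames give
  the 6 steps used everywhere. Gapped detections must be split upstream —
  `TrajectorySet` rejects non-consecutive frames so no gap displacement can
  enter P(r).
* **P(r)**: all consecutive-frame 2D displacement magnitudes, binned at
  25 nm over [0, 1.2] µm (overflow accumulates in the last bin; counts are
  conserved). The bin width is a package choice: with ~60 nm localization
  error, finer bins are noise-dominated.
* **P(⟨r⟩₆)**: one value per trajectory, the mean of its first six steps,
  binned at 25 nm over [0, 0.8] µm. Averaging makes it narrower than P(r)
  and sensitive to state exchange on the ~10 ms scale.
* **MSD(τ)**: mean squared 2D displacement over all within-trajectory
  pairs at lags 1–6, trajectories truncated to 7 frames (configurable).
  Error bars are the standard error of the mean of the squared
  displacements (a flag-free interpretation of "±1σ of the MSD values"; the
  population SD is recoverable from `sem` and `n_pairs`). D and σ come from
  the line through the first two points: D = slope/4, σ = √(intercept/4),
  a negative intercept clamps to σ = 0 with a flag.
* **Axial distributions**: per-cell x positions (cell frame, origin at
  mid-cell) are scaled by that cell's length to [−0.5, 0.5]; cells are
  pooled within 1-µm length windows (default 3.5–4.5 µm). Localizations
  nominally outside the cell (noise) are dropped and counted, not
  projected. For goodness-of-fit tests against the uniform null the
  profile is built from one position per molecule (`per_molecule=True`):
  successive localizations of one trajectory are strongly correlated, and
  Poisson statistics on the pooled-localization profile would overstate
  significance several-fold.

The slope-derived ensemble ⟨D⟩ deserves a caveat: it is *not* the
population-weighted mean of the input coefficients once confinement acts.
Simulating the wild-type parameters in a 0.9 × 4 µm cell yields ⟨D⟩ ≈ 2.4–
2.5 µm²/s, below the unconfined weighted mean of 3.07, because D_fast = 4.3
walkers feel the cell radius within one frame. The acceptance script
reports this simulated value as is.

## Fitting

Because P_model(r; D, σ) has no closed form, `build_model_library`
simulates a static single-state ensemble per (D, σ) — ≥ 10,000 steps each,
deterministic child seeds per entry — with the same binning as the target.

**Reduced chi-square.** χ² = Σᵢ (p_exp,i − p_model,i)² / varᵢ with
varᵢ = p_exp,i/n_exp + p_model,i/n_model — both histograms carry counting
noise. For a two-component mixture the variance term is propagated exactly:
f²·p_slow/n_slow + (1−f)²·p_fast/n_fast. Adjacent bins are merged until
each group holds ≥ 5 counts in the experimental **and** the model
histogram; the "and" matters because with observed-count errors a tail bin
with an experimental zero against a populated model bin would otherwise
get a vanishing variance and a divergent contribution. ν = n_groups −
n_free − 1 (normalization costs one). Calibration is covered by a null
test: two independent simulations of the same model give χ²ν ≈ 1.

**Static fits** are exhaustive grid searches — D log-spaced 0.05–20 µm²/s
at 25 points/decade, f_slow in steps of 0.05, D_slow ≤ D_fast enforced,
ties broken toward smaller D_fast then smaller f_slow, boundary minima
flagged. σ_slow/σ_fast are inputs (from MSD intercepts or quoted values),
not free parameters. D_slow may be constrained (e.g. to the ribosome value
0.2 µm²/s — the bound-state rms true step of 40 nm is below the ~60 nm
localization error, so the data cannot determine D_slow). Parameter
uncertainties are the per-parameter extent of the χ²ν ≤ 1.5 region of the
grid; when the global minimum exceeds the threshold the region is reported
as an error ("fit inadequate") rather than silently widened.

**Lifetime fits** scan τ_free over a log grid (default 12 points,
0.1–100 ms) with τ_free/τ_bound = f_fast/f_slow fixed by the static fit,
simulating 15,000 exchange trajectories per grid point with common random
numbers across points (variance reduction; the objective is itself noisy).
An optional refinement pass inserts geometric midpoints around the coarse
minimum. The fast-exchange end of the grid collapses P(⟨r⟩₆) to a single
averaged-mobility population and the slow end reproduces the static
two-peak shape, so the scan discriminates exchange on the 2–20 ms scale.

## Spot tracking front end

Frames are 3×3-boxcar smoothed, the frame median is subtracted and
negatives clamped (both kernel and background estimator are explicit
package choices). Peaks are strict 8-neighbor maxima above a user-set
threshold, merged within 4 px keeping the brighter. Localization is the
intensity-weighted centroid of a 7×7 window (robust to the asymmetric
blur of a moving emitter; edge peaks are dropped). Linking solves, per
frame pair, the optimal assignment that maximizes matches within the
search radius and minimizes total squared displacement (Hungarian
algorithm with an unmatched cost of max_displacement²); memory is 0, so a
missed detection ends a trajectory. The renderer integrates Gaussian PSFs
(via the error function, so photons are conserved) over substep positions,
adds uniform background and Poisson noise; EMCCD excess noise can be
approximated by scaling the background/photon budget, exact EM statistics
are out of scope.

## Census

Pro-Pro duets are counted with the overlapping convention (PPP → 2 duets,
PPPP → 3); the motif fraction is Σ(duets·copies)/Σ(length·copies). The
budget chain: cycle time τ_free + τ_bound = 23 ms → ~43 cycles per copy
per second → 2.2–8.7 × 10⁵ E-site interrogations/s for 5,000–20,000
copies, against 8 × 10⁵ elongation cycles/s by 40,000 translating
ribosomes — with only ~280 Pro-Pro motifs present in the transcriptome at
any instant, implying most binding events are not Pro-Pro rescues.
k_bimol = (1/τ_free)/[ribosome] ≈ 2.8 × 10⁶ M⁻¹s⁻¹, about 140× below the
diffusion limit (k_diff = 4 × 10⁸ M⁻¹s⁻¹, a literature constant taken as
input). Headline values are reported unrounded with a two-significant-
figure companion.

The synthetic proteome draws gamma-distributed lengths (mean 260 codons),
lognormal copy numbers rescaled to 4.8 × 10⁶ total, assigns duets
binomially at the target rate and then corrects on low-copy genes until
the copy-weighted fraction is within 10% (in practice ~5%) of target.
Sequences place duets isolated (never adjacent), so counts are exact by
construction and re-derivable from the sequences.

## Synthetic study bundles

`fixtures.generate_study` emits a cell table and trajectory table per
condition preset. Cell lengths are truncated-normal (mean ≈ 4 µm, sd
0.8 µm) within the condition's range, so most cells fall in the 3.5–4.5 µm
analysis window; 15 trajectories per cell with geometric length of mean 9
frames (a photobleaching stand-in) leave ~860 six-step trajectories after
filtering at the default 120 cells — the scale of the wild-type dataset.
For conditions with real binding, initially-bound molecules start from a
three-zone axial weighting (Gaussian zones at scaled x = −0.31, 0, +0.31,
width 0.07, over a 0.25 uniform floor) emulating the ribosome-rich
regions between and outside the nucleoid lobes; free molecules start
uniform. The zone weights are qualitative — no published peak-to-trough
contrast exists to calibrate against — so axial tests assert structure
(peaks versus troughs, uniformity statistics), not numeric contrast.

What the generator does *not* emulate: photophysics beyond length
truncation (no blinking), anomalous diffusion, polysome size variation,
nucleoid polymer physics, bent cells, or drift. Passing tests therefore
demonstrate correct inference *given the two-state confined-diffusion
model*, not robustness to every real-data pathology.

## Problem sizes and runtime

The acceptance script uses the study-scale sizes throughout: 5,200 single
steps and 20 replicates for static recovery, 859 six-step trajectories,
15,000 model trajectories per τ point and 10 replicates for lifetime
recovery, 10⁵–10⁶ samples for the closed-form oracles, and 25 rendered
movies for the imaging loop. The simulator is vectorized across
trajectories (a 15,000-trajectory, 7-frame exchange ensemble takes well
under a second), so the full script completes in a couple of minutes on
one CPU; the test suite runs in about two minutes.

## Known limitations

* D_slow is unidentifiable from 2 ms steps when √(4DΔt) ≲ σ; constrained
  fitting is the supported path, matching practice.
* The χ²ν ≤ 1.5 region quantifies grid-resolution-limited uncertainty; it
  is not a calibrated confidence interval, and when the minimum χ²ν
  exceeds 1.5 (a few percent of replicates at n ≈ 5,200) the region method
  reports failure by design.
* Lifetime resolution is bounded by the 6-step (12 ms) observation window:
  τ_free beyond ~50 ms is indistinguishable from static, and below ~1 ms
  only the averaged mobility is recoverable.
* The linker assumes ≤ a few spots per frame (sparse activation); dense
  fields would need track memory and cost models out of scope here.
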