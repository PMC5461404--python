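# efptrack

Single-particle tracking analysis of two-state diffusion in live bacteria.

Elongation factor P (EF-P) rescues ribosomes stalled at Pro-Pro motifs, but
in a living *E. coli* cell it can only act if it finds a ribosome with an
empty E site. Fast sptPALM imaging (2 ms/frame) of EF-P–mEos2 makes the
ribosome-bound and free populations distinguishable by their mobility:
bound copies diffuse like translating ribosomes (D ≈ 0.2 µm²/s, below the
localization error) while free copies diffuse an order of magnitude faster.
`efptrack` implements the complete quantitative pipeline for this kind of
experiment, for microscopists and modelers who want to extract binding
fractions and on/off kinetics from fast tracking data — or to test how well
such parameters *can* be extracted at a given sample size.

## Model

A molecule switches between two diffusive states with first-order kinetics,

    free  --(1/τ_free)-->  bound        bound  --(1/τ_bound)-->  free

so the stationary bound fraction is f_slow = τ_bound / (τ_bound + τ_free).
Motion is Brownian (D_slow or D_fast) confined to a spherocylindrical cell
(diameter d, tip-to-tip length L), observed in 2D every Δt = 2 ms with a
state-dependent dynamic localization error σ per coordinate. Because
confinement and localization error leave no closed form, the fitted model
distributions are themselves simulated: single-state libraries
P_model(r; D, σ) are compared to the measured single-step distribution
P(r) through a reduced chi-square over a (D_slow, D_fast, f_slow) grid, and
the exchange lifetimes are then fit to the six-step-mean distribution
P(⟨r⟩₆) — which is sensitive to switching on the ~10 ms scale — by scanning
τ_free with τ_free/τ_bound pinned to f_fast/f_slow.

Modules:

| module | what it does |
| --- | --- |
| `cellgeom` | spherocylinder containment/confinement, uniform sampling, axial profiles |
| `kinetic_sim` | vectorized forward simulator of confined two-state walkers |
| `traj_stats` | P(r), P(⟨r⟩₆), MSD(τ) with (D, σ) estimates, axial pooling |
| `model_fit` | simulated-library χ²ν grid fits, confidence regions, lifetime scans |
| `spot_tracking` | synthetic movie rendering, peak finding, 7×7 centroids, linking |
| `census` | proteome Pro-Pro census and the E-site interrogation budget |
| `fixtures` | one-command synthetic study bundles per experimental condition |

A thin CLI (`efptrack simulate / stats / fit / track / census / fixtures`)
wraps the library.

## Worked example

Recover the wild-type binding fraction from a synthetic experiment of the
study's size — 867 seven-frame trajectories, i.e. ~5,200 single 2-ms steps:

```python
from efptrack.kinetic_sim import SimConfig, TwoStateModel, simulate_ensemble
from efptrack.model_fit import (build_model_library, confidence_region,
                                default_d_grid, fit_static)
from efptrack.traj_stats import displacement_pdf

truth = TwoStateModel(D_slow=0.2, D_fast=4.3, f_slow=0.30,
                      sigma_slow=50.0, sigma_fast=75.0)
config = SimConfig(n_frames=7)          # 2 ms frames, 0.9 x 4.0 µm cell
ens = simulate_ensemble(truth, config, n_traj=867, seed=3, static=True)
target = displacement_pdf(ens.step_lengths().ravel())

library = build_model_library(default_d_grid(), [50.0, 75.0], config,
                              n_traj=1700, seed=42)
fit, grid = fit_static(target, library, n_states=2, D_slow_fixed=0.2,
                       sigma_slow=50.0, sigma_fast=75.0)
print(f"f_slow = {fit.f_slow:.2f}   D_fast = {fit.D_fast:.2f} um^2/s   "
      f"chi2_nu = {fit.chi2_nu:.2f}")
region = confidence_region(grid, threshold=1.5)
print("f_slow range:", region["f_slow"], " D_fast range:", region["D_fast"])
```

prints

```
f_slow = 0.30   D_fast = 4.27 um^2/s   chi2_nu = 0.94
f_slow range: (0.3, 0.35)  D_fast range: (3.9028087568292342, 4.679803021916213)
```

So with D_slow constrained to the ribosome value, ~5,200 steps determine
the bound fraction to about ±0.05 and the free diffusion coefficient to
about ±0.4 µm²/s here; the χ²ν ≤ 1.5 region is the quoted uncertainty.
About 30% of copies are ribosome-bound at any instant, and the companion
lifetime scan (`fit_lifetimes`) on P(⟨r⟩₆) resolves how that 30% is
maintained: brief ~7 ms binding events separated by ~16 ms diffusive
searches rather than a static subpopulation.

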