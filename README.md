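# mechanoquant

Quantification pipeline for macrophage–fibroblast mechanotransduction
assays.  When profibrotic (IL-4/13-polarized) macrophages touch a
fibroblast, the fibroblast contracts — a mechanical trigger on the path to
myofibroblast activation and tissue fibrosis.  Measuring that response spans
several very different readouts, and this package implements the
quantification for each of them, together with synthetic-data generators
that make every stage verifiable against known ground truth:

- **Micropattern (FLECS) contraction kinetics** — cells on cross-shaped
  adhesive micropatterns (70 µm diagonal, 10 µm bars) shrink the pattern as
  they contract.  Per-pattern area fraction `A(t)/A(0)` is measured from
  binarized time-lapse frames, contraction is its inverse, and kinetics are
  summarised by the maximum contraction within 90 min of stimulation and the
  *speed ratio* (post-stimulus / baseline slope of the contraction curve).
  Nuclear-channel gating excludes patterns without a cell.
- **Bead-displacement traction cytometry** — fluorescent beads on a soft
  (~0.2 kPa) gel report surface displacements via two-pass block
  cross-correlation PIV; displacement fields are summarised as summed vector
  norms and inverted to traction stress (Pa) by regularized
  Fourier-transform traction cytometry (FTTC) using the Boussinesq
  half-space Green's function
  `u(k) = 2(1+ν)/(E k³) [[k²−ν kx², −ν kx ky], [−ν kx ky, k²−ν ky²]] t(k)`.
- **Cell-shape polarization** — circularity `4πA/P²` and solidity
  `A/A_hull` of binary cell masks quantify local membrane retraction.
- **Nuclear translocation** — nuclear/cytoplasmic mean-fluorescence ratios
  (YAP, NFAT1, pSmad2/3) from a DAPI-derived nuclear mask; frame-0
  normalized nuclear MFI time series for live reporters (TAZ).
- **Calcium dynamics** — F/F₀ normalization, sustained-onset detection, and
  line-scan kymographs for GCaMP/Fluo-4 recordings.
- **AFM indentation** — Hertz-model fitting of force curves,
  `F = (4/3) E √R δ^{3/2} / (1−ν²)`, with joint contact-point estimation
  (profiled linear least squares) and Young's-modulus maps.
- **Gap-junction dye transfer** — log-linear calcein loading standard
  curves (`MFI = b + a·log₁₀ c`) inverted to estimate acceptor-cell dye
  concentration, with extrapolation flagging.

## Worked example

```python
from mechanoquant import (FlecsSimSpec, simulate_flecs_stack, analyze_flecs,
                          HertzSimSpec, simulate_force_curve, fit_hertz,
                          hertz_force)

spec = FlecsSimSpec(n_patterns=12, occupancy_fraction=0.75, rng_seed=0)
stack, truth = simulate_flecs_stack(spec, n_frames=45)
curves, metrics = analyze_flecs(stack, stimulus_frame=spec.stimulus_frame)
defined = metrics[metrics.speed_ratio_defined]
print(f"occupied patterns quantified : {len(metrics)}")
print(f"mean max contraction (90 min): {metrics.max_contraction.mean():.3f}")
print(f"mean speed ratio             : {defined.speed_ratio.mean():.2f} "
      f"(generator multiplier m = {spec.stimulus_multiplier})")

f_max = hertz_force(1e4, 1e-6, 0.5, 2e-6)
curve = simulate_force_curve(HertzSimSpec(noise_sd_n=0.02 * f_max,
                                          rng_seed=1), 200)
print(fit_hertz(curve, R_m=1e-6, nu=0.5).summary())
```

prints

```
occupied patterns quantified : 9
mean max contraction (90 min): 1.105
mean speed ratio             : 3.31 (generator multiplier m = 3.0)

Hertz indentation fit
---------------------
model           : sphere
status          : converged
Young's modulus : 1.003e+04 Pa (10.03 kPa)
contact point   : 1.005e-06 m
probe radius    : 1e-06 m
Poisson ratio   : 0.5
residual RMS    : 9.304e-10 N
```

The 9 of 12 patterns are those carrying a cell (nuclear gating); the mean
speed ratio of ~3.3 recovers the generator's 3-fold post-stimulus
contraction-rate multiplier (the small excess is the documented convexity
bias of fitting a straight line to an exponential contraction curve — see
`docs/methods.md`).  The Hertz fit recovers the generating 10 kPa modulus
from a noisy curve to 0.3%.

A CLI mirrors the library (`mechanoquant simulate|flecs|piv|traction|shape|
translocate|calcium|hertz|calcein`); each run writes its outputs plus a
`manifest.json` with the config snapshot, input hashes and seed.

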