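# Methods

This note documents the models, estimators and numerical choices behind
each pipeline stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Image model and conventions

All imaging stages exchange `ImageStack` objects with axis order
`(time, channel, y, x)`, y increasing downward, 0-based pixel indices.
Physical calibration (µm/px, s/frame) is supplied by the caller and never
read from TIFF tags, because tag dialects vary between acquisition systems
and silent mis-calibration is worse than an explicit argument.  Stack
registration is translation-only phase correlation with sub-pixel
refinement; rotation and scaling drift are out of scope.

## Micropattern contraction

**Measurement.** Patterns are segmented on frame 0 by Otsu threshold,
connected components above a minimum area (default 200 px²), border-touching
components excluded (truncated geometry biases area).  Components much
larger than the median (default 1.8×) are kept but flagged as suspected
merges of touching patterns.  A pattern is *occupied* iff at least
`min_overlap_px` (default 5) thresholded nuclear-channel pixels fall inside
its ROI; unoccupied patterns cannot contract and never enter kinetic
outputs.  Per frame, each pattern's dilated frame-0 bounding box is
re-binarized by Otsu and the foreground area of the components overlapping
the frame-0 ROI is recorded.

Two numerical choices matter here.  First, the box is bilinearly upsampled
4× before thresholding.  The per-frame area change of a slowly contracting
pattern (fractions of a percent) is smaller than the area quantum of a
digitized boundary, so binarized areas move in staircase steps; measured on
whole pixels, baseline slopes are dominated by this quantization and
per-pattern slope ratios become heavy-tailed.  Sub-pixel binarization
shrinks the quantum 16-fold and removes the effect.  Second, only
components overlapping the frame-0 ROI are counted, so tips of neighbouring
patterns entering the dilated box do not inflate the area.

**Kinetics.** Contraction is the inverse area fraction, 1 at frame 0.
Baseline and post-stimulus slopes are ordinary least squares of contraction
vs time over frames `[0, stimulus)` and `(stimulus, stimulus + 90 min]`;
the speed ratio is their quotient, defined only for a positive baseline
slope.  Maximum contraction is taken over the same 90-min post window.  A
track ends when its area falls below 25% of the initial value (detachment);
metrics computed on the remaining frames are flagged truncated.  A cell is
classified *accelerated* when its speed ratio exceeds the mean speed ratio
of the control group.

**Estimator bias.** For a pattern losing a constant fraction k of its area
per frame (k·m after the stimulus), contraction grows exponentially and a
straight-line fit over a 90-min window overestimates the late-window slope.
At the default k = 0.001/frame and m = 3 the expected recovered ratio is
3.17 rather than 3.00; the bias grows with k·m·T (≈3.33 at k = 0.002).
This is a property of the slope-ratio readout itself, not of the
implementation, and is shared by any analysis that fits lines to convex
contraction curves.

**Generator.** Crosses (70 µm diagonal, 10 µm bars — the assay's pattern
geometry) are rendered as unions of two rectangles, each rotated by a
per-pattern random angle, laid out on a jittered grid at 0.8 µm/px.
Contraction is isotropic scaling about the centroid with the closed-form
area fraction `s(t) = (1−k)^min(t,t0) (1−km)^max(t−t0,0)`, which keeps the
oracle exact; real cells deform patterns anisotropically.  Rendering uses
4×4 subsampled coverage plus a 1-px Gaussian optical blur, so the
50%-intensity contour sits on the true boundary and binarized areas stay
faithful.  Occupied patterns carry a static Gaussian nuclear blob.  The
defaults — 3-min frames, stimulus at frame 15 (45-min baseline within a
2.5-h recording), k = 0.001/frame, additive Gaussian noise σ = 2 on a
10–200 intensity range — emulate a gradually contracting control population
whose rate triples on stimulation; per-frame area loss and imaging noise
are not quantities the assay literature pins down, so they are fixture
choices, not claims about real data.  Photobleaching, drift and focus
changes are not modelled, so passing tests demonstrate estimator
correctness on clean geometry, not robustness to those artefacts.

## Bead displacement and traction

**PIV.** Two-pass block cross-correlation: pass 1 takes the integer peak of
the normalized circular cross-correlation per interrogation window (default
32 px window, 16 px step), validated against a 3×3 median of the integer
field; pass 2 re-correlates against the moving window offset by the
predictor, which removes loss-of-pairs error, and refines the peak with a
3-point Gaussian fit per axis.  Nodes with peak correlation below
`min_corr` (default 0.3) or without texture are masked as NaN, never
zeroed.  On rendered bead fields the scheme is accurate to <0.2 px RMS for
shift magnitudes up to window/4 with ≥10 beads per window; beyond that the
first pass can lock onto wrong peaks.  Displacements are always computed
against the initial frame, so summed vector norms are cumulative
contraction readouts; their baseline/post-stimulus slopes reuse the
micropattern kinetics code.

**Elasticity.** The gel is modelled as a linear elastic half-space with
tangential surface tractions (Boussinesq).  The forward model multiplies
the traction spectrum by the Green's tensor on a grid zero-padded 4× to the
next power of two (the kernel decays only as 1/r, so padding matters); the
inverse (FTTC) inverts the 2×2 system per wave vector with 0th-order
Tikhonov regularization, nulls the zero-frequency component and re-centres
the cropped field, enforcing global force balance.  Masked nodes are filled
by bilinear interpolation and the field is cosine-tapered to zero at the
boundary before the FFT.  λ defaults to 0; `select_lambda` picks the corner
of a coarse log-grid L-curve when displacement noise calls for
regularization.  ν defaults to 0.5 (incompressible gel).  The test-suite
oracle is a direct real-space convolution with the surface Green's tensor,
using the analytic self-cell integral ∫1/r dA = 4 d ln(1+√2) for a square
cell of side d; Fourier and real-space routes agree to ~1% RMS on a 64×64
grid.  Real gels are 60–80 µm thick; the half-space assumption is retained
and not corrected, which overestimates compliance at long wavelengths.

**Bead generator.** Beads are Gaussians with sub-pixel centres; the
displacement field is applied to the centres, not by image warping, so PIV
error is attributable to the estimator.  Substrate defaults (E = 200 Pa,
ν = 0.5, 0.5 µm/px) put tens-of-Pa traction patches and sub-µm-to-µm
displacements in the physically relevant regime for soft gels.

## Shape metrics

Circularity `4πA/P²` and solidity `A/A_hull`.  On masks, area is the pixel
count, the perimeter is the Crofton 4-direction estimator — chosen because
a naive boundary-pixel count overestimates the perimeter of smooth shapes
and breaks the circle→1 calibration (a radius-50 disk scores ≈0.99 with
Crofton) — and the convex area is the pixel count of the hull image.
Crofton is calibrated for smooth boundaries; on an axis-aligned digital
square it overestimates circularity (0.88 vs the continuous π/4), so exact
values for polygonal geometry come from `shape_metrics_polygon`
(shapely-based continuous geometry), which the analytic test oracles use.
Solidity from pixel hulls is rotation-invariant to ~2%, the rasterization
tolerance.  Fold *decreases* across a perturbation are reported as
before/after.  The hull-area route is used rather than a convex-perimeter
(Feret-based) construction, since solidity is a ratio of areas.

## Translocation

Nuclei: Otsu on the nuclear stain, hole filling, minimum-size filter.
Nuclear MFI is the marker mean inside the nuclear mask, cytoplasmic MFI the
mean over cell-minus-nucleus; background (default: intensity mode outside
the cell mask, overridable, including whether subtraction happens at all)
is subtracted from both, negatives clipped and flagged.  The ratio is
undefined when the cytoplasmic compartment is empty or non-positive.  The
ratio is exactly invariant to global intensity scaling and, with the offset
supplied as background, to additive offsets.  Time series track one nucleus
by nearest-centroid linking (default max jump 30 px) and normalize nuclear
MFI to frame 0; losing the nucleus truncates the series with a flag.

## Calcium

Traces are normalized by the mean over a configurable baseline window
(default: the pre-stimulus frames) rather than the single first frame, for
noise robustness; single-frame normalization is the window `(0, 1)`.
Onset is the first frame exceeding `1 + k_sd·SD(baseline)` for at least 2
consecutive frames (default k_sd = 3); the sustain rule rejects
single-frame spikes, and on flat noisy traces the false-positive rate stays
below 5%.  Kymographs sample a line ROI at ~1 px spacing with bilinear
interpolation, averaged over the line width.

## Hertz fitting

The spherical-probe contact law `F = (4/3)E√R δ^{3/2}/(1−ν²)` is the
default even though quadratic-pyramid cantilevers are common for cell work;
a four-sided-pyramid law (`F = 0.7453 E tan α δ²/(1−ν²)`) is available via
`model="pyramid"`, and the choice is the caller's.  Fitting exploits that
force is linear in E at fixed contact point: the contact point is profiled
over a 101-point grid spanning the curve and refined by bounded scalar
minimization, with E given in closed form at each candidate.  This is
robust where a joint 2-D descent across the `max(δ,0)` kink stalls in local
minima.  When a cantilever spring constant is supplied, indentation is
corrected by the measured deflection, `δ = (z − z_c) − F/k`.  Curves whose
force span never clears 5 baseline-noise SDs fail explicitly instead of
returning a spurious modulus.  ν defaults to 0.5 (incompressible cell).
Viscoelasticity and tip-shape calibration are out of scope.

## Calcein transfer

The loading standard curve is a least-squares line in
(log₁₀ concentration, MFI), requiring ≥3 concentrations spanning ≥1 decade;
replicate rows are averaged (mean; a median option exists at the table
level before fitting).  The log-linear form matches dye-loading response
over the calibrated range; a 4-parameter logistic is deliberately not
fitted.  Acceptor MFI inverts to `c = 10^{(MFI−b)/a}`, reported in nM;
estimates below the lowest standard are flagged *extrapolated* (the
interesting regime for gap-junction transfer, where acceptor concentrations
sit orders of magnitude below loading), and MFIs at or below the unstained
background return no estimate.

## Determinism and orchestration

Every generator takes an explicit seed and is bit-reproducible; identical
seed + config + inputs give byte-identical CSV/TIFF outputs across the CLI
workflow (manifests contain wall-clock timestamps and are excluded from
byte comparison).  Problem sizes used by the bundled verification script
(`scripts/acceptance.py`) — 50 occupied patterns, 256² bead fields, 64²
traction grids, 100-curve Hertz ensembles, 200-trace onset nulls — were
chosen so each block completes in seconds to a couple of minutes on one
core while keeping Monte-Carlo errors well inside the tolerances being
checked.
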