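# Methods

This note records the models, parameter choices and numerical decisions
behind the package, and what the synthetic setting can and cannot say about
real deliveries.

## MLC leaf-tip model

A leaf end is modeled as a double step in transmission along the leaf-travel
axis: fully open beyond the *effective* tip, a partially transmitting tip
region of width `w` under the leaf end, and the intraleaf transmission `T`
beyond it.  The effective tip is the nominal position retracted outward by
the signed leaf-tip offset `delta`; positive offsets enlarge the effective
field.  Decisions taken where the model statement is ambiguous:

* **Tip transmission τ.**  A tip region transmitting exactly `T` would
  collapse the double step to a single one, contradicting "partial"
  transmission.  Default `tau = sqrt(T)` (geometric midpoint between open
  and fully attenuated, `T < tau < 1`); `tip_rule="intraleaf"` restores
  `tau = T` for users who prefer the literal reading.  Both rules satisfy
  `T <= tau <= 1`.
* **Per-bank offset.**  The offset retracts *each* leaf, so +1 mm of offset
  widens a gap by 2 mm.  This matches the reading of the offset as a shift
  of the MLC from its nominal position applied to every leaf.
* **Degenerate gaps.**  If retraction would invert a pair, the pair clamps
  to a zero-width gap at the nominal gap midpoint; this keeps the model
  total and monotone in `delta` (a key invariant: every transmission-map
  value is non-decreasing in `delta`).
* **Pair combination.**  A pair's profile is the pointwise **minimum** of
  its two single-leaf profiles: a photon path attenuated by both tips cannot
  transmit more than the more attenuating leaf, and products would dip
  unphysically below `T`.
* Bank geometry is Agility-like: 40 pairs at 5 mm pitch; `T = 0.005`
  (typical intraleaf leakage) by default.  Rows outside the bank are treated
  as blocked by the backup jaws (transmission `T`).

## Dose engine

The engine is a deliberately simple surrogate for a clinical algorithm, not
an attempt to mimic one.  Per beam, MU-weighted transmission maps are
convolved with a radially symmetric two-Gaussian kernel — primary
`sigma = 1 mm` (penumbra sharpness), scatter `sigma = 20 mm` with weight
0.1 — and composite dose at a point sums, over beams, the planar dose at the
point's beam's-eye-view projection attenuated by `exp(-mu * depth)` with
`mu = 0.05 /cm` along the ray through the 80 mm cylinder.  Inverse-square
falloff, divergence, heterogeneity and 3-D scatter are all omitted.  What
the surrogate *does* preserve — and what the analysis depends on — is the
sensitivity structure: penumbra positions respond linearly to the leaf-tip
offset, high-gradient points amplify that response, and broad open fields
suppress it.

The convolution is an FFT product with an analytically sampled kernel,
normalized so a flat field reproduces itself at the grid center to <0.1 %;
the periodic wraparound is negligible because the 256 × 256 mm grid extends
several scatter sigmas beyond the fields.  Dose units are arbitrary
(per-MU); every reported quantity is a percent difference or a pass rate,
both scale-free.  For this reason the plan suite is *not* renormalized to a
prescription dose: total MU per plan is fixed instead (below).

## Synthetic plan suite

Nine plans mirror the published suite design: five step-and-shoot plans with
7/7/7/9/9 equally spaced beams and four arc plans with 2/2/2/3 full arcs
(discretized at 4° control-point spacing, one static segment per control
point), with the published per-plan total MU (1469–2114) adopted verbatim.
Apertures are constructed, not inverse-optimized: per leaf pair, the opening
spans the spherical-target projections plus a 3 mm margin; wherever the
spinal-cord shadow (cord radius + 2 mm) falls inside the opening, the pair
pulls to one side of it — usually the wider side, occasionally (p = 0.25)
the narrower one — so every beam direction lays a penumbra across the cord.
Segments beyond the first add seeded random inward leaf perturbations
(per-plan modulation strength drawn from U(0.15, 0.35), emulating "uniquely
optimized" plans) and segment MU is a jittered uniform split renormalized to
the plan total.  The generator is validated to produce a ≥3 %/mm composite
dose falloff across the PTV-to-cord gap under the clinical model; the
default run gives ~9 %/mm.

The phantom is a transverse-plane abstraction of an anthropomorphic
head-and-neck geometry: an 80 mm cylinder holding PTV1 (r = 20 mm, near
axis), PTV2 (r = 12 mm, anterolateral) and a posterior cord (r = 4 mm) with
a 6 mm PTV1-to-cord gap.  Four 3 mm TLD-like disk ROIs (mean dose over the
disk, sampled center + ring) sit at PTV1 center, the PTV1 edge facing the
cord, PTV2, and the cord center; the first and third are tagged low-gradient
and the other two high-gradient.

## Virtual QA and gamma analysis

QA "measurements" are the truth-model (always the clinical model) composite
dose sampled on a planar diode array — 10 mm pitch over ±60 mm at the
isocenter coronal plane — plus zero-mean Gaussian noise with standard
deviation 0.5 % of the map maximum, seeded per replicate (20 replicates per
plan stand in for repeat deliveries; the planar array is a deliberate
simplification of a cylindrical device that keeps the pointwise-comparison
character at centimeter pitch).  "Calculations" are the candidate-model dose,
noiseless, on a 2 mm plane grid extending one gamma search radius beyond the
diodes.

Gamma follows the standard generalized-distance formalism with global
normalization (ΔD as a percent of the reference maximum), a 10 % low-dose
threshold, and presets 2 %/2 mm and 3 %/3 mm.  Numerical choices: the
distance-to-agreement search minimizes over a disk of radius 3 × Δd sampled
at 0.05 × Δd with bilinear interpolation of the evaluated distribution,
pruned losslessly by the spatial lower bound (displacement shells beyond the
current best gamma are skipped); reference = measured, evaluated =
calculated; γ = 1 ties count as passing.  The search resolution matches the
brute-force oracle's dense grid, which bounds the implementation to within
0.01 in gamma on random fields — a coarser 0.1 × Δd pass missed that bound
(disagreements up to ~0.02 on steep fields), which is why 0.05 × Δd is the
default.

## ROC detectability

Each QA comparison is labeled negative if the candidate model's (offset,
width) exactly match the clinical model and positive otherwise.  Low pass
rates flag failure, so the decision rule is `pass_rate <= threshold`; the
curve sweeps all distinct observed pass rates (ties grouped), is anchored at
(0,0) and (1,1), and the trapezoidal AUC equals the tie-corrected
Mann-Whitney concordance probability (asserted by brute force in the tests).
ROCs are built per offset-deviation magnitude against the shared clinical
negatives, plus a pooled variant; the detectability sweep holds the width at
its clinical value, mirroring the focus of the source analysis on the
offset.

## Problem sizes and determinism

The default study is 9 plans × 27 models on a 1 mm, 256 × 256 dose grid,
with 20 noise replicates × 9 candidate offsets × 2 criteria of gamma
comparisons (3240 records); it completes in a few minutes on one CPU, and
the end-to-end determinism check in the test suite runs a reduced
configuration (two plans, three offsets, one width, two replicates) twice
and compares output files byte for byte.  A master seed fans out through
`numpy.random.SeedSequence` to per-plan generator seeds and per-(plan,
replicate) noise seeds; all seeds are recorded in the run manifest.

## What passing tests do and do not show

The generator reproduces the *structural* conditions of the original
measurement campaign — modulated apertures, penumbrae across a high-gradient
cord, TLD-scale ROIs, centimeter-pitch array sampling — so ordering results
(high-gradient ROIs dominate; width effect ≪ offset effect; open fields
insensitive; AUC grows with offset deviation; near-chance AUC at 0.5 mm) are
meaningful qualitative reproductions.  Absolute numbers are not calibrated
to any commissioned beam: peak deviations, pass rates and AUCs depend on the
surrogate kernel, the heuristic modulation and the noise model.  One known
divergence: with purely Gaussian 0.5 % noise, clinical-model comparisons
pass 3 %/3 mm at exactly 100 %, so the 3 %/3 mm ROC saturates later than
2 %/2 mm and the two criteria are *not* nearly identical at intermediate
deviations, unlike measurements against real deliveries, whose baseline
disagreement (setup, calibration, detector response) spreads pass rates for
both criteria.  Emulating that baseline would require a systematic-error
model the source provides no parameters for.

## Known limitations

No tongue-and-groove, interleaf leakage, rounded-tip ray tracing, leaf
gain/curvature, collimator rotation, 3-D scatter or heterogeneity; arcs are
static control points (no dynamic delivery simulation); the diode array is
planar and noise is uncorrelated Gaussian; plans are heuristic, so DVH-based
plan quality is out of scope.
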