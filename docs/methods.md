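# Methods

`wristpet` is a desk-scale, fully seeded re-implementation of an in-silico
feasibility study of a wrist-worn PET coincidence detector for measuring
the arterial blood time-activity curve (BTAC) non-invasively.  It replaces
a full Geant4/GATE Monte Carlo with a simplified but end-to-end physics
chain: analytic forearm phantom, dynamic tracer kinetics, plug-flow
advection, single-scatter 511-keV photon transport, a per-block digitizer,
and a window-based coincidence sorter.  This note records the model, its
assumptions, the defaults, and the choices made where the design was open.

## Phantom

A water cylinder (radius 4 cm, length 20 cm) centered at the origin, axis
along Z, contains two cortical-bone cylinders (radius 1.25 cm, surface gap
1.1 cm, centers at (±1.8, +0.5) cm), two blood-filled arteries (radius
0.125 cm at (±2.0, −2.5) cm) and two veins (radius 0.075 cm at
(±2.4, −2.5) cm).  Y is vertical with the volar aspect at negative Y; the
background is air.  Overlaps resolve by priority (vessels > bones > arm).
The transaxial vessel/bone coordinates are schematic anatomy, not measured
values; they are configurable, and several downstream observables (most
notably the volar singles fraction, see Limitations) are sensitive to the
vessel depth.

511-keV linear attenuation coefficients are narrow-beam textbook values —
water 0.0958 /cm, cortical bone 0.178 /cm, blood 0.101 /cm — configurable
in the phantom config block.  The Compton fraction of interactions is 0.99
for all tissues (photoelectric absorption is negligible at 511 keV in
light media).

## Blood time-activity curves (the synthetic-data generator)

Arterial and venous whole-blood concentration curves follow a piecewise
linear-exponential model

    AIF(t) = 0                              t ≤ t0
           = a·t + b                        t0 < t < t1
           = c1·e^(d1·t) + c2·e^(d2·t)      t ≥ t1

with published fit coefficients for [15O]-H2O (1000 MBq injections) and
[18F]-fallypride (250 MBq) stored exactly as printed.  These shipped
parameter sets are the synthetic stand-in for curves measured with an
automated arterial blood sampler; passing tests against them demonstrates
the detector chain, not the biology of any individual subject.

Two conventions deserve emphasis:

* **Sign convention.**  The model is typeset with e^(−d·t) while the
  printed rate constants are negative.  Applied literally the tail would
  grow without bound, so the tails are evaluated as c·exp(d·t) with the
  printed (negative) d values, giving a decaying tail.
* **Breakpoints.**  t0 and t1 are not published.  t0 = max(0, −b/a) (ramp
  zero-crossing, clamped at zero) and t1 is the first ramp/tail
  intersection, bracketed on a dense grid and polished by Brent's method.
  This is the only choice that makes the curve continuous and
  single-peaked given the printed coefficients.  One printed quirk is kept
  verbatim: the 15O arterial intercept is positive (b = +1535), so that
  curve steps to 1535 kBq/ml at t = 0+ rather than rising from zero.

Concentration units are not stated with the published coefficients; the
package adopts kBq/ml (consistent with the expected < 500 kBq/ml at the
wrist) and exposes a global scale factor.  Half-lives are standard nuclear
data: 15O 122.24 s, 18F 6586.2 s.  Venous return uses the separate
(dispersed: lower, later peak) venous parameter sets delayed by 5 s.

Curve fitting (`fit_aif`) refits all six coefficients by least squares
with the breakpoints re-solved at every trial point, which enforces
continuity structurally.  At 1% multiplicative noise and 1-s sampling all
six parameters are recovered within 5% for the venous sets; in the 15O
arterial set the minor exponential (c2 ≈ 2 against a ≈ 2563 kBq/ml peak)
lies below the noise floor and only the dominant parameters (a, b, c1,
d1) are identifiable — an intrinsic property of those coefficients, not
of the fitter.

## Flow model

Each vessel is a 1-D plug-flow tube: the inlet curve advects without
internal mixing, so concentration at distance x from the inlet equals the
inlet curve at the retarded time τ with displacement(t) − displacement(τ)
= x.  Arteries flow +Z (inlet at z = −10 cm), veins −Z at a uniform
5 cm/s, delayed 5 s.  Dispersion inside the phantom is deliberately absent;
the venous broadening is carried entirely by the venous parameter set.

The pulsatile waveform is a parametric single beat, v(φ) = v_dia +
(v_sys − v_dia)·max(0, sin(πφ/w))², defaults v_sys = 40 cm/s, v_dia =
5 cm/s, systolic width w = 0.35, period 1 s (60 bpm).  The measured
literature profile it stands in for is not published; the parametric form
reproduces the mean-flow role (mean ≈ 15 cm/s is used for the uniform
closed-ring protocol).  Retarded times are found by monotone bisection
(per-point API) or by inverse interpolation on a dense displacement table
(2-ms grid, vectorized path); the two agree to 1e−6 cm by test.

Discretization: vessels are split into 0.5-cm axial segments and time
into 0.1-s bins; concentration is sampled at segment/bin midpoints and
converted to activity by exact segment volume.  Halving the segment
length changes the peak-time total activity by < 0.5%.

## Detector and digitizer

Monolithic scintillator blocks of 2.45 (tangential) × 3.0 (axial) × 2.0
(radial) cm sit with inner faces tangent to an 11.0-cm-diameter ring (the
closed ring of 14 blocks needs ≥ 10.92 cm; the diameter is configurable).
Blocks are numbered 1–14 clockwise (viewed from +Z) with blocks 1/14
straddling +Y, which places blocks 4 and 11 on the horizontal equator and
makes the volar arc 4–11 symmetric about −Y.  The half-ring system keeps
blocks 4–11 only and can be stacked into 1–4 axial rings at 3.0-cm pitch
centered on z = 0 (axial FoV 3 cm per ring); coincidences are allowed
between any two blocks, including cross-ring.

Crystal physics per material (GSO, LSO, BGO, CeBr3, LaBr3): density,
decay time, energy resolution at 511 keV, attenuation length at 511 keV
and coincidence window are package constants; Z_eff, emission wavelength,
light output and refractive index are carried as metadata only.

Detection model: an escaping photon is tested against the first block its
ray intersects; the interaction probability is 1 − exp(−ℓ/λ) over the
chord ℓ.  A detected photon deposits its full incident energy (no
partial-deposit spectrum): scatter rejection is carried by
phantom-scattered photons arriving with Compton-reduced energy.  Energy is
blurred with a Gaussian of FWHM = r511·511·√(511/E) (resolution quoted at
511 keV, 1/√E scaling) and accepted in a closed 350–650 keV window (a
conventional default; the window is configurable).  Deadtime is
non-paralyzable, applied per block, with τ = 3 × the crystal decay time by
default (ties the unpublished digitizer constant to the crystal physics
while remaining overridable).  Timestamps are decay times plus a Gaussian
timing jitter (σ = 1 ns default); photon time of flight is neglected.

## Transport and coincidence engine

Decays are drawn per (segment, window) as Poisson(activity × duration),
with uniform times in the window and uniform positions in the segment.
Each decay emits two exactly antiparallel 511-keV photons in a uniform
random direction (positron range and acollinearity are neglected —
sub-millimeter effects irrelevant to count rates at this geometry).  Free
paths are sampled exponentially on the exact segmented attenuation
profile along the ray (interaction points recovered by bisection on the
piecewise-linear optical depth, 32 iterations).  An interaction is a
Compton scatter with the material's Compton fraction, with the angle drawn
from the Klein-Nishina distribution by rejection (envelope 2, valid at all
energies) and the energy updated by the Compton formula; at most one
scatter is followed — a second interaction absorbs the photon.  Attenuation
coefficients are not re-evaluated at the scattered energy (single-μ
approximation).

The coincidence sorter opens a window at the earliest unconsumed single
and collects everything within the coincidence window.  Exactly two
singles on different blocks form a prompt; for multiples, all pairs are
emitted only if every pair is on distinct blocks, otherwise the whole
multiple is discarded (keep-if-all-are-good).  Classification uses decay
ids and scatter flags: same decay and no phantom scatter → true; same
decay with scatter → scattered; different decays → random.

All hot paths are vectorized over photon batches; the per-event API wraps
batches of one.  A single seed sequence spawns independent substreams for
decay sampling, transport, and per-scanner detection, so multi-scanner
comparisons (crystal materials, ring counts) share the identical source
realization and differ only in detector physics — and identical
(config, seed) pairs reproduce outputs bit for bit.

## Experiments and history scaling

* **Crystal comparison** — closed 14-block ring, 15O BTAC, uniform
  15-cm/s arterial flow, no venous return; one shared transport, per-
  material detection; ranking by peak coincidence rate.
* **NECR study** — decaying 18F point source (14 MBq start, ~1 mm³) in
  the 8-cm water-only phantom at Y = −1/−2/−3 cm inside the single
  half-ring.  Acquisition windows start at linearly spaced times across 5
  half-lives (log-spaced activities); each window's duration targets a
  fixed expected decay count, so counting precision is uniform along the
  curve while deadtime and randoms act at their physical rates (histories
  are scaled through duration, never through activity).  NECR =
  T²/(T+S+kR), k = 1; the peak is located by quadratic interpolation
  through the three samples around the maximum.
* **BTAC acquisition** — half-ring, pulsatile arteries + venous return;
  arterial-only, venous-only and combined components.
* **Ring scaling** — 1–4 axial rings sharing one decay realization;
  gains are ratios of peak rates on 1-s bins; sensitivities are total
  counts divided by the time-integrated activity (cps/kBq).

BTAC experiments run at a configurable activity scale (default 1/100 of
the clinical curves); every reported acceptance quantity is a rate ratio
or fraction that is invariant under this scaling (deadtime is negligible
at the scaled wrist concentrations).  Problem sizes used by the shipped
acceptance script: ~5.8M decays for the volar-fraction run, 2 × 5M for
the NECR positions, ~5.8M (shared across ring counts) for ring scaling.

## Known limitations

* **Volar singles fraction.**  With the default vessel depth (arteries at
  y = −2.5 cm) the half-ring arc subtends ~80% of singles — above the
  70–75% reference band reported for this design from full GATE
  simulations, whose (unpublished) vessel coordinates were evidently
  shallower.  The fraction is a strong function
  of vessel depth; the geometry block makes it easy to explore.
* **Ring-scaling singles gains.**  In this solid-angle-driven model the
  4-ring/1-ring singles gain is ~3, bounded near 4 for a 20-cm line
  source under a 12-cm detector stack, versus the ~7.3–7.4 reference
  values from full GATE simulations (a superlinear-in-rings gain this
  model cannot produce).  Coincidence gains are strongly superlinear here as well
  (~10×), because oblique cross-ring pairs open phase space
  quadratically.
* **Crystal separability.**  The full-deposition efficiency model
  separates CeBr3 and LaBr3 singles by ~13% (their attenuation lengths
  differ); detailed partial-deposit physics with their near-identical
  effective Z would bring them closer together (they are reported as
  indistinguishable in full simulations).
* **NECR absolute values** depend on the unpublished digitizer constants
  (deadtime, window); only cross-position ratios and orderings are
  meaningful here, and the simulated NECR curves remain on the rising
  limb up to 14 MBq rather than turning over near 3.5 MBq.
* No image formation, no positioning within the monolithic block, no
  inter-crystal scatter, no multiple phantom scatter, no metabolite or
  hematocrit handling, no superficial veins.
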