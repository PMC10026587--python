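# Methods

This note records the models implemented by `pimidetect`, the conventions
and defaults chosen where the problem left the design open, and what the
synthetic scenes do and do not establish about real data.

## Per-pixel demodulation

The modulation law `I = (1/2) I0 [1 + sinδ · sin 2(θ − φ)]` is linear in
`(a, s, c) = (I0/2, I0/2·sinδ·cos2φ, −I0/2·sinδ·sin2φ)`, so each pixel is
inverted by harmonic regression on the design matrix `[1, sin2θ, cos2θ]`.
For equally spaced angles (the default 10 × 18° protocol) this is the exact
discrete Fourier estimate; for arbitrary non-degenerate angle sets it is the
least-squares solution. A whole stack shares one design matrix, so
demodulation is a single (3 × n) pseudo-inverse applied to the flattened
frames — a 512 × 512 × 10 stack takes well under a second on one CPU.

Conventions and edge cases:

* **Mean-level normalization.** `i0` is defined as twice the fitted mean
  level, so the modulation law holds verbatim with the returned parameters.
  (Describing `I0` as "the average intensity over all polarization states"
  is inconsistent with the law by a factor of two; the formula wins.)
* `sinδ` is reported non-negative with `φ ∈ [0°, 180°)`; the sign of the
  modulation is not separately identifiable from a 90° shift of `φ`.
* `sinδ` estimates above 1 (possible under noise) are **kept and flagged**,
  not clamped, so downstream statistics are not biased.
* A non-positive fitted mean level forces `sinδ = 0` with a flag; zero
  modulation amplitude leaves `φ` undefined, which is reported as 0 with a
  flag. Amplitudes below 10⁻¹² of the mean level are treated as
  least-squares dust and zeroed.
* Fewer than 5 samples, or angles not pairwise distinct modulo 180°, are
  errors at the series level; whole-stack demodulation never aborts on a
  degenerate pixel — it flags it.

## Lattice registration and segmentation

The unit pitch is estimated from the image autocorrelation (peak within
±25 % of the user's guess, sub-pixel by 3-point parabolic interpolation) and
the unit centres from the peak of the map's circular self-convolution: the
rendered unit motif is symmetric about its centre, and self-convolution
peaks where two symmetry centres align. That peak determines the centre only
modulo half a pitch; the ambiguity is resolved by choosing the candidate
whose pitch-periodic comb collects more mean intensity (ring centres are
bright, inter-unit gaps dim). Registration fails loudly when the
autocorrelation peak is below 0.2 of the zero-lag value (no periodic signal)
or the map spans fewer than 3 × 3 pitches.

Crops are aligned to the **nearest pixel**, never interpolated: the
downstream statistics are pixelwise sums and resampling would blur them.
Units whose crop leaves the image are marked invalid and excluded from all
statistics. A supplied layout (JSON) bypasses estimation entirely.

One degenerate geometry is worth knowing about: if the dipole-lobe offset
equals exactly a quarter pitch, the clean lattice pattern is half-pitch
periodic along the longitudinal axis and the symmetry-based registration is
inherently ambiguous. The default scene geometry (13 px offset at 64 px
pitch, i.e. ~200 nm — the gap position of a 130 nm-radius ring) avoids this.

## Extended Laplace operator

Each valid unit with a complete ring of 8 valid neighbours gets the
pixelwise neighbour-mean subtracted. The operator is linear, annihilates any
unit field constant or affine in lattice index (hence smooth background
trends), and returns exactly the hand-computable stencil value on scalar
units. Border units are excluded, not padded: padding would fabricate
background that the subtraction then "detects".

## Asymmetry statistic

`As = Isum · (A/B + B/A − 2)` with `A`/`B` the upper/lower half-sums of the
unit patch (an odd middle row belongs to neither half — symmetric
treatment) and `Isum` the sum of strictly positive pixels. Edge cases: a
zero half-sum leaves the ratio undefined and marks the record invalid
(never raises); a patch with no positive pixels scores 0 and stays valid.
Calls use strict inequality `|As| > threshold`, default 7; a recalibration
utility (`threshold_from_clean`) returns a margin times the largest clean
|As| for arrays whose noise departs from the defaults.

**Which image the statistic reads.** The statistic is evaluated by default
on the **raw sinδ unit patch**, with unit validity still requiring the full
Laplace neighbourhood (so both variants report the same interior units);
`score_source="laplace"` switches to the background-subtracted patch. The
raw patch is the default because its half-sums are bounded away from zero
by the unit's baseline, which keeps the ratio statistic stable: on the
Laplace patch of a virus-bearing unit every pixel is ≤ 0 (the unit is a
pure deficit relative to its neighbours), so `Isum ≈ 0` there, while clean
Laplace patches have near-zero half-sums whose ratio is heavy-tailed noise.
The Laplace image remains essential as the background-cancelled *display*
and for locating deficits; the ratio statistic just should not divide by
its residuals.

**Direction and sign.** The formula is symmetric under `A ↔ B`, so the
score's own sign cannot encode the attachment side (it is negative exactly
when the half-sums have opposite signs). The side is therefore derived from
which half is weaker, and reports carry a *signed* directional score
(= |As|, positive for a top-side deficit, negative for bottom-side), which
is the form in which per-unit values are displayed. The convention "top ↔
positive" is arbitrary but fixed and recorded in every run manifest.

## Detection-limit model

Closed form throughout: `P1 = πR²/L²` (capture of a single uniformly
deposited particle within radius `R_det` of a ring on a pitch-`L` lattice),
`P2` the misdetection probability of a captured particle (plug-in estimate:
missed/attached), and `P_N = 1 − (1 − P1(1−P2))^N` for `N` independent
particles. The real-valued bound is
`N* = log(1 − P_target)/log(1 − P1(1−P2))`; with the reference inputs
(`R_det = 210 nm`, `L = 1 µm`, `P2 = 1/6`, target 0.999) `N* ≈ 56.31`.
The **reported** minimum uses round-to-nearest (56), matching the
established reporting convention for this quantity; the mathematically
strict ceiling (57) is always returned alongside. The 150 µL reference
volume is a report-formatting parameter only. Multiple particles on one
ring are neglected (their probability is small at these concentrations),
and deposition is treated as Bernoulli-independent; droplet evaporation
dynamics are not modelled.

## Synthetic scenes

The generator emulates the phenomenology the analysis relies on, not the
electromagnetics that produces it:

* a clean unit is a baseline sinδ floor (0.1) plus two mirror-symmetric
  Gaussian lobes (amplitude 0.5, σ = 6 px, offset ±13 px) along the
  longitudinal axis — the minimal shape with the observed symmetric-dipole
  pattern;
* a virus multiplies one lobe by an attenuation (default 0.5) and lowers
  the unit floor (default 0.02) — the "weaker lobe, deeper valley"
  signature;
* field-wide background unevenness enters as a trend affine in unit index
  (amplitude 0.02 corner to corner), per-unit lobe-amplitude jitter
  (σ = 2 %) stands in for fabrication variability, and frames carry
  additive Gaussian camera noise (σ = 2 counts on a 1000-count level);
  Poisson shot noise is not modelled;
* geometry: 1 µm pitch sampled at 15.625 nm/px → 64 px units; 10 angles at
  18°; all parameters exposed on `SceneSpec`; everything is deterministic
  given the seed (scene and noise use separate spawned substreams).

What passing the synthetic end-to-end check does **not** show: robustness
to real point-spread blur, focus drift, shot noise, lattice distortion or
rotation, non-specific binding, or quantitative lobe shapes (unpublished
for real arrays — the defaults were set once so that planted effects are
detectable without being trivial at the stated noise). The default 10 × 10
end-to-end scene (six planted viruses) runs the full chain in a few seconds
on one CPU; this size was chosen to give 64 interior units, comfortably
enough to demonstrate a zero-false-positive operating point.

## Known limitations

* The lattice registration assumes an axis-aligned rectangular lattice of
  symmetric unit motifs; rotated or distorted arrays are out of scope.
* Transverse (left/right) asymmetries are not scored; only the
  longitudinal split the attachment geometry makes informative.
* One virus per unit is assumed; multi-occupancy is not disambiguated.
* The statistic's absolute scale depends on the unit's positive mass, so
  the threshold 7 is meaningful at the reference imaging conditions;
  `threshold_from_clean` exists precisely because other conditions shift
  the clean envelope.
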