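# Methods

## Deformability model

A trapped object's projected area is treated as quasi-static per pressure
step and linear in the applied acoustic pressure over 0–1 MPa:

    A(P) / A(0) = 1 + s·P,

with `s` (per MPa) the deformability index. Normalization divides by the
zero-pressure baseline area, so the curve is exactly 1 with the trap off;
this is the only normalization consistent with ramps that start at 1.000
and grow above 1. `s` is fit by ordinary least squares with a free
intercept, the baseline point included. Forcing the intercept to 1 changes
the fitted slope by well under 1% on the reference ramps; the free
intercept doubles as a linearity diagnostic. A fit requires at least three
points; a ramp truncated because the object burst mid-ramp (the softest
hydrogel spheres burst at 0.43 MPa) is fit on its available points with
`n_points` recorded so users can weight or exclude it. The group summary
is the arithmetic mean and sample standard deviation (ddof = 1) of the
per-sample slopes.

## Area segmentation

Manual polygon tracing is replaced by a deterministic recipe: Gaussian
pre-smoothing (σ = 1 px, configurable) to suppress shot noise, Otsu global
thresholding, polarity auto-detection (the thresholded side covering the
minority of the field is taken as the object; bright-field contrast can go
either way), hole filling, and retention of the largest connected
component. Area is the pixel count times the squared pixel size. Pixel
counting differs from polygon vertex area by well under a percent at the
≥ 25 px radii this assay produces and has no vertex-ordering ambiguity.
QC failures are hard errors, not silent values: a frame with no resolvable
object, or whose dominant component touches two or more image borders, is
rejected with the frame index in the message.

## Punch-model aspiration

Young's modulus of an aspirated sphere follows `E = 3RΔPφ(η)/(2πD)`. The
wall function φ(η) is a configured scalar — 2.014 by default, with the
common literature value ~2.05 selectable; the punch-model functional form
itself is out of scope. Since the model implies `D ∝ ΔP` through the
origin, the default estimator fits that proportionality by least squares
through the origin and inverts the slope; a pointwise per-step estimator
(mean ± sd of single-step evaluations) is kept for comparability, and the
two agree to numerical precision on noiseless linear traces. The
regression R² is uncentered (the model has no intercept), so a flat,
non-proportional trace scores poorly instead of trivially reaching 1.
Units are µm and Pa; the two lengths cancel, so E carries the unit of ΔP.

## Calibration curve

The five AHS groups supply (slope, E) knots, joined by label, sorted by
slope, and validated for strict monotonicity (E must decrease as slope
increases). Interpolation is piecewise linear in (slope, E): it reproduces
the reference interpolated moduli essentially exactly, whereas log-E
interpolation does not (it remains available behind `scheme="log"` for
sensitivity analysis). Queries outside the knot range [0.016, 0.728] are
refused rather than extrapolated — the surrogate calibration carries no
information there; callers may clamp explicitly. A cell group's modulus is
the mean ± sd of its per-sample interpolated moduli; out-of-range samples
are counted, excluded and warned about. An alternative uncertainty
(propagating the knot E sds) was considered and not made default, since
the per-sample spread is the quantity the assay actually observes.

## Statistics

One-way fixed-effects ANOVA is computed from the classical sums of
squares; Scheffé pairwise comparisons use the omnibus MSE:
`F_ij = (ȳ_i−ȳ_j)² / (MSE(1/n_i+1/n_j))`, referred to `F(k−1, N−k)` after
division by `k−1`. Unequal group sizes are supported. Scheffé is never
more liberal than the omnibus test, nor than the same contrast referred to
`F(1, N−k)` unadjusted. Viability uses a two-tailed two-sample t-test
(pooled-variance Student's by default, Welch by flag) of post-trap vs
pre-trap fluorescence, with the post-trap values reported normalized by
the pre-trap mean; significance defaults: 0.05 for ANOVA/Scheffé, 0.01 for
viability, both configurable.

## Acoustics utilities

The lateral beam width uses `LBW = N·c/(D·f)` with `N` the focal distance.
For this strongly focused element (f-number 0.8) the focus sits at the
geometric focal distance, and only that reading yields the ~17 µm
subcellular spot at 70 MHz; a flat-element near-field distance does not.
This working interpretation is documented, not asserted as general. Sound
speed defaults to 1500 m/s (water, room temperature). The voltage→pressure
mapping interpolates linearly inside the hydrophone-calibrated table and
refuses queries outside it; the packaged table is the six-step 0–23.7 Vpp
/ 0–1.00 MPa calibration of the 50 MHz device, with the finer
0.234/0.431/0.627/0.824 MPa step values used throughout.

## Synthetic data: what it emulates, and what it does not

The generators implement exactly the phenomenology the analysis fits, with
stored ground truth for recovery tests:

- per-sample slope `s_i ~ Normal(mean, sd)` truncated at 0 (rejection
  sampling); defaults: group means at the reference values, between-sample
  sd 0.02 per MPa for cells, 10% CV for the manufactured spheres;
- measurement noise `Normal(0, 0.005)` on the *normalized* area at P > 0,
  keeping the baseline anchor exact — matching ramps that all start at
  1.000; the 0.005 default makes 20-sample group means match the printed
  three-decimal precision and is configurable;
- baseline radii `Normal(10, 1) µm` (≈ 20 µm objects);
- frames: a filled centred ellipse of matching pixel area (fixed
  eccentricity; only projected area is modelled), Gaussian blur, additive
  Gaussian pixel noise; rasterization error is sub-percent at ≥ 25 px
  radii;
- aspiration: the punch model inverted, `D = 3RΔPφ/(2πE)`, plus length
  noise (0.05 µm default) floored at zero; per-sphere true E drawn with
  the reference between-sphere sds; suction ramps scaled per sphere so the
  tongue reaches ~3 µm within the 33.3 kPa controller ceiling;
- burst behaviour: an optional truncation pressure per group removes all
  steps above it (the 0.1% spheres keep three points).

Not emulated: acoustic radiation force physics and trap stiffness, cell
shape irregularity and blebbing, size-dependent energy delivery,
viscoelastic creep, optical artefacts beyond blur and additive noise, and
multi-object scenes. Passing recovery tests therefore demonstrate the
correctness of the measurement and calibration chain under the assumed
phenomenology, not robustness to every real-microscopy failure mode.

## Recovery oracles and problem sizes

Recovery tests compare pipeline outputs against the generator's *stored
realized draws*: fitted slopes against the drawn `s_i`, group moduli
against the curve built from the drawn spheres' mean true E at the drawn
samples' mean true slopes. Conditioning on the realized draws isolates the
measurement chain from finite-sample variation of the study design itself
(with the reference between-sphere modulus sds, five knots at n = 20
spheres carry ~4% sampling error before any measurement is simulated).
The shipped synthetic study uses 20 samples per group — the reference
design — with six-step ramps, rendered frames for two samples per cell
group (192×192 px, 0.25 µm/px), and 10-step aspiration traces; at these
sizes the whole suite runs in seconds. Statistical calibration checks use
1000 null replicates (viability type-I error) and 100 seeded studies
(significance pattern).

## Numerical choices and degenerate inputs

Slope fits require ≥ 3 points and nonzero pressure variance. A zero
within-group variance with nonzero between-group variance yields an
infinity-guarded F with p = 0; all-identical data is a validation error.
Single-sample groups report sd = 0 with an explicit flag. All generators
take integer seeds and are bit-reproducible; reports embed the seed, the
config hash and the package version. Tabular I/O is CSV with explicit
headers (pressures in MPa, areas in µm², suction in Pa, lengths in µm,
moduli in kPa); curves, reports and transducer specs are JSON.

## Known limitations

- φ(η) is constant per configuration; pipette-to-pipette geometry
  variation within a study is not modelled.
- The linear pressure–area law is phenomenological; no mechanism links the
  slope to modulus other than through the surrogate calibration, and the
  calibration is only as good as the surrogates' resemblance to cells.
- Interpolated moduli need not match contact methods (AFM) in absolute
  terms; the curve is internally consistent, not method-universal.
- Segmentation assumes one dominant object; partial occlusion or debris
  merging with the object inflates areas silently if it passes QC.
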