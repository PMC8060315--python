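# Methods

## Coordinate frame and viewing conventions

All geometry lives in a right-handed thoracic frame with origin at the
center of the aortic valvar orifice: `+x` toward the subject's left, `+y`
dorsal, `+z` cranial. The three body planes are viewed as a radiologist
would: sagittal from the subject's right, frontal from the front,
horizontal from above. Projection angles are measured from a per-view
reference line, increasing in the view's positive rotational sense:

| plane      | reference line            | angle formula      | positive sense    |
|------------|---------------------------|--------------------|-------------------|
| sagittal   | horizontal line (`+y`)    | `atan2(z, y)`      | toward cranial    |
| frontal    | sagittal line (`+z`)      | `atan2(x, z)`      | toward left       |
| horizontal | horizontal line (`+x`)    | `atan2(y, x)`      | toward dorsal     |
| horizontal | sagittal line (`+y`)      | `atan2(-x, y)`     | same sense        |

Cardiac (`X`) and sinus-node (`alpha`) angles use the horizontal-line
reference in the horizontal view; the AV-conduction-axis (`beta`) and
bundle-branch (`gamma`, `delta`) angles use the sagittal-line reference
there. These senses are chosen so that a positive rotation about a plane's
normal body axis increases every angle measured in that plane by exactly
the rotation amount — the property the posture simulation and several
exactness tests rely on. The source describes its references only
verbally, so the reference/sense assignment is a package convention, not a
reported fact; any fixed convention yields a self-consistent pipeline.

Angles are stored in degrees wrapped to `[0, 360)` (the horizontal SN mean
sits near 272°). Composed posture rotations are extrinsic, about the fixed
thoracic axes, in the documented default order sagittal → frontal →
horizontal (configurable via `rotation_order`).

## Reference axes

* cardiac axis: aortic valve center → left-ventricular apex;
* SN axis: total-least-squares line through the SN head, the top of the
  terminal crest, and the valve center (the line is over-determined by
  three points), oriented head → valve;
* AVCA axis: end of the compact AV node → branching point of the right
  bundle branch (the straight His-bundle segment);
* bundle branches: branch point → distal RBB / central LBB landmark,
  horizontal plane only.

## Over-determined angle triples

A 3D axis has two degrees of freedom, but three projection angles are
recorded per axis, so a requested angle triple is generally
over-determined. Axis directions are reconstructed by circular least
squares on the sphere (closed form, hence exact, when the triple is
internally consistent; `scipy.optimize.least_squares` over the best-ranked
starts otherwise), and the RMS angular residual is recorded in the
geometry's provenance rather than treated as an error.

This matters because the published summary values are *mutually
inconsistent as projections of single axes*: for any axis-aligned
convention the three plane tangents of one direction must multiply to
unity, and no sign/cotangent variant of the printed cardiac means (99.8,
46.8, 61.5) satisfies that identity (best case misses by a factor ≈ 3).
The mean-pose compromise axes therefore carry residuals of ~25–28° RMS,
and the fitted mean cardiac axis sits nearer the vertical than real
anatomy. Consequences handled explicitly:

* fitted directions are kept off exact view poles by a tiny (1e-5)
  in-plane nudge at the target angle, so every requested angle remains
  measurable;
* rigid-mode simulation trajectories of the mean heart are monotone in the
  sagittal sequence but not in all planes (tests compare against an
  explicit rigid-rotation oracle instead of assuming monotonicity);
* the measure → rebuild round trip is exact (< 1e-6°) precisely for
  internally consistent angle sets, e.g. angles measured from an actual
  direction.

## Synthetic cohort generator

The generator reproduces the *statistical* structure of the 23-heart
cohort; it does not model walls, valves, the Purkinje network, or
age-related change.

* Cardiac angles: independent normals with the published marginal
  means/SDs — (99.8, 12.1), (46.8, 8.1), (61.5, 13.4) degrees. All three
  are sampled (rather than deriving one from the other two) because the
  published marginals are not jointly representable by one axis under any
  fixed convention; the geometric compromise is pushed into the
  reconstruction residual, keeping every marginal faithful.
* CCS angles: `slope · X + intercept + eps` per plane, with
  `eps ~ N(0, sd_resid)` and `sd_resid = sqrt(sd_y² − slope² sd_x²)`
  (variance-addition law), so component marginal SDs reproduce the
  published ones. Where the summary table and the running text disagree
  (beta_sgt, beta_frt, delta) the defaults are the text values, which
  satisfy the OLS through-the-means identity.
* The horizontal SN equation as printed (`0.481 X − 244.2`) cannot pass
  through the printed means under any 360° branch; prediction keeps the
  printed equation (flagged in logs and the run manifest), while the
  generator alone substitutes the through-the-means intercept
  `272.4 − 0.481·61.5 = 242.82` so cohort marginals stay faithful with the
  printed slope.
* Dimensions: normals truncated to the printed ranges by rejection
  sampling (mean ± SD (range), mm).
* Randomness: a single integer seed, split into independent substreams per
  stage (angles, dimensions) via `numpy.random.SeedSequence.spawn`, so
  adding a stage does not shift existing draws. Identical parameters and
  seed give byte-identical outputs.

### Canonical layout

Anchor distances are stylised design values (the source prints component
dimensions, not distances to the valve): valve → apex 80 mm; SN head 35 mm
and terminal-crest top 18 mm from the valve along the SN axis; compact-node
end at (−3, −3, −4) mm; His bundle = penetrating + branching lengths from
the dimension table (mean 4.7 + 9.6 mm); bundle-branch courses of 2 × 24 mm
(RBB) and 2 × 15 mm (LBB) at their horizontal angles with a fixed 35°
caudal dip (which leaves the horizontal angles untouched). The
bundle-branch course deliberately extends the AV conduction axis farther
from the thoracic origin than the SN head anchor, so rigid posture
rotations displace the distal AVCA more than the SN — the displacement
ordering reported for postural change, which in vivo is caused by the
pulmonary-vein tethering of the SN (soft tissue is *not* modelled; the
package reports displacement metrics only).

## Regression and recovery

Fits are ordinary least squares on raw (unwrapped) degree values
(statsmodels OLS behind `fit_ols`); the cohort ranges are narrow enough
that circular regression is unnecessary, with the horizontal SN angle
generated in a contiguous branch around 272°. `residual_sd` is the RMSE on
n − 2 degrees of freedom, and every fitted line passes through the sample
mean point (asserted in tests against a hand-rolled normal-equations
oracle). Reported angles round half-up to one decimal, matching the
source's presentation. No significance machinery is attached: the package
reports estimates, residual SDs, and R² only.

`recover_parameters` runs a simulate-and-refit loop (default 1000
replicates of n = 23) and reports mean estimate, bias, and RMSE per pair;
slope estimates are unbiased within Monte-Carlo error and RMSE shrinks as
n grows.

## Posture simulation

`stepwise_positions` realises the five-pose grid `mean + k·SD`,
k ∈ {−2, −1, 0, +1, +2}, with the cohort SDs (12.1, 8.1, 13.4)° as
per-axis steps; standing is k = −1, lying k = +1. Increments are absolute
offsets from the mean pose, not cumulative steps. Two modes:

* **rigid** — heart and CCS rotate as one body; all angles re-measured.
  Conserves all inter-landmark distances to 1e-9 and shifts every
  horizontal-plane angle exactly under horizontal-only rotation.
* **regression** — component angles predicted from the published slopes,
  anchored at the base measurement (`y_k = y_0 + slope·(X_k − X_0)`), so
  both modes coincide at k = 0. This is the per-plane description the
  scatterplot fits make, and the mode in which the frontal AVCA
  counter-rotates (slope −0.733) while all SN pairs are concomitant.

Classification is the sign of the least-squares slope of component angle
against cardiac angle in the same plane; |slope| < 0.01 deg/deg reports
"flat" (a numerical guard, not a reported value). The standing/lying
report carries both nominal pose angles (base + k·SD, whose lying −
standing span is exactly 2·SD per axis) and measured angles (which differ,
since the three single-axis factors interact in a composed rigid
rotation).

## Numerical choices

* Geometric assertions at 1e-9 (exact arithmetic); generator round trips
  at 1e-6°; degenerate-projection threshold 1e-9 on the projected norm.
* Direction fitting: candidate starts from the closed-form pair solutions
  plus a 32-point Fibonacci sphere, ranked by raw cost, best six refined;
  deterministic, ties broken by order.
* Truncated-normal sampling by rejection (acceptance is high: printed
  ranges span roughly ±2 SD).
* Problem sizes: cohorts of n = 23 as published; large-sample fidelity
  checks at n = 1e5 on the (vectorised, geometry-free) angle table;
  recovery experiments at 1000 replicates.

## Known limitations

* The printed summary angles are internally inconsistent as 3D
  projections (see above); the package reports residuals instead of
  resolving the inconsistency, and the mean-pose heart is a documented
  compromise, not an anatomical reconstruction.
* The pipeline's `fit` stage uses the generated angle table; fitting
  angles re-measured from reconstructed geometries would fold the
  reconstruction compromise of over-determined triples into the frontal
  estimates.
* No soft tissue, no Purkinje network, no imaging: the pipeline starts
  from landmark geometry and emulated statistics, so passing tests show
  fidelity to the published summary statistics and self-consistency of the
  measurement scheme — not anatomical accuracy of any individual synthetic
  heart.
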