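# Methods

This note records the models behind `logradient`, the parameter choices
that matter, and what the synthetic tests do and do not demonstrate.

## Local-gradient operator

The local gradient at a pixel is the intensity-weighted centroid of the
pixels within radius *r*, relative to the window center.  Conventions:

* **Window**: side K = 2⌊r⌋+1 — odd, so the window is centered on a pixel
  (r = 2.5 gives the canonical 5×5 window).  The circular mask keeps
  offsets with distance ≤ r (21 of 25 pixels at r = 2.5).
* **Output geometry**: the full valid-correlation region,
  (m−K+1)×(n−K+1), with origin offset (K−1)/2 recorded on the field so
  every reported center is in source-image pixel coordinates (0-based,
  x = column, y = row, pixel centers at integers).
* **Computation**: direct spatial correlation for K ≤ 7, FFT otherwise;
  both agree with the nested-loop sliding-window definition to 1e−9
  (asserted against an independent loop oracle).  `precompute_transforms`
  caches the kernel FFTs for repeated same-shaped frames; the cache is a
  pure optimization (results agree to 1e−12) and is validated against the
  image shape and radius at use time.
* **Low-support windows**: windows whose total mass is below 1% of the
  maximal window mass get gradient (0, 0) (`support_floor=0.01`).  The
  centroid of a PSF's far tail is numerically defined but meaningless;
  on a near-zero-background frame those tail windows would otherwise
  saturate the magnitude raster out to its edge, which breaks translation
  equivariance of the thresholded pipeline and degrades the center
  estimate.  On any frame with an appreciable background the floor is
  inactive and the operator is the plain centroid everywhere.
* **Image normalization**: the xy entry points (`localize`,
  `detect_particles`) shift the image minimum to zero by default.  The
  gradients are exactly invariant to brightness scaling, and the
  least-squares center to constant offsets, so this costs nothing — but
  on noisy frames it leaves a ~4σ pedestal (the magnitude of the most
  negative noise excursion) that keeps window masses positive and the
  centroid bound |G| ≤ r valid.  This mirrors the common practice of
  scaling camera frames to [0, 1].  The brightfield and double-helix
  z-metrics take frames as-is: brightfield sums depend on the intensity
  scale that the per-particle calibration absorbs, and both modalities
  carry an optical background that min-shifting would remove.

## xy localization

Selected gradient pixels (|G| ≥ threshold_frac · max|G|) each define a
line through their position along their gradient direction.  The center
solves the 2×2 normal equations of the weighted perpendicular-distance
objective; lines are weighted by gradient magnitude (a uniform-weight
switch exists).  The normal matrix is declared singular above condition
number 1e8 (all-parallel lines).  The solver is checked against a 0.01-px
grid search of the stated objective.

The estimator assumes the gradient lines concur, which holds for radially
symmetric particles.  For a strongly astigmatic PSF the lines converge
toward the two astigmatic foci instead, and the xy error grows to a few
pixels at ±500 nm defocus — intrinsic to the estimator, not noise.  The
double-helix lobe midpoint is recovered to ~0.15 px (the two-lobe
structure is 180°-symmetric about it).

## z-metrics

* **Brightfield**: z = ½[(Σ G_x over columns right of center) − (left)] +
  ½[(Σ G_y below) − (above)], with the center row/column excluded to
  avoid double counting.  The sums run over the full gradient raster;
  thresholding is only used for the xy step.  For a radially symmetric
  bead, G_x is antisymmetric in x, so the metric equals twice the
  right-half sum and tracks the radial ring profile, which inverts
  through focus.
* **Astigmatism**: selected lines are split into half-planes about the
  center; the four per-half least-squares intersections form a vertical
  pair and a horizontal pair.  The metric is the *signed* difference of
  the axis-projected separations, (P_bottom−P_top)·ŷ − (P_right−P_left)·x̂.
  The sign matters: the intersection points pass through each other at
  focus, and an unsigned distance folds there, producing a plateau that
  amplifies noise ~10×.  The signed form is linear through focus, zero
  for a round PSF, and negates under 90° rotation.
* **Double-helix**: θ = ½·atan2(2μ₁₁, μ₂₀−μ₀₂)·180/π ∈ (−90°, 90°] from
  the magnitude-weighted central second moments of the thresholded
  magnitude raster (a binarized-weights switch exists).  Angles are
  unwrapped with period 180° against neighboring planes before a
  calibration is built.  An isotropic moment tensor raises an
  undefined-orientation error rather than returning an arbitrary angle.

## Calibration

A calibration stack must have ≥ 3 planes, strictly increasing stage
positions, and strictly monotonic metric values (violations raise an
error naming the offending interval).  Inversion is piecewise-linear
interpolation in look-up mode — monotone by construction, exact at the
nodes, and refusing to extrapolate — or an ordinary-least-squares linear
fit.  Because the calibration particle is a fixed fiducial, the stack
protocols estimate one robust center (median of per-plane localizations)
and evaluate every plane against it; this also covers brightfield planes
near the contrast crossing where the bead vanishes and per-plane
localization fails.

Calibrations are per-particle: the metrics are in arbitrary units whose
scale depends on particle size, illumination, and r, so curves transfer
between particles only up to a bias, as is standard for this kind of
axial readout.

## Synthetic models

All renderers integrate the analytic intensity over each pixel by 4×
supersampling (16× agrees to <1e−3) and return ground truth; noise is
seeded and bit-reproducible.  SNR is defined operationally as max signal
over noise standard deviation; additive Gaussian noise is the default,
with a Poisson option scaled so the peak shot-noise SNR matches.

* **Gaussian spot**: symmetric, σ default 3 px (benchmarks use σ = 5 px so
  the r = 12 study window is matched to the particle, as the method
  prescribes).
* **Defocused bead**: difference-of-Gaussians ring,
  I = B + (z/z_range)(A₁g(σ₁) − A₂g(σ₂)) with σ₁ = 6, σ₂ = 12 px,
  A₁ = 1, A₂ = 0.6, B = 1, z_range = 500 nm.  The amplitude is odd-linear
  in z: contrast inverts through z = 0 (as brightfield bead images do),
  which makes the brightfield metric odd and strictly monotonic, and the
  focal plane has exactly zero contrast.  This is a parametric stand-in
  for an experimentally recorded radial bead profile, not a diffraction
  model; consequently the ≈0.7 nm axial accuracy the acceptance protocol
  reports at SNR 200 shows the metric + calibration machinery at its
  noise floor on a well-behaved profile, not the accuracy on any
  particular microscope.
* **Astigmatic PSF**: elliptical Gaussian with σx = σ0(1 + z/S),
  σy = σ0(1 − z/S); σ0 = 7 px, S = 1000 nm (3:1 axis ratio at ±500 nm),
  background 0.1 of peak.  A range error is raised once either width
  would collapse below 20% of σ0.
* **Double-helix PSF**: two equal Gaussian lobes (σ = 3.5 px) separated by
  20 px about the midpoint, axis angle 0.1°/nm·z.  The separation is
  deliberately comparable to the r = 15 analysis window: much smaller
  separations make the thresholded magnitude a featureless ring and the
  moment orientation meaningless.  The model matches the described
  two-lobe geometry only, not a full engineered-PSF simulation.

What the synthetic data does **not** emulate: diffraction rings and
aberrations beyond the parametric forms, pixel-correlated camera noise,
EMCCD gain statistics, uneven illumination, or sample motion blur.
Passing tests therefore demonstrate correctness and noise behavior of the
algorithms under the stated models, not end-to-end accuracy on real
hardware.

## Multi-particle detection and linking

DBSCAN clusters the selected gradient pixels (eps defaults to r/2,
min_samples 5); each cluster is localized from its member lines only.
Two geometric filters reject noise clusters, which exist because the
window-averaged gradient field is spatially correlated and its noise
excursions pass a pure density test: a cluster must have rms spatial
spread ≥ 0.45r (a real particle's selected pixels ring it at the window
scale; measured noise blobs stay below 0.36r) and intersection residual
≤ 0.15× its spread (particle lines converge with measured ratios ≤ 0.13
down to SNR 3; noise lines do not).  Overlapping particles merge — only
separations > 2(r + eps) carry a fidelity guarantee, matching the
single-particle result on a crop to 0.1 px.

Linking is greedy mutual-nearest assignment per frame transition with a
distance gate and a gap budget — chosen over global (Hungarian)
assignment because the intended regime is online tracking; every
detection ends up in exactly one trajectory.

## Feedback simulation

The plant is a virtual stage (linear ramp + random walk + sinusoid drift,
nm units) with a first-order-lag actuator and travel/integral clamps; the
sensor is the full render → localize → calibrate chain (pixel size
18.3 nm, z through a linear fit over a ±500 nm, 100 nm-step scan); the
controller is PI per axis, defaults kp = 0.5, ki = 0.05 per step — kp = 0.5
contracts a step disturbance by ×0.5 per iteration with an ideal actuator,
and the small integral term removes ramp bias.  The loop locks at a
defocused setpoint (+400 nm on a z_range = 1000 nm bead) where the bead
has contrast; stabilization needs a locally monotonic metric, not an
absolute z.  Matched-seed on/off runs share the identical drift
realization, so the residual-std ratio isolates the controller's effect.
Real-hardware stability figures are outside what a simulation can claim;
the tests assert relative suppression and convergence only.

## Benchmarks

The accuracy-vs-SNR harness renders the same seeded image set per SNR
level for every localizer and reports mean Euclidean error with failures
counted separately, never silently averaged.  The default grid
{2, 3, 4, 5, 7, 10, 15, 20, 30, 50, 100, 200} spans the regimes from
noise-dominated to discretization-dominated.  Baselines: threshold-
subtracted intensity centroid, adjacent-pixel central-difference
gradients through the same intersection backend (initialized Gaussian σ
at a quarter of the frame for a wide basin), and a nonlinear 2D Gaussian
fit with termination tolerance 1e−4.

## Problem sizes

The stack protocols use 101 planes of 128×128 px (brightfield, r = 35) or
100×100 px (astigmatism, r = 10) and 151 planes of 80×80 px
(double-helix); the feedback runs use 120–200 steps of 96×96 px frames.
These sizes put every estimate well past its asymptotic regime while a
full test run stays in the tens of seconds.
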