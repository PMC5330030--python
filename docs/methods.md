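# Methods

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of `avpdtrack`. It documents design
decisions; every empirical statement here is one the test suite or the
acceptance script computes itself.

## Coordinate and sign conventions

Images are indexed (row, col), 0-based and pixel-centered. All geometry is
carried out in millimetre space: landmark coordinates are multiplied by the
per-axis pixel spacing before any line fit or projection, so anisotropic
spacing cannot bias the AV-plane direction. Displacement is the projection of
the motion vector onto the unit apex direction, negated: motion toward the
apex is **negative**, matching the convention in which a healthy LV AVPD
curve reaches ≈ −13 mm at end systole. Frame 0 is end diastole (retrospective
gating starts at the R-wave) and every curve is anchored to exactly 0 there.

## AV-plane definition

- 2-chamber: the line through the two points (forced).
- 4-chamber: the total-least-squares line (first principal direction of the
  three points in mm space), i.e. orthogonal — not vertical-residual —
  minimization. Ordinary regression would make the fit depend on the image
  orientation; TLS is rotation-invariant.
- 3-chamber: the line through the LV-lateral point and the midpoint of the
  septal and RV-outflow points — the simplest construction that passes
  between the two right-sided points while intersecting the lateral one.
- The apex side of the perpendicular cannot be inferred from the line alone.
  An explicit apex hint point is used when given; otherwise the perpendicular
  is pointed toward the image centroid, which is below the annulus in
  standard long-axis acquisitions. With neither available the fit refuses.

## The statistical curve prior

Training curves (signed mm displacement over one cycle) are linearly
interpolated to a common 30-frame grid on normalized cycle time
t&nbsp;=&nbsp;i/(n−1), preserving both endpoints, then normalized by their
amplitude, defined as the maximum absolute displacement (AVPD curves are
one-signed, so max-abs is the natural amplitude; an all-zero curve is passed
through with amplitude 0 and a warning rather than an error). Resampling
happens before normalization; the order matters only at the third decimal
for smooth curves.

PCA is an eigen-decomposition of the covariance of the mean-subtracted
normalized matrix. Five components are retained by default; on the synthetic
training family the five leading eigenvalues carry ≥ 99% of the eigenvalue
sum (asserted in the acceptance suite). Reconstruction normalizes the input
curve by its own amplitude, projects the mean-subtracted curve onto the
retained eigenvectors, back-projects, restores mean and amplitude, and
re-pins frame 0 to exactly 0. Component weights are not clamped during
reconstruction. One subtlety is worth recording: the prediction curve is
proportional to the training mean, and because the mean of unit-amplitude
curves itself has amplitude slightly below 1 (subjects peak at different
frames), reconstructing the prediction curve reproduces it only up to a
residual (1−M)·(I−VVᵀ)·mean·amplitude, about 0.25 mm here — far below pixel
resolution but not machine zero. The complete 30-component basis is an exact
identity.

The prediction curve — the reconstructed mean rescaled by the mean training
amplitude — drives the tracker's search-window placement. It is deliberately
**not** scaled to the individual subject; the consequences are discussed
under Limitations. Curve sampling for visualizing the prior's span draws
component weights uniformly within ±2 SD of the prediction curve's weights
(uniform rather than truncated-normal: the span illustration needs the
envelope, not the density).

Models serialize to a single versioned JSON document keyed by landmark
(`view/label`); arrays are stored as plain nested lists, which round-trip
floats exactly.

## Tracking

Patch sizes in mm are converted per axis to the nearest odd pixel count
(ties round up, so 12 mm at 1.5 mm/px → 9 px); centered templates need odd
sizes. The template (ROI) is never clipped — landmarks are interior by
anatomy, and a template leaving the image is an error — while the search
window (ROS) is clipped at image borders, erroring only if clipped below the
template size.

The correlation map is evaluated directly (vectorized over all placements)
rather than via FFT, keeping it bit-faithful to the definition; the map is
clipped to [−1, 1] against rounding. Zero-variance templates or windows make
γ undefined there; those placements report 0 and a degeneracy flag, and if
every placement is degenerate the tracker falls back to the predicted
position with a warning. The argmax is taken with deterministic tie-breaks:
smallest Euclidean distance to the prediction-centered placement, then
row-major order.

Tracking is integer-pixel by default; an optional three-point parabolic
refinement per axis (vertex clamped to ±0.5 px) is available behind the
`subpixel` flag. Both directions traverse the cycle cyclically from end
diastole — forward to the last frame, backward through the wrap — which
assumes full-cycle (retrospectively gated) data. The two displacement curves
are merged with weights linear in each run's own tracking order (first
tracked frame 1, last 0), making the weights complementary at every cycle
frame; the merged curve is therefore pointwise between the two tracks, and
each run contributes most where it has accumulated least drift. Merged
curves are resampled to the 30-frame grid, reconstructed through the prior,
and resampled back.

Default ROI 13 mm / ROS 27 mm are fallbacks sized to cover ±2 SD of
per-frame AVPD steps at 30 frames/cycle; the optimizer module exists
precisely to replace them with per-landmark tuned values, and the
acceptance-level noisy-recovery check runs under optimizer-tuned sizes.

## Derived measures

LVAVPD is the frame-wise mean of the six left-sided landmark curves; RVAVPD
is (rv_lateral + rv_outflow + mean(septum₃ch, septum₄ch))/3. End systole is
the curve minimum, earliest frame on ties. Velocities: the curve is smoothed
with a centered cyclic 3-sample moving average, differentiated by forward
differences (cyclic at the wrap; mm/ms × 100 → cm/s), and the reported value
is a chord slope of the *averaged* curve — frames [t*−2, t*+2] around the
most negative derivative for emptying (reported negative), the asymmetric
window [t*−1, t*+2] around the most positive derivative for filling
(reported positive). The asymmetric filling window is implemented as
printed. Using the averaged curve for the chord keeps the slope consistent
with the extremum localization.

Atrial contraction searches for the diastasis plateau as the frame after
peak filling where |second forward difference| of the averaged curve is
minimal, and reports 100·|AVPD(ED) − AVPD(plateau)| / |AVPD(ES)|. The
degenerate branch (empty post-filling window → value computed over the full
diastole, flagged) is structurally rare: for an anchored, non-positive
curve the averaged last-frame difference is dominated by its predecessor, so
the filling peak cannot land on the final frame unless the curve overshoots
baseline early in the cycle. A flat curve reports 0%, flagged. Note the
printed velocities are dimensionally consistent (a 14 mm excursion over
~350 ms peaks near 6 cm/s, the familiar echocardiographic s′ range).

## The phantom

The generator's task is to emulate exactly the image properties the tracker
relies on, with closed-form ground truth — not anatomical realism.

- **Curve family:** piecewise-cosine segments with C¹ joins — descent to
  −amplitude at the end-systolic fraction (snapped to the frame grid so the
  minimum is sampled exactly), rapid early-diastolic return, a flat diastasis
  plateau, an atrial kick back to 0 at the wrap. Parameters: amplitude (mm),
  ES fraction (default 0.37), diastasis level (fraction of amplitude, 0.30),
  atrial-kick fraction (0.15), rapid-fill fraction (0.20).
- **Populations:** subject amplitudes are drawn per group — LV 11 ± 2 mm
  (patient-like), 14 ± 3 (control), 16 ± 2 (athlete); RV 17 ± 4 / 20 ± 4 /
  22 ± 3 — with per-landmark factors (lateral walls excurse slightly more
  than the septum, the RV free wall most). The default training mix is 16
  patients, 9 athletes, 15 controls (n = 40). Timing parameters vary mildly
  per subject; a smooth two-harmonic perturbation of SD 0.05 mm is added so
  training curves are not exactly low-rank while the family stays
  five-dimensional to the 99% level — the compactness the prior assumes.
- **Rendering:** 128 × 128 images at 1.5 × 1.5 mm, 30 frames, 1000 ms cycle.
  Around each landmark a persistent tile — a blood/myocardium intensity step
  plus band-limited speckle — is translated rigidly along the apex axis by
  that landmark's curve (sampled with linear interpolation, exact for
  integer shifts); overlapping tiles are resolved by nearest-landmark
  ownership so every annulus point keeps its own motion. Optional Gaussian
  noise is scaled to the blood/myocardium contrast. Motion leaving the image
  is an error. A `quantize_px` mode snaps shifts to whole pixels (adjusting
  the truth accordingly) for exact-recovery checks.

What the phantom does *not* model: through-plane motion, myocardial
deformation, SSFP banding, breathing, flow artifacts. Tests passing on
phantoms therefore demonstrate the algorithmic properties of the pipeline
(formula fidelity, recovery under translation + noise, the algebra of
merging and reconstruction), not clinical accuracy on patient images.

On noise-free phantoms with integer-pixel motion, recovery is exact. With
continuous subpixel motion, integer-grid matching shows a small systematic
systolic lag (up to ~1.3 px at 30 frames/cycle; identical forward and
backward, so it is a sampling-phase effect rather than drift) — comparable
to the bias floor one expects from any integer-grid template tracker.

## Parameter optimization

Every (ROI, ROS) pair with ROI < ROS on the grid is evaluated by tracking
all training subjects; Pearson R, bias and SD of the end-systolic
difference, and the mean curve 2-norm are computed per cross-validation fold
and averaged. Folds are subject-level contiguous blocks after a seeded
shuffle; the fold count is reduced when needed so that every fold holds at
least two subjects (R and SD are undefined below that). The selected pair
minimizes SD subject to R ≥ the 75th percentile of all evaluated pairs,
|bias| ≤ the 25th percentile of |bias| (a large negative bias is as bad as a
positive one), and 2-norm ≤ its 75th percentile; if no pair satisfies all
three, constraints are dropped one at a time — 2-norm, then bias, then R —
down to the unconstrained SD minimum. Equal-SD ties resolve to the smallest
ROS, then smallest ROI (cheaper, less drift risk). Percentiles are pooled
over all evaluated pairs of that landmark.

## Problem sizes

Desk-scale runs use 40 synthetic training subjects for the prior, ~10–12
phantom subjects for grid searches, and 50 phantoms for the noisy-recovery
rates; images are 128 × 128 × 30 frames. These sizes keep every derived
statistic stable (the compactness figure varies by < 0.3 percentage points
across seeds) while the whole suite runs in about a minute.

## Known limitations

- The prediction amplitude is the training-population mean, not
  subject-adaptive. Subjects far from that mean (very large athlete RV
  excursions, or a motionless plane) can carry their true match outside the
  search window; the optimizer's wider per-landmark ROS mitigates but does
  not eliminate this, and a motionless subject needs a search window
  covering the full prediction excursion.
- Prospectively gated (partial-cycle) data are out of scope: backward
  tracking, the prior, and the cyclic measures all assume a periodic,
  full-cycle acquisition.
- Velocities are annular-plane velocities in cm/s, not volumetric rates.
- The 3-D (scanner-coordinate) AV-plane variant is not implemented; planes
  are per-view 2-D lines.
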