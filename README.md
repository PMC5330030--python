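# avpdtrack

Time-resolved tracking of the atrioventricular (AV) plane in cardiac
long-axis cine MRI.

The AV plane — the fibrous ring carrying the cardiac valves — moves like a
piston toward the apex in systole and back in diastole, and its longitudinal
excursion (atrioventricular plane displacement, AVPD; the CMR analogue of
echocardiographic MAPSE/TAPSE) accounts for the majority of both ventricles'
stroke volume. `avpdtrack` turns 8 manually placed end-diastolic annulus
points in the 2-, 3- and 4-chamber views into full AVPD curves over the
cardiac cycle, plus the derived clinical measures: left- and right-ventricular
end-systolic AVPD, peak emptying and filling velocities, and atrial
contraction. It is aimed at cardiac-MR researchers who want a reproducible,
scriptable displacement measurement and a fully synthetic test bed for it.

## Method

Each landmark is tracked independently through four stages:

1. **AV-plane definition.** Per view, a line is fitted through the
   end-diastolic landmarks (total-least-squares for three points; through the
   LV-lateral point and the septal/RV midpoint in the 3-chamber view). Only
   motion perpendicular to this line counts, measured in mm with apex-ward
   displacement negative, so a normal LV curve dips to ≈ −13 mm at end systole.

2. **Template tracking with a position prior.** A square template (ROI)
   around the current position is matched inside a square search window (ROS)
   centered on the *predicted* position in the next frame, maximizing the
   normalized cross-correlation

   γ(u,v) = Σₓᵧ [S(x,y) − S̄ᵤᵥ][I(x−u, y−v) − Ī] /
   √( Σₓᵧ [S(x,y) − S̄ᵤᵥ]² · Σₓᵧ [I(x−u, y−v) − Ī]² ).

   The prediction comes from a per-landmark PCA model of AVPD curve shape,
   trained on amplitude-normalized curves interpolated to 30 timeframes; five
   principal components capture ≥ 99% of the training variance.

3. **Forward/backward merging and shape reconstruction.** The cycle is
   tracked forward from end diastole and backward through the wrap; the two
   displacement curves are merged with complementary linear weights (each run
   trusted most near its own start), then projected onto the five leading
   eigenvectors as a physiological smoothing.

4. **Clinical measures.** LVAVPD is the mean of the 6 left-sided curves;
   RVAVPD is (RV-lateral + RV-outflow + septal mean)/3. End systole is the
   curve minimum; peak velocities are chord slopes around the extrema of the
   forward-difference derivative of the 3-sample moving-averaged curve; atrial
   contraction is the late-diastolic step from the diastasis plateau back to
   baseline, as % of the end-systolic AVPD.

ROI/ROS side lengths per landmark are tuned by an exhaustive, 10-fold
cross-validated grid search minimizing the SD of the end-systolic difference
under percentile constraints on R, bias and curve 2-norm.

Because no patient data ship with the package, a phantom module renders
SSFP-like long-axis cines (1.5 × 1.5 mm pixels, 30 frames/cycle) with known
ground truth: persistent speckle texture translated rigidly along the apex
axis by parametric, physiologically shaped AVPD curves, with population
amplitude statistics for post-infarction patients, healthy controls and
athletes.

## Worked example

The whole workflow runs from the command line on synthetic data:

```sh
avpdtrack simulate --out study --seed 7 --noise-sd 0.05
avpdtrack train --out model.json --seed 1
avpdtrack track --image study/2ch.tiff --image study/3ch.tiff \
    --image study/4ch.tiff --landmarks study/landmarks.json \
    --model model.json --out curves.csv
avpdtrack measure --curves curves.csv --out summary.json
```

`train` prints the fitted prior per landmark, e.g.

```
4ch/septum: amplitude 12.2 mm, 5 components carry 99.66% of variance
4ch/rv_lateral: amplitude 22.7 mm, 5 components carry 99.81% of variance
```

(the mean training amplitude in mm, and how compact the PCA shape basis is),
and `measure` reports

```
LV AVPD at ES: -13.3 mm (frame 11); RV AVPD at ES: -19.4 mm (frame 11)
```

for this control-like phantom — a normal LV excursion of 13.3 mm reached at
frame 11 of 30 (≈ 37% of the cycle), with the larger RV excursion expected
from the tricuspid annulus. `summary.json` carries the full curves and the
derived measures (peak emptying −5.2 cm/s, peak filling +6.4 cm/s, atrial
contraction 25.7% of ES AVPD for this run). An `optimize` command fits
per-landmark ROI/ROS sizes and writes a params file `track` consumes.

The same pipeline is available as a library: `phantom.make_phantom_study`,
`prior.CurvePriorModel.train`, `tracking.track_landmark` and
`measures.assemble_result` compose in a few lines (see `tests/` for worked
fixtures), and the PCA prior is a scikit-learn-compatible transformer.

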