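# Methods

## Power-vector decomposition

All analysis happens in power-vector space (EQ, C0, C45), where
spherocylindrical powers form a vector space and differences between
devices or time points are componentwise. Radii-based measurements convert
through an index step `delta_n`: a meridian of radius R mm has power
`1000·delta_n/R` dpt, the equivalent power is the mean of the two
meridional powers, and the signed cylinder `1000·delta_n·(1/R_steep −
1/R_flat)` is projected at twice the flat-meridian axis. The factor 1000
(500 in the EQ term, which averages two meridians) is the mm→dpt scale and
is applied to the astigmatism components as well as to EQ — dimensional
consistency requires it, and it reproduces the schematic-eye reference
values (0.6228/0.0804 dpt front/back astigmatism for a 0.1 mm front
meridional difference at the fixed 7.77/6.4 ratio).

Conventions, fixed throughout:

* axes in [0, 180) degrees; the **flat** meridian's axis drives the double
  angle; the steep axis is derived, never stored;
* flat/steep are ordered **by radius** (R_flat ≥ R_steep) and by power
  (P_steep ≥ P_flat); mislabelled input is swapped (axis rotated 90°) with
  a warning rather than rejected. For the back surface (negative index
  step) this makes the cylinder negative at the front-flat axis, i.e.
  back-surface astigmatism opposes the front's, as anatomy dictates;
* astigmatism is signed steep-minus-flat, so with-the-rule astigmatism has
  C0 > 0;
* zero-cylinder vectors get polar axis 0° with an explicit
  `axis_undefined` flag;
* left-eye (OS) vectors are pooled with right eyes by flipping C45 exactly
  once ("mirroring", an involution).

Index steps: front +0.376 and back −0.040 (Liou–Brennan cornea 1.376,
aqueous 1.336), keratometric +0.332 (keratometer index 1.332). The
keratometric vector is therefore exactly the front vector scaled by
0.332/0.376.

## Cohort pipeline

The per-eye CSV uses the device-export vocabulary (IOLMR1a…, CASIAP1r_pre…)
with an overridable column map; unparseable cells become missing values,
never zeros, and a measurement group (4 cells) is only built when complete.
Exclusions: 'Failed'/'Warning' quality flags (case-insensitive; all other
strings pass — flags are opaque device markers), missing
keratometry/total-keratometry/back-surface/biometry or tomography,
mydriasis (pupil > 5.5 mm, strict, checked at **both** visits — the
conservative reading, since the rule's timing is not specified), pupil
change > 1.5 mm (strict), and one random eye per patient under a seed
dedicated to that choice so it is reproducible independently of the
model-fitting seed. Decomposition yields a wide panel of 3 devices
(biometer preop, tomographer pre/post) × 4 layers (front, back,
keratometric, total) × 3 components; the biometer's total keratometry and
the tomographer's real power both report under the `total` layer.

Summary tables report mean, SD (n−1), median and the empirical 2.5/97.5
percentiles (linear interpolation); the percentile pair is what the "95%
confidence interval" columns of such tables contain, not mean ± 1.96 SD.
Difference panels subtract paired per-eye vectors, so the mean difference
equals the difference of means exactly on a shared eye set.

## Confidence ellipses

Centroid = componentwise mean; sample covariance (n−1) eigendecomposed;
half-axes √(λ·q) with q the chi-square quantile at the level with 2 df
(−2 ln(1−level); 4.60517 at 90%). Chi-square (large-sample) scaling is the
default because the procedure being reproduced names only "eigenvalue
decomposition"; a `small_sample=True` flag switches to the Hotelling-style
factor 2(n−1)/(n−2)·F(level; 2, n−2) for sensitivity analysis. Orientation
is reported in [0, 180); fewer than 3 points or a collinear cloud raises a
degenerate-ellipse error; level 0 degenerates to the centroid point.
Empirical coverage for bivariate normal data at level 0.90 is verified to
lie in [0.88, 0.92] at n = 10⁵ (seeded).

## Predictors

**Split rule.** train = round(0.70·n); the remainder is split as evenly as
possible with the validation set taking the odd element — 62/13/13 at
n = 88, (7, 2, 1) at n = 10. Seeded permutation.

**Regression.** Ordinary least squares on [X, 1] with two outputs,
minimum-norm solution (a degenerate design warns and zeroes the collapsed
coefficients, so an all-zero predictor yields intercept = column means).
An optional iteratively-reweighted bisquare variant (`robust=True`,
Tukey c = 4.685 on the radial residual) is provided for outlier-heavy
cohorts. The stored log-likelihood is the bivariate Gaussian value with the
maximum-likelihood residual covariance, `−(n/2)(2 ln 2π + ln det Σ̂ + 2)`;
residual scales below ~1e−6 dpt are treated as a degenerate (perfect) fit.
OD↔OS model conversion is conjugation with diag(1, −1): both off-diagonal
matrix entries and the second intercept entry flip sign.

**Network.** 2–10–8–2 feedforward, tanh hidden layers, linear output,
inputs z-scored with training-set statistics (tanh + z-scoring is the
standard recipe for LM-trained shallow regression networks). Weights are
initialised N(0, 1/fan-in) under a seed, biases zero. Training is
Levenberg–Marquardt on the residual vector scaled so its squared norm is
the mean squared prediction error: each epoch computes the analytic
Jacobian (per-output backward pass, vectorised over eyes) and takes one
accepted damped Gauss–Newton step — damping λ₀ = 1e−3, ×10 on rejection,
÷10 on acceptance, abort of the epoch loop when no step is acceptable at
λ ≤ 1e12 — so the training objective is non-increasing by construction.
Per-epoch train/validation/test objectives are recorded; training stops
after 6 validation epochs without improvement (max 1000), and the returned
weights are those of the validation-optimal epoch.

## Synthetic cohort generator

The generator defines the conditions every statistical test runs under.
Truth is specified in power-vector space (the analysis is linear there) and
converted to meridional radii by inverting the decomposition; axis
distributions therefore emerge from the Gaussian (C0, C45) model rather
than being sampled directly. Per eye: a Gaussian front-surface vector
(right-eye orientation); a back surface via a front-to-back radius ratio
(mean 7.77/6.4, jittered) **plus** an extra astigmatism component —
without it the ratio model would give back astigmatism ≈ front/7.74,
far less than real corneas show, and the extra term is precisely the
phenomenon the prediction models exist to capture; a per-eye surgically
induced change; device readings = truth + device bias + noise, with
derived layers (keratometric, total) computed from the device's own
front/back readings, total power as the thin-lens front+back sum
(real devices also use corneal thickness for total keratometry; that
refinement is out of scope and documented as such). OS eyes are generated
in right-eye orientation and un-mirrored into raw axes at the end.

Default parameters are the emulated study's conditions: preoperative
marginal means/SDs from the published summary panels (biometer front
surface treated as unbiased; the tomographer's bias and the biometer's
back-surface bias carry the published mean gaps, reproducing the
front/back mean-power ratios ≈ −8.38 vs −7.87), and the surgically induced
change from the published paired post-minus-pre differences. Those two
published panels are mutually inconsistent for paired data (the marginal
mean gaps do not equal the paired difference means); the generator
prioritises the preoperative marginals and the paired change, so the
generated postoperative marginals deviate slightly from the published
postoperative column — no paired-data generator can satisfy both.
Measurement noise SDs (0.10/0.15/0.12 dpt front EQ/C0/C45, 0.03/0.04/0.04
back) were chosen once so that paired pre/post difference SDs land near
the published ones after adding the per-eye surgical variability; they are
approximations, overridable in the config. Between-device correlation is
induced solely by the shared truth plus independent noise — the emulated
study reports no cross-device correlations, so this structure is an
assumption. An optional linear teacher overrides the postoperative
real-power astigmatism with a known map A x + b + noise of the
preoperative biometer keratometric components, giving exact ground truth
for recovery tests.

`inject_quality_issues` corrupts a clean cohort with flags, missing
groups, mydriatic pupils and pupil changes at configured rates (default 5%
each), recording the affected eye ids so exclusion bookkeeping can be
checked exactly.

What passing tests on this generator do **not** show about real data:
instrument physics (alignment, tear film, fixation), non-Gaussian
astigmatism distributions, age/axial-length correlations with astigmatism,
repeated-measurement variability, and any true nonlinearity in the
keratometry-to-total-power relation (the teacher is linear, so the network
is only verified to *match* the regression, not to beat it).

## Problem sizes and numerical choices

Statistical tests use the sizes at which their asymptotic properties are
observable: parameter recovery and marginal calibration at n = 2000 eyes,
ellipse coverage at n = 10⁵ points, the network-vs-regression equivalence
at n = 1000 eyes (at the study-sized n = 88 the 13-eye test set makes that
ratio fluctuate far beyond 10% for any correct implementation), and
cohort-pipeline checks at 30–150 eyes. Round-trip identities hold to
1e−9 dpt; meridian perpendicularity is enforced to 1e−6 degrees; the
standardisation floor is 1e−8. All randomness (generation, corruption,
exclusion tie-breaks, splits, network initialisation) flows through
explicit seeds.

## Known limitations

* Total keratometry is modelled as a thin-lens sum; no vergence
  propagation or raytracing.
* The published regression coefficient sets are bundled for replay; their
  log-likelihood values depend on the original clinical data and are
  stored for reference, not recomputed.
* The published CASIA-based intercept is bundled exactly as printed
  (both components equal), which looks like a transcription artifact in
  the source; only the structure of the model is used.
* One prediction model per eye-side pair, via mirror symmetry; true
  left/right asymmetries are not modelled.
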