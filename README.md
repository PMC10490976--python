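# cornvec

Corneal power-vector analysis for cataract surgery with toric intraocular
lens (tIOL) implantation.

Planning a tIOL requires the astigmatism of the *pseudophakic* cornea, but
what is measured preoperatively is mostly front-surface keratometry, which
converts front radii to "keratometric power" through a fictitious index and
thereby assumes a fixed front-to-back surface ratio. Real corneal back
surfaces carry more against-the-rule astigmatism than that assumption
admits, and surgery itself changes the cornea. `cornvec` is a library for
quantifying and predicting these effects: it decomposes keratometric and
tomographic measurements into power vectors, summarises device and
pre/post-surgery differences, draws double-angle confidence ellipses, and
predicts postoperative total corneal power from preoperative keratometry.

## The model

Every spherocylindrical measurement is mapped to a power vector
(EQ, C0, C45): equivalent power, and the astigmatism projected onto the
0°/90° and 45°/135° meridians at twice the axis angle. For meridional radii
R1 (flat, axis A1) and R2 (steep) across an index step n2 − n1:

    EQ  = 500 (n2 − n1) (1/R2 + 1/R1)            [R in mm, EQ in dpt]
    Cyl = 1000 (n2 − n1) (1/R2 − 1/R1)
    C0  = Cyl · cos(2 A1),   C45 = Cyl · sin(2 A1)

with index steps +0.376 (front surface), −0.040 (back surface) from the
Liou–Brennan schematic eye, and +0.332 (keratometer index 1.332).
Measurements already in dioptres (tomographer "real power", refraction,
tIOL thin-lens split IOLP ∓ ½·IOLT) use EQ = ½(P1 + P2), Cyl = P2 − P1.
Left-eye (OS) C45 components are sign-flipped so both eyes pool in one
right-eye orientation. In this space vectors add and subtract
componentwise, so device differences and surgically induced astigmatism are
plain arithmetic, cohorts are summarised by mean/SD/median/2.5–97.5
percentiles, and (C0, C45) clouds get 90% confidence ellipses from the
eigendecomposition of the sample covariance (half-axes √(λ·q),
q = −2 ln 0.1).

Two predictors map preoperative keratometric astigmatism (C0, C45) to
postoperative real-power astigmatism: a multivariate linear regression
y = A x + b (with the left-eye model obtained by negating the off-diagonal
entries of A and the second entry of b), and a shallow 2–10–8–2 tanh
network trained by Levenberg–Marquardt with validation-based early stopping
on a 70/15/15 split, both minimising the mean squared prediction error
½((ΔC0)² + (ΔC45)²). A synthetic cohort generator emulates the per-eye
clinical CSV (two devices, two time points, front/back surfaces, biometry,
quality flags) so the whole pipeline is testable without patient data.

## Worked example

```python
import cornvec as cv

front = cv.radii_to_power_vector(
    cv.SurfaceMeasurement(R_flat=7.82, A_flat=0, R_steep=7.72, A_steep=90),
    cv.FRONT_SURFACE)
print(front)          # PowerVector(EQ=48.3933, C0=0.6228, C45=0.0)
```

A 0.1 mm meridional radius difference on the front surface is 0.6228 dpt of
with-the-rule astigmatism; the fixed-ratio schematic back surface returns
only 0.0804 dpt against the rule (ratio −7.7426), which is why keratometry
alone mis-states total corneal astigmatism. Running
`python examples/04_predict_postop_power.py` fits both predictors on a
synthetic 88-eye cohort and replays the bundled published right-eye
regression:

```
split: 62 train / 13 val / 13 test
network: best epoch 7 of 13 run
  regression test mean squared prediction error: 0.0847 dpt^2
  network    test mean squared prediction error: 0.1451 dpt^2
published right-eye model, worked input (1.5, -0.3) dpt:
  predicted postoperative total astigmatism: (+1.2044, -0.2342) dpt
```

The published model's intercept (−0.1823, −0.0229) dpt is the systematic
against-the-rule shift of postoperative total power that front-surface
keratometry cannot see. The other scripts in `examples/` walk through the
cohort pipeline (generation, exclusion rules, summary and difference
tables) and the double-angle ellipse plots.

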