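# Methods

## The synthetic LV population

The generator stands in for a multi-center case–control CMR study whose
images and fitted surface models cannot be redistributed.  It produces
corresponded two-surface LV point sets at ED and ES together with baseline
covariates and a binary disease label, with the statistical structure the
downstream analysis assumes: population shape variation dominated by size,
then sphericity/thickening/orientation, and patient-vs-control differences
in EDV, ESV, mass, sphericity, contraction pattern and covariates.

### Shape family

The endocardial cavity is a half prolate spheroid truncated at the basal
plane: equatorial radius `a`, base-to-apex length `c`, sampled on a fixed
37 (circumferential) × 37 (longitudinal) grid per surface (2738 points per
frame; the apex row degenerates to the pole, which preserves
correspondence).  The epicardium is the same family offset outward by the
wall thickness `t` in both semi-axes.  Six latent factors control each
heart:

| latent | meaning | control mean ± SD | patient mean ± SD |
| --- | --- | --- | --- |
| `base_endo_radius` (mm) | volume-equivalent cavity size r₀ | 25.62 ± 2.12 | 31.20 ± 2.80 |
| `sphericity` (–) | short/long axis ratio a/c | 0.285 ± 0.014 | 0.330 ± 0.018 |
| `wall_thickness` (mm) | reference-shape wall thickness | 8.67 ± 1.76 | 9.09 ± 1.39 |
| `mitral_tilt` (deg) | basal-plane tilt (shear) | 5 ± 13 | 5 ± 13 |
| `radial_shortening` (–) | ED→ES radial contraction | 0.337 ± 0.063 | 0.175 ± 0.079 |
| `longitudinal_shortening` (–) | ED→ES long-axis contraction | 0.17 ± 0.03 | 0.145 ± 0.03 |

ES is derived from ED by the two shortening fractions with wall volume
conserved exactly (the ES thickness solves a monotone cubic), so myocardial
mass is constant over the cycle, as in real fitted models.  The basal tilt
is a shear `dz = tan(tilt)·x·(φ/φ_max)²`, which is volume-preserving and —
unlike a rigid rotation — survives Procrustes alignment as a genuine shape
factor.

### Orthogonalized realization

Latent draws are realized so that the named factors drive near-orthogonal
shape directions, as they do in real LV populations where sphericalization
is a shape change, not a volume change:

- the realized radius is `a = r₀·(s/s̄)^{1/3}` with `c = a/s`, so the
  sphericity draw changes neither cavity volume (EDV = ⅔π r₀³/s̄ exactly)
  nor, to first order, anything the size factor encodes;
- the thickness draw fixes the **wall volume** at the group-reference
  sphericity; the realized thickness solves the wall-volume cubic for the
  case's actual `a, c`.  Sphericity therefore changes neither EDV nor mass.

Without this, size and sphericity load on nearly parallel directions (the
long-axis block dominates both) and the first PCA mode is an
uninterpretable blend.

### Regional variation and noise

Real anatomical eigen-spectra decay gradually (tens of modes to 90%
variance), not as a rank-6 factor model.  Each heart therefore carries a
smooth regional deviation: a random combination of 32 surface harmonics
`sin(πφ̂/2)·cos(ℓπφ̂)·{cos,sin}(mθ)` (ℓ = 0..3, m = 1..4) displacing both
surfaces along their normals, with amplitude 3.0 mm decaying as
(1+ℓ+m)^{-1}.  The same coefficients act on ED and ES — it is per-heart
anatomy, not frame noise — and every harmonic has m ≥ 1, so it integrates
to zero around each circumference and perturbs neither volumes nor mass to
first order.  On top of this, isotropic per-point measurement noise
(SD 0.7 mm) is added independently per frame.

### Calibration

The latent means are calibrated (once, by Monte-Carlo over the latent
distribution with a closed-form volume model and the measured
grid-discretization factor) so the realized cohort reproduces the reference
demographic table: control EDV/ESV/mass 125.45/47.48/126.24, patient
196.32/118.60/168.55 (ml/ml/g), within sampling error at the default sizes
n = 1991/300.  The SDs follow from the printed index SDs through the volume
model; the radial-shortening SD and its −0.6 coupling to size are set so
the EDV–ESV Pearson correlation is ≈ 0.91, the collinearity regime the
reference mass/volume model was fitted in.  Sphericity SD, tilt SD and the
noise level are chosen so the first pooled ED mode carries ~50% of total
variance and tracks the size factor at |r| > 0.9; the patient sphericity
mean (+16%) and the radially-dominant contraction deficit (radial
shortening halves while longitudinal shortening falls only ~15%, at a fixed
ESV/EDV ratio) encode the sphericalization and systolic-shape abnormality
of post-infarction remodeling.  Height correlates with the size latent at
r = 0.3, giving the baseline covariates genuine shape signal.

### What the generator does not emulate

No regional (infarct-locality) wall-motion abnormality, papillary muscles,
trabeculation or outflow-tract geometry; no spatially correlated
segmentation error (measurement noise is iid per point); covariates other
than height are independent of shape; both frames share one rigid pose.
Passing tests therefore show the pipeline machinery is correct and that the
published qualitative ranking emerges under these stylized conditions — not
that it would re-emerge at the printed effect sizes on real data.

## Pipeline stages

**Clinical indices.** The endocardial lattice is triangulated, closed at
the apex and basal rings by centroid fans, and integrated by the divergence
theorem; mass is (epi − endo volume) × 1.05 g/ml (standard myocardial
density; the source study does not state one).  Volumes are integrated to
the (tilted) basal plane.  Note the inscribed-polyhedron bias: with 37
circumferential samples the chord loss is 1 − (n/2π)sin(2π/n) ≈ 0.48%, so
default-grid volumes sit ~0.5% below the continuum closed forms;
the deficit vanishes as O(h²) under grid refinement and cancels in all
group comparisons.

**Alignment.** Generalized Procrustes per frame: iterate {align all shapes
to the running mean by Kabsch SVD with determinant correction (no
reflections, no scaling); recompute the mean} from the first shape as
reference until the mean moves < 1e-8 mm RMS (pipeline default 1e-6 mm;
convergence takes 3–5 iterations at cohort scale) or 100 iterations, then
rotate mean and cohort into a deterministic principal-axis gauge (long axis
on z, signs fixed by coordinate skewness).

**Protocol correction.** The biased protocol is emulated by displacing the
control group's surfaces along a template inward-normal field (endo 1.0 mm,
epi 0.5 mm by default).  From 40 dual-protocol pairs (acquisition noise
SD 0.5 mm, applied to the biased scan) aligned to the atlas mean, the map
`x → g·(x − m) + m + b` is estimated by least squares: per-axis gain `g` on
coordinates centered at the training source mean `m`, per-point offset `b`
equal to the mean paired displacement.  Centering decouples the offset from
the gain, so source noise cannot leak attenuation bias into the offset; the
offset standard error is noise_sd/√n_pairs per coordinate.  An optional
ridge shrinks the gain toward 1 (needed only below 2 pairs).  Correction is
applied after alignment (configurable by omitting the bias stage).

**Atlas.** PCA of raw-mm shape vectors on the sample covariance (divisor
n−1); no per-variable standardization, since coordinates are commensurate
and size must stay in the model.  For n < d the eigendecomposition goes
through the n×n Gram matrix (exact dual route; the 2291 × 16428 ED&ES atlas
takes seconds).  Modes are sign-fixed (largest-|entry| positive); the
retention rule is the smallest m with cumulative variance ≥ 0.90, evaluated
with a 1e-12 slack so an exactly attained threshold is not lost to
rounding.  Retained counts are data-dependent (13 ED / 12 ES / 14 ED&ES at
seed 1).

**Models.** Logistic regression by damped Newton–Raphson (step halving on
likelihood decrease) to gradient ∞-norm < 1e-10, max 100 iterations;
per-iteration log-likelihoods are recorded and are non-decreasing.
Standard errors from the inverse observed information; p-values two-sided
normal; CIs exp(β ± 1.96·SE) with 1.96 exactly (matching the reference
tables' printed rounding); standardized coefficients β·s_x·√3/π (the
logistic-latent-scale convention consistent with the reference tables'
standardized column); report formatting shows p < 1e-4 as "<.0001" and
flags significance at 0.05/0.01.  Divergence (‖β‖ > 1e3) is reported as a
distinct separation condition; rank deficiency is reported with the
offending columns (pivoted QR).  BIC uses n = cases entering the fit; the
reference study's own BIC column implies an n (≈ 2209) that matches neither
its stated cohort sizes — the bundled-table checks therefore assert a
*common* ln(n) across models rather than a particular n.  AUC is the
midrank Mann–Whitney statistic; the ROC polygon is evaluated at every
distinct threshold.

**Demographics.** Continuous variables: two-sided Wilcoxon rank-sum
(midranks, tie-corrected variance, continuity-corrected normal
approximation).  The reference table's footnote says "signed-rank", but the
two cohorts are unpaired and of unequal size, for which the signed-rank
test is undefined; the unpaired rank-sum test is the applicable rank test.
Categorical: Pearson χ² (1 df, no continuity correction).

## Reproducibility and problem sizes

Every stochastic element derives from one run seed through named substreams
(cohort, protocol pairs), so runs are bit-identical and stages re-runnable
in isolation.  The default analysis scale is the full study size
(1991 + 300 cases, 2738 points per frame); a complete run takes roughly
half a minute on one core, and the test suite's end-to-end checks use five
such runs plus a held-out null-cohort evaluation.  Unit tests run on
reduced grids (11–16 points per direction) and smaller cohorts; small
test cohorts shrink the group mean differences, because at the default
effect sizes a few hundred cases are linearly separable and the
maximum-likelihood logistic fit rightly refuses to converge.

A note on the null control: the in-sample AUC of a maximum-likelihood fit
with k predictors is upward-biased under the null (≈ 0.54 at k = 7 to
≈ 0.59 at k ≈ 20 at this n), which is overfitting, not signal.  Chance-level
behavior is therefore asserted on held-out scores: a second null cohort is
aligned to the trained atlas, projected, and scored with the trained
coefficients; all five models then sit within 3 SE of AUC 0.5.

## Known limitations

- The shape family is globally smooth; discrimination rests on global
  geometry and contraction balance, so absolute AUC/deviance values are not
  comparable to the reference study's — only the model ranking and variance
  structure are.
- The protocol-bias model is a fixed template displacement plus noise; the
  real bias is regionally variable per subject and the cited
  maximum-likelihood correction is deliberately replaced by the linear map
  above.
- Volumes carry the ~0.5% inscribed-polyhedron deficit at the default grid
  (documented above); all comparisons are internally consistent since every
  case is measured identically.
- The basal closure (centroid fan) and integration-to-basal-plane
  convention are one of several defensible choices for the outflow region;
  comparative statistics are insensitive to it.
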