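# lvatlas — statistical shape atlas of the left ventricle and quantification of post-infarction remodeling

After myocardial infarction the left ventricle (LV) remodels: it dilates,
becomes more spherical, and its wall mass and contraction pattern change.
Clinically this is usually summarized by three numbers — end-diastolic volume
(EDV), end-systolic volume (ESV) and LV mass — which discard most of the
available shape information.  `lvatlas` implements an atlas-based alternative
for researchers working with corresponded cardiac surface models: build a
statistical shape atlas of the LV across a case–control population, express
every heart by its principal-component mode scores, and quantify how much
better those scores characterize disease than the traditional indices.

The framework is exercised end-to-end on a built-in synthetic LV cohort
generator (the original multi-center MR cohorts are not redistributable), so
every pipeline stage is testable against ground truth.

## The model

Each LV is a corresponded point sample of its endocardial and epicardial
surfaces at end-diastole (ED) and end-systole (ES) — 2 × 37 × 37 = 2738
points per frame.  The analysis pipeline is:

1. **Indices.** Cavity volume by the divergence theorem on the triangulated,
   basally-closed endocardial surface; mass as (epi − endo volume) × 1.05 g/ml;
   EF = (EDV − ESV)/EDV.
2. **Alignment.** Generalized Procrustes analysis with rotation and
   translation only (Kabsch SVD with reflection exclusion).  Scale is
   deliberately **retained**: heart size is itself a marker of disease.
3. **Protocol correction.** MR protocols (GRE vs SSFP) bias surface
   placement.  From paired dual-protocol scans a linear map (per-point offset
   + per-axis gain) is learned by least squares and applied to the biased
   cohort.
4. **Atlas.** PCA of the shape vectors (concatenated coordinates, mm) at ED,
   ES and their ED&ES concatenation, on the sample covariance (divisor n−1);
   modes φ_k with eigenvalues λ_k; enough modes retained to explain 90% of
   total variance.  A case's predictors are its mode scores
   x_k = φ_kᵀ(s − s̄).
5. **Disease association.** Maximum-likelihood logistic regression
   P(patient) = 1/(1 + e^{−(β₀ + Σβ_i x_i)}), with Wald standard errors,
   odds ratios exp(β) and 95% CIs.  Five models are compared — baseline
   covariates (age, sex, height, weight, SBP, DBP); baseline + EDV/ESV/mass
   ("MASSVOL"); baseline + ED, ES, or ED&ES mode scores — by deviance (−2L),
   AIC (deviance + 2k), BIC (deviance + k ln n) and the ROC AUC
   (Mann–Whitney statistic with midranks).

## Worked example

```python
from lvatlas.pipeline import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1))   # 1991 controls + 300 patients
print(result.comparison.table.round(4))
```

prints (about half a minute on one core):

```
            deviance        aic        bic     auc   k     n
model
Baseline   1474.6341  1488.6341  1528.7913  0.7891   7  2291
MASSVOL     568.7202   588.7202   646.0876  0.9673  10  2291
ED PCA      196.9372   236.9372   351.6721  0.9968  20  2291
ES PCA      333.3091   371.3091   480.3072  0.9901  19  2291
ED&ES PCA   112.2960   154.2960   274.7676  0.9989  21  2291
```

Reading: every shape-mode model separates patients from controls better than
the traditional mass/volume model (higher AUC, lower deviance/AIC/BIC), and
the combined ED&ES model is best — remodeling is a joint shape-and-function
signature, not a volume.  On this run the first ED mode carries 49.6% of the
pooled shape variance and correlates with the generator's size factor at
|r| = 0.93; 13 ED / 12 ES / 14 ED&ES modes are retained at the 90% rule.
`result.mode_interpretation["ED"]` tabulates each mode against the latent
factors (size, sphericity, wall thickness, mitral orientation, contraction).

The same pipeline is available from the shell
(`lvatlas run --seed 1 --out results/run1`), and the numbered scripts under
`analysis/` walk through the stages one at a time:

| script | what it does |
| --- | --- |
| `analysis/01_generate_cohort.py` | synthetic cohort + demographics table with rank-sum/χ² tests |
| `analysis/02_clinical_indices.py` | EDV/ESV/mass/EF per case; calibration vs configured targets |
| `analysis/03_align_and_correct.py` | Procrustes alignment and protocol-bias correction recovery |
| `analysis/04_build_atlases.py` | PCA atlases, scree tables, mode interpretation, mode extremes |
| `analysis/05_fit_models.py` | the five-model comparison, coefficient tables, ROC curves |
| `analysis/06_reference_table_checks.py` | arithmetic checks of the bundled published tables |

## Layout

```
src/lvatlas/     geometry, synthetic, alignment, correction, atlas,
                 models, cohortstats, pipeline, io, reference, cli
analysis/        numbered narrative drivers (see table above)
scripts/         acceptance.py
tests/           pytest suite (unit, property and end-to-end checks)
docs/methods.md  model, calibration, numerical choices, limitations
```
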