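"""Published reference values bundled for arithmetic self-consistency checks.

These tables reproduce the printed model-comparison and coefficient tables of
a large published atlas study of post-infarction LV remodeling (300 patients
with myocardial infarction vs 1991 asymptomatic volunteers).  The underlying
images and shape models are not redistributable, so the printed summaries
serve two purposes here: (a) fixtures for exact internal-relation checks
(AIC = deviance + 2k, OR = exp(beta), CI = exp(beta +/- 1.96 se), a common
ln(n) behind every BIC), and (b) the calibration targets of the synthetic
cohort generator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_COEFFICIENT_FILES = {
    "Baseline": "coefficients_baseline.tsv",
    "ES PCA": "coefficients_es_pca.tsv",
    "MASSVOL": "coefficients_massvol.tsv",
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("lvatlas.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def model_comparison() -> pd.DataFrame:
    """Reference goodness-of-fit table: deviance, AIC, BIC and AUC of the five
    published logistic models, with the parameter count k of each (intercept +
    6 baseline covariates + 0 / 3 / 13 / 14 / 20 model-specific predictors)."""
    return _read("model_comparison.tsv").set_index("model")


def coefficient_table(model: str) -> pd.DataFrame:
    """Reference coefficient table (coefficient, SE, standardized coefficient,
    odds ratio and 95% CI) for 'Baseline', 'ES PCA' or 'MASSVOL'."""
    if model not in _COEFFICIENT_FILES:
        raise KeyError(f"no reference coefficients for {model!r}; "
                       f"available: {sorted(_COEFFICIENT_FILES)}")
    return _read(_COEFFICIENT_FILES[model]).set_index("parameter")
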