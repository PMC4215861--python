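"""Two-group demographic comparison table.

Continuous variables are compared with the two-sided Wilcoxon rank-sum
(Mann-Whitney) test using midranks and the continuity-corrected normal
approximation; categorical variables with Pearson's chi-square test (1 df).
The cohorts are unpaired, so the unpaired rank-sum test is the applicable
rank test.  Significance flags follow the usual convention: one dagger for
p < 0.05, two for p < 0.01.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

FLAG_05 = "†"   # †
FLAG_01 = "‡"   # ‡


def rank_test(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value (midranks, tie-corrected variance,
    continuity-corrected normal approximation)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             use_continuity=True, method="asymptotic")
    return float(res.pvalue)


def chisq_test(table: np.ndarray) -> float:
    """Pearson chi-square p-value (two-sided, 1 df for a 2x2 table, no
    continuity correction)."""
    t = np.asarray(table, dtype=float)
    if t.min() < 0:
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square test undefined")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if (expected <= 0).any():
        raise ValueError("all expected counts must be positive")
    _, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(p)


def _flag(p: float) -> str:
    if p < 0.01:
        return FLAG_01
    if p < 0.05:
        return FLAG_05
    return ""


def demographics_table(covariates: pd.DataFrame, labels: np.ndarray,
                       indices: pd.DataFrame | None = None) -> pd.DataFrame:
    """Group comparison table (patients vs controls): mean +/- SD and rank-sum
    p for continuous variables, counts and chi-square p for sex; clinical
    indices (EDV/ESV/mass) are appended when supplied."""
    labels = np.asarray(labels, dtype=int)
    is_pat = labels == 1
    rows = []

    female = (covariates["sex"] == 0).to_numpy()
    counts = np.array([
        [int((female & is_pat).sum()), int((~female & is_pat).sum())],
        [int((female & ~is_pat).sum()), int((~female & ~is_pat).sum())],
    ])
    p_sex = chisq_test(counts)
    rows.append({
        "variable": "Sex (Female/Male)", "units": "",
        "patient": f"{counts[0, 0]}/{counts[0, 1]}",
        "control": f"{counts[1, 0]}/{counts[1, 1]}",
        "test": "chi-square", "p": p_sex, "flag": _flag(p_sex),
    })

    continuous = [("age", "years"), ("height", "cm"), ("weight", "kg"),
                  ("sbp", "mmHg"), ("dbp", "mmHg")]
    frames = [(covariates, continuous)]
    if indices is not None:
        frames.append((indices.reset_index(drop=True),
                       [("edv_ml", "ml"), ("esv_ml", "ml"), ("mass_g", "g")]))
    for frame, variables in frames:
        for name, units in variables:
            vals = frame[name].to_numpy(dtype=float)
            p = rank_test(vals[is_pat], vals[~is_pat])
            rows.append({
                "variable": name, "units": units,
                "patient": f"{vals[is_pat].mean():.2f}±{vals[is_pat].std(ddof=1):.2f}",
                "control": f"{vals[~is_pat].mean():.2f}±{vals[~is_pat].std(ddof=1):.2f}",
                "test": "rank-sum", "p": p, "flag": _flag(p),
            })
    return pd.DataFrame(rows)
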