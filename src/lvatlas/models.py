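"""Disease-association models: maximum-likelihood logistic regression with
Wald inference, and deviance / AIC / BIC / AUC goodness-of-fit comparison.

The probability that a case is a patient is modeled as
``P = 1 / (1 + exp(-(b0 + sum_i b_i x_i)))`` where the predictors are
baseline covariates plus either PCA mode scores or traditional mass/volume
indices.  Coefficients are found by Newton-Raphson (IRLS); standard errors
come from the inverse observed information; models are compared by
deviance = -2L, AIC = deviance + 2k, BIC = deviance + k ln(n), and by the
area under the ROC curve computed from the fitted probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, rankdata

INTERCEPT = "Intercept"
#: Normal quantile used for the 95% Wald confidence intervals.
Z_95 = 1.96
#: Scale factor mapping a logistic-regression coefficient to a standardized
#: coefficient: beta * sd(x) * sqrt(3)/pi (the logistic distribution has
#: standard deviation pi/sqrt(3), so this expresses the effect of one
#: predictor SD on the latent scale in logistic-SD units).
STD_COEF_SCALE = math.sqrt(3.0) / math.pi


class SeparationError(RuntimeError):
    """The likelihood is unbounded: the classes are (quasi-)separable and the
    coefficient norm diverges."""


class RankDeficientError(ValueError):
    """The design matrix is rank deficient (collinear columns)."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"design matrix is rank deficient; suspect columns: {columns}")


@dataclass
class LogisticFit:
    """Fitted logistic model with Wald inference and information criteria."""

    summary: pd.DataFrame          # per-parameter table (see fit_logistic)
    loglik: float
    n: int
    k: int                         # number of estimated parameters
    fitted_probabilities: np.ndarray
    n_iter: int
    converged: bool
    loglik_path: list[float] = field(default_factory=list)

    @property
    def params(self) -> pd.Series:
        return self.summary["coefficient"]

    @property
    def deviance(self) -> float:
        return -2.0 * self.loglik

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.k

    @property
    def bic(self) -> float:
        return self.deviance + self.k * math.log(self.n)


def _check_design(x: np.ndarray, names: list[str]) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError("design matrix contains non-finite values")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # pivoted QR flags the dependent columns
        from scipy.linalg import qr

        _, r, piv = qr(x, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        bad = piv[diag <= diag[0] * 1e-10] if diag[0] > 0 else piv
        raise RankDeficientError([names[i] for i in np.atleast_1d(bad)])


def fit_logistic(predictors: pd.DataFrame, y: np.ndarray,
                 add_intercept: bool = True, tol: float = 1e-10,
                 max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton-Raphson.

    Iterates to a gradient infinity-norm below ``tol``.  The summary table
    carries, per parameter: coefficient, standard error, Wald z, two-sided
    normal p-value, standardized coefficient (beta * sd_x * sqrt(3)/pi; not
    defined for the intercept), odds ratio exp(beta) and its 95% Wald CI.
    """
    x_df = pd.DataFrame(predictors).astype(float)
    y = np.asarray(y, dtype=float)
    if len(x_df) != len(y):
        raise ValueError("predictors and outcome must have the same length")
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class")
    if x_df.isna().any().any():
        raise ValueError("predictors contain missing values")
    if add_intercept:
        x_df = pd.concat(
            [pd.Series(1.0, index=x_df.index, name=INTERCEPT), x_df], axis=1)
    names = list(x_df.columns)
    x = x_df.to_numpy()
    n, k = x.shape
    _check_design(x, names)

    beta = np.zeros(k)
    loglik_path: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = x @ beta
        # numerically safe log-likelihood: sum y*eta - log(1+exp(eta))
        ll = float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))
        loglik_path.append(ll)
        p = expit(eta)
        grad = x.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        if np.linalg.norm(beta) > 1e3:
            raise SeparationError(
                "coefficient norm exceeds 1e3: classes appear separable and "
                "maximum-likelihood estimates do not exist"
            )
        w = p * (1.0 - p)
        info = x.T @ (x * w[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "observed information is singular during Newton iteration; "
                "classes appear separable"
            ) from exc
        # damped Newton: halve the step until the likelihood does not decrease
        new_beta = beta + step
        for _ in range(30):
            eta_new = x @ new_beta
            ll_new = float(np.sum(y * eta_new) - np.sum(np.logaddexp(0.0, eta_new)))
            if ll_new >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2.0
        beta = new_beta
    if np.linalg.norm(beta) > 1e3:
        raise SeparationError(
            "coefficient norm exceeds 1e3: classes appear separable and "
            "maximum-likelihood estimates do not exist"
        )

    eta = x @ beta
    p = expit(eta)
    ll = float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))
    if not loglik_path or ll > loglik_path[-1]:
        loglik_path.append(ll)
    w = p * (1.0 - p)
    cov = np.linalg.inv(x.T @ (x * w[:, None]))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * norm.sf(np.abs(z))
    sd_x = x_df.std(axis=0, ddof=1).to_numpy()
    std_coef = beta * sd_x * STD_COEF_SCALE
    if add_intercept:
        std_coef[0] = np.nan
    summary = pd.DataFrame({
        "coefficient": beta,
        "se": se,
        "z": z,
        "p": pvals,
        "std_coef": std_coef,
        "odds_ratio": np.exp(beta),
        "ci_low": np.exp(beta - Z_95 * se),
        "ci_high": np.exp(beta + Z_95 * se),
    }, index=pd.Index(names, name="parameter"))
    return LogisticFit(summary=summary, loglik=ll, n=n, k=k,
                       fitted_probabilities=p, n_iter=n_iter,
                       converged=converged, loglik_path=loglik_path)


def goodness_of_fit(fit: LogisticFit) -> tuple[float, float, float]:
    """(deviance, AIC, BIC); lower is better in all three."""
    return fit.deviance, fit.aic, fit.bic


def roc_auc(scores: np.ndarray, y: np.ndarray) -> tuple[float, pd.DataFrame]:
    """AUC by the Mann-Whitney rank statistic (midranks for ties) and the ROC
    polygon evaluated at every distinct threshold.

    The AUC is the probability that a random patient scores above a random
    control, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    if scores.shape != y.shape:
        raise ValueError("scores and outcome must have the same length")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1)

    order = np.argsort(-scores, kind="mergesort")
    sorted_scores = scores[order]
    tp = np.cumsum(y[order] == 1)
    fp = np.cumsum(y[order] == 0)
    distinct = np.flatnonzero(np.diff(sorted_scores)) if len(sorted_scores) > 1 else []
    idx = np.append(distinct, len(sorted_scores) - 1)
    curve = pd.DataFrame({
        "threshold": np.concatenate([[np.inf], sorted_scores[idx]]),
        "fpr": np.concatenate([[0.0], fp[idx] / n0]),
        "tpr": np.concatenate([[0.0], tp[idx] / n1]),
    })
    return float(auc), curve


#: Canonical model names in presentation order.
MODEL_ORDER = ("Baseline", "MASSVOL", "ED PCA", "ES PCA", "ED&ES PCA")


@dataclass
class ModelComparison:
    """Per-model goodness-of-fit table plus the underlying fits, coefficient
    tables and ROC curves."""

    table: pd.DataFrame                       # index model, columns dev/aic/bic/auc
    fits: dict[str, LogisticFit]
    roc_curves: dict[str, pd.DataFrame]

    def coefficient_table(self, model: str) -> pd.DataFrame:
        return self.fits[model].summary


def compare_models(covariates: pd.DataFrame, y: np.ndarray,
                   mode_scores: dict[str, pd.DataFrame] | None = None,
                   indices: pd.DataFrame | None = None,
                   models: tuple[str, ...] = MODEL_ORDER) -> ModelComparison:
    """Fit the requested disease-association models and tabulate their fit.

    Models: ``Baseline`` (covariates only), ``MASSVOL`` (baseline + EDV, ESV,
    mass), ``ED PCA`` / ``ES PCA`` / ``ED&ES PCA`` (baseline + the retained
    mode scores of the corresponding atlas, supplied via ``mode_scores`` with
    keys "ED", "ES", "ED&ES").
    """
    covariates = covariates.reset_index(drop=True)
    designs: dict[str, pd.DataFrame] = {}
    for model in models:
        if model == "Baseline":
            designs[model] = covariates
        elif model == "MASSVOL":
            if indices is None:
                raise ValueError("MASSVOL model requires the clinical indices table")
            extra = indices.reset_index(drop=True)[["edv_ml", "esv_ml", "mass_g"]]
            extra.columns = ["EDV", "ESV", "MASS"]
            designs[model] = pd.concat([covariates, extra], axis=1)
        elif model.endswith(" PCA"):
            key = model[:-4]
            if mode_scores is None or key not in mode_scores:
                raise ValueError(f"model {model!r} requires mode scores for {key!r}")
            designs[model] = pd.concat(
                [covariates, mode_scores[key].reset_index(drop=True)], axis=1)
        else:
            raise ValueError(f"unknown model {model!r}")

    fits, rows, curves = {}, [], {}
    for model, design in designs.items():
        fit = fit_logistic(design, y)
        auc, curve = roc_auc(fit.fitted_probabilities, y)
        fits[model] = fit
        curves[model] = curve
        rows.append({"model": model, "deviance": fit.deviance, "aic": fit.aic,
                     "bic": fit.bic, "auc": auc, "k": fit.k, "n": fit.n})
    table = pd.DataFrame(rows).set_index("model")
    return ModelComparison(table=table, fits=fits, roc_curves=curves)
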