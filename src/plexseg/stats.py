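"""Cohort-level statistics: Gaussian GLMs with McFadden pseudo-R2, the
lifespan volume-vs-age model, paired Wilcoxon comparisons and
Benjamini-Hochberg FDR correction.

The lifespan model regresses per-subject structure volume on age with sex
and total intracranial volume as covariates (Gaussian family, identity
link).  The age effect is summarised as percent volume change per decade of
life relative to the cohort mean volume: 100 * (10 * beta_age) / mean(v).
McFadden's R2 = 1 - ll_model / ll_null is computed from the Gaussian
log-likelihoods of the fitted and intercept-only models.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class DegenerateDataError(ValueError):
    pass


@dataclasses.dataclass
class RegressionResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    mcfadden_r2: float
    n: int
    formula: str
    loglik: float
    loglik_null: float


def glm_gaussian(response, design: pd.DataFrame,
                 formula: str = "") -> RegressionResult:
    """Gaussian-identity GLM with per-coefficient Wald p-values.

    An intercept column is added; the intercept-only model's log-likelihood
    is retained for McFadden's pseudo-R2.
    """
    y = np.asarray(response, dtype=float)
    X = pd.DataFrame(design).astype(float)
    if np.isnan(y).any() or X.isna().any().any():
        raise ValueError("missing values are not supported")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.GLM(y, Xc, family=sm.families.Gaussian()).fit()
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Gaussian()).fit()
    return RegressionResult(
        params=fit.params, bse=fit.bse, pvalues=fit.pvalues,
        mcfadden_r2=mcfadden_r2(fit.llf, null.llf),
        n=len(y), formula=formula or f"y ~ {' + '.join(X.columns)}",
        loglik=float(fit.llf), loglik_null=float(null.llf))


def mcfadden_r2(loglik_model: float, loglik_null: float) -> float:
    """1 - ll_model / ll_null; warns when the fitted model is worse than null."""
    if loglik_null == 0:
        raise ZeroDivisionError("null log-likelihood is zero; McFadden R2 undefined")
    if loglik_model < loglik_null:
        warnings.warn("model log-likelihood below null; check the fit",
                      RuntimeWarning, stacklevel=2)
    return 1.0 - loglik_model / loglik_null


@dataclasses.dataclass
class LifespanResult:
    regression: RegressionResult
    percent_per_decade: float
    sequence: str


def lifespan_model(records: pd.DataFrame, sequence: str = "t1like",
                   volume_column: Optional[str] = None) -> LifespanResult:
    """Volume ~ age + sex + TIV on a cohort covariate table.

    ``records`` needs columns ``age``, ``sex`` (M/F), ``tiv_cm3`` and the
    volume column (default ``cp_volume_cm3_<sequence>``).  Single-sex
    cohorts drop the sex covariate with a warning.
    """
    col = volume_column or f"cp_volume_cm3_{sequence}"
    if len(records) < 20:
        raise ValueError("need at least 20 records for the lifespan model")
    v = records[col].to_numpy(dtype=float)
    design = pd.DataFrame({"age": records["age"].to_numpy(dtype=float)})
    sexes = set(records["sex"])
    if len(sexes) > 1:
        design["sex_male"] = (records["sex"] == "M").astype(float).to_numpy()
    else:
        warnings.warn("single-sex cohort; dropping the sex covariate",
                      RuntimeWarning, stacklevel=2)
    design["tiv_cm3"] = records["tiv_cm3"].to_numpy(dtype=float)
    reg = glm_gaussian(v, design, formula=f"{col} ~ {' + '.join(design.columns)}")
    pct = 100.0 * (10.0 * float(reg.params["age"])) / float(v.mean())
    return LifespanResult(regression=reg, percent_per_decade=pct, sequence=sequence)


def wilcoxon_paired(x, y, zero_method: str = "wilcox") -> float:
    """Two-tailed Wilcoxon signed-rank p-value on paired samples.

    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution is used for n <= 25 without ties, otherwise the normal
    approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    nz = d[d != 0]
    if len(nz) == 0:
        raise DegenerateDataError("all paired differences are zero")
    ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not ties) else "approx"
    res = sps.wilcoxon(x, y, zero_method=zero_method,
                       alternative="two-sided", method=method)
    return float(res.pvalue)


def rank_sum(x, y) -> float:
    """Two-tailed Mann-Whitney rank-sum p-value (unpaired alternative)."""
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a nonempty 1-D vector")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
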