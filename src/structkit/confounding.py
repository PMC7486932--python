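"""Phenotype variance explained by structure covariates (Nagelkerke R²).

Population-based PCs should not predict case/control status; when they do,
(sub)populations are stratified across phenotype and association statistics
are confounded.  The Nagelkerke pseudo-R² of a logistic model of phenotype
on structure covariates quantifies this:

    R² = (1 - exp((2/n)(l0 - l1))) / (1 - exp((2/n) l0)),

with l0, l1 the intercept-only and full-model log-likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, \
    PerfectSeparationWarning


@dataclass(frozen=True)
class NagelkerkeResult:
    """Cumulative and per-covariate pseudo-R² of phenotype on covariates."""

    r2: float                    # full model, all covariates
    marginal: pd.Series          # each covariate alone
    cumulative: pd.Series        # covariates added left to right
    separated: bool = False      # perfect separation encountered (R² capped at 1)


def _nagelkerke(ll_null: float, ll_full: float, n: int) -> float:
    denom = 1.0 - np.exp(2.0 / n * ll_null)
    if denom <= 0:
        return 0.0
    r2 = (1.0 - np.exp(2.0 / n * (ll_null - ll_full))) / denom
    return float(min(max(r2, 0.0), 1.0))


def _fit_ll(y: np.ndarray, X: np.ndarray) -> tuple[float, bool]:
    """Log-likelihood of a logistic fit; flags perfect separation."""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        return float(res.llf), False
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        return 0.0, True  # saturated likelihood: log L = 0


def nagelkerke_r2(phenotype, covariates) -> NagelkerkeResult:
    """Nagelkerke R² of a binary phenotype on covariate columns.

    ``covariates`` is a DataFrame or 2-D array; an intercept is always
    included.  Reports the full-model R² plus per-covariate marginal values
    and cumulative values as covariates are added in column order.  Perfect
    separation is flagged and R² capped at 1 with a warning.
    """
    y = np.asarray(phenotype, dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ValueError("phenotype must be binary 0/1")
    if (y == 0).sum() < 2 or (y == 1).sum() < 2:
        raise ValueError("need at least 2 of each phenotype class")
    X = covariates if isinstance(covariates, pd.DataFrame) else \
        pd.DataFrame(np.atleast_2d(np.asarray(covariates, dtype=float)).reshape(len(y), -1))
    if not np.isfinite(X.to_numpy()).all():
        raise ValueError("covariates must be finite")
    n = len(y)
    ones = np.ones((n, 1))
    ll_null, _ = _fit_ll(y, ones)

    def model_r2(cols: list) -> tuple[float, bool]:
        # zero-variance covariates are collinear with the intercept and add
        # nothing: drop them rather than letting the fit go singular
        arr = X[cols].to_numpy()
        arr = arr[:, arr.std(axis=0) > 0]
        if arr.shape[1] == 0:
            return 0.0, False
        mat = np.column_stack([ones, arr])
        ll, sep = _fit_ll(y, mat)
        return _nagelkerke(ll_null, ll, n), sep

    separated = False
    marginal = {}
    cumulative = {}
    for i, col in enumerate(X.columns):
        marginal[col], sep_m = model_r2([col])
        cumulative[col], sep_c = model_r2(list(X.columns[:i + 1]))
        separated = separated or sep_m or sep_c
    full_cols = list(X.columns)
    r2_full, sep_f = model_r2(full_cols)
    separated = separated or sep_f
    if separated:
        warnings.warn("perfect separation: Nagelkerke R² capped at 1",
                      stacklevel=2)
    return NagelkerkeResult(r2=r2_full,
                            marginal=pd.Series(marginal),
                            cumulative=pd.Series(cumulative),
                            separated=separated)
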