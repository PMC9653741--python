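"""Small shared linear-model helpers.

Vectorized OLS across many responses with a common design matrix, plus a
route selector for the random-grouping structures that occur here:

* paired designs (each group has exactly two samples and the factor flips
  within every group) reduce exactly to OLS on within-group differences;
* group-constant factors with a random intercept reduce, for balanced
  groups, to OLS on group means;
* a grouping with only two levels (the two sequencing batches) falls back
  to fixed-effect dummies, which is logged;
* anything else goes through statsmodels MixedLM per response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class OlsFit:
    """Slopes, standard errors and two-sided p-values for one design column
    across many response columns."""

    coef: np.ndarray
    se: np.ndarray
    p: np.ndarray
    df_resid: int


def ols_many(Y: np.ndarray, X: np.ndarray, test_col: int) -> OlsFit:
    """OLS of each column of ``Y`` on the common design ``X``.

    Returns the coefficient of ``X[:, test_col]``, its standard error and
    the two-sided t-test p-value, for every response column at once.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"not enough observations ({n}) for {k} parameters")
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ X.T @ Y  # k x m
    resid = Y - X @ beta
    df = n - np.linalg.matrix_rank(X)
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[test_col, test_col], 0.0))
    coef = beta[test_col]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return OlsFit(coef=coef, se=se, p=p, df_resid=df)


def encode_factor(values: pd.Series) -> tuple[np.ndarray, str]:
    """Encode a test factor as a single numeric column.

    Numeric factors pass through; binary categoricals become 0/1 with the
    lexicographically larger level coded 1 (the returned label names the
    level coded 1). Multi-level categoricals are rejected here — the
    single-coefficient operations of this package test binary or numeric
    factors.
    """
    if pd.api.types.is_numeric_dtype(values):
        arr = values.to_numpy(dtype=float)
        if np.all(arr == arr[0]):
            raise ValueError("factor is constant across samples")
        return arr, values.name or "factor"
    levels = sorted(pd.unique(values.dropna()))
    if len(levels) < 2:
        raise ValueError("factor is constant across samples")
    if len(levels) > 2:
        raise ValueError(
            f"factor has {len(levels)} levels; binary or numeric required"
        )
    coded = (values == levels[1]).astype(float).to_numpy()
    return coded, str(levels[1])


def dummy_columns(values: pd.Series) -> np.ndarray:
    """Drop-first dummy encoding of a categorical column (n x L-1)."""
    dummies = pd.get_dummies(values.astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


def mixedlm_single(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, test_col: int
) -> tuple[float, float]:
    """Random-intercept mixed model for one response; returns (slope, p)."""
    import statsmodels.api as sm

    model = sm.MixedLM(y, X, groups=groups)
    fit = model.fit(reml=True, method="lbfgs")
    return float(fit.params[test_col]), float(fit.pvalues[test_col])
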