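"""Model diagnostics: multicollinearity, rater agreement, rank correlation."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError

__all__ = ["vif", "icc_agreement", "spearman", "pearson"]


def vif(predictors: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 - R2_j).

    R2_j comes from an ordinary least-squares regression of predictor j on
    the remaining predictors plus an intercept.  VIF > 10 is the
    conventional multicollinearity flag.  A perfectly collinear predictor
    is reported as ``inf``.
    """
    X = predictors.astype(float)
    if X.shape[1] < 2:
        raise InputError("VIF needs at least two predictors")
    if X.shape[0] <= X.shape[1] + 1:
        raise InputError("VIF needs n > number of predictors + 1")
    out = {}
    for col in X.columns:
        y = X[col].to_numpy()
        others = X.drop(columns=col).to_numpy()
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            raise InputError(f"predictor {col!r} is constant")
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def icc_agreement(ratings) -> float:
    """Intraclass correlation, two-way random effects, absolute agreement,
    single rater (ICC(2,1)).

    ``ratings`` is an (n_subjects, 2) array: the same quantity measured by
    two raters (here: manual vs semi-automated rich-club counts).  Values
    <= 0 indicate no agreement beyond chance.
    """
    Y = np.asarray(ratings, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise InputError("ratings must be an (n_subjects, 2) array")
    n, k = Y.shape
    if n < 3:
        raise InputError("ICC needs at least 3 subjects")
    grand = Y.mean()
    if np.allclose(Y, grand):
        raise InputError("zero total variance: ICC undefined")
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((Y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    return float((msr - mse) / denom)


def _average_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    Computed as the Pearson correlation of average-ranked data, which
    handles ties; p is two-sided from t = rho * sqrt((n-2) / (1-rho^2))
    on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise InputError("spearman needs at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("constant input: rank correlation undefined")
    rx, ry = _average_ranks(x), _average_ranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)


def pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("constant input: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
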