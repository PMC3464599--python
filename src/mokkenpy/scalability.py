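"""Loevinger scalability coefficients H_ij, H_i and H, and the transposed
coefficient H^T.

For item scores X_i, X_j the pairwise coefficient is

    H_ij = Cov(X_i, X_j) / Covmax(X_i, X_j),

where Covmax is the maximum covariance attainable by any joint distribution
with the observed marginals (the comonotonic, Guttman-ordered coupling of
the two score distributions).  Item and scale coefficients are the
corresponding ratios of summed covariances:

    H_i = sum_{j != i} Cov_ij / sum_{j != i} Covmax_ij
    H   = sum_{i < j}  Cov_ij / sum_{i < j}  Covmax_ij

Under the monotone homogeneity model every coefficient lies in [0, 1] as a
population property: H = 1 for error-free cumulative (Guttman) data, H = 0
when the items carry no linear association.  The conventional strength
bands are H < 0.3 unscalable, [0.3, 0.4) weak, [0.4, 0.5) medium and
>= 0.5 strong.

H^T applies the same coefficient to the transposed matrix (respondents as
"items") and summarizes how accurately the items are ordered; its bands are
< 0.3 too inaccurate, [0.3, 0.4) low, [0.4, 0.5) medium, >= 0.5 high.

All covariances use the population divisor N so numerator and denominator
(and the enumeration oracle used in the tests) share one convention; the
ratios are invariant to that choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._validation import as_score_matrix
from .data import DataError

__all__ = [
    "pair_covariance",
    "pair_covmax",
    "coef_h",
    "coef_ht",
    "hij_positivity_test",
    "classify_h",
    "classify_ht",
    "ScalabilityResult",
    "ScalabilityAnalysis",
]


def classify_h(h: float) -> str:
    """Strength band of a scale-level H coefficient."""
    if h < 0.3:
        return "unscalable"
    if h < 0.4:
        return "weak"
    if h < 0.5:
        return "medium"
    return "strong"


def classify_ht(ht: float) -> str:
    """Accuracy band of the item-ordering coefficient H^T."""
    if ht < 0.3:
        return "inaccurate"
    if ht < 0.4:
        return "low accuracy"
    if ht < 0.5:
        return "medium accuracy"
    return "high accuracy"


def pair_covariance(x, y) -> float:
    """Sample covariance of two score columns, divisor N."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("columns must have equal length")
    if x.size < 2:
        raise DataError("need at least 2 observations")
    return float(np.mean(x * y) - np.mean(x) * np.mean(y))


def pair_covmax(x_marginals, y_marginals) -> float:
    """Maximum covariance given two category frequency tables.

    ``x_marginals[c]`` is the count of respondents scoring c on the item.
    The maximum over all joint tables with these marginals is attained by
    the comonotonic (sorted, Guttman-ordered) coupling.
    """
    fx = np.asarray(x_marginals, dtype=np.int64)
    fy = np.asarray(y_marginals, dtype=np.int64)
    if fx.sum() != fy.sum():
        raise DataError("marginal totals differ")
    n = int(fx.sum())
    if n < 1:
        raise DataError("empty marginals")
    xs = np.repeat(np.arange(fx.size), fx).astype(float)
    ys = np.repeat(np.arange(fy.size), fy).astype(float)
    return float(np.mean(xs * ys) - np.mean(xs) * np.mean(ys))


def _cov_covmax_matrices(values: np.ndarray):
    """Pairwise covariance and max-covariance matrices (divisor N)."""
    n, k = values.shape
    v = values.astype(float)
    means = v.mean(axis=0)
    cov = v.T @ v / n - np.outer(means, means)
    sorted_cols = np.sort(v, axis=0)
    covmax = sorted_cols.T @ sorted_cols / n - np.outer(means, means)
    # comonotonic coupling of a column with itself is just the variance row
    return cov, covmax


@dataclass
class ScalabilityResult:
    """H_ij matrix, H_i vector and scale H with classification."""

    item_labels: list[str]
    item_means: np.ndarray
    hij: np.ndarray
    hi: np.ndarray
    h: float
    classification: str
    cov: np.ndarray
    covmax: np.ndarray
    n_respondents: int

    def to_frame(self) -> pd.DataFrame:
        """Per-item table mirroring the Label / Mean / ItemH report layout."""
        return pd.DataFrame(
            {
                "Label": self.item_labels,
                "Mean": np.round(self.item_means, 4),
                "ItemH": np.round(self.hi, 4),
            }
        )


def coef_h(X) -> ScalabilityResult:
    """Loevinger scalability coefficients for a complete score matrix.

    Raises an error naming any zero-variance item (its pairwise maximum
    covariances are all 0, leaving H_i undefined).
    """
    values, labels = as_score_matrix(X, min_items=2)
    variances = values.var(axis=0)
    dead = [labels[j] for j in np.flatnonzero(variances == 0)]
    if dead:
        raise DataError(f"zero-variance item(s): {dead}; remove before scaling")
    cov, covmax = _cov_covmax_matrices(values)
    k = values.shape[1]
    off = ~np.eye(k, dtype=bool)
    hij = np.full((k, k), np.nan)
    hij[off] = cov[off] / covmax[off]
    hi = (cov * off).sum(axis=1) / (covmax * off).sum(axis=1)
    iu = np.triu_indices(k, 1)
    h = float(cov[iu].sum() / covmax[iu].sum())
    return ScalabilityResult(
        item_labels=labels,
        item_means=values.mean(axis=0),
        hij=hij,
        hi=hi,
        h=h,
        classification=classify_h(h),
        cov=cov,
        covmax=covmax,
        n_respondents=values.shape[0],
    )


def coef_ht(X) -> float:
    """Scalability of the transposed matrix: accuracy of the item ordering.

    Respondents with a constant response pattern carry no information about
    the ordering of the items and are dropped before transposing (they would
    otherwise be zero-variance "items" of the transposed matrix).

    Memory and time are quadratic in the number of respondents (they play
    the role of items in the transposed matrix).
    """
    values, _ = as_score_matrix(X, min_items=3)
    keep = values.var(axis=1) > 0
    reduced = values[keep]
    if reduced.shape[0] < 2:
        raise DataError(
            "H^T undefined: fewer than 2 non-constant response patterns"
        )
    return coef_h(reduced.T).h


def hij_positivity_test(X, alpha: float = 0.05) -> pd.DataFrame:
    """One-sided asymptotic test of H_ij > 0 for every item pair.

    Uses the normal approximation z = r_ij * sqrt(N - 1) on the item-pair
    correlation (positive correlation and positive H_ij are equivalent when
    covmax > 0).  Pairs with covmax = 0 are flagged degenerate, not tested.
    Small samples (N < 10) are flagged but still tested.
    """
    values, labels = as_score_matrix(X, min_items=2)
    n, k = values.shape
    cov, covmax = _cov_covmax_matrices(values)
    sd = np.sqrt(np.diag(cov))
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            degenerate = covmax[i, j] <= 0
            if degenerate:
                z = np.nan
                p = np.nan
                sig = False
            else:
                r = cov[i, j] / (sd[i] * sd[j])
                z = r * np.sqrt(n - 1)
                p = float(stats.norm.sf(z))
                sig = p < alpha
            rows.append(
                {
                    "item_i": labels[i],
                    "item_j": labels[j],
                    "hij": np.nan if degenerate else cov[i, j] / covmax[i, j],
                    "z": z,
                    "p": p,
                    "significant": sig,
                    "degenerate": degenerate,
                    "small_sample": n < 10,
                }
            )
    return pd.DataFrame(rows)


class ScalabilityAnalysis(BaseEstimator):
    """Estimator computing Loevinger scalability coefficients.

    Parameters
    ----------
    compute_ht : bool, default=False
        Also compute the transposed-matrix coefficient H^T (requires >= 3
        items and >= 2 distinct non-constant response patterns).

    Attributes
    ----------
    h_ : float
        Scale scalability coefficient.
    h_i_ : ndarray of shape (k,)
        Item scalability coefficients.
    h_ij_ : ndarray of shape (k, k)
        Pairwise coefficients (diagonal is NaN).
    classification_ : str
        Strength band: unscalable / weak / medium / strong.
    ht_ : float
        Only set when ``compute_ht=True``.
    result_ : ScalabilityResult
        Full result object including covariances for audit.
    """

    def __init__(self, compute_ht: bool = False):
        self.compute_ht = compute_ht

    def fit(self, X, y=None):
        result = coef_h(X)
        self.result_ = result
        self.h_ = result.h
        self.h_i_ = result.hi
        self.h_ij_ = result.hij
        self.item_labels_ = result.item_labels
        self.classification_ = result.classification
        self.n_features_in_ = len(result.item_labels)
        if self.compute_ht:
            self.ht_ = coef_ht(X)
            self.ht_classification_ = classify_ht(self.ht_)
        return self
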