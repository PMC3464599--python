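"""Total-score reliability: the Molenaar-Sijtsma estimate Rho and
Cronbach's alpha.

Rho estimates the reliability of the total score X+ as the (unobservable)
probability of giving the same responses twice.  Writing p_a for the
popularity of binary item-step indicator a and pi_ab for the proportion
endorsing steps a and b jointly, the covariance between two independent
replications of the total score is

    Cov(X+, X+') = sum_ab [ E(P_a(theta) P_b(theta)) - p_a p_b ].

For steps of *different* items local independence makes the expectation
equal the observed joint proportion; for steps of the same item (including
each step with itself, the matrix diagonal) it is unobservable and is
estimated by interpolation along the popularity-ordered neighbours, which
the non-intersection (double monotonicity) assumption justifies.  Rho is
this covariance divided by the observed variance of X+.  The estimate is
exact (Rho = 1) on deterministic Guttman data and close to unbiased under
the double monotonicity model, whereas alpha is a lower bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from ._validation import as_score_matrix
from .data import DataError

__all__ = ["ReliabilityResult", "cronbach_alpha", "ms_rho", "reliability",
           "MSReliability"]


@dataclass
class ReliabilityResult:
    """MS reliability Rho, Cronbach's alpha and caveat notes."""

    rho_ms: float
    cronbach_alpha: float
    notes: list[str] = field(default_factory=list)


def cronbach_alpha(X) -> float:
    """k/(k-1) * (1 - sum of item variances / total-score variance)."""
    values, _ = as_score_matrix(X, min_items=2)
    k = values.shape[1]
    total_var = values.sum(axis=1).var()
    if total_var == 0:
        raise DataError("total score has zero variance; alpha undefined")
    return float(k / (k - 1) * (1 - values.var(axis=0).sum() / total_var))


def _step_indicators(values: np.ndarray):
    """Binary step indicator columns I(X_j >= s), s = 1..m_j, per item."""
    cols = []
    owners = []
    for j in range(values.shape[1]):
        m = int(values[:, j].max())
        for s in range(1, m + 1):
            cols.append(values[:, j] >= s)
            owners.append(j)
    return np.column_stack(cols).astype(float), np.asarray(owners)


def _loglinear_extrapolate(j1: float, j2: float, p0: float, p1: float,
                           p2: float) -> float:
    """Extrapolate a joint proportion log-linearly in popularity.

    Fits log(joint with neighbour) against log(neighbour popularity)
    through the two nearest neighbours and evaluates at the item's own
    popularity.  On deterministic Guttman data the fitted slope is exactly
    1, so the rule is exact there.
    """
    if min(j1, j2, p0, p1, p2) <= 0 or p1 == p2:
        return np.nan
    slope = (np.log(j1) - np.log(j2)) / (np.log(p1) - np.log(p2))
    return float(np.exp(np.log(j1) + (np.log(p0) - np.log(p1)) * slope))


def _interpolate_unobservables(P: np.ndarray, p: np.ndarray,
                               masked: np.ndarray, sweeps: int = 25):
    """Fill unobservable joint proportions by neighbour interpolation.

    Steps are in popularity order (descending p).  Interior entries blend
    two estimators that bracket the two regimes a Mokken scale can occupy:

    * the multiplicative stencil G[a-1,b] * G[a,b+1] / G[a-1,b+1], exact on
      deterministic Guttman (scalogram) data, and
    * linear interpolation of the joint proportion in the neighbours'
      popularities, accurate for smooth stochastic response functions,

    weighted by the observed scalability (pairwise H, clipped to [0, 1]) of
    the flanking pair - the data's own measure of how close the scale is to
    the deterministic extreme.  First/last entries use log-linear
    extrapolation through the two nearest neighbours (slope exactly 1 on
    Guttman data, hence exact there; the last item works on reversed
    scorings).  Estimates are clamped to the [p_a*p_b, min(p_a, p_b)] band
    implied by monotone response functions and iterated to a fixed point
    (entries of a stencil may themselves be unobservable when several steps
    of one item are adjacent in the popularity order).
    """
    K = P.shape[0]
    G = P.copy()
    lower = np.outer(p, p)
    upper = np.minimum.outer(p, p)
    G[masked] = upper[masked]  # start at the Guttman (perfect-scaling) bound
    pairs = [(a, b) for a in range(K) for b in range(a, K) if masked[a, b]]
    for _ in range(sweeps):
        delta = 0.0
        for a, b in pairs:
            est = np.nan
            if a > 0 and b < K - 1 and a == b:
                est = _blend_diagonal(G, p, lower, upper, a)
            elif a > 0 and b < K - 1:
                # same-item off-diagonal (polytomous): scalogram stencil
                den = G[a - 1, b + 1]
                est = G[a - 1, b] * G[a, b + 1] / den if den > 0 else np.nan
            elif a == 0 and b < K - 1 and K >= 3:
                # no more-popular neighbour: extrapolate along row b using
                # the two nearest steps below (skipping b itself)
                nbrs = [j for j in range(1, K) if j != b][:2]
                if len(nbrs) == 2:
                    n1, n2 = nbrs
                    est = _loglinear_extrapolate(
                        G[n1, b], G[n2, b], p[0], p[n1], p[n2]
                    )
            elif a > 0 and b == K - 1 and K >= 3:
                if a == b:
                    # reversed-scoring extrapolation at the least popular end
                    q = 1 - p
                    j1 = 1 - p[b] - p[b - 1] + G[b, b - 1]
                    j2 = 1 - p[b] - p[b - 2] + G[b, b - 2]
                    est0 = _loglinear_extrapolate(
                        j1, j2, q[b], q[b - 1], q[b - 2]
                    )
                    est = est0 - 1 + 2 * p[b] if np.isfinite(est0) else np.nan
                else:
                    # same-item off-diagonal at the last column: leftward
                    # scalogram stencil
                    den = G[a - 1, b - 1]
                    est = G[a - 1, b] * G[a, b - 1] / den if den > 0 else np.nan
            if not np.isfinite(est):
                est = 0.5 * (lower[a, b] + upper[a, b])
            est = min(max(est, lower[a, b]), upper[a, b])
            delta = max(delta, abs(est - G[a, b]))
            G[a, b] = est
            G[b, a] = est
        if delta < 1e-12:
            break
    return G


def _blend_diagonal(G, p, lower, upper, a) -> float:
    """Scalability-weighted blend of two diagonal estimators.

    The multiplicative stencil G[a-1,a]*G[a,a+1]/G[a-1,a+1] is exact on
    deterministic Guttman data; linear interpolation of the joint
    proportion in the neighbours' popularities is accurate for smooth
    response functions.  The weight is the observed pairwise scalability
    (H of the flanking pair, clipped to [0, 1]), which equals 1 exactly at
    the Guttman extreme.
    """
    den = G[a - 1, a + 1]
    mult = G[a - 1, a] * G[a, a + 1] / den if den > 0 else np.nan
    hi_j, lo_j = G[a - 1, a], G[a, a + 1]
    hi_p, lo_p = p[a - 1], p[a + 1]
    if hi_p == lo_p:
        lin = 0.5 * (lo_j + hi_j)
    else:
        lam = min(max((p[a] - lo_p) / (hi_p - lo_p), 0.0), 1.0)
        lin = lam * hi_j + (1 - lam) * lo_j
    cmax = upper[a - 1, a + 1] - lower[a - 1, a + 1]
    if cmax > 0:
        w = min(max((G[a - 1, a + 1] - lower[a - 1, a + 1]) / cmax, 0.0), 1.0)
    else:
        w = 1.0
    if not np.isfinite(mult):
        return lin
    return w * mult + (1 - w) * lin


def ms_rho(X, dmm_checked: bool = False) -> ReliabilityResult:
    """Molenaar-Sijtsma reliability of the total score (with alpha).

    Requires at least 3 items (the diagonal interpolation needs two
    popularity-ordered neighbours).  Polytomous items enter through their
    item-step indicators; the total score is unchanged.
    """
    values, labels = as_score_matrix(X, min_items=3)
    if np.any(values.max(axis=0) == 0):
        dead = [labels[j] for j in np.flatnonzero(values.max(axis=0) == 0)]
        raise DataError(f"degenerate marginals (constant items): {dead}")
    steps, owners = _step_indicators(values)
    n, K = steps.shape
    if len(np.unique(owners)) < 3:
        raise DataError("MS rho needs at least 3 non-constant items")
    p = steps.mean(axis=0)
    order = np.argsort(-p, kind="stable")
    steps = steps[:, order]
    owners = owners[order]
    p = p[order]
    P = steps.T @ steps / n
    masked = np.equal.outer(owners, owners)
    G = _interpolate_unobservables(P, p, masked)
    cross_cov = G - np.outer(p, p)           # replication covariances
    sample_cov = P - np.outer(p, p)          # within-replication covariances
    numerator = np.where(masked, cross_cov, sample_cov).sum()
    total_var = values.sum(axis=1).var()
    if total_var == 0:
        raise DataError("total score has zero variance; reliability undefined")
    rho = float(numerator / total_var)
    notes = []
    if not dmm_checked:
        notes.append(
            "double monotonicity (non-intersection) diagnostics were not run; "
            "Rho assumes non-intersecting item response functions - check the "
            "DMM assumptions before interpreting this estimate"
        )
    return ReliabilityResult(
        rho_ms=rho,
        cronbach_alpha=cronbach_alpha(values),
        notes=notes,
    )


def reliability(X, dmm_checked: bool = False) -> ReliabilityResult:
    """Alias for :func:`ms_rho`."""
    return ms_rho(X, dmm_checked=dmm_checked)


class MSReliability(BaseEstimator):
    """Estimator computing MS Rho and Cronbach's alpha for the total score.

    Attributes
    ----------
    rho_ : float
        Molenaar-Sijtsma reliability estimate.
    alpha_ : float
        Cronbach's alpha (a lower bound on the reliability).
    notes_ : list of str
    """

    def __init__(self, dmm_checked: bool = False):
        self.dmm_checked = dmm_checked

    def fit(self, X, y=None):
        result = ms_rho(X, dmm_checked=self.dmm_checked)
        self.result_ = result
        self.rho_ = result.rho_ms
        self.alpha_ = result.cronbach_alpha
        self.notes_ = result.notes
        return self
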