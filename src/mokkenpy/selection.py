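"""Automated item selection: partition an item pool into Mokken scales.

The bottom-up ("normal") search starts a scale from the best significantly
positive item pair whose H_ij clears the lower bound c, then repeatedly adds
the unselected item that maximizes the scale's H subject to (a) a
significantly positive H_ij with every selected item and (b) every member's
within-scale H_i staying at or above c.  When no item qualifies, the next
scale is started from the remaining pool; leftovers are marked unscalable
(scale id 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from ._validation import as_score_matrix
from .data import DataError
from .scalability import ScalabilityResult, _cov_covmax_matrices, coef_h

__all__ = ["AispConfig", "ScalePartition", "aisp", "cutoff_sweep", "ScalePartitioner"]


@dataclass
class AispConfig:
    """Search settings: H_i lower bound c, significance level, strategy."""

    lowerbound: float = 0.3
    alpha: float = 0.05
    strategy: str = "normal"

    def __post_init__(self) -> None:
        if not 0 <= self.lowerbound < 1:
            raise DataError("lowerbound must be in [0, 1)")
        if not 0 < self.alpha < 1:
            raise DataError("alpha must be in (0, 1)")
        if self.strategy != "normal":
            warnings.warn(
                f"search strategy {self.strategy!r} is not implemented; "
                "falling back to the bottom-up 'normal' search",
                stacklevel=2,
            )
            self.strategy = "normal"


@dataclass
class ScalePartition:
    """Assignment of items to scales (1, 2, ... ; 0 = unscalable)."""

    item_labels: list[str]
    assignment: np.ndarray
    scales: list[ScalabilityResult] = field(default_factory=list)
    config: AispConfig = field(default_factory=AispConfig)

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def items_in_scale(self, scale_id: int) -> list[str]:
        return [
            lab
            for lab, a in zip(self.item_labels, self.assignment)
            if a == scale_id
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Label": self.item_labels, "Scale": self.assignment}
        )


def _subset_h(cov, covmax, items):
    """Scale H and within-subset H_i from precomputed pair matrices."""
    idx = np.asarray(items)
    c = cov[np.ix_(idx, idx)]
    cm = covmax[np.ix_(idx, idx)]
    off = ~np.eye(len(idx), dtype=bool)
    iu = np.triu_indices(len(idx), 1)
    h = c[iu].sum() / cm[iu].sum()
    hi = (c * off).sum(axis=1) / (cm * off).sum(axis=1)
    return float(h), hi


def aisp(X, config: AispConfig | None = None) -> ScalePartition:
    """Greedy bottom-up partition of the item pool into Mokken scales."""
    config = config or AispConfig()
    values, labels = as_score_matrix(X, min_items=2)
    n, k = values.shape
    cov, covmax = _cov_covmax_matrices(values)
    sd = np.sqrt(np.diag(cov))
    z_crit = stats.norm.isf(config.alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / np.outer(sd, sd)
    sig = np.zeros((k, k), dtype=bool)
    ok = np.isfinite(r)
    sig[ok] = r[ok] * np.sqrt(n - 1) >= z_crit
    np.fill_diagonal(sig, False)
    with np.errstate(divide="ignore", invalid="ignore"):
        hij = np.where(covmax > 0, cov / covmax, np.nan)

    c = config.lowerbound
    assignment = np.zeros(k, dtype=int)
    remaining = list(range(k))
    scale_members: list[list[int]] = []
    while len(remaining) >= 2:
        # best admissible starting pair
        best_pair = None
        for ii, a in enumerate(remaining):
            for b in remaining[ii + 1:]:
                if not sig[a, b] or not np.isfinite(hij[a, b]):
                    continue
                if hij[a, b] < c:
                    continue
                if best_pair is None or hij[a, b] > hij[best_pair]:
                    best_pair = (a, b)
        if best_pair is None:
            break
        scale = list(best_pair)
        remaining = [x for x in remaining if x not in scale]
        while remaining:
            admissible = []
            for x in remaining:
                if not all(sig[x, s] for s in scale):
                    continue
                trial = scale + [x]
                h, hi = _subset_h(cov, covmax, trial)
                if np.all(hi >= c):
                    covmax_sum = covmax[x, scale].sum()
                    admissible.append((h, covmax_sum, -x))
            if not admissible:
                break
            h, covmax_sum, neg_x = max(admissible)
            scale.append(-neg_x)
            remaining.remove(-neg_x)
        scale_members.append(sorted(scale))
    scales = []
    for sid, members in enumerate(scale_members, start=1):
        assignment[members] = sid
        scales.append(coef_h(values[:, members]))
    return ScalePartition(
        item_labels=labels,
        assignment=assignment,
        scales=scales,
        config=config,
    )


def cutoff_sweep(X, cutoffs, alpha: float = 0.05) -> list[ScalePartition]:
    """Run aisp at each H_i lower bound (ascending) to show fragmentation."""
    cutoffs = list(cutoffs)
    if cutoffs != sorted(cutoffs):
        raise DataError("cutoffs must be ascending")
    return [
        aisp(X, AispConfig(lowerbound=cut, alpha=alpha)) for cut in cutoffs
    ]


class ScalePartitioner(TransformerMixin, BaseEstimator):
    """Estimator form of the automated item selection procedure.

    Parameters
    ----------
    lowerbound : float, default 0.3
        Within-scale H_i cutoff c.
    alpha : float, default 0.05
        Level of the one-sided H_ij > 0 screen.

    Attributes
    ----------
    labels_ : ndarray of shape (k,)
        Scale id per item; 0 marks unscalable items.
    scales_ : list of ScalabilityResult
        Per-scale scalability results (scale ids 1, 2, ...).
    partition_ : ScalePartition

    ``transform`` restricts a matrix to the items of the first scale.
    """

    def __init__(self, lowerbound: float = 0.3, alpha: float = 0.05):
        self.lowerbound = lowerbound
        self.alpha = alpha

    def fit(self, X, y=None):
        self.partition_ = aisp(
            X, AispConfig(lowerbound=self.lowerbound, alpha=self.alpha)
        )
        self.labels_ = self.partition_.assignment
        self.scales_ = self.partition_.scales
        self.item_labels_ = self.partition_.item_labels
        self.n_features_in_ = len(self.labels_)
        return self

    def transform(self, X):
        if not hasattr(self, "partition_"):
            raise RuntimeError("ScalePartitioner is not fitted")
        if self.partition_.n_scales == 0:
            raise DataError("no scale was found; nothing to select")
        values, _ = as_score_matrix(X, min_items=2)
        cols = np.flatnonzero(self.labels_ == 1)
        return values[:, cols]
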