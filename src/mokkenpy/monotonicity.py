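"""Manifest monotonicity checks of item (step) response functions.

Monotonicity of an item's response function is assessed manifestly: the
unobserved latent trait is replaced by the restscore (total score on the
other items).  If monotonicity holds then, apart from sampling error, a
higher restscore group endorses each item step at least as often as a
lower one.  For every ordered pair of restscore groups (an "active
comparison", #ac) a decrease of the endorsement proportion of at least
``minvi`` counts as a violation (#vi); each flagged decrease is tested with
a one-sided two-proportion z-test and significant ones count toward #zsig.

For polytomous items the check applies per item step response function
(ISRF), the probability of scoring at or above each category boundary.

The ``crit`` severity statistic is a composite screening index (values
below 40 are conventionally treated as not serious).  No closed formula
for it is published; the MSP-style weighted composite implemented here is
documented in docs/methods.md and all of its components are exported so
users can apply their own rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._validation import as_score_matrix
from .data import DataError
from .grouping import RestscoreGroups, default_minsize, group_restscores
from .scalability import coef_h

__all__ = [
    "CheckSettings",
    "MonotonicityReport",
    "build_restscore_groups",
    "check_monotonicity",
    "export_monotonicity_plotdata",
    "MonotonicityCheck",
]


@dataclass
class CheckSettings:
    """Settings shared by monotonicity and item-ordering checks.

    minsize : minimum restscore-group size (None = sample-size default rule)
    minvi : minimum decrease counted as a violation (0.03 by default; the
        worked-example configurations use 0.18 for item-ordering checks)
    alpha : per-comparison significance level for violation tests
    """

    minsize: int | None = None
    minvi: float = 0.03
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.minsize is not None and self.minsize < 1:
            raise DataError("minsize must be >= 1")
        if self.minvi < 0:
            raise DataError("minvi must be >= 0")
        if not 0 < self.alpha < 1:
            raise DataError("alpha must be in (0, 1)")

    def resolve_minsize(self, n: int) -> int:
        return self.minsize if self.minsize is not None else default_minsize(n)


def build_restscore_groups(
    X, focal_item: int, settings: CheckSettings | None = None
) -> RestscoreGroups:
    """Restscore groups for one focal item (restscore excludes the item)."""
    settings = settings or CheckSettings()
    values, _ = as_score_matrix(X, min_items=2)
    restscore = values.sum(axis=1) - values[:, focal_item]
    return group_restscores(restscore, settings.resolve_minsize(values.shape[0]))


def _two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> float:
    """One-sided pooled z for p1 > p2 (decrease toward higher restscore)."""
    pooled = (x1 + x2) / (n1 + n2)
    denom = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if denom <= 0:
        return 0.0
    return float((x1 / n1 - x2 / n2) / np.sqrt(denom))


@dataclass
class MonotonicityReport:
    """Per-item violation counts and plot-ready step response series."""

    summary: pd.DataFrame              # Label, ItemH, #ac, #vi, #zsig, crit, ...
    plot_data: pd.DataFrame            # long: item, step, group, n, proportion
    groups: dict = field(default_factory=dict)
    settings: CheckSettings = field(default_factory=CheckSettings)

    def to_frame(self) -> pd.DataFrame:
        return self.summary[["Label", "ItemH", "#ac", "#vi", "#zsig", "crit"]]


def check_monotonicity(X, settings: CheckSettings | None = None) -> MonotonicityReport:
    """Count manifest monotonicity violations per item (step)."""
    settings = settings or CheckSettings()
    values, labels = as_score_matrix(X, min_items=3)
    n, k = values.shape
    minsize = settings.resolve_minsize(n)
    z_crit = stats.norm.isf(settings.alpha)
    hi = coef_h(values).hi
    total = values.sum(axis=1)

    rows = []
    plot_rows = []
    groups = {}
    for i in range(k):
        restscore = total - values[:, i]
        grp = group_restscores(restscore, minsize)
        groups[labels[i]] = grp
        r = grp.n_groups
        m_i = int(values[:, i].max())
        ac = vi = zsig = 0
        vi_mags: list[float] = []
        z_stats: list[float] = []
        sizes = grp.group_sizes
        for s in range(1, m_i + 1):
            endorsed = values[:, i] >= s
            counts = np.bincount(grp.group_index, weights=endorsed, minlength=r)
            props = counts / sizes
            for g in range(r):
                plot_rows.append(
                    {
                        "item": labels[i],
                        "step": s,
                        "group": grp.labels()[g],
                        "n": int(sizes[g]),
                        "proportion": props[g],
                    }
                )
            for g1 in range(r):
                for g2 in range(g1 + 1, r):
                    ac += 1
                    decrease = props[g1] - props[g2]
                    if decrease > 0 and decrease >= settings.minvi:
                        vi += 1
                        vi_mags.append(decrease)
                        z = _two_proportion_z(
                            int(counts[g1]), int(sizes[g1]),
                            int(counts[g2]), int(sizes[g2]),
                        )
                        z_stats.append(z)
                        if z >= z_crit:
                            zsig += 1
        crit, comp = _crit_statistic(hi[i], ac, vi_mags, z_stats)
        rows.append(
            {
                "Label": labels[i],
                "ItemH": hi[i],
                "#ac": ac,
                "#vi": vi,
                "#zsig": zsig,
                "crit": crit,
                "maxvi": comp["maxvi"],
                "sum_vi": comp["sum_vi"],
                "maxz": comp["maxz"],
                "sum_z": comp["sum_z"],
                "n_groups": r,
            }
        )
    return MonotonicityReport(
        summary=pd.DataFrame(rows),
        plot_data=pd.DataFrame(plot_rows),
        groups=groups,
        settings=settings,
    )


def _crit_statistic(hi: float, ac: int, vi_mags: list[float], z_stats: list[float]):
    """MSP-style composite severity score; 0 when there are no violations."""
    nvi = len(vi_mags)
    comp = {
        "maxvi": max(vi_mags) if vi_mags else 0.0,
        "sum_vi": float(sum(vi_mags)),
        "maxz": max(z_stats) if z_stats else 0.0,
        "sum_z": float(sum(z_stats)),
    }
    if nvi == 0 or ac == 0:
        return 0, comp
    crit = (
        50 * (0.30 - hi)
        + np.sqrt(nvi)
        + 100 * nvi / ac
        + 100 * comp["maxvi"]
        + 10 * np.sqrt(comp["sum_vi"])
        + 1000 * comp["sum_vi"] / ac
        + 5 * comp["maxz"]
        + 10 * np.sqrt(comp["sum_z"])
        + 100 * comp["sum_z"] / ac
    )
    return int(round(max(crit, 0.0))), comp


def export_monotonicity_plotdata(report: MonotonicityReport) -> pd.DataFrame:
    """Long-format series (item, step, group, n, proportion) for plotting."""
    return report.plot_data.copy()


class MonotonicityCheck(BaseEstimator):
    """Estimator form of the manifest monotonicity check.

    Parameters mirror :class:`CheckSettings`.

    Attributes
    ----------
    summary_ : pandas.DataFrame
        One row per item with ItemH, #ac, #vi, #zsig and crit.
    report_ : MonotonicityReport
        Full report including plot data and restscore groups.
    """

    def __init__(self, minvi: float = 0.03, minsize: int | None = None,
                 alpha: float = 0.05):
        self.minvi = minvi
        self.minsize = minsize
        self.alpha = alpha

    def fit(self, X, y=None):
        settings = CheckSettings(
            minsize=self.minsize, minvi=self.minvi, alpha=self.alpha
        )
        self.report_ = check_monotonicity(X, settings)
        self.summary_ = self.report_.summary
        self.n_features_in_ = len(self.summary_)
        return self
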