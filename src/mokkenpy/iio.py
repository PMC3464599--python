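"""Invariant item ordering (IIO) diagnostics.

Under the double monotonicity model the items keep the same "difficulty"
ordering at every level of the latent trait (for binary items this is
exactly non-intersection of the item characteristic curves).  The manifest
MIIO check orders items by overall mean and, for every pair with a strict
expected order, compares the conditional item means within restscore groups
(the restscore excludes both items of the pair).  A reversal of at least
``minvi`` is a violation; flagged reversals are tested with a one-sided
paired t-test on the within-respondent score difference, and significant
ones count toward #tsig for both items of the pair.

Backward selection repeatedly removes the single item with the most
significant violations (ties broken by lowest item scalability H_i) until
no significant violations remain, and reports H^T of the surviving set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._validation import as_score_matrix
from .data import DataError
from .grouping import group_restscores
from .monotonicity import CheckSettings
from .scalability import classify_ht, coef_h, coef_ht

__all__ = [
    "IIOReport",
    "check_iio_miio",
    "check_nonintersection_dichotomous",
    "backward_select_iio",
    "IIOCheck",
]


@dataclass
class IIOReport:
    """Per-item MIIO violation counts, pair detail and removal trace."""

    summary: pd.DataFrame                  # Label, Mean, #ac, #vi, #tsig
    pair_detail: pd.DataFrame
    removal_trace: pd.DataFrame | None = None   # items x steps, NaN = removed
    ht_final: float | None = None
    selected_items: list[str] = field(default_factory=list)
    settings: CheckSettings = field(default_factory=CheckSettings)

    @property
    def ht_classification(self) -> str | None:
        if self.ht_final is None:
            return None
        return classify_ht(self.ht_final)

    def to_frame(self) -> pd.DataFrame:
        return self.summary[["Label", "Mean", "#ac", "#vi", "#tsig"]]


def _paired_one_sided_t(diff: np.ndarray) -> float:
    """p-value for mean(diff) > 0 via a paired t-test on the differences."""
    n = diff.size
    if n < 2:
        return 1.0
    sd = diff.std(ddof=1)
    mean = diff.mean()
    if sd == 0:
        return 0.0 if mean > 0 else 1.0
    t = mean / (sd / np.sqrt(n))
    return float(stats.t.sf(t, df=n - 1))


def check_iio_miio(X, settings: CheckSettings | None = None) -> IIOReport:
    """Manifest invariant item ordering check (MIIO) for >= 3 items."""
    settings = settings or CheckSettings()
    values, labels = as_score_matrix(X, min_items=3)
    n, k = values.shape
    minsize = settings.resolve_minsize(n)
    total = values.sum(axis=1)
    means = values.mean(axis=0)

    ac = np.zeros(k, dtype=int)
    vi = np.zeros(k, dtype=int)
    tsig = np.zeros(k, dtype=int)
    detail_rows = []
    for a in range(k):
        for b in range(a + 1, k):
            if means[a] == means[b]:
                continue  # no defined order to violate; pair skipped
            lo, hi = (a, b) if means[a] < means[b] else (b, a)
            restscore = total - values[:, a] - values[:, b]
            grp = group_restscores(restscore, minsize)
            ac[a] += grp.n_groups
            ac[b] += grp.n_groups
            for g in range(grp.n_groups):
                in_g = grp.group_index == g
                diff = (values[in_g, lo] - values[in_g, hi]).astype(float)
                reversal = diff.mean()
                if reversal > 0 and reversal >= settings.minvi:
                    vi[a] += 1
                    vi[b] += 1
                    p = _paired_one_sided_t(diff)
                    significant = p < settings.alpha
                    if significant:
                        tsig[a] += 1
                        tsig[b] += 1
                    detail_rows.append(
                        {
                            "item_low": labels[lo],
                            "item_high": labels[hi],
                            "group": grp.labels()[g],
                            "n": int(in_g.sum()),
                            "magnitude": reversal,
                            "p": p,
                            "significant": significant,
                        }
                    )
    summary = pd.DataFrame(
        {
            "Label": labels,
            "Mean": means,
            "#ac": ac,
            "#vi": vi,
            "#tsig": tsig,
        }
    )
    return IIOReport(
        summary=summary,
        pair_detail=pd.DataFrame(
            detail_rows,
            columns=[
                "item_low", "item_high", "group", "n",
                "magnitude", "p", "significant",
            ],
        ),
        settings=settings,
    )


def check_nonintersection_dichotomous(
    X, settings: CheckSettings | None = None
) -> IIOReport:
    """Non-intersection check for binary items (MIIO specialized)."""
    values, _ = as_score_matrix(X, min_items=3)
    if values.max() > 1:
        raise DataError(
            "non-binary items present; use check_iio_miio for polytomous data"
        )
    return check_iio_miio(values, settings)


def backward_select_iio(X, settings: CheckSettings | None = None) -> IIOReport:
    """Remove items violating IIO one at a time until none remain.

    At each step the item with the most significant violations is removed;
    ties are broken by removing the item with the lowest scalability H_i.
    The trace mirrors the stepwise report layout (NaN = item removed), and
    H^T of the surviving set is attached.
    """
    settings = settings or CheckSettings()
    values, labels = as_score_matrix(X, min_items=3)
    current = list(range(values.shape[1]))
    trace: dict[str, list] = {lab: [] for lab in labels}
    last_report = None
    while True:
        report = check_iio_miio(values[:, current], settings)
        last_report = report
        tsig = report.summary["#tsig"].to_numpy()
        for lab in labels:
            if lab in set(report.summary["Label"]):
                idx = list(report.summary["Label"]).index(lab)
                trace[lab].append(int(tsig[idx]))
            else:
                trace[lab].append(np.nan)
        if tsig.max() == 0:
            break
        worst = int(tsig.max())
        candidates = [current[i] for i in np.flatnonzero(tsig == worst)]
        if len(candidates) > 1:
            hi = coef_h(values[:, current]).hi
            hi_by_col = {current[i]: hi[i] for i in range(len(current))}
            candidates.sort(key=lambda c: (hi_by_col[c], c))
        current.remove(candidates[0])
        if len(current) < 3:
            warnings.warn(
                "backward IIO selection stopped: fewer than 3 items remain",
                stacklevel=2,
            )
            break
    steps = len(next(iter(trace.values())))
    removal_trace = pd.DataFrame(
        trace, index=[f"Step {s + 1}" for s in range(steps)]
    ).T
    selected = [labels[c] for c in current]
    ht_final = coef_ht(values[:, current]) if len(current) >= 3 else None
    return IIOReport(
        summary=last_report.summary,
        pair_detail=last_report.pair_detail,
        removal_trace=removal_trace,
        ht_final=ht_final,
        selected_items=selected,
        settings=settings,
    )


class IIOCheck(BaseEstimator):
    """Estimator form of the invariant item ordering check.

    Parameters
    ----------
    method : {"MIIO"}, default "MIIO"
        Manifest invariant item ordering.  The MSCPM and IT variants are
        not implemented.
    minvi, minsize, alpha : see :class:`~mokkenpy.monotonicity.CheckSettings`.
    item_selection : bool, default False
        Run backward removal of violating items; enables :meth:`transform`.

    Attributes
    ----------
    summary_ : pandas.DataFrame
    selected_items_ : list of str (only with item_selection)
    removal_trace_ : pandas.DataFrame (only with item_selection)
    ht_ : float or None
        H^T of the surviving item set (only with item_selection).
    """

    def __init__(self, method: str = "MIIO", minvi: float = 0.03,
                 minsize: int | None = None, alpha: float = 0.05,
                 item_selection: bool = False):
        self.method = method
        self.minvi = minvi
        self.minsize = minsize
        self.alpha = alpha
        self.item_selection = item_selection

    def _settings(self) -> CheckSettings:
        return CheckSettings(minsize=self.minsize, minvi=self.minvi,
                             alpha=self.alpha)

    def fit(self, X, y=None):
        if self.method.upper() != "MIIO":
            raise NotImplementedError(
                f"method {self.method!r} not implemented; only MIIO is available"
            )
        if self.item_selection:
            self.report_ = backward_select_iio(X, self._settings())
            self.selected_items_ = self.report_.selected_items
            self.removal_trace_ = self.report_.removal_trace
            self.ht_ = self.report_.ht_final
        else:
            self.report_ = check_iio_miio(X, self._settings())
        self.summary_ = self.report_.summary
        self.n_features_in_ = len(self.report_.summary)
        return self

    def transform(self, X):
        """Restrict X to the items surviving backward selection."""
        if not hasattr(self, "report_"):
            raise RuntimeError("IIOCheck is not fitted")
        if not self.item_selection:
            raise RuntimeError("transform requires item_selection=True")
        values, labels = as_score_matrix(X, min_items=2)
        cols = [labels.index(lab) for lab in self.selected_items_]
        return values[:, cols]
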