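"""Restscore grouping: the observable proxy for the latent trait.

A respondent's restscore is the total score on all items except the focal
item (or except both items of a pair, for item-ordering checks).  Groups
are formed from the lowest restscore upward; an adjacent group smaller than
``minsize`` is merged into its right neighbour, and a final undersized
group merges left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataError

__all__ = ["default_minsize", "group_restscores", "RestscoreGroups"]


def default_minsize(n: int) -> int:
    """Default minimum restscore-group size for a sample of size n.

    The rule is N/10 for N > 500, N/5 for 250 < N <= 500 and N/3 (but at
    least 50) for N <= 250, truncated to an integer.
    """
    if n < 1:
        raise DataError("sample size must be positive")
    if n > 500:
        return n // 10
    if n > 250:
        return n // 5
    return max(n // 3, 50)


@dataclass
class RestscoreGroups:
    """Partition of respondents into ordered restscore groups."""

    group_index: np.ndarray        # per respondent group id, 0 = lowest
    group_sizes: np.ndarray
    group_lower: np.ndarray        # inclusive restscore range per group
    group_upper: np.ndarray

    @property
    def n_groups(self) -> int:
        return int(self.group_sizes.size)

    def labels(self) -> list[str]:
        out = []
        for lo, hi in zip(self.group_lower, self.group_upper):
            out.append(str(lo) if lo == hi else f"{lo}-{hi}")
        return out


def group_restscores(
    restscore: np.ndarray, minsize: int, min_groups: int = 2
) -> RestscoreGroups:
    """Bucket restscores ascending, merging adjacent buckets below minsize."""
    if minsize < 1:
        raise DataError("minsize must be >= 1")
    restscore = np.asarray(restscore)
    values, counts = np.unique(restscore, return_counts=True)
    boundaries = []  # list of (lo, hi, size)
    acc = 0
    lo = values[0] if values.size else 0
    for v, c in zip(values, counts):
        acc += int(c)
        if acc >= minsize:
            boundaries.append((lo, v, acc))
            acc = 0
            nxt = np.searchsorted(values, v, side="right")
            lo = values[nxt] if nxt < values.size else v
    if acc > 0:
        if boundaries:
            plo, _, psize = boundaries[-1]
            boundaries[-1] = (plo, values[-1], psize + acc)
        else:
            boundaries.append((lo, values[-1], acc))
    if len(boundaries) < min_groups:
        raise DataError(
            f"cannot form {min_groups} restscore groups of size >= {minsize}; "
            "monotonicity cannot be meaningfully assessed - lower minsize"
        )
    lows = np.array([b[0] for b in boundaries])
    highs = np.array([b[1] for b in boundaries])
    sizes = np.array([b[2] for b in boundaries])
    group_index = np.searchsorted(highs, restscore, side="left")
    return RestscoreGroups(
        group_index=group_index,
        group_sizes=sizes,
        group_lower=lows,
        group_upper=highs,
    )
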