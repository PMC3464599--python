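"""Independent brute-force oracles used to validate the coefficient code.

These deliberately avoid the comonotonic-coupling shortcut of the library:
the maximum covariance is found by exhaustively enumerating every joint
contingency table compatible with the observed marginals.  Feasible for
k <= 4 items, scores 0..2 and N <= 12.
"""

import itertools

import numpy as np


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    rows = len(row_sums)
    if rows == 1:
        yield [list(col_sums)]
        return
    ranges = [range(min(row_sums[0], c) + 1) for c in col_sums]
    for first in itertools.product(*ranges):
        if sum(first) != row_sums[0]:
            continue
        rest_cols = [c - f for c, f in zip(col_sums, first)]
        for tail in _enumerate_tables(row_sums[1:], rest_cols):
            yield [list(first)] + tail


def brute_covmax(x, y):
    """Maximum covariance over all joint tables with the observed margins."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = x.size
    mx = int(x.max())
    my = int(y.max())
    fx = np.bincount(x, minlength=mx + 1)
    fy = np.bincount(y, minlength=my + 1)
    best = -np.inf
    for table in _enumerate_tables(list(fx), list(fy)):
        exy = sum(
            t * a * b
            for a, row in enumerate(table)
            for b, t in enumerate(row)
        ) / n
        best = max(best, exy - x.mean() * y.mean())
    return best


def brute_coef_h(values):
    """H_ij, H_i and H from first principles with enumerated covmax."""
    values = np.asarray(values)
    n, k = values.shape
    cov = np.zeros((k, k))
    cmx = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            x, y = values[:, i], values[:, j]
            cov[i, j] = (x * y).mean() - x.mean() * y.mean()
            cmx[i, j] = brute_covmax(x, y)
    off = ~np.eye(k, dtype=bool)
    hij = np.full((k, k), np.nan)
    hij[off] = cov[off] / cmx[off]
    hi = (cov * off).sum(axis=1) / (cmx * off).sum(axis=1)
    iu = np.triu_indices(k, 1)
    h = cov[iu].sum() / cmx[iu].sum()
    return hij, hi, h
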