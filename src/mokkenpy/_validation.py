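"""Input coercion shared by all estimators and functions."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import DataError, ItemResponseMatrix, listwise_complete


def as_score_matrix(X, min_items: int = 2):
    """Coerce input to a complete, zero-based integer score matrix.

    Accepts an :class:`~mokkenpy.data.ItemResponseMatrix`, a pandas DataFrame
    or any 2-D array-like of integer scores.  Missing entries are removed
    listwise; each item's scores are shifted so their minimum is 0.

    Returns
    -------
    values : ndarray of int64, shape (N, k)
    labels : list of str
    """
    if isinstance(X, ItemResponseMatrix):
        irm = X
    elif isinstance(X, pd.DataFrame):
        irm = ItemResponseMatrix.from_dataframe(X)
    else:
        arr = np.asarray(X)
        if arr.ndim != 2:
            raise DataError("expected a 2-D respondents x items matrix")
        labels = [f"item{j + 1}" for j in range(arr.shape[1])]
        mask = None
        if np.issubdtype(arr.dtype, np.floating):
            mask = ~np.isfinite(arr)
        irm = ItemResponseMatrix(
            values=np.where(mask, 0, arr) if mask is not None else arr,
            item_labels=labels,
            missing_mask=mask,
        )
    if not irm.is_complete:
        irm = listwise_complete(irm)
    irm = irm.normalized()
    if irm.n_items < min_items:
        raise DataError(f"need at least {min_items} items, got {irm.n_items}")
    return irm.values, list(irm.item_labels)
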