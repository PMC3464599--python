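"""Item-response data model: validation, recoding and delimited-file I/O.

The universal input for every analysis in this package is a rectangular
respondents x items matrix of small non-negative integer category scores
(0..m per item), with an optional missing-value mask.  All coefficient and
diagnostic routines operate on complete rectangles, so missing responses are
removed listwise (:func:`listwise_complete`) before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemResponseMatrix",
    "RecodeMap",
    "load_matrix",
    "save_matrix",
    "recode",
    "listwise_complete",
]


class DataError(ValueError):
    """Structural problem with item-response data."""


@dataclass
class ItemResponseMatrix:
    """N x k matrix of integer category scores with missing-value handling.

    Parameters
    ----------
    values : ndarray of int, shape (N, k)
        Category scores.  Entries under ``missing_mask`` are ignored.
    item_labels : list of str
        Unique short item names (column headers).
    missing_mask : ndarray of bool, shape (N, k), optional
        True where the response is missing.
    """

    values: np.ndarray
    item_labels: list[str]
    missing_mask: np.ndarray | None = None
    score_offsets: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise DataError("item response data must be 2-dimensional")
        n, k = self.values.shape
        if n < 1:
            raise DataError("need at least one respondent")
        if k < 2:
            raise DataError(f"need at least 2 items, got {k}")
        self.item_labels = [str(lab) for lab in self.item_labels]
        if len(self.item_labels) != k:
            raise DataError("number of item labels must match number of columns")
        if len(set(self.item_labels)) != k:
            dup = sorted({x for x in self.item_labels if self.item_labels.count(x) > 1})
            raise DataError(f"duplicate item labels: {dup}")
        if self.missing_mask is None:
            self.missing_mask = np.zeros((n, k), dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != (n, k):
                raise DataError("missing_mask shape must match values")
        if not np.issubdtype(self.values.dtype, np.integer):
            vals = np.asarray(self.values, dtype=float)
            obs = vals[~self.missing_mask]
            if not np.all(np.isfinite(obs)) or not np.all(obs == np.round(obs)):
                raise DataError("non-integer category score encountered")
            filled = np.where(self.missing_mask, 0, vals)
            self.values = np.round(filled).astype(np.int64)
        else:
            self.values = self.values.astype(np.int64)
        obs = self.values[~self.missing_mask]
        if obs.size and obs.min() < 0:
            raise DataError("negative category score encountered")

    # ------------------------------------------------------------------
    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def n_categories(self) -> np.ndarray:
        """Per-item number of categories m+1, from the observed score range."""
        out = np.empty(self.n_items, dtype=int)
        for j in range(self.n_items):
            col = self.values[~self.missing_mask[:, j], j]
            out[j] = int(col.max()) + 1 if col.size else 1
        return out

    @property
    def is_complete(self) -> bool:
        return not bool(self.missing_mask.any())

    def to_dataframe(self, missing_code: str = "NA") -> pd.DataFrame:
        df = pd.DataFrame(self.values.astype(object), columns=self.item_labels)
        df = df.mask(self.missing_mask, missing_code)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ItemResponseMatrix":
        mask = df.isna().to_numpy()
        values = df.fillna(0).to_numpy()
        return cls(values=values, item_labels=list(df.columns), missing_mask=mask)

    def normalized(self) -> "ItemResponseMatrix":
        """Shift each item's scores so the observed minimum is 0.

        The per-item shifts are recorded in ``score_offsets``.  Scalability,
        monotonicity and IIO statistics are invariant to these shifts; a
        single 0..m convention removes ambiguity in restscores and tables.
        """
        offsets = np.zeros(self.n_items, dtype=np.int64)
        vals = self.values.copy()
        for j in range(self.n_items):
            col = vals[~self.missing_mask[:, j], j]
            if col.size:
                offsets[j] = col.min()
                vals[~self.missing_mask[:, j], j] = col - offsets[j]
        return ItemResponseMatrix(
            values=vals,
            item_labels=list(self.item_labels),
            missing_mask=self.missing_mask.copy(),
            score_offsets=offsets,
        )


@dataclass
class RecodeMap:
    """Per-item mapping from observed codes to analysis scores.

    ``mapping`` maps an item label to a ``{observed_code: score}`` dict; the
    optional ``default`` dict applies to items not listed.  Each map's image
    must be consecutive integers starting at 0 (scores 0..m).
    """

    mapping: Mapping[str, Mapping[int, int]] = field(default_factory=dict)
    default: Mapping[int, int] | None = None

    def __post_init__(self) -> None:
        for label, m in list(self.mapping.items()) + (
            [("<default>", self.default)] if self.default is not None else []
        ):
            scores = sorted(set(int(v) for v in m.values()))
            if scores != list(range(len(scores))):
                raise DataError(
                    f"recode map for {label!r} must map onto consecutive scores "
                    f"0..m, got image {scores}"
                )

    def map_for(self, label: str) -> Mapping[int, int] | None:
        if label in self.mapping:
            return self.mapping[label]
        return self.default


# GHQ "traditional" screening dichotomization of 1..4 Likert responses.
GHQ_TRADITIONAL = {1: 0, 2: 0, 3: 1, 4: 1}


def load_matrix(
    path,
    missing_code: str = "NA",
    delimiter: str = ",",
) -> ItemResponseMatrix:
    """Read a headered delimited file of integer category scores.

    Cells equal to ``missing_code`` become missing; any other non-integer
    cell raises a parse error naming its row and column.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
    labels = [tok.strip() for tok in header.split(delimiter)]
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise DataError(f"{path}: duplicate header labels {dup}")
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    if df.shape[1] < 2:
        raise DataError(f"{path}: need at least 2 item columns, got {df.shape[1]}")
    df.columns = labels
    n, k = df.shape
    values = np.zeros((n, k), dtype=np.int64)
    mask = np.zeros((n, k), dtype=bool)
    for j, col in enumerate(df.columns):
        raw = df[col].astype(str).str.strip()
        is_missing = (raw == missing_code) | df[col].isna()
        mask[:, j] = is_missing.to_numpy()
        for i, cell in enumerate(raw):
            if mask[i, j]:
                continue
            try:
                values[i, j] = int(cell)
            except ValueError as exc:
                raise DataError(
                    f"{path}: non-integer value {cell!r} at row {i + 1}, "
                    f"column {labels[j]!r}"
                ) from exc
    return ItemResponseMatrix(values=values, item_labels=labels, missing_mask=mask)


def save_matrix(
    data: ItemResponseMatrix,
    path,
    missing_code: str = "NA",
    delimiter: str = ",",
) -> None:
    """Write the matrix back in the same dialect (round-trip safe)."""
    data.to_dataframe(missing_code).to_csv(path, sep=delimiter, index=False)


def recode(data: ItemResponseMatrix, recode_map: RecodeMap) -> ItemResponseMatrix:
    """Apply per-item code-to-score maps; missing entries are unchanged.

    Every observed non-missing code of a mapped item must appear in its map;
    unmapped codes raise an error listing the offenders.
    """
    values = data.values.copy()
    for j, label in enumerate(data.item_labels):
        m = recode_map.map_for(label)
        if m is None:
            continue
        col = data.values[:, j]
        observed = ~data.missing_mask[:, j]
        codes = {int(c) for c in col[observed]}
        missing_codes = sorted(codes - {int(c) for c in m})
        if missing_codes:
            raise DataError(
                f"item {label!r}: codes {missing_codes} not present in recode map"
            )
        lut = {int(c): int(v) for c, v in m.items()}
        values[observed, j] = np.array([lut[int(c)] for c in col[observed]])
    return ItemResponseMatrix(
        values=values,
        item_labels=list(data.item_labels),
        missing_mask=data.missing_mask.copy(),
    )


def listwise_complete(data: ItemResponseMatrix) -> ItemResponseMatrix:
    """Drop every respondent with at least one missing entry."""
    keep = ~data.missing_mask.any(axis=1)
    if not keep.any():
        raise DataError("listwise deletion removed every respondent")
    return ItemResponseMatrix(
        values=data.values[keep],
        item_labels=list(data.item_labels),
        missing_mask=data.missing_mask[keep],
    )
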