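"""Fixed-width text and TSV rendering of analysis reports.

Zero counts are always printed as zeros (never blanks), and removed items
in an item-selection trace print as ``NA``.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .iio import IIOReport
from .monotonicity import MonotonicityReport
from .reliability import ReliabilityResult
from .scalability import ScalabilityResult
from .selection import ScalePartition

__all__ = ["render_table", "to_tsv", "to_json_summary"]


def _frame_text(df: pd.DataFrame, float_fmt: str = "%.2f") -> str:
    return df.to_string(
        index=False,
        float_format=lambda x: float_fmt % x,
        na_rep="NA",
    )


def render_table(result, style: str = "text") -> str:
    """Render a module report as fixed-width text or TSV."""
    if style not in {"text", "tsv"}:
        raise ValueError(f"unknown style {style!r}")
    if isinstance(result, ScalabilityResult):
        df = result.to_frame()
        body = _to_style(df, style)
        return body + f"\nScale H = {result.h:.2f} ({result.classification})"
    if isinstance(result, MonotonicityReport):
        return _to_style(result.to_frame(), style)
    if isinstance(result, IIOReport):
        parts = [_to_style(result.to_frame(), style)]
        if result.removal_trace is not None:
            trace = result.removal_trace.reset_index(names="Label")
            parts.append("")
            parts.append(_to_style(trace, style))
        if result.ht_final is not None:
            parts.append(
                f"HT (final item set) = {result.ht_final:.2f} "
                f"({result.ht_classification})"
            )
        return "\n".join(parts)
    if isinstance(result, ScalePartition):
        parts = []
        for sid, scale in enumerate(result.scales, start=1):
            parts.append(f"Scale {sid}:")
            parts.append(_to_style(scale.to_frame(), style))
            parts.append(f"Scale H = {scale.h:.2f} ({scale.classification})")
            parts.append("")
        unscalable = result.items_in_scale(0)
        parts.append(f"Unscalable items: {unscalable if unscalable else 'none'}")
        return "\n".join(parts)
    if isinstance(result, ReliabilityResult):
        lines = [
            f"MS Rho          = {result.rho_ms:.3f}",
            f"Cronbach alpha  = {result.cronbach_alpha:.3f}",
        ]
        for note in result.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)
    if isinstance(result, pd.DataFrame):
        return _to_style(result, style)
    raise TypeError(f"cannot render {type(result).__name__}")


def _to_style(df: pd.DataFrame, style: str) -> str:
    if style == "tsv":
        return df.to_csv(sep="\t", index=False, na_rep="NA").rstrip("\n")
    return _frame_text(df)


def to_tsv(result) -> str:
    return render_table(result, style="tsv")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def to_json_summary(payload: dict) -> str:
    """Machine-readable JSON for any mixture of report quantities."""
    return json.dumps(_jsonable(payload), indent=2)
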