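"""Derived white-matter FA predictors from per-subject ROI tables.

Consumes a subjects x 48 table of mean fractional anisotropy (FA) values, one
column per JHU atlas tract, and derives the two scalar predictors used in the
univariate analyses:

* global FA — the weighted average of the 48 ROI means.  The per-ROI weights
  (typically skeleton voxel counts) are optional; with none supplied every ROI
  weighs equally.
* callosal FA — the arithmetic mean of the genu, body and splenium of the
  corpus callosum.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .atlas import CALLOSAL_LABELS, JHU_LABELS, normalize_label, validate_labels

__all__ = [
    "validate_roi_table",
    "global_mean_fa",
    "callosal_fa",
    "derive_fa",
]


def validate_roi_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a subjects x ROI FA table against the 48-label atlas.

    Column names are whitespace-normalized and checked for exact coverage of
    the atlas; FA values must lie strictly inside (0, 1).  Returns a copy with
    normalized column names, columns in canonical atlas order.
    """
    normalized = validate_labels(df.columns)
    out = df.copy()
    out.columns = normalized
    out = out[list(JHU_LABELS)]
    values = out.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = out.columns[np.isnan(values).any(axis=0)].tolist()
        raise ValueError(f"missing FA values in ROI columns: {bad}")
    if (values <= 0).any() or (values >= 1).any():
        raise ValueError("FA values must lie strictly in (0, 1)")
    return out


def _row_values(row: Mapping[str, float], labels: Sequence[str]) -> np.ndarray:
    lookup = {normalize_label(k): v for k, v in dict(row).items()}
    values = []
    for label in labels:
        if label not in lookup or pd.isna(lookup[label]):
            raise KeyError(f"missing FA value for ROI {label!r}")
        values.append(float(lookup[label]))
    return np.asarray(values)


def global_mean_fa(row: Mapping[str, float], weights: Optional[Mapping[str, float]] = None) -> float:
    """Weighted mean FA over the 48 ROIs; equal weights when none supplied."""
    values = _row_values(row, JHU_LABELS)
    if weights is None:
        w = np.ones_like(values)
    else:
        w = _row_values(weights, JHU_LABELS)
        if (w <= 0).any():
            raise ValueError("ROI weights must be positive")
    return float(np.dot(w, values) / w.sum())


def callosal_fa(row: Mapping[str, float]) -> float:
    """Mean FA of the three callosal segments (genu + body + splenium)/3."""
    values = _row_values(row, CALLOSAL_LABELS)
    return float(values.mean())


def derive_fa(df: pd.DataFrame, weights: Optional[Mapping[str, float]] = None) -> pd.DataFrame:
    """Per-subject global and callosal FA for a validated ROI table."""
    table = validate_roi_table(df)
    if weights is None:
        w = np.ones(len(JHU_LABELS))
    else:
        w = _row_values(weights, JHU_LABELS)
        if (w <= 0).any():
            raise ValueError("ROI weights must be positive")
    values = table.to_numpy(dtype=float)
    global_fa = values @ w / w.sum()
    callosal = values[:, [list(JHU_LABELS).index(c) for c in CALLOSAL_LABELS]].mean(axis=1)
    return pd.DataFrame(
        {"global_fa": global_fa, "callosal_fa": callosal}, index=table.index
    )
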