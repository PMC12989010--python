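"""CSV reading/writing for facet and condition tables.

Dialect: comma-separated, UTF-8, header row required.  A participant-ID
first column is optional and auto-detected: if the first column cannot be
parsed as numbers it is treated as the participant index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import validate_facets

__all__ = ["read_facet_csv", "read_condition_csv", "write_matrix_csv"]


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, header=0)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"{path}: empty table")
    first = df.columns[0]
    try:
        pd.to_numeric(df[first])
    except (ValueError, TypeError):
        df = df.set_index(first)
        df.index = df.index.astype(str)
    else:
        df.index = pd.Index([f"P{i + 1:04d}" for i in range(len(df))])
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric cell in data columns ({exc})") from exc
    df.columns = [str(c) for c in df.columns]
    return df


def read_facet_csv(path) -> pd.DataFrame:
    """Load and validate an n x p facet-score table (complete, labeled, p>=3)."""
    df = _read_table(path)
    validate_facets(df)
    lo, hi = df.to_numpy().min(), df.to_numpy().max()
    if lo < 0 or hi > 3:
        raise ValueError(f"{path}: facet scores must lie in [0, 3] (found [{lo}, {hi}])")
    return df


def read_condition_csv(path, n_expected: int | None = None) -> pd.DataFrame:
    """Load an n x q condition severity table; missing cells are allowed."""
    df = _read_table(path)
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate condition labels")
    if n_expected is not None and len(df) != n_expected:
        raise ValueError(
            f"{path}: {len(df)} rows but the facet table has {n_expected}"
        )
    return df


def write_matrix_csv(df: pd.DataFrame, path, index_label: str = "participant_id") -> None:
    df.to_csv(path, index=True, index_label=index_label)
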