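"""Delimited-text I/O and descriptive reporting for response matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DataError
from .model import MISSING, ResponseMatrix

__all__ = ["read_responses", "write_responses", "descriptives_report"]


def read_responses(
    path,
    missing_token: str = "NA",
    category_counts=None,
    delimiter: str = ",",
) -> ResponseMatrix:
    """Read a persons x items matrix of integer categories from CSV/TSV.

    One header row of item labels is required; cells are integer categories
    or the ``missing_token``.  Category counts are inferred from the data
    maximum per item unless supplied (supply them when the top category
    may be unobserved).
    """
    df = pd.read_csv(
        path, sep=delimiter, na_values=[missing_token], keep_default_na=False,
        dtype=str, skipinitialspace=True,
    )
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise DataError(f"{path}: empty response table")
    values = np.full(df.shape, MISSING, dtype=int)
    for j, col in enumerate(df.columns):
        raw = df[col]
        present = raw.notna() & (raw.astype(str).str.strip() != "")
        try:
            values[present.to_numpy(), j] = raw[present].astype(int).to_numpy()
        except (ValueError, TypeError) as exc:
            bad = raw[present][~raw[present].str.fullmatch(r"-?\d+")]
            row = bad.index[0] if len(bad) else "?"
            raise DataError(
                f"{path}: non-integer cell at row {row}, column '{col}'"
            ) from exc
    if category_counts is None:
        category_counts = values.max(axis=0) + 1
    return ResponseMatrix(
        values=values,
        item_labels=list(df.columns),
        category_counts=np.asarray(category_counts, dtype=int),
    )


def write_responses(data: ResponseMatrix, path, missing_token: str = "NA"):
    """Write a response matrix back to CSV (inverse of :func:`read_responses`)."""
    df = pd.DataFrame(data.values, columns=data.item_labels).astype(object)
    df[df == MISSING] = missing_token
    df.to_csv(path, index=False)


def descriptives_report(data: ResponseMatrix, percent: bool = True) -> pd.DataFrame:
    """Per-item mean, sample SD and relative category frequencies.

    Frequencies are in percent by default; SD uses the n-1 convention.
    """
    rows = []
    for i, label in enumerate(data.item_labels):
        x = data.values[:, i]
        x = x[x != MISSING]
        c = int(data.category_counts[i])
        freqs = np.bincount(x, minlength=c) / x.size
        if percent:
            freqs = 100.0 * freqs
        rows.append(
            {
                "item": label,
                "M": float(x.mean()),
                "SD": float(x.std(ddof=1)) if x.size > 1 else 0.0,
                **{str(k): freqs[k] for k in range(c)},
            }
        )
    return pd.DataFrame(rows).set_index("item")
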