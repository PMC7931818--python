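"""Reading and writing expression and fraction tables.

All on-disk tables are UTF-8, tab-separated. An expression table has a
header row with one label per data column (nothing over the gene column)
and one gene symbol per subsequent row; a fraction table is samples x
cell types with a leading sample-id column. In memory both are plain
:class:`pandas.DataFrame` objects — genes (or samples) on the index,
labels on the columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTableError",
    "DuplicateGeneError",
    "read_expression_table",
    "write_expression_table",
    "read_fraction_table",
    "write_fraction_table",
    "validate_expression",
]

_COLLAPSE_STRATEGIES = ("max_mean", "sum", "error")

FRACTION_SUM_TOL = 1e-9


class ExpressionTableError(ValueError):
    """Malformed or invalid expression table."""


class DuplicateGeneError(ExpressionTableError):
    """Duplicate gene symbols encountered with collapse strategy 'error'."""


def validate_expression(df: pd.DataFrame, name: str = "matrix") -> pd.DataFrame:
    """Check the invariants every expression matrix must satisfy.

    Values must be finite and non-negative; gene and column labels must
    be unique and non-empty. Returns *df* unchanged so the call can be
    inlined.
    """
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ExpressionTableError(f"{name}: empty expression matrix")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateGeneError(f"{name}: duplicate gene symbols {dupes[:5]}")
    if df.columns.duplicated().any():
        raise ExpressionTableError(f"{name}: duplicate column labels")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ExpressionTableError(f"{name}: non-numeric values present")
    if not np.isfinite(values).all():
        raise ExpressionTableError(f"{name}: non-finite values present")
    if (values < 0).any():
        raise ExpressionTableError(f"{name}: negative expression values present")
    return df


def _collapse_duplicates(df: pd.DataFrame, strategy: str, path) -> pd.DataFrame:
    if not df.index.duplicated().any():
        return df
    if strategy == "error":
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateGeneError(f"{path}: duplicate gene symbols {dupes[:5]}")
    if strategy == "sum":
        # groupby(sort=False) keeps first-appearance order
        return df.groupby(level=0, sort=False).sum()
    # max_mean: keep, per symbol, the row with the highest mean expression
    means = df.mean(axis=1).to_numpy()
    keep = (
        pd.Series(means)
        .groupby(df.index.to_numpy(), sort=False)
        .idxmax()
        .to_numpy()
    )
    return df.iloc[np.sort(keep)]


def read_expression_table(
    path, collapse_strategy: str = "max_mean"
) -> pd.DataFrame:
    """Read a tab-separated genes x columns expression table.

    Parameters
    ----------
    path
        File to read. First row: column labels. Each following row:
        gene symbol, then one non-negative number per column.
    collapse_strategy
        How to resolve duplicate gene symbols: ``"max_mean"`` keeps the
        duplicate row with the highest row mean, ``"sum"`` adds the
        duplicate rows (appropriate for transcript-level counts), and
        ``"error"`` aborts.
    """
    if collapse_strategy not in _COLLAPSE_STRATEGIES:
        raise ValueError(
            f"collapse_strategy must be one of {_COLLAPSE_STRATEGIES}, "
            f"got {collapse_strategy!r}"
        )
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap parser failures uniformly
        raise ExpressionTableError(f"{path}: cannot parse table: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ExpressionTableError(f"{path}: table has no data rows or columns")
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +header +1-based
        elif converted.isna().any():
            line = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 2
        else:
            line = None
        if line is not None:
            raise ExpressionTableError(
                f"{path}: malformed or missing number in column {col!r}, line {line}"
            )
        numeric[col] = converted.astype(float)
    if (numeric.to_numpy() < 0).any():
        gene = numeric.index[(numeric < 0).any(axis=1)][0]
        raise ExpressionTableError(f"{path}: negative value for gene {gene!r}")
    numeric = _collapse_duplicates(numeric, collapse_strategy, path)
    return validate_expression(numeric, name=str(path))


def write_expression_table(df: pd.DataFrame, path) -> None:
    """Write an expression matrix so that :func:`read_expression_table`
    recovers it exactly (values kept to full double precision)."""
    validate_expression(df, name="matrix to write")
    df.to_csv(path, sep="\t", index_label=False, float_format="%.12g")


def write_fraction_table(fractions: pd.DataFrame, path) -> None:
    """Write a samples x cell-types fraction table.

    Every fraction must lie in [0, 1] and each sample's row must sum to
    1 within ``FRACTION_SUM_TOL``; violations refuse the write rather
    than silently emitting an invalid table.
    """
    values = fractions.to_numpy(dtype=float)
    if ((values < 0) | (values > 1)).any():
        raise ValueError("fraction table contains values outside [0, 1]")
    sums = values.sum(axis=1)
    off = np.abs(sums - 1.0) > FRACTION_SUM_TOL
    if off.any():
        sample = fractions.index[np.flatnonzero(off)[0]]
        raise ValueError(
            f"fractions for sample {sample!r} sum to {sums[off][0]:.6g}, not 1"
        )
    fractions.to_csv(path, sep="\t", index_label=False, float_format="%.12g")


def read_fraction_table(path) -> pd.DataFrame:
    """Read a fraction table written by :func:`write_fraction_table`."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0).astype(float)
    return df
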