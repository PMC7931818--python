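"""Making reference and mixture matrices comparable.

Three steps, in fixed order: intersect the gene sets, drop genes with no
detected expression in any reference cell type, and quantile normalize
both matrices to a common target distribution. The target is the
mean-of-sorted-columns of the reference matrix *before* normalization,
so every column of both matrices ends up following the reference's own
starting distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TargetDistribution",
    "intersect_genes",
    "drop_unexpressed_reference_genes",
    "quantile_normalize_pair",
    "quantile_normalize_to_target",
]


@dataclass(frozen=True)
class TargetDistribution:
    """Sorted vector of quantile values shared by all normalized columns."""

    sorted_values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.sorted_values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("target distribution needs >= 2 values")
        if (np.diff(v) < 0).any():
            raise ValueError("target distribution must be non-decreasing")
        if (v < 0).any():
            raise ValueError("target distribution must be non-negative")
        object.__setattr__(self, "sorted_values", v)

    def __len__(self) -> int:
        return len(self.sorted_values)


def intersect_genes(
    ref: pd.DataFrame, mix: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to their shared genes, in a common order.

    The order is the reference's gene order restricted to the shared
    set, so the operation is deterministic.
    """
    shared = ref.index[ref.index.isin(mix.index)]
    if len(shared) == 0:
        raise ValueError("reference and mixture share zero genes")
    return ref.loc[shared], mix.loc[shared]


def drop_unexpressed_reference_genes(
    ref: pd.DataFrame, mix: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove genes whose reference row is all zeros from both matrices.

    Such genes carry no information about cell-type composition: the
    mixing model cannot attribute their mixture signal to any reference
    profile.
    """
    if not ref.index.equals(mix.index):
        raise ValueError("matrices must be gene-aligned")
    expressed = (ref.to_numpy() > 0).any(axis=1)
    if not expressed.any():
        raise ValueError("every gene is unexpressed in the reference")
    return ref.loc[expressed], mix.loc[expressed]


def _normalize_column(col: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Map one column onto the target distribution, rank-preservingly.

    Ties receive the mean of the target values at the tied ranks, which
    makes the result independent of the (stable) sort's ordering of
    equal values.
    """
    order = np.argsort(col, kind="stable")
    out = np.empty_like(target)
    out[order] = target
    # average target values over groups of equal input values
    return pd.Series(out).groupby(col, sort=False).transform("mean").to_numpy()


def quantile_normalize_to_target(
    df: pd.DataFrame, target: TargetDistribution
) -> pd.DataFrame:
    """Quantile normalize every column of *df* onto *target*."""
    if df.shape[0] != len(target):
        raise ValueError(
            f"target length {len(target)} != gene count {df.shape[0]}"
        )
    tv = target.sorted_values
    out = np.column_stack(
        [_normalize_column(df[c].to_numpy(dtype=float), tv) for c in df.columns]
    )
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def quantile_normalize_pair(
    ref: pd.DataFrame, mix: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, TargetDistribution]:
    """Quantile normalize reference and mixture to the reference's
    starting distribution.

    The target is the mean across reference columns of each column's
    sorted values — the standard quantile-normalization target — taken
    from the reference before any normalization. Afterwards every
    column of both outputs, sorted, equals the target (exactly when
    there are no ties; with ties, tied entries share the mean of the
    tied target values).
    """
    if not ref.index.equals(mix.index):
        raise ValueError("matrices must be gene-aligned")
    if ref.shape[0] < 2:
        raise ValueError("quantile normalization needs >= 2 genes")
    target = TargetDistribution(np.sort(ref.to_numpy(dtype=float), axis=0).mean(axis=1))
    ref_qn = quantile_normalize_to_target(ref, target)
    mix_qn = quantile_normalize_to_target(mix, target)
    return ref_qn, mix_qn, target
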