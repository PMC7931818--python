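"""Building reference matrices from single-cell clusters and replicates.

Two averaging rules: single cells belonging to one cluster are mean-
averaged into a pseudo-bulk profile, and replicate bulk profiles of the
same cell type are collapsed by the per-gene median.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import validate_expression

__all__ = ["pseudobulk_from_clusters", "merge_replicates", "read_cluster_assignments"]


def read_cluster_assignments(path) -> pd.Series:
    """Read a two-column TSV (cell_id, cluster) into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "cluster"], dtype=str)
    if df["cell_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate cell ids in cluster assignments")
    return df.set_index("cell_id")["cluster"]


def pseudobulk_from_clusters(
    cells: pd.DataFrame,
    clusters: pd.Series | dict,
    normalize_totals: float | None = None,
) -> pd.DataFrame:
    """Mean-average single cells of each cluster into reference columns.

    Parameters
    ----------
    cells
        Dense cells x genes expression table (cell ids on the index).
    clusters
        Cluster label per cell id; every cell in *cells* must be
        assigned, and every assigned cluster must have >= 1 cell.
    normalize_totals
        If given, rescale each cell to this total expression before
        averaging (off by default: plain averaging of raw values).

    Returns a genes x clusters expression matrix.
    """
    clusters = pd.Series(clusters, dtype=str)
    missing = cells.index[~cells.index.isin(clusters.index)]
    if len(missing) > 0:
        raise ValueError(f"cells without cluster assignment: {list(missing[:5])}")
    labels = clusters.loc[cells.index]
    empty = clusters[~clusters.isin(labels)].unique()
    if len(empty) > 0:
        raise ValueError(f"cluster(s) with no member cells: {sorted(empty)}")
    values = cells.astype(float)
    if normalize_totals is not None:
        totals = values.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("cannot normalize a cell with zero total expression")
        values = values.div(totals, axis=0) * float(normalize_totals)
    profile = values.groupby(labels.to_numpy(), sort=True).mean().T
    profile.index.name = None
    return validate_expression(profile, name="pseudobulk reference")


def merge_replicates(profiles: pd.DataFrame, groups: pd.Series | dict) -> pd.DataFrame:
    """Collapse replicate columns into one per group via per-gene median.

    Even-sized groups use the midpoint of the two central values. A
    single-member group passes through unchanged.
    """
    groups = pd.Series(groups, dtype=str)
    missing = profiles.columns[~profiles.columns.isin(groups.index)]
    if len(missing) > 0:
        raise ValueError(f"columns without group label: {list(missing[:5])}")
    labels = groups.loc[profiles.columns].to_numpy()
    merged = profiles.astype(float).T.groupby(labels, sort=True).median().T
    merged.index.name = None
    return validate_expression(merged, name="merged reference")
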