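"""Signature-gene scoring and selection.

A signature gene is one whose expression across the reference cell
types is strongly concentrated in a single type. Genes are scored
(by default with Shannon entropy of the normalized expression vector,
in bits), assigned to the cell type in which they are maximally
expressed, and the best-scoring genes per cell type are selected under
a per-type budget with an optional global fill.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SCORING_METHODS

__all__ = [
    "SignatureSet",
    "filter_majority_zero_genes",
    "impute_zero_expression",
    "entropy_score",
    "score_genes",
    "select_signatures",
    "write_signature_table",
]


def filter_majority_zero_genes(ref: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with zero expression in half or more of the cell types.

    Exact zeros usually reflect detection limits rather than true
    absence; a gene that is "off" in most columns can score as highly
    specific purely through resolution artifacts. The boundary is
    inclusive: with K columns, a gene with exactly K/2 zeros is removed.
    """
    K = ref.shape[1]
    if K < 2:
        raise ValueError("need >= 2 reference cell types")
    zeros = (ref.to_numpy() == 0).sum(axis=1)
    return ref.loc[2 * zeros < K]


def impute_zero_expression(ref: pd.DataFrame) -> pd.DataFrame:
    """Replace remaining zeros with the matrix's smallest nonzero value.

    This floor keeps genes with scattered zeros from achieving
    artificially extreme specificity scores while leaving measured
    values untouched.
    """
    values = ref.to_numpy(dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("cannot impute: matrix is entirely zero")
    floor = nonzero.min()
    if (values > 0).all():
        return ref
    return ref.mask(ref == 0, floor)


def entropy_score(expr) -> float:
    """Shannon entropy, in bits, of an expression vector over cell types.

    The vector is normalized to probabilities p_i = x_i / sum(x); the
    score is H = -sum p_i log2 p_i, bounded by [0, log2 K]. Low entropy
    means expression concentrated in few cell types — a good signature.
    """
    x = np.asarray(expr, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("entropy needs a vector over >= 2 cell types")
    if (x <= 0).any():
        raise ValueError("entropy requires strictly positive values (impute zeros first)")
    p = x / x.sum()
    return float(-(p * np.log2(p)).sum())


def _entropy_rows(values: np.ndarray) -> np.ndarray:
    p = values / values.sum(axis=1, keepdims=True)
    return -(p * np.log2(p)).sum(axis=1)


def score_genes(ref: pd.DataFrame, method: str = "entropy") -> pd.DataFrame:
    """Score every gene for cell-type specificity.

    Returns a table indexed by gene with columns:

    ``score``
        The method's raw score.
    ``best_cell_type``
        Column label where the gene is maximally expressed (first in
        column order on ties).
    ``tied``
        True when the maximum was tied between cell types.
    ``desirability``
        Unified sort key — smaller is better for every method (entropy
        ascends; all other scores are negated).

    The reference must already be zero-filtered and imputed; all values
    must be strictly positive.
    """
    method = str(method).lower()
    if method not in SCORING_METHODS:
        raise ValueError(f"unknown scoring method {method!r}")
    values = ref.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("scoring requires strictly positive values (impute zeros first)")
    K = values.shape[1]
    if K < 2:
        raise ValueError("need >= 2 reference cell types")

    order = np.sort(values, axis=1)
    top, second = order[:, -1], order[:, -2]
    if method == "entropy":
        score = _entropy_rows(values)
    elif method == "meanrat":
        others = (values.sum(axis=1) - top) / (K - 1)
        score = top / others
    elif method == "meandiff":
        others = (values.sum(axis=1) - top) / (K - 1)
        score = top - others
    elif method == "zscore":
        sd = values.std(axis=1, ddof=0)
        sd = np.where(sd == 0, np.inf, sd)  # constant rows: no specificity
        score = (top - values.mean(axis=1)) / sd
    elif method == "fsrat":
        score = top / second
    else:  # fsdiff
        score = top - second

    argmax = values.argmax(axis=1)  # first tied column wins
    tied = (values == top[:, None]).sum(axis=1) > 1
    desirability = score if method == "entropy" else -score
    return pd.DataFrame(
        {
            "score": score,
            "best_cell_type": ref.columns.to_numpy()[argmax],
            "tied": tied,
            "desirability": desirability,
        },
        index=ref.index,
    ).assign(method=method)


@dataclass
class SignatureSet:
    """Selected signature genes grouped by their best cell type."""

    genes_by_cell_type: dict[str, list[str]]
    #: genes admitted by the global fill step outside their own type's quota
    fill_genes: list[str] = field(default_factory=list)

    @property
    def all_genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.genes_by_cell_type.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)

    def __len__(self) -> int:
        return len(self.all_genes)


def select_signatures(
    scores: pd.DataFrame,
    cell_types,
    num_sigs: int = 50,
    min_sigs: int | None = None,
) -> SignatureSet:
    """Select signature genes under the per-type / global-fill scheme.

    The total budget is ``num_sigs * K``. First every cell type receives
    its best ``min_sigs`` genes among those maximally expressed in it
    (fewer if it has fewer candidates, with a warning). When
    ``min_sigs < num_sigs`` the remaining budget is filled with the
    globally best-ranked unselected genes regardless of cell type; when
    ``min_sigs == num_sigs`` (the default) no fill occurs and selection
    is exactly per-type top-N. Ranking ties break on the gene symbol,
    so the selection is independent of input row order.
    """
    if len(scores) == 0:
        raise ValueError("no scored genes to select from")
    cell_types = list(cell_types)
    K = len(cell_types)
    if min_sigs is None:
        min_sigs = num_sigs
    budget = num_sigs * K
    if budget < K:
        raise ValueError("budget num_sigs * K is smaller than the number of cell types")

    # deterministic boundary ties: desirability, then gene symbol
    ranked = scores.assign(_gene=scores.index).sort_values(
        ["desirability", "_gene"], kind="stable"
    )

    chosen: dict[str, list[str]] = {ct: [] for ct in cell_types}
    selected: set[str] = set()
    for ct in cell_types:
        candidates = ranked[ranked["best_cell_type"] == ct]
        take = candidates.index[:min_sigs].tolist()
        if len(candidates) == 0:
            warnings.warn(f"cell type {ct!r} has no candidate signature genes")
        elif len(take) < min_sigs:
            warnings.warn(
                f"cell type {ct!r} has only {len(take)} candidate genes "
                f"(< min_sigs={min_sigs})"
            )
        chosen[ct] = take
        selected.update(take)

    fill: list[str] = []
    if min_sigs < num_sigs:
        remaining = budget - len(selected)
        if remaining > 0:
            pool = ranked.index[~ranked.index.isin(selected)]
            fill = pool[:remaining].tolist()
            for g in fill:
                chosen[ranked.loc[g, "best_cell_type"]].append(g)
            selected.update(fill)
    return SignatureSet(genes_by_cell_type=chosen, fill_genes=fill)


def write_signature_table(sig: SignatureSet, path) -> None:
    """Export a signature set as a two-column TSV (gene, cell type)."""
    rows = [
        (gene, ct)
        for ct, genes in sig.genes_by_cell_type.items()
        for gene in genes
    ]
    pd.DataFrame(rows, columns=["gene", "cell_type"]).to_csv(
        path, sep="\t", index=False
    )
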