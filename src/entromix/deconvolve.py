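"""Row scaling, non-negative regression, and the end-to-end pipeline.

The mixing model is linear: each bulk sample's expression vector is
approximately a non-negative combination of the reference cell-type
profiles, restricted to signature genes. Per-gene row scaling puts
genes of very different magnitudes on a comparable footing before the
fit, so a highly expressed gene cannot dominate the least-squares
objective. Coefficients are normalized to fractions summing to one and
are interpreted as fractions of mRNA, not of cells.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from . import preprocess, signatures
from .config import DeconvolutionConfig
from .signatures import SignatureSet

__all__ = [
    "RowScaleParams",
    "DeconvolutionDetails",
    "row_scale",
    "nnls_fit",
    "normalize_fractions",
    "deconvolve",
    "aggregate_subtypes",
    "combine_reference_predictions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RowScaleParams:
    """Per-gene min/max (over reference and mixture columns jointly) and
    the exponent used by the row-scaling transform."""

    min_val: pd.Series
    max_val: pd.Series
    p: float


def row_scale(
    ref_sig: pd.DataFrame, mix_sig: pd.DataFrame, p: float = 0.0
) -> tuple[pd.DataFrame, pd.DataFrame, RowScaleParams]:
    """Rescale each gene row of both matrices jointly.

    Every value is transformed as

        x_new = (x_old - Min) / (Max - Min) * Max**p

    where Min and Max are taken per gene over ALL columns of both
    matrices together. With p = 0 each row spans exactly [0, 1]; with
    p = 1 and Min = 0 the transform is the identity. Because Min/Max
    cover the whole submitted batch, a sample's scaled values (and thus
    its predictions) can depend on which other samples accompany it.

    Constant rows (Max == Min) carry no contrast and are mapped to
    all-zeros with a warning, preserving gene alignment.
    """
    if not ref_sig.index.equals(mix_sig.index):
        raise ValueError("matrices must be gene-aligned")
    if not 0.0 <= p <= 1.0:
        raise ValueError("row-scale exponent p must lie in [0, 1]")
    combined = np.hstack([ref_sig.to_numpy(dtype=float), mix_sig.to_numpy(dtype=float)])
    lo = combined.min(axis=1)
    hi = combined.max(axis=1)
    span = hi - lo
    constant = span == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene row(s) mapped to zeros during row scaling"
        )
    safe_span = np.where(constant, 1.0, span)
    scale = np.where(constant, 0.0, hi**p / safe_span)

    def _apply(df: pd.DataFrame) -> pd.DataFrame:
        out = (df.to_numpy(dtype=float) - lo[:, None]) * scale[:, None]
        return pd.DataFrame(out, index=df.index, columns=df.columns)

    params = RowScaleParams(
        min_val=pd.Series(lo, index=ref_sig.index),
        max_val=pd.Series(hi, index=ref_sig.index),
        p=p,
    )
    return _apply(ref_sig), _apply(mix_sig), params


def nnls_fit(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Exact non-negative least squares for one mixture column.

    Solves argmin_x ||A x - b||^2 subject to x >= 0 with no intercept
    and no regularization (active-set algorithm). Returns the
    coefficients, the residual norm, and a flag that is True when A is
    column-rank-deficient (the solution may then be non-unique).
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float).ravel()
    if A.ndim != 2 or A.shape[0] < 1 or A.shape[1] < 1:
        raise ValueError("design matrix must be 2-D and non-empty")
    if A.shape[0] != b.size:
        raise ValueError("design matrix and target share the gene dimension")
    coef, rnorm = scipy.optimize.nnls(A, b)
    deficient = np.linalg.matrix_rank(A) < A.shape[1]
    return coef, float(rnorm), bool(deficient)


def normalize_fractions(x) -> tuple[np.ndarray, bool]:
    """Turn non-negative coefficients into fractions summing to 1.

    A degenerate all-zero coefficient vector (nothing fit the sample)
    falls back to uniform fractions 1/K with a flag.
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("coefficients must be non-negative")
    total = x.sum()
    if total == 0:
        return np.full(x.size, 1.0 / x.size), True
    return x / total, False


@dataclass
class DeconvolutionDetails:
    """Per-run provenance: signature set, stage gene counts, and flags."""

    signature_set: SignatureSet
    gene_counts: dict[str, int]
    degenerate_samples: list[str] = field(default_factory=list)
    rank_deficient: bool = False
    residuals: pd.Series | None = None


def deconvolve(
    ref: pd.DataFrame,
    mix: pd.DataFrame,
    config: DeconvolutionConfig | None = None,
    return_details: bool = False,
):
    """Estimate cell-type mRNA fractions for every mixture column.

    Pipeline: intersect genes -> drop all-zero reference genes ->
    quantile normalize both matrices to the reference's starting
    distribution -> filter/impute/score the reference and select
    signature genes -> restrict both matrices to the signatures ->
    row scale -> per-sample non-negative least squares -> normalize
    coefficients to fractions.

    Returns a samples x cell-types :class:`pandas.DataFrame` whose rows
    sum to 1 (plus a :class:`DeconvolutionDetails` when
    ``return_details`` is true).
    """
    if config is None:
        config = DeconvolutionConfig()
    counts: dict[str, int] = {"input_ref": ref.shape[0], "input_mix": mix.shape[0]}

    ref, mix = preprocess.intersect_genes(ref, mix)
    counts["shared"] = ref.shape[0]
    if counts["shared"] < 2:
        raise ValueError("need >= 2 shared genes to deconvolve")
    if counts["shared"] < 50:
        warnings.warn(
            f"only {counts['shared']} genes shared between reference and mixture"
        )
    ref, mix = preprocess.drop_unexpressed_reference_genes(ref, mix)
    counts["expressed"] = ref.shape[0]
    ref_qn, mix_qn, _target = preprocess.quantile_normalize_pair(ref, mix)

    scoring_ref = signatures.filter_majority_zero_genes(ref_qn)
    counts["zero_filtered"] = scoring_ref.shape[0]
    if scoring_ref.shape[0] == 0:
        raise ValueError("no genes survive the majority-zero filter")
    scoring_ref = signatures.impute_zero_expression(scoring_ref)
    scores = signatures.score_genes(scoring_ref, config.sig_method)
    sig_set = signatures.select_signatures(
        scores, ref_qn.columns, config.num_sigs, config.min_sigs
    )
    if len(sig_set) == 0:
        raise ValueError("signature selection produced an empty set")
    counts["signatures"] = len(sig_set)
    logger.info(
        "gene counts: %s",
        " -> ".join(f"{k}={v}" for k, v in counts.items()),
    )

    sig_genes = pd.Index(sig_set.all_genes)
    ref_sig = ref_qn.loc[sig_genes]
    mix_sig = mix_qn.loc[sig_genes]
    ref_rs, mix_rs, _params = row_scale(ref_sig, mix_sig, config.row_scale_p)

    A = ref_rs.to_numpy(dtype=float)
    fractions = np.empty((mix_rs.shape[1], ref_rs.shape[1]))
    residuals = np.empty(mix_rs.shape[1])
    degenerate: list[str] = []
    deficient = False
    for j, sample in enumerate(mix_rs.columns):
        coef, rnorm, flag = nnls_fit(A, mix_rs[sample].to_numpy(dtype=float))
        deficient = deficient or flag
        frac, degen = normalize_fractions(coef)
        if degen:
            degenerate.append(str(sample))
        fractions[j] = frac
        residuals[j] = rnorm
    table = pd.DataFrame(fractions, index=mix_rs.columns, columns=ref_rs.columns)
    if return_details:
        details = DeconvolutionDetails(
            signature_set=sig_set,
            gene_counts=counts,
            degenerate_samples=degenerate,
            rank_deficient=deficient,
            residuals=pd.Series(residuals, index=table.index, name="rss"),
        )
        return table, details
    return table


def aggregate_subtypes(
    fractions: pd.DataFrame, subtype_map: dict[str, str]
) -> pd.DataFrame:
    """Sum fine-grained subtype fractions into parent cell types.

    Labels absent from *subtype_map* pass through unchanged; row sums
    are conserved exactly.
    """
    parents = [subtype_map.get(ct, ct) for ct in fractions.columns]
    out = fractions.T.groupby(pd.Index(parents, name=fractions.columns.name), sort=False).sum().T
    return out


def combine_reference_predictions(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Median-combine fraction tables from runs against different references.

    For each sample and cell type, the estimate is the median across
    the tables that contain that cell type (fewer than all, if a type
    is missing from some references); each sample's combined vector is
    then renormalized to sum to 1. Tables are aligned on the
    intersection of their sample sets.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 fraction tables to combine")
    samples = tables[0].index
    for t in tables[1:]:
        samples = samples[samples.isin(t.index)]
    if len(samples) == 0:
        raise ValueError("fraction tables share no samples")
    stacked = pd.concat(
        [t.loc[samples] for t in tables], keys=range(len(tables)), names=["table"]
    )
    median = stacked.groupby(level=1, sort=False).median()  # NaN-ignoring per cell type
    median = median.loc[samples]
    return median.div(median.sum(axis=1), axis=0)
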