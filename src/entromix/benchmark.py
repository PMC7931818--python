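"""Synthetic mixtures of known composition and accuracy metrics.

The simulator draws cell-type proportions uniformly from the simplex
(flat Dirichlet), blends reference columns accordingly, and optionally
applies multiplicative unit-mean noise. A companion generator produces
well-separated synthetic reference matrices, and a perturbation helper
emulates cross-platform differences through per-gene multiplicative
log-normal biases, so the deconvolution reference need not be the one
that generated the mixtures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DeconvolutionConfig
from .deconvolve import deconvolve

__all__ = [
    "MixtureTruth",
    "make_synthetic_reference",
    "simulate_mixtures",
    "perturb_reference",
    "mean_abs_error",
    "correlation_by_celltype",
    "parameter_sweep",
]


@dataclass
class MixtureTruth:
    """Known composition of a batch of simulated mixtures."""

    proportions: pd.DataFrame  # samples x all reference cell types, rows sum to 1
    reference_label: str
    n_celltypes: int
    seed: int

    def __post_init__(self) -> None:
        sums = self.proportions.to_numpy().sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("truth proportions must sum to 1 per sample")


def make_synthetic_reference(
    n_genes: int = 2000,
    n_celltypes: int = 10,
    marker_fraction: float = 0.5,
    marker_fold: float = 8.0,
    fold_sigma: float = 0.5,
    baseline_sigma: float = 1.0,
    profile_jitter: float = 0.2,
    seed: int = 0,
    label: str = "synthetic",
) -> pd.DataFrame:
    """Generate a well-separated synthetic purified-profile matrix.

    Each gene has a log-normal baseline level shared across cell types
    plus mild per-profile log-normal jitter. A ``marker_fraction`` of
    genes is assigned a preferred cell type and up-regulated there by a
    log-normal fold with median ``marker_fold``; the rest behave as
    housekeeping genes. Cell types are labelled ``{label}_ct00`` ...
    """
    if n_celltypes < 2:
        raise ValueError("need >= 2 cell types")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    cols = [f"{label}_ct{k:02d}" for k in range(n_celltypes)]
    base = rng.lognormal(mean=np.log(10.0), sigma=baseline_sigma, size=n_genes)
    expr = base[:, None] * rng.lognormal(
        mean=0.0, sigma=profile_jitter, size=(n_genes, n_celltypes)
    )
    is_marker = rng.random(n_genes) < marker_fraction
    marker_of = rng.integers(0, n_celltypes, size=n_genes)
    folds = rng.lognormal(mean=np.log(marker_fold), sigma=fold_sigma, size=n_genes)
    expr[np.arange(n_genes)[is_marker], marker_of[is_marker]] *= folds[is_marker]
    return pd.DataFrame(expr, index=genes, columns=cols)


def simulate_mixtures(
    ref: pd.DataFrame,
    n_mixtures: int,
    n_celltypes,
    seed: int = 0,
    noise_cv: float = 0.0,
) -> tuple[pd.DataFrame, MixtureTruth]:
    """Simulate bulk mixtures of known proportions from a reference.

    For each mixture, ``n_celltypes`` distinct cell types are drawn
    uniformly, proportions come from a flat Dirichlet over those types,
    and each gene's value is the proportion-weighted sum of the chosen
    reference columns. ``n_celltypes`` may also be a sequence of counts
    cycled over the mixtures (e.g. ``(4, 5, 6, 10)``), so a single
    batch can span several mixture complexities. If ``noise_cv > 0``
    every value is multiplied by an independent log-normal factor with
    unit mean and the given coefficient of variation. Fully
    reproducible from *seed*.
    """
    K = ref.shape[1]
    counts = (
        [int(n_celltypes)] * n_mixtures
        if np.isscalar(n_celltypes)
        else [int(c) for c in n_celltypes]
    )
    if any(not 1 <= c <= K for c in counts):
        raise ValueError(f"n_celltypes must be in [1, {K}]")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    props = np.zeros((n_mixtures, K))
    for i in range(n_mixtures):
        k = counts[i % len(counts)]
        chosen = rng.choice(K, size=k, replace=False)
        props[i, chosen] = rng.dirichlet(np.ones(k))
    values = ref.to_numpy(dtype=float) @ props.T
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        factors = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=values.shape)
        values = values * factors
    samples = [f"mix{i:04d}" for i in range(n_mixtures)]
    mixtures = pd.DataFrame(values, index=ref.index, columns=samples)
    truth = MixtureTruth(
        proportions=pd.DataFrame(props, index=samples, columns=ref.columns),
        reference_label=str(ref.columns[0]).rsplit("_", 1)[0],
        n_celltypes=max(counts),
        seed=seed,
    )
    return mixtures, truth


def perturb_reference(ref: pd.DataFrame, sigma: float = 0.3, seed: int = 0) -> pd.DataFrame:
    """Apply per-gene multiplicative log-normal biases to a reference.

    The same factor multiplies every column of a gene, mimicking
    platform- or batch-specific gene effects between the matrix that
    generated a mixture and the one used to deconvolve it.
    """
    rng = np.random.default_rng(seed)
    factors = rng.lognormal(mean=0.0, sigma=sigma, size=ref.shape[0])
    return ref.mul(factors, axis=0)


def _align(pred: pd.DataFrame, truth: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if set(pred.index) != set(truth.index):
        raise ValueError("prediction and truth cover different samples")
    pred = pred.loc[truth.index]
    all_types = truth.columns.union(pred.columns, sort=False)
    # cell types absent from the prediction score as 0
    return (
        pred.reindex(columns=all_types, fill_value=0.0),
        truth.reindex(columns=all_types, fill_value=0.0),
    )


def mean_abs_error(
    pred: pd.DataFrame, truth: MixtureTruth | pd.DataFrame
) -> tuple[pd.Series, float]:
    """Mean absolute error between predicted and true fractions.

    Returns the per-sample mean |predicted - true| over cell types and
    the overall mean over all (sample, cell type) pairs.
    """
    truth_df = truth.proportions if isinstance(truth, MixtureTruth) else truth
    pred, truth_df = _align(pred, truth_df)
    abs_err = (pred - truth_df).abs()
    per_sample = abs_err.mean(axis=1)
    per_sample.name = "mean_abs_error"
    return per_sample, float(abs_err.to_numpy().mean())


def correlation_by_celltype(
    pred: pd.DataFrame, truth: MixtureTruth | pd.DataFrame
) -> tuple[pd.Series, float]:
    """Pearson correlation of predicted vs true fractions.

    Computed per cell type across samples (NaN where fewer than 3
    samples or either vector is constant) and pooled over all
    (sample, cell type) pairs.
    """
    truth_df = truth.proportions if isinstance(truth, MixtureTruth) else truth
    pred, truth_df = _align(pred, truth_df)
    per_type = {}
    for ct in truth_df.columns:
        x, y = truth_df[ct].to_numpy(), pred[ct].to_numpy()
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            per_type[ct] = np.nan
        else:
            per_type[ct] = float(np.corrcoef(x, y)[0, 1])
    xs, ys = truth_df.to_numpy().ravel(), pred.to_numpy().ravel()
    if len(xs) < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
        overall = float("nan")
    else:
        overall = float(np.corrcoef(xs, ys)[0, 1])
    return pd.Series(per_type, name="pearson_r"), overall


def parameter_sweep(
    ref_gen: pd.DataFrame,
    ref_dec: pd.DataFrame,
    grid: dict[str, list],
    n_mixtures: int = 100,
    n_celltypes: int | None = None,
    seed: int = 0,
    noise_cv: float = 0.0,
) -> pd.DataFrame:
    """Evaluate deconvolution accuracy over a grid of configurations.

    Mixtures are simulated once from *ref_gen* (shared across the whole
    grid so configurations are compared on identical inputs) and
    deconvolved with *ref_dec*, which may be a perturbed or unrelated
    reference. *grid* maps :class:`DeconvolutionConfig` field names to
    lists of values; the sweep covers their Cartesian product. Returns
    a long-format table with one row per configuration and summary
    statistics of the per-sample error distribution.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    if n_celltypes is None:
        n_celltypes = ref_gen.shape[1]
    mixtures, truth = simulate_mixtures(
        ref_gen, n_mixtures, n_celltypes, seed=seed, noise_cv=noise_cv
    )
    keys = list(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = DeconvolutionConfig(**dict(zip(keys, combo)), seed=seed)
        pred = deconvolve(ref_dec, mixtures, cfg)
        per_sample, overall = mean_abs_error(pred, truth)
        _, r = correlation_by_celltype(pred, truth)
        rows.append(
            {
                **cfg.to_dict(),
                "n_mixtures": n_mixtures,
                "n_celltypes": n_celltypes,
                "noise_cv": noise_cv,
                "mean_error": overall,
                "median_error": float(per_sample.median()),
                "max_error": float(per_sample.max()),
                "pearson_r": r,
            }
        )
    return pd.DataFrame(rows)
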