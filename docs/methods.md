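# Methods

## Mixing model and scope

`entromix` models a bulk expression profile as a non-negative linear
combination of purified cell-type profiles: for sample j,
`m_j ≈ R f_j` with `f_j ≥ 0`, where R is the reference matrix restricted
to signature genes. The estimated `f_j`, normalized to sum to 1, is the
fraction of **mRNA** attributable to each cell type. No correction for
per-cell mRNA content is applied, so these are not cell-count
proportions; cell types with high transcriptional output are weighted
accordingly. The model assumes the reference panel spans the cell types
actually present — mRNA from an unrepresented type is redistributed
over the panel.

## Preprocessing

Reference and mixture are first restricted to their shared genes (gene
symbols matched case-sensitively after whitespace stripping; no alias
or cross-species mapping). Genes with zero expression in every
reference cell type are removed: the model cannot attribute their
signal. Both matrices are then quantile normalized to a common target
so that platform- and scale-differences between columns are removed
while within-column ranks are preserved.

The target distribution is operationalized as the mean of the sorted
columns of the reference matrix *before* normalization — the standard
quantile-normalization target, applied here so every column of both
matrices follows the reference's own starting distribution. Ties within
a column receive the mean of the target values at the tied ranks, which
makes the result deterministic and invariant to row permutations.
Normalization happens once, before signature reduction; it is not
re-applied to the reduced matrices.

A consequence worth knowing: quantile normalization is exactly
rank-based, so predictions are invariant to any positive rescaling of a
mixture column (library-size effects vanish), but a *blend* of columns
that individually follow the target has a more concentrated empirical
distribution than the target itself, and normalization re-stretches it.
This produces a small systematic error floor (~0.01 mean absolute
error on noiseless synthetic mixtures) that is a property of the
pipeline, not of the solver; see "Accuracy floor" below.

## Signature gene scoring and selection

Scoring operates on the (normalized) reference only. Two safeguards
precede it: genes with zero expression in **half or more** of the K
cell types are excluded (boundary inclusive — exactly K/2 zeros removes
the gene), because exact zeros usually reflect detection limits and
make artificially extreme signatures; remaining zeros are floored at
the smallest nonzero value in the matrix. The floored values are used
for scoring only — the regression design matrix keeps the un-imputed
normalized values, since flooring is a scoring safeguard rather than a
measurement correction.

The default score is Shannon entropy in bits of the gene's expression
vector re-normalized to probabilities: `H = −Σ p_i log₂ p_i`,
`p_i = x_i / Σx`. H ranges from 0 (all expression in one cell type;
ideal signature) to log₂ K (perfectly uniform; useless). Entropy is
scale-invariant, so the choice of expression units does not matter.
The base affects only the scale, never the ranking.

Five alternative scores are provided under their conventional names;
their exact definitions are this package's documented conventions (the
names circulate without fixed formulas):

| method   | score (per gene)                         | better when |
|----------|------------------------------------------|-------------|
| entropy  | −Σ p_i log₂ p_i                          | lower       |
| meanrat  | max / mean of the other K−1 values       | higher      |
| meandiff | max − mean of the other K−1 values       | higher      |
| zscore   | (max − mean of all) / sd of all (ddof 0) | higher      |
| fsrat    | highest / second-highest                 | higher      |
| fsdiff   | highest − second-highest                 | higher      |

Each gene is assigned to the cell type where it is maximally expressed
(ties: first tied column in order, and the gene is flagged). Selection
has a total budget of `num_sigs × K` genes. Every cell type first
receives its best `min_sigs` genes among its own candidates; if
`min_sigs < num_sigs` the remaining budget is filled with the globally
best-ranked unselected genes regardless of cell type, letting types
with many sharp markers claim extra slots. With the default
`min_sigs = num_sigs` the fill step is empty and selection is per-type
top-N. The fill ranking uses the active scoring method's ordering (not
entropy unconditionally): mixing orderings from two different scores
would make the fill incoherent when a non-default method is chosen.
Score ties at a selection boundary break on the gene symbol, so the
selected set never depends on input row order.

Defaults: `sig_method=entropy`, `num_sigs=50`, `min_sigs=num_sigs`,
`row_scale_p=0`, chosen as the configuration that performed best in
large simulated-mixture tuning experiments of this design.

## Row scaling

Expression spans orders of magnitude, so without rescaling a single
highly expressed signature gene dominates the least-squares objective.
Each signature-gene row is transformed as

```
x_new = (x_old − Min) / (Max − Min) · Max^p
```

with Min and Max taken over **all** reference and mixture columns of
that gene jointly. `p = 0` (default) maps every row onto [0, 1] — the
strongest equalization; `p = 1` with Min = 0 is the identity; values in
between interpolate. Because Min/Max cover the whole submitted batch, a
sample's predictions can depend on which other samples were submitted
with it; the run manifest records the batch. Rows that are constant
across all columns (possible after normalization) are mapped to zeros
with a warning rather than dropped — a constant row contributes nothing
to the fit either way, and keeping it preserves gene alignment.

## Regression and normalization

Per sample, the exact non-negative least-squares problem
`argmin_x ‖Ax − b‖₂², x ≥ 0` is solved with the Lawson–Hanson
active-set algorithm (`scipy.optimize.nnls`) — no intercept, no
regularization. This matches a linear model constrained to non-negative
coefficients with zero penalty. Rank-deficient designs still return a
solution but are flagged as potentially non-unique. Coefficients are
divided by their sum; an all-zero solution (nothing in the panel fits)
falls back to uniform fractions 1/K with the sample flagged. Subtype
fractions can afterwards be summed into parent types (row sums are
conserved exactly), and predictions from several references can be
median-combined per cell type — using only the references containing
that type — then renormalized per sample.

## Reference construction

Pseudo-bulk profiles are arithmetic means over all cells of a cluster,
computed on raw values by default; an option rescales each cell to a
fixed total first, off by default because plain averaging is the
convention being reproduced. Replicate bulk profiles of one cell type
are collapsed by the per-gene median (even group sizes: midpoint of the
two central values). Duplicate gene symbols at read time are resolved
by keeping the row with the highest mean (`max_mean`, default,
appropriate when duplicates are alternative transcript summaries) or by
summing (`sum`, appropriate for transcript-level counts).

## Synthetic data: what it emulates and what it does not

`make_synthetic_reference` emulates a panel of well-separated purified
profiles: per-gene log-normal baselines (σ = 1 on the log scale, median
10 units) shared across cell types, mild per-profile log-normal jitter
(σ = 0.2) standing in for biological and technical variation between
purified populations, and a marker structure in which half the genes
are up-regulated in one preferred cell type by a log-normal fold with
median 8 (σ = 0.5). `simulate_mixtures` draws the participating cell
types uniformly, proportions from a flat Dirichlet (uniform on the
simplex), forms exact convex combinations of reference columns, and
optionally multiplies each value by independent unit-mean log-normal
noise with a chosen coefficient of variation — multiplicative because
expression noise scales with magnitude. Mixture batches can cycle
through several cell-type counts (e.g. 4/5/6/10) to cover a range of
mixture complexities. Cross-platform stress is emulated by multiplying
each gene of the deconvolution reference by a log-normal factor
(σ = 0.3 in the benchmarks) shared across its columns.

These choices make the truth exactly recoverable in principle and every
run reproducible from a single seed. What they do **not** emulate:
correlated marker programs between related cell types (closely related
subtypes in real panels are far more collinear), count noise at low
expression, compositional library-size artifacts, missing cell types,
or real batch structure. Passing benchmarks on this generator therefore
demonstrates correctness of the machinery and the direction of
parameter effects, not field performance on real tissue.

## Accuracy floor on noiseless mixtures

With quantile normalization bypassed, the pipeline recovers noiseless
same-reference mixtures to machine precision (mean absolute error
~1e-17), confirming the selection/scaling/regression chain is exact.
With normalization active — as the pipeline specifies — noiseless
recovery has a floor of roughly 0.009–0.014 mean absolute error
(across generator seeds, mixtures of 4–10 cell types), caused by the
blend-concentration effect described under Preprocessing, and growing
with the number of cell types mixed. Per-cell-type correlations remain
above 0.99. The floor is reported honestly by the benchmark suite
rather than tuned away, because the normalization step is what buys
robustness to platform and scale differences on real data.

## Numerical choices and degenerate inputs

- Fraction tables are validated on write: values in [0, 1], rows
  summing to 1 within 1e-9.
- Expression values are written with 12 significant digits so
  round-trips preserve at least 9.
- Entropy requires strictly positive inputs (enforced); the zscore of
  a constant row is defined as 0 specificity (sd treated as infinite).
- Empty gene intersections, all-zero references, all-zero matrices,
  single-gene normalization, empty clusters, and unassigned cells all
  raise immediately with a message naming the offender.
- Determinism: the core pipeline has no randomness; simulators take a
  single seed; identical seeds give byte-identical output files.

## Benchmark problem sizes

The shipped benchmarks use 1,000–2,000-gene references with 5–10 cell
types, 100–200 simulated mixtures per evaluation, and 50 random
regression instances against an exhaustive simplex grid oracle at step
0.01 — sizes chosen so the whole suite runs in well under a minute
while keeping the statistics stable at the two decimal places being
asserted.

## Known limitations

- mRNA fractions, not cell fractions; no mRNA-content correction.
- One reference per run must share a platform-comparable scale across
  its own columns; combining heterogeneous references into one matrix
  is deliberately unsupported (batch effects dominate) — run each
  reference separately and median-combine the predictions instead.
- The five non-entropy scoring methods are conventions, as tabled
  above.
- Batch-dependence of row scaling (documented above) means adding
  samples to a submission can shift existing samples' predictions
  slightly.
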