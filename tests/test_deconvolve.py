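import numpy as np
import pandas as pd
import pytest

import importlib

import entromix as em

# the package re-exports the deconvolve() function under the module's
# name, so fetch the submodule explicitly
dc = importlib.import_module("entromix.deconvolve")
from entromix.config import DeconvolutionConfig


def _df(values, genes=None, cols=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = cols or [f"c{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cols)


def simplex_grid_nnls(A, b, step=0.01):
    """Oracle: exhaustive search over normalized coefficient directions.

    Enumerates the simplex at the given step; for each direction f the
    optimal non-negative scale is closed-form, so the best direction is
    the grid point with minimal residual. Independent of the active-set
    solver it checks.
    """
    K = A.shape[1]
    ticks = np.arange(0, int(round(1 / step)) + 1)
    if K == 2:
        grid = np.stack([ticks, ticks[::-1]], axis=1) * step
    elif K == 3:
        pts = [
            (i, j, int(round(1 / step)) - i - j)
            for i in ticks
            for j in ticks
            if i + j <= int(round(1 / step))
        ]
        grid = np.array(pts) * step
    else:
        raise ValueError("oracle supports K in {2, 3}")
    directions = A @ grid.T  # genes x P
    num = directions.T @ b
    den = (directions**2).sum(axis=0)
    scale = np.where(den > 0, np.clip(num, 0, None) / np.where(den > 0, den, 1), 0.0)
    rss = (b @ b) - 2 * scale * num + scale**2 * den
    return grid[np.argmin(rss)]


class TestRowScale:
    def test_p0_maps_rows_to_unit_interval(self):
        ref = _df([[0, 5]])
        mix = _df([[10]], cols=["s"])
        r, m, params = dc.row_scale(ref, mix, p=0.0)
        assert np.allclose(r.to_numpy(), [[0.0, 0.5]])
        assert np.allclose(m.to_numpy(), [[1.0]])
        assert params.min_val.iloc[0] == 0 and params.max_val.iloc[0] == 10

    def test_p1_with_zero_min_is_identity(self):
        ref = _df([[0, 5]])
        mix = _df([[10]], cols=["s"])
        r, m, _ = dc.row_scale(ref, mix, p=1.0)
        assert np.allclose(r.to_numpy(), [[0.0, 5.0]])
        assert np.allclose(m.to_numpy(), [[10.0]])

    def test_intermediate_exponent_hand_value(self):
        # row {2, 4, 6}, p = 0.5: (x - 2)/4 * sqrt(6)
        ref = _df([[2, 4]])
        mix = _df([[6]], cols=["s"])
        r, m, _ = dc.row_scale(ref, mix, p=0.5)
        assert np.allclose(r.to_numpy(), [[0.0, 0.5 * np.sqrt(6)]], atol=1e-4)
        assert np.allclose(m.to_numpy(), [[np.sqrt(6)]], atol=1e-4)

    def test_constant_row_zeroed_with_warning(self):
        ref = _df([[3, 3], [1, 2]])
        mix = _df([[3], [4]], cols=["s"])
        with pytest.warns(UserWarning, match="constant"):
            r, m, _ = dc.row_scale(ref, mix, p=0.0)
        assert np.allclose(r.iloc[0], 0) and m.iloc[0, 0] == 0
        assert np.allclose(r.iloc[1], [0.0, 1 / 3])

    def test_min_max_joint_over_both_matrices(self, rng):
        ref = _df(rng.uniform(1, 100, size=(30, 4)))
        mix = _df(rng.uniform(1, 100, size=(30, 6)), cols=[f"s{j}" for j in range(6)])
        r, m, _ = dc.row_scale(ref, mix, p=0.0)
        combined = np.hstack([r.to_numpy(), m.to_numpy()])
        assert np.allclose(combined.min(axis=1), 0, atol=1e-12)
        assert np.allclose(combined.max(axis=1), 1, atol=1e-12)


class TestNNLS:
    def test_exact_column_recovers_unit_vector(self, rng):
        A = rng.uniform(0, 10, size=(20, 3))
        coef, rnorm, deficient = dc.nnls_fit(A, A[:, 1])
        assert np.allclose(coef, [0, 1, 0], atol=1e-8)
        assert rnorm < 1e-8 and not deficient

    def test_known_blend_recovered(self, rng):
        A = rng.uniform(0, 10, size=(20, 2))
        b = 0.3 * A[:, 0] + 0.7 * A[:, 1]
        coef, _, _ = dc.nnls_fit(A, b)
        assert np.allclose(coef, [0.3, 0.7], atol=1e-6)

    def test_zero_target_gives_zero_solution(self, rng):
        A = rng.uniform(0, 10, size=(10, 2))
        coef, rnorm, _ = dc.nnls_fit(A, np.zeros(10))
        assert np.allclose(coef, 0) and rnorm == 0

    def test_rank_deficiency_flagged(self):
        A = np.ones((5, 2))
        coef, _, deficient = dc.nnls_fit(A, np.ones(5))
        assert deficient and (coef >= 0).all()

    def test_matches_simplex_grid_oracle(self, rng):
        for _ in range(10):
            K = int(rng.integers(2, 4))
            A = rng.uniform(0, 10, size=(20, K))
            x_true = rng.dirichlet(np.ones(K))
            b = A @ x_true + rng.normal(0, 0.1, size=20).clip(min=-A.min())
            coef, _, _ = dc.nnls_fit(A, b)
            frac, _ = dc.normalize_fractions(coef)
            oracle = simplex_grid_nnls(A, b, step=0.01)
            assert np.abs(frac - oracle).max() < 0.02


class TestNormalizeFractions:
    @pytest.mark.parametrize(
        "x,expected",
        [((2, 2), (0.5, 0.5)), ((0.3, 0.7), (0.3, 0.7)), ((1, 3), (0.25, 0.75))],
    )
    def test_normalization(self, x, expected):
        frac, degenerate = dc.normalize_fractions(x)
        assert np.allclose(frac, expected) and not degenerate

    def test_all_zero_falls_back_to_uniform(self):
        frac, degenerate = dc.normalize_fractions((0.0, 0.0, 0.0))
        assert np.allclose(frac, 1 / 3) and degenerate

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            dc.normalize_fractions((-0.1, 1.1))


class TestDeconvolvePipeline:
    def test_pure_reference_column_recovered(self, synth_ref_small):
        mix = synth_ref_small.iloc[:, [2]].rename(columns=lambda c: "sample")
        fractions = em.deconvolve(synth_ref_small, mix)
        assert fractions.loc["sample", synth_ref_small.columns[2]] >= 0.99

    def test_fifty_fifty_blend(self, synth_ref_small):
        blend = 0.5 * synth_ref_small.iloc[:, 0] + 0.5 * synth_ref_small.iloc[:, 1]
        mix = pd.DataFrame({"blend": blend})
        fractions = em.deconvolve(synth_ref_small, mix)
        assert abs(fractions.loc["blend", synth_ref_small.columns[0]] - 0.5) < 0.05
        assert abs(fractions.loc["blend", synth_ref_small.columns[1]] - 0.5) < 0.05

    def test_rows_sum_to_one(self, synth_ref_small):
        mix, _ = em.simulate_mixtures(synth_ref_small, 8, 3, seed=5)
        fractions = em.deconvolve(synth_ref_small, mix)
        assert np.allclose(fractions.sum(axis=1), 1.0, atol=1e-9)
        assert (fractions.to_numpy() >= 0).all()

    def test_mixture_scale_invariance(self, synth_ref_small):
        # quantile normalization is rank-based, so b -> c*b changes nothing
        mix, _ = em.simulate_mixtures(synth_ref_small, 3, 3, seed=9)
        f1 = em.deconvolve(synth_ref_small, mix)
        f2 = em.deconvolve(synth_ref_small, mix * 37.5)
        pd.testing.assert_frame_equal(f1, f2)

    def test_few_shared_genes_warns_but_runs(self, toy_ref):
        mix = pd.DataFrame({"s": [50.0, 3.0, 2.0, 5.0, 8.0, 3.0]}, index=toy_ref.index)
        with pytest.warns(UserWarning, match="shared"):
            fractions = em.deconvolve(toy_ref, mix, DeconvolutionConfig(num_sigs=2))
        assert np.allclose(fractions.sum(axis=1), 1.0)

    def test_details_report_stage_counts(self, synth_ref_small):
        mix, _ = em.simulate_mixtures(synth_ref_small, 2, 2, seed=1)
        _, details = em.deconvolve(synth_ref_small, mix, return_details=True)
        counts = details.gene_counts
        assert counts["shared"] == synth_ref_small.shape[0]
        assert counts["signatures"] == len(details.signature_set)
        assert counts["signatures"] <= 50 * synth_ref_small.shape[1]


class TestAggregateSubtypes:
    def test_subtype_fractions_sum_into_parent(self):
        f = pd.DataFrame(
            {"naive_B": [0.1], "memory_B": [0.2], "T": [0.7]}, index=["s1"]
        )
        out = dc.aggregate_subtypes(f, {"naive_B": "B", "memory_B": "B"})
        assert out.loc["s1", "B"] == pytest.approx(0.3)
        assert out.loc["s1", "T"] == pytest.approx(0.7)

    def test_identity_map_unchanged(self):
        f = pd.DataFrame({"A": [0.4], "B": [0.6]}, index=["s1"])
        pd.testing.assert_frame_equal(dc.aggregate_subtypes(f, {}), f)

    def test_row_sums_conserved(self, rng):
        raw = rng.dirichlet(np.ones(6), size=4)
        f = pd.DataFrame(raw, index=list("wxyz"), columns=list("ABCDEF"))
        mapping = {"A": "P", "B": "P", "C": "Q", "D": "Q", "E": "Q"}
        out = dc.aggregate_subtypes(f, mapping)
        assert np.allclose(out.sum(axis=1), f.sum(axis=1))
        assert out.loc["w", "P"] == pytest.approx(f.loc["w", ["A", "B"]].sum())


class TestCombineReferencePredictions:
    def test_median_of_equal_values(self):
        t = pd.DataFrame({"A": [0.2], "B": [0.8]}, index=["s"])
        out = dc.combine_reference_predictions([t, t.copy(), t.copy()])
        assert out.loc["s", "A"] == pytest.approx(0.2)

    def test_missing_cell_type_uses_available_tables(self):
        t1 = pd.DataFrame({"A": [0.5], "B": [0.5]}, index=["s"])
        t2 = pd.DataFrame({"A": [0.3], "B": [0.3], "C": [0.4]}, index=["s"])
        out = dc.combine_reference_predictions([t1, t2])
        # C comes only from t2: median of one value, then renormalized
        expect = np.array([0.4, 0.4, 0.4])
        assert np.allclose(out.loc["s", ["A", "B", "C"]], expect / expect.sum())

    def test_hand_median_then_renormalized(self):
        tables = [
            pd.DataFrame({"A": [a], "B": [1 - a]}, index=["s"])
            for a in (0.1, 0.2, 0.6)
        ]
        out = dc.combine_reference_predictions(tables)
        assert out.loc["s", "A"] == pytest.approx(0.2 / (0.2 + 0.8))
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_disjoint_samples_error(self):
        t1 = pd.DataFrame({"A": [1.0]}, index=["s1"])
        t2 = pd.DataFrame({"A": [1.0]}, index=["s2"])
        with pytest.raises(ValueError, match="no samples"):
            dc.combine_reference_predictions([t1, t2])
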