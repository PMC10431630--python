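import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphts.embedding import (
    NormalizedMatrix,
    SubseqMatrix,
    embed,
    extract_subsequences,
    project_2d,
    znormalize,
)
from graphts.io import TimeSeries


class TestExtraction:
    def test_rows_are_contiguous_slices(self, rng):
        ts = TimeSeries(rng.normal(size=10))
        Z = extract_subsequences(ts, 4)
        assert Z.data.shape == (7, 4)
        np.testing.assert_array_equal(Z.data[0], ts.values[:4])
        np.testing.assert_array_equal(Z.data[6], ts.values[6:10])

    def test_window_count_formula(self, rng):
        ts = TimeSeries(rng.normal(size=2000))
        assert extract_subsequences(ts, 80).n_windows == 2000 - 80 + 1

    @pytest.mark.parametrize("w", [0, 1, 10, 11])
    def test_out_of_range_window_rejected(self, rng, w):
        ts = TimeSeries(rng.normal(size=10))
        with pytest.raises(ValueError):
            extract_subsequences(ts, w)


class TestZNormalize:
    def test_population_sd_convention(self):
        # sd of [1,2,3] with divisor N is sqrt(2/3); frozen expected values
        Zn = znormalize(SubseqMatrix(np.array([[1.0, 2.0, 3.0]])))
        np.testing.assert_allclose(
            Zn.data[0], [-1.224744871391589, 0.0, 1.224744871391589], atol=1e-12
        )

    def test_constant_row_degenerates_to_zeros(self):
        Zn = znormalize(SubseqMatrix(np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])))
        assert Zn.degenerate_rows == frozenset({0})
        np.testing.assert_array_equal(Zn.data[0], 0.0)

    def test_rows_have_zero_mean_unit_sd(self, rng):
        Zn = znormalize(SubseqMatrix(rng.normal(size=(40, 16))))
        np.testing.assert_allclose(Zn.data.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(Zn.data.std(axis=1), 1.0, atol=1e-9)

    @given(
        a=st.floats(0.01, 100.0),
        b=st.floats(-100.0, 100.0),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_affine_invariance(self, a, b, seed):
        X = np.random.default_rng(seed).normal(size=(8, 12))
        base = znormalize(SubseqMatrix(X)).data
        scaled = znormalize(SubseqMatrix(a * X + b)).data
        np.testing.assert_allclose(scaled, base, atol=1e-9)


class TestProjection:
    def test_identical_rows_collapse_to_identical_points(self):
        X = np.tile(np.array([1.0, -1.0, 0.5, 0.5]), (6, 1))
        emb = project_2d(NormalizedMatrix(X, frozenset()))
        assert emb.points.shape == (6, 2)
        np.testing.assert_allclose(emb.points - emb.points[0], 0.0, atol=1e-12)

    def test_output_shape_and_determinism(self, rng):
        Zn = znormalize(SubseqMatrix(rng.normal(size=(50, 10))))
        e1, e2 = project_2d(Zn), project_2d(Zn)
        assert e1.points.shape == (50, 2)
        np.testing.assert_array_equal(e1.points, e2.points)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planar_data_distances_preserved(self, seed):
        # rows in an exact 2D affine subspace: projection must be an isometry
        g = np.random.default_rng(seed)
        X = g.normal(size=(30, 2)) @ g.normal(size=(2, 8)) + g.normal(size=8)
        emb = project_2d(NormalizedMatrix(X, frozenset()))
        d_high = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        d_low = np.linalg.norm(emb.points[:, None] - emb.points[None, :], axis=-1)
        np.testing.assert_allclose(d_low, d_high, atol=1e-8)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_projection_matches_svd_oracle_error(self, seed):
        # reconstruction error of the kept plane equals the optimal top-2
        # truncation error from a full SVD
        X = np.random.default_rng(seed).normal(size=(50, 10))
        Xc = X - X.mean(axis=0)
        sv = np.linalg.svd(Xc, compute_uv=False)
        optimal_err = np.sum(sv[2:] ** 2)
        emb = project_2d(NormalizedMatrix(X, frozenset()))
        ours_err = np.sum(Xc**2) - np.sum(emb.points**2)
        np.testing.assert_allclose(ours_err, optimal_err, rtol=1e-8)
        np.testing.assert_allclose(
            emb.explained, sv[:2] ** 2 / np.sum(sv**2), rtol=1e-8
        )

    def test_periodic_series_maps_period_shifted_windows_together(self):
        # noiseless exact periodicity: windows one period apart are the same
        # subsequence, hence the same embedded point
        p = 50
        ts = TimeSeries(np.sin(2 * np.pi * np.arange(20 * p) / p))
        emb = embed(ts, 30)
        np.testing.assert_allclose(emb.points[: 10 * p], emb.points[p : 11 * p], atol=1e-8)
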