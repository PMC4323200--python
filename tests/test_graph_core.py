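import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st

from heatpass.graph_core import (
    build_weighted_graph,
    graph_laplacian,
    normalized_laplacian,
    spectral_decompose,
    heat_kernel,
    average_temperature,
    heat_distance,
    heat_coordinates,
    rank_by_heat_distance,
    distances_to_weights,
)
from heatpass.synthetic_data import karate_graph

from conftest import random_connected_graph


class TestBuildWeightedGraph:
    def test_single_edge(self):
        g = build_weighted_graph([(1, 2, 1.0)])
        assert g.n == 2
        assert np.array_equal(g.W, [[0.0, 1.0], [1.0, 0.0]])

    def test_dense_diagonal_zeroed_with_warning(self):
        W = np.array([[0.0, 1.0], [1.0, 5.0]])
        with pytest.warns(UserWarning, match="diagonal"):
            g = build_weighted_graph(W)
        assert g.W[1, 1] == 0.0
        assert g.W[0, 1] == 1.0

    def test_edge_list_self_loop_dropped(self):
        with pytest.warns(UserWarning, match="self-loop"):
            g = build_weighted_graph([(1, 2, 1.0), (2, 2, 3.0)])
        assert np.all(np.diagonal(g.W) == 0)

    def test_reciprocal_entries_merged(self):
        g = build_weighted_graph([(1, 2, 0.5), (2, 1, 0.5)])
        assert g.W[0, 1] == 0.5

    def test_asymmetric_dense_rejected_names_pair(self):
        W = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="not symmetric"):
            build_weighted_graph(W)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            build_weighted_graph([(1, 2, -1.0)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_weighted_graph([])

    def test_karate_has_34_nodes(self):
        g = karate_graph()
        assert g.n == 34
        assert g.labels == tuple(range(1, 35))


class TestLaplacians:
    def test_k2_laplacian(self, k2):
        assert np.allclose(graph_laplacian(k2), [[1, -1], [-1, 1]])

    def test_rowsums_zero(self, rng):
        g = random_connected_graph(12, rng)
        assert np.allclose(graph_laplacian(g).sum(axis=1), 0.0, atol=1e-12)

    def test_degree_oracle(self, rng):
        # independent reconstruction from definitions
        g = random_connected_graph(5, rng)
        L = graph_laplacian(g)
        for i in range(5):
            assert L[i, i] == pytest.approx(sum(g.W[i, j] for j in range(5)))
            for j in range(5):
                if i != j:
                    assert L[i, j] == pytest.approx(-g.W[i, j])

    def test_k2_normalized_equals_unnormalized(self, k2):
        assert np.allclose(normalized_laplacian(k2), [[1, -1], [-1, 1]])

    def test_smallest_eigpair_is_sqrt_degree(self, rng):
        g = random_connected_graph(10, rng)
        LN = normalized_laplacian(g)
        vals, vecs = np.linalg.eigh(LN)
        assert vals[0] == pytest.approx(0.0, abs=1e-10)
        v = vecs[:, 0] / np.linalg.norm(vecs[:, 0])
        expect = np.sqrt(g.degrees) / np.linalg.norm(np.sqrt(g.degrees))
        assert np.allclose(np.abs(v), expect, atol=1e-10)

    def test_spectrum_in_0_2(self, rng):
        for _ in range(5):
            g = random_connected_graph(15, rng)
            vals = np.linalg.eigvalsh(normalized_laplacian(g))
            assert vals.min() > -1e-10
            assert vals.max() < 2 + 1e-10

    def test_isolated_node_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        g = build_weighted_graph(W, labels=("a", "b", "c"))
        with pytest.raises(ValueError, match="'c'"):
            normalized_laplacian(g)


class TestSpectralDecompose:
    def test_k2_closed_form(self, k2):
        dec = spectral_decompose(normalized_laplacian(k2))
        assert np.allclose(dec.eigenvalues, [0.0, 2.0], atol=1e-12)
        assert np.allclose(dec.eigenvectors[:, 0], [1 / np.sqrt(2)] * 2)
        assert dec.eigenvectors[0, 1] > 0  # sign fixed

    def test_unit_norm(self, rng):
        g = random_connected_graph(14, rng)
        dec = spectral_decompose(normalized_laplacian(g))
        norms = (dec.eigenvectors ** 2).sum(axis=0)
        assert np.allclose(norms, 1.0, atol=1e-12)

    def test_truncation_matches_full(self, rng):
        g = random_connected_graph(10, rng)
        LN = normalized_laplacian(g)
        full = spectral_decompose(LN, k="full")
        part = spectral_decompose(LN, k=3)
        assert np.allclose(part.eigenvalues, full.eigenvalues[:3], atol=1e-10)
        assert np.allclose(
            np.abs(part.eigenvectors), np.abs(full.eigenvectors[:, :3]), atol=1e-8
        )

    def test_k_too_large_rejected(self, k2):
        with pytest.raises(ValueError, match="out of range"):
            spectral_decompose(normalized_laplacian(k2), k=3)

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            spectral_decompose(np.array([[1.0, 2.0], [0.0, 1.0]]))


class TestHeatKernel:
    def test_k2_closed_form(self, k2):
        t = 0.7
        H = heat_kernel(spectral_decompose(normalized_laplacian(k2)), t).H
        assert H[0, 1] == pytest.approx((1 - np.exp(-2 * t)) / 2, abs=1e-12)
        assert H[0, 0] == pytest.approx((1 + np.exp(-2 * t)) / 2, abs=1e-12)

    def test_t0_identity(self, rng):
        g = random_connected_graph(8, rng)
        H = heat_kernel(spectral_decompose(normalized_laplacian(g)), 0.0).H
        assert np.allclose(H, np.eye(8), atol=1e-10)

    @pytest.mark.parametrize("t", [0.5, 4.0, 10.0])
    def test_matrix_exponential_oracle(self, rng, t):
        g = random_connected_graph(20, rng)
        LN = normalized_laplacian(g)
        H = heat_kernel(spectral_decompose(LN), t).H
        assert np.abs(H - scipy.linalg.expm(-t * LN)).max() < 1e-8

    def test_negative_t_rejected(self, k2):
        with pytest.raises(ValueError, match=">= 0"):
            heat_kernel(spectral_decompose(normalized_laplacian(k2)), -1.0)

    def test_symmetry_and_trace(self, rng):
        g = random_connected_graph(12, rng)
        dec = spectral_decompose(normalized_laplacian(g), k=5)
        kernel = heat_kernel(dec, 2.5)
        assert np.allclose(kernel.H, kernel.H.T, atol=1e-12)
        assert np.trace(kernel.H) == pytest.approx(
            np.exp(-dec.eigenvalues * 2.5).sum(), abs=1e-10
        )

    def test_truncation_error_nonincreasing(self, rng):
        g = random_connected_graph(12, rng)
        LN = normalized_laplacian(g)
        Hfull = heat_kernel(spectral_decompose(LN), 1.0).H
        errs = [
            np.abs(Hfull - heat_kernel(spectral_decompose(LN, k=k), 1.0).H).max()
            for k in range(1, 13)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_long_time_limit(self, rng):
        # connected graph: H_t(i,j) -> phi_1(i) phi_1(j) as t -> inf
        g = random_connected_graph(9, rng)
        dec = spectral_decompose(normalized_laplacian(g))
        H = heat_kernel(dec, 1e3).H
        phi1 = dec.eigenvectors[:, 0]
        assert np.abs(H - np.outer(phi1, phi1)).max() < 1e-6


class TestTemperature:
    def test_k2(self, k2):
        t = 1.3
        kernel = heat_kernel(spectral_decompose(normalized_laplacian(k2)), t)
        temp = average_temperature(kernel).temp
        assert temp[0] == pytest.approx((1 - np.exp(-2 * t)) / 2, abs=1e-12)

    def test_star_hub_hottest(self, star5):
        kernel = heat_kernel(spectral_decompose(normalized_laplacian(star5)), 2.0)
        temp = average_temperature(kernel).temp
        assert np.all(temp[0] > temp[1:])

    def test_karate_leaders_hottest(self):
        g = karate_graph()
        kernel = heat_kernel(spectral_decompose(normalized_laplacian(g)), 4.0)
        temp = average_temperature(kernel).temp
        top2 = {g.labels[i] for i in np.argsort(temp)[-2:]}
        assert top2 == {1, 34}


class TestHeatDistance:
    def test_zero_diagonal(self, rng):
        g = random_connected_graph(7, rng)
        kernel = heat_kernel(spectral_decompose(normalized_laplacian(g)), 1.0)
        D = heat_distance(kernel).D
        assert np.all(np.diagonal(D) == 0.0)
        assert np.allclose(D, D.T)

    def test_k2_closed_form(self, k2):
        t = 0.9
        kernel = heat_kernel(spectral_decompose(normalized_laplacian(k2)), t)
        assert heat_distance(kernel).D[0, 1] == pytest.approx(
            2 * np.exp(-2 * t), abs=1e-12
        )

    def test_matches_embedding_sq_distance(self, rng):
        g = random_connected_graph(11, rng)
        dec = spectral_decompose(normalized_laplacian(g))
        t = 2.0
        D = heat_distance(heat_kernel(dec, t)).D
        C = heat_coordinates(dec, t).coords
        diff = C[:, None, :] - C[None, :, :]
        assert np.abs(D - (diff ** 2).sum(axis=2)).max() < 1e-10


class TestHeatCoordinates:
    def test_k2(self, k2):
        t = 0.4
        dec = spectral_decompose(normalized_laplacian(k2))
        C = heat_coordinates(dec, t, k=2).coords
        assert C[0, 0] == pytest.approx(1 / np.sqrt(2))
        assert abs(C[0, 1]) == pytest.approx(np.exp(-t) / np.sqrt(2), abs=1e-12)

    def test_column_norms_decay(self, rng):
        g = random_connected_graph(10, rng)
        dec = spectral_decompose(normalized_laplacian(g))
        t = 3.0
        C = heat_coordinates(dec, t).coords
        norms = np.linalg.norm(C, axis=0)
        assert np.allclose(norms, np.exp(-dec.eigenvalues * t / 2), atol=1e-10)
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_time_doubling_scales_norms(self, rng):
        g = random_connected_graph(8, rng)
        dec = spectral_decompose(normalized_laplacian(g))
        n1 = np.linalg.norm(heat_coordinates(dec, 1.0).coords, axis=0) ** 2
        n2 = np.linalg.norm(heat_coordinates(dec, 2.0).coords, axis=0) ** 2
        assert np.allclose(n2, n1 * np.exp(-dec.eigenvalues * 1.0), atol=1e-12)

    def test_dim_too_large_rejected(self, k2):
        dec = spectral_decompose(normalized_laplacian(k2))
        with pytest.raises(ValueError, match="exceeds"):
            heat_coordinates(dec, 1.0, k=3)


class TestRanking:
    def test_query_first(self, path3):
        kernel = heat_kernel(spectral_decompose(normalized_laplacian(path3)), 1.0)
        D = heat_distance(kernel, labels=path3.labels)
        assert rank_by_heat_distance(D, 2)[0] == 2

    def test_path_order(self, path3):
        kernel = heat_kernel(spectral_decompose(normalized_laplacian(path3)), 0.8)
        D = heat_distance(kernel, labels=path3.labels)
        assert rank_by_heat_distance(D, 1) == [1, 2, 3]

    def test_tie_broken_by_label(self, star5):
        kernel = heat_kernel(spectral_decompose(normalized_laplacian(star5)), 1.0)
        D = heat_distance(kernel, labels=star5.labels)
        assert rank_by_heat_distance(D, 1) == [1, 2, 3, 4, 5]  # leaves tie

    def test_unknown_query(self, k2):
        kernel = heat_kernel(spectral_decompose(normalized_laplacian(k2)), 1.0)
        D = heat_distance(kernel, labels=k2.labels)
        with pytest.raises(KeyError):
            rank_by_heat_distance(D, 99)


class TestDistanceConversion:
    def test_gaussian_range(self, rng):
        D = np.abs(rng.normal(size=(6, 6)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        W = distances_to_weights(D)
        assert np.all(np.diagonal(W) == 0)
        off = W[~np.eye(6, dtype=bool)]
        assert np.all((off > 0) & (off <= 1))

    def test_zero_distance_full_weight(self):
        D = np.array([[0.0, 0.0, 3.0], [0.0, 0.0, 3.0], [3.0, 3.0, 0.0]])
        W = distances_to_weights(D, sigma=1.0)
        assert W[0, 1] == pytest.approx(1.0)


@settings(max_examples=25, deadline=None)
@given(
    n=st.integers(min_value=2, max_value=12),
    t=st.floats(min_value=0.0, max_value=20.0),
    seed=st.integers(min_value=0, max_value=2**31),
)
def test_heat_kernel_properties(n, t, seed):
    g = random_connected_graph(n, np.random.default_rng(seed))
    dec = spectral_decompose(normalized_laplacian(g))
    kernel = heat_kernel(dec, t)
    assert np.allclose(kernel.H, kernel.H.T, atol=1e-12)
    D = heat_distance(kernel).D
    assert np.all(np.diagonal(D) == 0.0)
    assert D.min() > -1e-10  # full spectrum: exact nonnegativity
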