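import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from recold import EmbeddingConfig, embed
from recold.alignment import DissimilarityMatrix
from recold.embedding import (
    embed_isomap,
    embed_mds,
    embed_spectral,
    embed_tsne,
    geodesic_distances,
    knn_graph,
    smacof,
)

from oracles import dijkstra_oracle


def dmat(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    return DissimilarityMatrix(
        tuple(f"{prefix}{i}" for i in range(values.shape[0])), values
    )


def embedded_distances(points):
    return squareform(pdist(points.coordinates))


class TestSmacofMds:
    def test_two_points_exactly_embeddable(self):
        s = dmat([[0, 5], [5, 0]])
        pts = embed_mds(s, EmbeddingConfig(max_iter=2000, tol=1e-15, seed=1))
        assert embedded_distances(pts)[0, 1] == pytest.approx(5.0, abs=1e-6)
        assert pts.extras["stress"] < 1e-10

    def test_equilateral_triangle_recovered(self):
        s = dmat(1 - np.eye(3))
        pts = embed_mds(s, EmbeddingConfig(max_iter=5000, tol=1e-16, seed=2))
        d = embedded_distances(pts)
        assert np.allclose(d[np.triu_indices(3, 1)], 1.0, atol=1e-6)

    def test_unit_square_recovered(self):
        r2 = np.sqrt(2)
        target = np.array(
            [[0, 1, r2, 1], [1, 0, 1, r2], [r2, 1, 0, 1], [1, r2, 1, 0]]
        )
        pts = embed_mds(dmat(target), EmbeddingConfig(max_iter=5000, tol=1e-16, seed=3))
        assert np.allclose(embedded_distances(pts), target, atol=1e-6)

    def test_stress_monotonically_non_increasing(self, rng):
        n = 20
        raw = rng.random((n, n))
        s = (raw + raw.T) / 2
        np.fill_diagonal(s, 0)
        _, history = smacof(s, seed=7, max_iter=200)
        assert np.all(np.diff(history) <= 1e-10)

    def test_determinism(self, rng):
        raw = rng.random((12, 12))
        s = dmat((raw + raw.T) / 2 - np.diag(np.diag(raw)))
        np.fill_diagonal(s.values, 0)
        a = embed_mds(s, EmbeddingConfig(seed=4))
        b = embed_mds(s, EmbeddingConfig(seed=4))
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            smacof(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestIsomap:
    def test_chain_geodesic(self):
        s = np.array([[0, 1, 2.5], [1, 0, 1], [2.5, 1, 0]])
        geo = geodesic_distances(s, k=1)
        assert geo[0, 2] == pytest.approx(2.0)  # via the middle point

    def test_path_graph_length(self):
        n = 5
        s = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        geo = geodesic_distances(s, k=1)
        assert geo[0, 4] == pytest.approx(4.0)

    def test_complete_graph_reduces_to_direct_distances(self, rng):
        # Euclidean (metric) dissimilarities: every shortcut obeys the
        # triangle inequality, so geodesics equal direct distances
        pts = rng.random((15, 2))
        s = squareform(pdist(pts))
        geo = geodesic_distances(s, k=14)
        assert np.allclose(geo, s)

    def test_geodesics_match_dijkstra_oracle(self, rng):
        for _ in range(5):
            raw = rng.random((20, 20)) + 0.05
            s = (raw + raw.T) / 2
            np.fill_diagonal(s, 0)
            k = 4
            graph = knn_graph(s, k)
            geo = geodesic_distances(s, k)
            for src in range(20):
                assert np.allclose(geo[src], dijkstra_oracle(graph, src))

    def test_disconnected_graph_reported(self):
        # two far blobs, k=1 keeps them separate
        s = np.array(
            [
                [0, 0.1, 10, 10],
                [0.1, 0, 10, 10],
                [10, 10, 0, 0.1],
                [10, 10, 0.1, 0],
            ],
            dtype=float,
        )
        with pytest.raises(ValueError, match="2 connected components"):
            geodesic_distances(s, k=1)

    def test_matches_mds_on_complete_graph(self, rng):
        pts = rng.random((15, 2))
        s = dmat(squareform(pdist(pts)))
        cfg = EmbeddingConfig(k_neighbors=14, max_iter=3000, tol=1e-15, seed=5)
        iso = embed_isomap(s, cfg)
        mds = embed_mds(s, cfg)
        assert np.allclose(
            embedded_distances(iso), embedded_distances(mds), atol=1e-4
        )


class TestSpectral:
    def test_two_blobs_separated_by_sign(self):
        # blocks of small dissimilarity, weak cross links
        n = 10
        s = np.full((n, n), 5.0)
        s[:5, :5] = 0.2
        s[5:, 5:] = 0.2
        np.fill_diagonal(s, 0)
        pts = embed_spectral(dmat(s), EmbeddingConfig(method="spectral", k_neighbors=5, dim=1))
        signs = np.sign(pts.coordinates[:, 0])
        assert len(set(signs[:5])) == 1 and len(set(signs[5:])) == 1
        assert signs[0] != signs[5]

    def test_shape_and_finiteness(self, rng):
        raw = rng.random((12, 12))
        s = (raw + raw.T) / 2
        np.fill_diagonal(s, 0)
        pts = embed_spectral(dmat(s), EmbeddingConfig(method="spectral", dim=2, k_neighbors=4))
        assert pts.coordinates.shape == (12, 2)
        assert np.all(np.isfinite(pts.coordinates))

    def test_determinism(self, rng):
        raw = rng.random((12, 12))
        s = (raw + raw.T) / 2
        np.fill_diagonal(s, 0)
        cfg = EmbeddingConfig(method="spectral", k_neighbors=4, seed=9)
        a = embed_spectral(dmat(s), cfg)
        b = embed_spectral(dmat(s), cfg)
        assert np.array_equal(a.coordinates, b.coordinates)


class TestTsne:
    def test_perplexity_validated(self):
        s = dmat(1 - np.eye(3))
        with pytest.raises(ValueError, match="perplexity"):
            embed_tsne(s, EmbeddingConfig(method="tsne", perplexity=3))

    def test_zero_distance_pair_stays_adjacent(self, rng):
        # two duplicate sequences (S = 0 between them) should embed next to
        # each other: mutually nearest in most runs, never far apart
        mutual_nn = 0
        for seed in range(10):
            n = 20
            pts2d = rng.random((n, 2)) * 3
            pts2d[1] = pts2d[0]
            s = squareform(pdist(pts2d))
            cfg = EmbeddingConfig(method="tsne", perplexity=5, seed=seed, max_iter=2000)
            out = embed_tsne(dmat(s), cfg)
            d = embedded_distances(out)
            np.fill_diagonal(d, np.inf)
            rank = int((d[0] < d[0, 1]).sum())
            assert rank <= 2  # always among the 3 nearest
            if d[0, 1] == d[0].min() and d[1, 0] == d[1].min():
                mutual_nn += 1
        assert mutual_nn >= 8

    def test_shape_and_determinism(self, rng):
        raw = rng.random((25, 25))
        s = (raw + raw.T) / 2
        np.fill_diagonal(s, 0)
        cfg = EmbeddingConfig(method="tsne", perplexity=8, seed=3)
        a = embed_tsne(dmat(s), cfg)
        b = embed_tsne(dmat(s), cfg)
        assert a.coordinates.shape == (25, 2)
        assert np.array_equal(a.coordinates, b.coordinates)


class TestDispatch:
    def test_row_order_matches_input_sequences(self, rng):
        raw = rng.random((8, 8))
        s = (raw + raw.T) / 2
        np.fill_diagonal(s, 0)
        sm = dmat(s)
        for method in ("mds", "isomap", "spectral"):
            out = embed(sm, EmbeddingConfig(method=method, k_neighbors=3))
            assert out.sequences == sm.sequences
            assert out.method == method
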