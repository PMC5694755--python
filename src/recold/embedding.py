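"""Low-dimensional embedding of the sequence dissimilarity matrix.

Because CDR3 sequences of different lengths have no natural fixed-dimension
coordinates, the pipeline embeds the precomputed dissimilarity matrix
directly.  Four interchangeable methods are provided:

* ``mds`` — metric MDS minimizing raw stress with the SMACOF majorization
  algorithm (run here in-package so the per-iteration stress trajectory is
  available; stress is non-increasing across iterations).
* ``isomap`` — geodesic distances along shortest paths of a k-nearest-
  neighbor graph (Floyd-Warshall), followed by the same stress minimization
  applied to the geodesic matrix.
* ``spectral`` — Laplacian eigenmaps on a weighted kNN adjacency.
* ``tsne`` — t-SNE on the precomputed dissimilarities.

All methods are deterministic given the configured seed.  Embedded
coordinates are defined only up to rigid motion (and, for spectral/tsne,
method-specific scale), so consumers should rely on inter-point distances
or densities, never absolute coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, floyd_warshall
from scipy.spatial.distance import pdist, squareform

from .alignment import DissimilarityMatrix

__all__ = [
    "EmbeddingConfig",
    "EmbeddedPoints",
    "smacof",
    "knn_graph",
    "geodesic_distances",
    "embed_mds",
    "embed_isomap",
    "embed_spectral",
    "embed_tsne",
    "embed",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Parameters shared by the four embedding methods.

    ``k_neighbors`` applies to the graph-based methods (isomap, spectral);
    ``perplexity`` to t-SNE.  ``max_iter``/``tol`` control the SMACOF
    optimizer (mds, isomap).
    """

    method: str = "mds"
    dim: int = 2
    k_neighbors: int = 10
    perplexity: float = 30.0
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.method not in ("tsne", "mds", "isomap", "spectral"):
            raise ValueError(f"unknown embedding method {self.method!r}")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")


@dataclass(frozen=True)
class EmbeddedPoints:
    """Per-sequence coordinates in the embedded space.

    ``coordinates`` has one row per unique sequence, in the same order as
    the input dissimilarity matrix.
    """

    sequences: tuple[str, ...]
    coordinates: np.ndarray  # (N, d)
    method: str
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coordinates.shape[0] != len(self.sequences):
            raise ValueError("one coordinate row per sequence required")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedded coordinates must be finite")


def _check_square_symmetric(mat: np.ndarray) -> np.ndarray:
    mat = np.asarray(mat, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("dissimilarity matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError("dissimilarity matrix must be symmetric")
    return mat


# ---------------------------------------------------------------------------
# SMACOF stress majorization
# ---------------------------------------------------------------------------

def smacof(
    delta: np.ndarray,
    dim: int = 2,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-9,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize raw stress sum_{i<j} (delta_ij - d_ij)^2 by majorization.

    Returns ``(coordinates, stress_history)``.  Each Guttman-transform
    update is guaranteed not to increase the stress; iteration stops when
    the relative stress decrease drops below *tol*.
    """
    delta = _check_square_symmetric(delta)
    n = delta.shape[0]
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, dim)) if init is None else np.array(init, dtype=float)

    def stress_of(coords: np.ndarray) -> tuple[float, np.ndarray]:
        d = squareform(pdist(coords))
        diff = delta - d
        return 0.5 * float((diff[~np.eye(n, dtype=bool)] ** 2).sum()), d

    history = []
    stress, d = stress_of(x)
    history.append(stress)
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, delta / d, 0.0)
        b = -ratio
        np.fill_diagonal(b, 0.0)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n  # Guttman transform (V = n*J for the unweighted case)
        new_stress, d = stress_of(x)
        history.append(new_stress)
        if stress - new_stress <= tol * max(stress, 1e-300):
            stress = new_stress
            break
        stress = new_stress
    return x, np.array(history)


def embed_mds(s: DissimilarityMatrix, cfg: EmbeddingConfig) -> EmbeddedPoints:
    """Metric MDS (SMACOF) of the dissimilarity matrix."""
    coords, history = smacof(
        s.values, dim=cfg.dim, seed=cfg.seed, max_iter=cfg.max_iter, tol=cfg.tol
    )
    return EmbeddedPoints(
        s.sequences, coords, "mds", {"stress_history": history, "stress": history[-1]}
    )


# ---------------------------------------------------------------------------
# Graph-based methods
# ---------------------------------------------------------------------------

def knn_graph(delta: np.ndarray, k: int) -> np.ndarray:
    """Union-symmetrized k-nearest-neighbor distance graph.

    Entry (i, j) holds delta_ij if j is among i's k nearest neighbors or
    vice versa, else 0 (no edge).  Self-edges are excluded.
    """
    delta = _check_square_symmetric(delta)
    n = delta.shape[0]
    if k >= n:
        k = n - 1
    order = np.argsort(delta + np.diag(np.full(n, np.inf)), axis=1, kind="stable")
    mask = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    mask[rows, order[:, :k].ravel()] = True
    mask |= mask.T
    graph = np.where(mask, delta, 0.0)
    return graph


def _require_connected(mask: np.ndarray, k: int) -> None:
    n_comp, _ = connected_components(csr_matrix(mask), directed=False)
    if n_comp > 1:
        raise ValueError(
            f"k-nearest-neighbor graph has {n_comp} connected components; "
            f"increase k_neighbors (currently {k})"
        )


def geodesic_distances(delta: np.ndarray, k: int) -> np.ndarray:
    """All-pairs shortest-path (geodesic) distances on the kNN graph,
    computed with the Floyd-Warshall algorithm."""
    graph = knn_graph(delta, k)
    mask = graph > 0
    _require_connected(mask, k)
    dense = np.where(mask, graph, np.inf)
    np.fill_diagonal(dense, 0.0)
    geo = floyd_warshall(dense)
    return geo


def embed_isomap(s: DissimilarityMatrix, cfg: EmbeddingConfig) -> EmbeddedPoints:
    """Stress minimization over geodesic (shortest-path) distances."""
    geo = geodesic_distances(s.values, cfg.k_neighbors)
    coords, history = smacof(
        geo, dim=cfg.dim, seed=cfg.seed, max_iter=cfg.max_iter, tol=cfg.tol
    )
    return EmbeddedPoints(
        s.sequences,
        coords,
        "isomap",
        {"stress_history": history, "stress": history[-1], "geodesics": geo},
    )


def embed_spectral(s: DissimilarityMatrix, cfg: EmbeddingConfig) -> EmbeddedPoints:
    """Laplacian eigenmaps on a weighted kNN adjacency.

    Edge weights are ``exp(-delta_ij / mean_edge_delta)`` so that closer
    sequences are more strongly coupled; the embedding uses the
    eigenvectors of the symmetric normalized Laplacian with the smallest
    nonzero eigenvalues.  Component signs are fixed deterministically.
    """
    from sklearn.manifold import spectral_embedding

    graph = knn_graph(s.values, cfg.k_neighbors)
    mask = graph > 0
    _require_connected(mask | np.eye(len(graph), dtype=bool), cfg.k_neighbors)
    scale = graph[mask].mean() if mask.any() else 1.0
    affinity = np.where(mask, np.exp(-graph / max(scale, 1e-300)), 0.0)
    # duplicate sequences (delta == 0) sit on the same point; give their
    # edge full weight
    affinity[mask & (graph == 0)] = 1.0
    coords = spectral_embedding(
        affinity,
        n_components=cfg.dim,
        random_state=np.random.RandomState(cfg.seed % (2**31)),
        norm_laplacian=True,
        drop_first=True,
    )
    # eigenvector sign is arbitrary: orient so the largest-magnitude entry
    # of each axis is positive
    for j in range(coords.shape[1]):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return EmbeddedPoints(s.sequences, coords, "spectral")


def embed_tsne(s: DissimilarityMatrix, cfg: EmbeddingConfig) -> EmbeddedPoints:
    """t-SNE on the precomputed dissimilarities.

    Gaussian kernel with perplexity-calibrated per-point bandwidth in the
    input space, Student-t kernel in the embedded space.
    """
    from sklearn.manifold import TSNE

    n = len(s.sequences)
    if cfg.perplexity >= n:
        raise ValueError(f"perplexity ({cfg.perplexity}) must be < n points ({n})")
    tsne = TSNE(
        n_components=cfg.dim,
        metric="precomputed",
        init="random",
        perplexity=cfg.perplexity,
        random_state=cfg.seed % (2**31),
        max_iter=max(cfg.max_iter, 250),
    )
    coords = tsne.fit_transform(s.values)
    return EmbeddedPoints(
        s.sequences, np.asarray(coords, dtype=np.float64), "tsne",
        {"kl_divergence": float(tsne.kl_divergence_)},
    )


_METHODS: dict[str, Callable[[DissimilarityMatrix, EmbeddingConfig], EmbeddedPoints]] = {
    "mds": embed_mds,
    "isomap": embed_isomap,
    "spectral": embed_spectral,
    "tsne": embed_tsne,
}


def embed(s: DissimilarityMatrix, cfg: EmbeddingConfig | None = None, **kwargs) -> EmbeddedPoints:
    """Dispatch to the configured embedding method."""
    cfg = cfg or EmbeddingConfig()
    if kwargs:
        cfg = replace(cfg, **kwargs)
    return _METHODS[cfg.method](s, cfg)
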