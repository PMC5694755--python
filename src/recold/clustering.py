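"""Hierarchical clustering of the pairwise-sample JSD matrix.

The sample-distance matrix produced by the divergence stage is converted
into a dendrogram by agglomerative clustering under Ward's minimum-variance
criterion, applied to the JSD values as-is through the Lance-Williams
update (JSD is not a squared-Euclidean distance, so Ward here is a
heuristic ordering criterion rather than a variance decomposition; average
and complete linkage are available as alternatives).  The cophenetic
correlation coefficient is provided as a goodness-of-fit diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, cut_tree, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

__all__ = ["Dendrogram", "ward_linkage", "cophenetic_correlation", "to_newick"]

_LINKAGES = ("ward", "average", "complete")


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration record: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray  # (M-1, 4) scipy format
    labels: tuple[str, ...]
    method: str = "ward"

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Flat cluster labels at the cut yielding ``n_clusters`` clusters."""
        assignment = cut_tree(self.linkage, n_clusters=n_clusters).ravel()
        return dict(zip(self.labels, (int(a) for a in assignment)))


def _validated_square(distances) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(distances, pd.DataFrame):
        labels = tuple(str(c) for c in distances.columns)
        mat = distances.to_numpy(dtype=float)
    else:
        mat = np.asarray(distances, dtype=float)
        labels = tuple(f"S{i}" for i in range(mat.shape[0]))
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or mat.shape[0] < 2:
        raise ValueError("need a square distance matrix over >= 2 samples")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(mat < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(np.diag(mat), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    return mat, labels


def ward_linkage(
    distances, labels: tuple[str, ...] | None = None, method: str = "ward"
) -> Dendrogram:
    """Agglomerate samples from a symmetric distance matrix.

    Accepts a pandas DataFrame (labels taken from its columns) or a plain
    array.  The matrix values are fed to the Lance-Williams recurrence
    unchanged.
    """
    if method not in _LINKAGES:
        raise ValueError(f"linkage method must be one of {_LINKAGES}")
    mat, auto_labels = _validated_square(distances)
    z = linkage(squareform(mat, checks=False), method=method)
    return Dendrogram(z, tuple(labels) if labels else auto_labels, method)


def cophenetic_correlation(distances, dendrogram: Dendrogram) -> float:
    """Pearson correlation between original and cophenetic distances.

    Equals 1 when the input matrix is ultrametric (exactly representable
    by the tree).  Undefined (raises) when the distance vector is constant,
    e.g. for only two samples.
    """
    mat, _ = _validated_square(distances)
    if mat.shape[0] != len(dendrogram.labels):
        raise ValueError("dendrogram was built from a different number of samples")
    orig = squareform(mat, checks=False)
    coph = cophenet(dendrogram.linkage)
    if np.ptp(orig) == 0 or np.ptp(coph) == 0:
        raise ValueError(
            "cophenetic correlation is undefined for constant distance vectors"
        )
    return float(pearsonr(orig, coph)[0])


def to_newick(dendrogram: Dendrogram) -> str:
    """Serialize the dendrogram as a Newick string.

    Branch lengths are differences of merge heights, so leaf-to-root path
    lengths reproduce each merge height.
    """
    z = dendrogram.linkage
    n = len(dendrogram.labels)
    height = {i: 0.0 for i in range(n)}

    def node_repr(i: int) -> str:
        if i < n:
            return dendrogram.labels[i]
        a, b, h, _ = z[i - n]
        parts = []
        for child in (int(a), int(b)):
            parts.append(f"{node_repr(child)}:{h - height[child]:.10g}")
        return "(" + ",".join(parts) + ")"

    for k in range(z.shape[0]):
        height[n + k] = float(z[k, 2])
    return node_repr(n + z.shape[0] - 1) + ";"
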