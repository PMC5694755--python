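"""Jensen-Shannon divergence between sample densities and its decomposition.

The inter-sample difference between two discretized densities P and Q is
the Jensen-Shannon divergence

    D_JS[P || Q] = sum_x 1/2 [ P(x) log(P(x)/M(x)) + Q(x) log(Q(x)/M(x)) ],

with M = (P + Q)/2 and the summand defined as the per-bin "local JSD".
Natural logarithms are used by default (values in [0, ln 2]); base-2 is
available.  The local map supports two further analyses:

* *contributing sequences* — the sequences whose embedded points fall in
  the top fraction (default 1%) of positive-local-JSD bins, i.e. the
  sequences that drive an observed pairwise difference;
* *bootstrap significance* — resampling points from a sample's density,
  re-estimating the density, and collecting the JSD between naive and
  re-estimated densities; the 99th percentile of those null JSDs is the
  one-sided 99% threshold against which a pairwise JSD is judged.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, log
from typing import Sequence

import numpy as np
import pandas as pd

from .density import BinnedKernel, DensityGrid, assign_bins, estimate_pdf
from .embedding import EmbeddedPoints

__all__ = [
    "JsdResult",
    "ContributingSet",
    "BootstrapResult",
    "jensen_shannon",
    "pairwise_sample_jsd",
    "contributing_sequences",
    "bootstrap_significance",
    "position_frequency_matrix",
]


@dataclass(frozen=True)
class JsdResult:
    """Global JSD of a sample pair plus its per-bin decomposition."""

    pair: tuple[str, str]
    global_jsd: float
    local_map: np.ndarray  # shape == grid.shape; sums to global_jsd
    grid: "object"  # Grid of the two densities


@dataclass(frozen=True)
class ContributingSet:
    """Sequences lying in the highest-local-JSD bins of a sample pair."""

    pair: tuple[str, str]
    selected_bins: np.ndarray  # flat bin indices
    members: dict[str, tuple[str, ...]]  # sample_id -> sequences in selected bins
    top_frac: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample": sid, "sequence": seq}
            for sid, seqs in self.members.items()
            for seq in seqs
        ]
        return pd.DataFrame(rows, columns=["sample", "sequence"])


@dataclass(frozen=True)
class BootstrapResult:
    """Null JSD distribution from resampling a sample's own density."""

    sample_id: str
    jsd_samples: np.ndarray
    threshold: float  # 99th percentile (or configured) of jsd_samples
    percentile: float = 99.0

    def is_significant(self, jsd_value: float) -> bool:
        return jsd_value > self.threshold


def _check_same_grid(p: DensityGrid, q: DensityGrid) -> None:
    if not p.grid.same_as(q.grid):
        raise ValueError("densities are defined on different grids")


def jensen_shannon(p: DensityGrid, q: DensityGrid, base: str = "nats") -> JsdResult:
    """Jensen-Shannon divergence between two densities on the same grid.

    Returns both the global value and the per-bin local map (which sums to
    the global value).  Symmetric in (P, Q); bins where a density is zero
    follow the 0 * log 0 = 0 convention.
    """
    _check_same_grid(p, q)
    if base not in ("nats", "bits"):
        raise ValueError("base must be 'nats' or 'bits'")
    pa, qa = p.probabilities, q.probabilities
    m = 0.5 * (pa + qa)

    def xlog_ratio(num: np.ndarray) -> np.ndarray:
        # num * log(num / m) with the 0 log 0 = 0 convention (m > 0 wherever
        # num > 0, since m is the average)
        out = np.zeros_like(num)
        mask = num > 0
        out[mask] = num[mask] * np.log(num[mask] / m[mask])
        return out

    local = 0.5 * (xlog_ratio(pa) + xlog_ratio(qa))
    if base == "bits":
        local = local / log(2.0)
    return JsdResult(
        (p.sample_id, q.sample_id), float(local.sum()), local, p.grid
    )


def pairwise_sample_jsd(pdfs: Sequence[DensityGrid], base: str = "nats") -> pd.DataFrame:
    """Symmetric matrix of pairwise JSDs over a list of sample densities."""
    if len(pdfs) < 2:
        raise ValueError("need at least 2 densities")
    for other in pdfs[1:]:
        _check_same_grid(pdfs[0], other)
    ids = [p.sample_id for p in pdfs]
    n = len(pdfs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jensen_shannon(pdfs[i], pdfs[j], base).global_jsd
    return pd.DataFrame(mat, index=ids, columns=ids)


def contributing_sequences(
    result: JsdResult,
    points_a: EmbeddedPoints,
    points_b: EmbeddedPoints,
    top_frac: float = 0.01,
) -> ContributingSet:
    """Sequences falling in the top-local-JSD bins of a sample pair.

    Bins with positive local JSD are ranked descending; the top
    ``ceil(top_frac * n_positive)`` are selected, extending through any
    ties at the cutoff.  Each sample's sequences are assigned to bins by
    half-open binning of their embedded coordinates; those landing in
    selected bins are returned per sample.
    """
    if not 0 < top_frac <= 1:
        raise ValueError("top_frac must be in (0, 1]")
    local = result.local_map.ravel()
    positive = np.flatnonzero(local > 0)
    if positive.size == 0:
        return ContributingSet(
            result.pair,
            np.array([], dtype=int),
            {result.pair[0]: (), result.pair[1]: ()},
            top_frac,
        )
    k = ceil(top_frac * positive.size)
    order = positive[np.argsort(local[positive], kind="stable")[::-1]]
    cutoff = local[order[k - 1]]
    selected = order[local[order] >= cutoff]  # include ties at the cutoff

    selected_set = set(int(b) for b in selected)
    members: dict[str, tuple[str, ...]] = {}
    for sid, pts in zip(result.pair, (points_a, points_b)):
        bins = assign_bins(pts.coordinates, result.grid)
        members[sid] = tuple(
            seq for seq, b in zip(pts.sequences, bins) if int(b) in selected_set
        )
    return ContributingSet(result.pair, np.sort(selected), members, top_frac)


def bootstrap_significance(
    pdf_naive: DensityGrid,
    n_points: int,
    n_boot: int = 100,
    seed: int = 0,
    percentile: float = 99.0,
    bandwidth: float | None = None,
    jitter: bool = False,
    base: str = "nats",
) -> BootstrapResult:
    """Null JSD distribution of a sample against its own resampled density.

    Each replicate draws ``n_points`` bin locations from the naive
    density's discrete distribution, re-estimates a density by KDE from
    those points (same grid; naive bandwidth unless overridden), and
    records JSD(naive, re-estimated).  The configured percentile (default
    99th, linear interpolation between order statistics) of the replicate
    JSDs is the one-sided significance threshold: a pairwise naive JSD
    exceeding it differs from resampling noise at the 1% level.

    Resampled points sit at bin centers by default, where the density can
    be re-estimated by FFT convolution; ``jitter=True`` instead spreads
    each point uniformly within its bin and uses the exact tree
    evaluation.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    h = float(bandwidth if bandwidth is not None else pdf_naive.bandwidth)
    rng = np.random.default_rng(seed)
    grid = pdf_naive.grid
    flat = pdf_naive.flat
    kernel = None if jitter else BinnedKernel(grid, h)
    jsds = np.empty(n_boot)
    for b in range(n_boot):
        counts = rng.multinomial(n_points, flat)
        if jitter:
            occupied = np.flatnonzero(counts)
            reps = counts[occupied]
            multi = np.unravel_index(np.repeat(occupied, reps), grid.shape)
            pts = np.stack(
                [grid.centers(ax)[ix] for ax, ix in enumerate(multi)], axis=1
            )
            pts = pts + (rng.random(pts.shape) - 0.5) * grid.bin_widths
            re_pdf = estimate_pdf(pts, grid, h, sample_id=pdf_naive.sample_id)
        else:
            re_pdf = kernel.density(counts, sample_id=pdf_naive.sample_id)
        jsds[b] = jensen_shannon(pdf_naive, re_pdf, base).global_jsd
    threshold = float(np.percentile(jsds, percentile, method="linear"))
    return BootstrapResult(pdf_naive.sample_id, jsds, threshold, percentile)


def position_frequency_matrix(sequences: Sequence[str]) -> pd.DataFrame:
    """Per-position relative amino-acid frequencies of equal-length sequences.

    Returns a (length x 20) table whose rows sum to 1.  Sequences of mixed
    length must be grouped by length before calling (insertion/deletion
    variants are not aligned here).
    """
    from .repertoire import CANONICAL_AA

    seqs = list(sequences)
    if not seqs:
        raise ValueError("need at least one sequence")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(
            f"sequences have mixed lengths {sorted(lengths)}; group by length first"
        )
    length = lengths.pop()
    counts = np.zeros((length, len(CANONICAL_AA)))
    index = {a: i for i, a in enumerate(CANONICAL_AA)}
    for s in seqs:
        for pos, aa in enumerate(s):
            counts[pos, index[aa]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        freqs, index=np.arange(1, length + 1), columns=list(CANONICAL_AA)
    )
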