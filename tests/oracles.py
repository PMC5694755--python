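"""Independent reference implementations used only as test oracles.

Everything here is deliberately written from first principles — full-matrix
dynamic programs, heap Dijkstra, explicit agglomeration — and stays
independent of the package code paths it checks.
"""

from __future__ import annotations

import heapq
import math

import numpy as np


def sw_score_oracle(a, b, sub, index, gap_open, gap_extend, first_gap=None):
    """Plain full-matrix Smith-Waterman with affine gaps (Gotoh).

    ``first_gap`` is the cost of the first gapped residue (defaults to
    ``gap_open``, i.e. a gap of length L costs open + (L-1)*extend).
    """
    if first_gap is None:
        first_gap = gap_open
    n, m = len(a), len(b)
    neg = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[neg] * (m + 1) for _ in range(n + 1)]
    F = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first_gap, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first_gap, F[i - 1][j] - gap_extend)
            match = H[i - 1][j - 1] + sub[index[a[i - 1]]][index[b[j - 1]]]
            H[i][j] = max(0, match, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def dijkstra_oracle(weights: np.ndarray, source: int) -> np.ndarray:
    """Single-source shortest paths on a dense non-negative weight matrix
    (0 = no edge off the diagonal)."""
    n = weights.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    heap = [(0.0, source)]
    done = set()
    while heap:
        d, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in range(n):
            if v != u and weights[u, v] > 0:
                nd = d + weights[u, v]
                if nd < dist[v]:
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
    return dist


def ward_agglomeration_oracle(dist: np.ndarray):
    """Naive Ward agglomeration via the Lance-Williams recurrence.

    Returns a list of merges ``(frozenset_of_leaves_a, frozenset_of_leaves_b,
    height)`` in merge order, with ties broken by the lowest index pair.
    """
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = float(dist[i, j])
    sizes = {i: 1 for i in range(n)}
    merges = []
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                key = (min(i, j), max(i, j))
                if best is None or d[key] < best[0] - 1e-15:
                    best = (d[key], i, j)
        h, i, j = best
        merges.append((clusters[i], clusters[j], h))
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            dki = d[(min(i, k), max(i, k))]
            dkj = d[(min(j, k), max(j, k))]
            dij = h
            val = math.sqrt(
                ((ni + nk) * dki**2 + (nj + nk) * dkj**2 - nk * dij**2)
                / (ni + nj + nk)
            )
            d[(min(new, k), max(new, k))] = val
        clusters[new] = clusters[i] | clusters[j]
        sizes[new] = ni + nj
        active = [k for k in active if k not in (i, j)] + [new]
    return merges


def cophenetic_matrix_from_merges(merges, n: int) -> np.ndarray:
    """Cophenetic distances implied by an agglomeration trace."""
    coph = np.zeros((n, n))
    for left, right, h in merges:
        for i in left:
            for j in right:
                coph[i, j] = coph[j, i] = h
    return coph


def kde_brute_force(query: np.ndarray, points: np.ndarray, h: float,
                    weights=None) -> np.ndarray:
    """Unnormalized exponential-kernel sums by direct summation."""
    if weights is None:
        weights = np.ones(len(points))
    out = np.zeros(len(query))
    for q in range(len(query)):
        r = np.sqrt(((points - query[q]) ** 2).sum(axis=1))
        out[q] = float((weights * np.exp(-r / h)).sum())
    return out


def jsd_direct_oracle(p, q) -> float:
    """JSD by direct per-bin summation with math.log."""
    total = 0.0
    for pi, qi in zip(np.ravel(p), np.ravel(q)):
        mi = 0.5 * (pi + qi)
        if pi > 0:
            total += 0.5 * pi * math.log(pi / mi)
        if qi > 0:
            total += 0.5 * qi * math.log(qi / mi)
    return total
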