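"""Pairwise Smith-Waterman scoring and the length-adjusted dissimilarity.

The pipeline's first stage scores every pair of unique CDR3 sequences with
local alignment (affine gaps, a PAM or BLOSUM substitution matrix) and
converts the raw score matrix ``D`` into a dissimilarity matrix

    S[i, j] = 1 - 2 * D[i, j] / (D[i, i] + D[j, j]),

which removes the dependence of alignment scores on sequence length: two
identical sequences get S = 0 regardless of length, and a short sequence
aligned perfectly inside a longer one still gets S > 0 because the longer
sequence's self-score inflates the denominator.

Scores are computed with a plain quadratic Gotoh dynamic program; the inner
loops are JIT-compiled with numba, with a bit-identical pure-Python
fallback.  By default a gap of length L costs ``gap_open + (L - 1) *
gap_extend`` (the convention of striped-SW implementations); the
alternative ``gap_open + L * gap_extend`` convention can be selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from .repertoire import CANONICAL_AA, RepertoireValidationError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


__all__ = [
    "SUBSTITUTION_MATRICES",
    "AlignmentParams",
    "PairwiseScoreMatrix",
    "DissimilarityMatrix",
    "load_substitution_matrix",
    "encode_sequence",
    "smith_waterman_score",
    "pairwise_score_matrix",
    "dissimilarity_from_scores",
]

#: The ten substitution matrices supported for CDR3 scoring.
SUBSTITUTION_MATRICES = (
    "PAM30",
    "PAM100",
    "PAM120",
    "PAM160",
    "PAM250",
    "BLOSUM45",
    "BLOSUM50",
    "BLOSUM62",
    "BLOSUM80",
    "BLOSUM100",
)

_AA_INDEX = {a: i for i, a in enumerate(CANONICAL_AA)}


@lru_cache(maxsize=None)
def load_substitution_matrix(name: str) -> np.ndarray:
    """Load a named NCBI substitution matrix as a symmetric 20x20 int array
    over the canonical alphabet (alphabetical order)."""
    if name not in SUBSTITUTION_MATRICES:
        raise ValueError(
            f"unknown substitution matrix {name!r}; choose one of {SUBSTITUTION_MATRICES}"
        )
    from biotite.sequence import ProteinSequence
    from biotite.sequence.align import SubstitutionMatrix

    alph = ProteinSequence.alphabet
    full = SubstitutionMatrix(alph, alph, name).score_matrix()
    idx = np.array([alph.encode(a) for a in CANONICAL_AA])
    sub = np.ascontiguousarray(full[np.ix_(idx, idx)], dtype=np.int64)
    assert np.array_equal(sub, sub.T)
    return sub


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an amino-acid string as canonical-alphabet indices."""
    try:
        return np.array([_AA_INDEX[a] for a in seq], dtype=np.int64)
    except KeyError as exc:
        raise RepertoireValidationError(
            f"sequence {seq!r} contains non-canonical residue {exc.args[0]!r}"
        ) from None


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring parameters for local alignment.

    ``gap_open``/``gap_extend`` default to 10 and 1.  With the default
    ``"open-first"`` convention a gap of length L costs
    ``gap_open + (L - 1) * gap_extend``; with ``"open-plus-extend"`` it
    costs ``gap_open + L * gap_extend``.
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 10
    gap_extend: int = 1
    gap_convention: str = "open-first"

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_convention not in ("open-first", "open-plus-extend"):
            raise ValueError(f"unknown gap convention {self.gap_convention!r}")

    @property
    def scores(self) -> np.ndarray:
        return load_substitution_matrix(self.matrix)

    @property
    def first_gap_cost(self) -> int:
        """Cost of the first residue of a gap."""
        if self.gap_convention == "open-first":
            return self.gap_open
        return self.gap_open + self.gap_extend


@njit(cache=True)
def _sw_kernel(a, b, sub, first_gap, gap_extend):  # pragma: no cover - jitted
    n = a.shape[0]
    m = b.shape[0]
    h_prev = np.zeros(m + 1, dtype=np.int64)
    h_cur = np.zeros(m + 1, dtype=np.int64)
    f_prev = np.full(m + 1, np.iinfo(np.int64).min // 2, dtype=np.int64)
    f_cur = np.empty(m + 1, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        h_cur[0] = 0
        e = np.iinfo(np.int64).min // 2
        for j in range(1, m + 1):
            e = max(h_cur[j - 1] - first_gap, e - gap_extend)
            f = max(h_prev[j] - first_gap, f_prev[j] - gap_extend)
            f_cur[j] = f
            h = h_prev[j - 1] + sub[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
        f_prev, f_cur = f_cur, f_prev
    return best


@njit(cache=True)
def _sw_condensed(seqs, lengths, sub, first_gap, gap_extend):  # pragma: no cover
    n = seqs.shape[0]
    out = np.zeros(n * (n - 1) // 2, dtype=np.int64)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            out[k] = _sw_kernel(
                seqs[i, : lengths[i]], seqs[j, : lengths[j]], sub, first_gap, gap_extend
            )
            k += 1
    return out


def smith_waterman_score(a: str, b: str, params: AlignmentParams | None = None) -> int:
    """Maximum local-alignment score of two sequences under affine gaps.

    Symmetric in its sequence arguments and always non-negative (the empty
    alignment scores 0).
    """
    params = params or AlignmentParams()
    ea, eb = encode_sequence(a), encode_sequence(b)
    return int(
        _sw_kernel(ea, eb, params.scores, params.first_gap_cost, params.gap_extend)
    )


@dataclass(frozen=True)
class PairwiseScoreMatrix:
    """Symmetric Smith-Waterman score matrix over a set of unique sequences."""

    sequences: tuple[str, ...]
    scores: np.ndarray  # (N, N) int64
    params: AlignmentParams = field(default_factory=AlignmentParams)


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Length-adjusted dissimilarity: S = 1 - 2 D_ij / (D_ii + D_jj)."""

    sequences: tuple[str, ...]
    values: np.ndarray  # (N, N) float64, zero diagonal, symmetric

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")


def pairwise_score_matrix(
    sequences: Sequence[str], params: AlignmentParams | None = None
) -> PairwiseScoreMatrix:
    """Score all pairs (and self-alignments) of a list of unique sequences.

    Only the upper triangle is computed and mirrored.  Raises if the input
    contains duplicates: downstream stages require one point per unique
    sequence, so callers must deduplicate first.
    """
    params = params or AlignmentParams()
    sequences = tuple(sequences)
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    if len(set(sequences)) != len(sequences):
        raise ValueError("duplicate sequences in input; deduplicate before scoring")

    encoded = [encode_sequence(s) for s in sequences]
    lengths = np.array([len(e) for e in encoded], dtype=np.int64)
    packed = np.zeros((len(encoded), int(lengths.max())), dtype=np.int64)
    for i, e in enumerate(encoded):
        packed[i, : len(e)] = e

    sub = params.scores
    condensed = _sw_condensed(
        packed, lengths, sub, params.first_gap_cost, params.gap_extend
    )
    n = len(sequences)
    mat = np.zeros((n, n), dtype=np.int64)
    iu = np.triu_indices(n, k=1)
    mat[iu] = condensed
    mat = mat + mat.T
    # Self local alignments: with strictly positive diagonal substitution
    # scores the optimum is the full gapless self-match.
    diag = np.array([sub[e, e].sum() for e in encoded], dtype=np.int64)
    mat[np.diag_indices(n)] = diag
    return PairwiseScoreMatrix(sequences, mat, params)


def dissimilarity_from_scores(score_matrix: PairwiseScoreMatrix) -> DissimilarityMatrix:
    """Convert raw scores to the length-adjusted dissimilarity.

    ``S[i, j] = 1 - 2 D[i, j] / (D[i, i] + D[j, j])``; the diagonal is
    exactly zero and every entry is at most 1 (local scores are
    non-negative).
    """
    d = score_matrix.scores.astype(np.float64)
    diag = np.diag(d)
    if np.any(diag <= 0):
        bad = int(np.argmax(diag <= 0))
        raise FloatingPointError(
            f"sequence {score_matrix.sequences[bad]!r} has non-positive self-score; "
            "cannot normalize"
        )
    s = 1.0 - 2.0 * d / (diag[:, None] + diag[None, :])
    np.fill_diagonal(s, 0.0)
    return DissimilarityMatrix(score_matrix.sequences, s)
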