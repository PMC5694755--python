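"""Clonotype tables: reading, validation, subsampling and count-based statistics.

A *repertoire* is the collection of unique CDR3 amino-acid sequences
(clonotypes) observed in one sample together with their read counts.  This
module is the data entry point of the pipeline: it parses tab-separated
clonotype tables (a minimal two-column dialect and the MiXCR export dialect),
enforces the canonical 20-letter amino-acid alphabet, and provides the
count-based operations used elsewhere: inverse-CDF subsampling to a target
read depth, read-depth equalization across samples, and the classical
overlap / Bray-Curtis baseline statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_AA",
    "Clonotype",
    "Repertoire",
    "RepertoireFormatError",
    "RepertoireValidationError",
    "read_clonotype_table",
    "write_clonotype_table",
    "subsample_repertoire",
    "equalize_read_depth",
    "overlap_fraction",
    "bray_curtis",
]

#: The 20 canonical amino acids, alphabetically ordered.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)


class RepertoireFormatError(ValueError):
    """A clonotype table does not conform to the requested dialect."""


class RepertoireValidationError(ValueError):
    """A clonotype violates the sequence/count invariants."""


def _validate_sequence(seq: str, context: str = "") -> None:
    if not isinstance(seq, str) or len(seq) == 0:
        raise RepertoireValidationError(f"empty or non-string sequence{context}")
    bad = set(seq) - _CANONICAL_SET
    if bad:
        raise RepertoireValidationError(
            f"sequence {seq!r}{context} contains non-canonical residues "
            f"{sorted(bad)}; only the 20 canonical uppercase amino acids are allowed"
        )


@dataclass(frozen=True)
class Clonotype:
    """A unique CDR3 amino-acid sequence with its observed read count."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        _validate_sequence(self.sequence)
        if not isinstance(self.count, (int, np.integer)) or self.count < 1:
            raise RepertoireValidationError(
                f"count for {self.sequence!r} must be a positive integer, got {self.count!r}"
            )


@dataclass(frozen=True)
class Repertoire:
    """One sample's unique clonotypes.

    Sequences are unique within a repertoire; ``total_reads`` always equals
    the sum of counts.
    """

    sample_id: str
    clonotypes: tuple[Clonotype, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.clonotypes) == 0:
            raise RepertoireValidationError(
                f"repertoire {self.sample_id!r} has no clonotypes"
            )
        seqs = [c.sequence for c in self.clonotypes]
        if len(set(seqs)) != len(seqs):
            raise RepertoireValidationError(
                f"repertoire {self.sample_id!r} contains duplicate sequences"
            )

    @classmethod
    def from_counts(cls, sample_id: str, counts: Mapping[str, int]) -> "Repertoire":
        return cls(
            sample_id,
            tuple(Clonotype(s, int(c)) for s, c in counts.items()),
        )

    @property
    def sequences(self) -> tuple[str, ...]:
        return tuple(c.sequence for c in self.clonotypes)

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.count for c in self.clonotypes], dtype=np.int64)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    @property
    def n_unique(self) -> int:
        return len(self.clonotypes)

    def frequencies(self) -> np.ndarray:
        """Relative clone frequencies (counts / total reads)."""
        c = self.counts
        return c / c.sum()

    def as_dict(self) -> dict[str, int]:
        return {c.sequence: c.count for c in self.clonotypes}


# ---------------------------------------------------------------------------
# Table input / output
# ---------------------------------------------------------------------------

#: Header names accepted for the MiXCR tab-separated export, across versions.
MIXCR_AA_COLUMNS = ("aaSeqCDR3", "AA. Seq. CDR3", "AA. Seq.CDR3", "aaSeqImputedCDR3")
MIXCR_COUNT_COLUMNS = ("cloneCount", "Clone count", "readCount", "Read count")


def _pick_column(df: pd.DataFrame, candidates: Sequence[str], what: str) -> str:
    for name in candidates:
        if name in df.columns:
            return name
    raise RepertoireFormatError(
        f"missing {what} column; expected one of {list(candidates)}, "
        f"found {list(df.columns)}"
    )


def read_clonotype_table(
    path: str | Path,
    dialect: str = "simple",
    sample_id: str | None = None,
    aa_column: str | None = None,
    count_column: str | None = None,
) -> Repertoire:
    """Read a tab-separated clonotype table into a :class:`Repertoire`.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"simple"`` expects columns ``sequence`` and ``count``;
        ``"mixcr-export"`` expects the amino-acid CDR3 and clone-count
        columns of MiXCR's tab-separated export (exact header names vary by
        MiXCR version and may be overridden with *aa_column* /
        *count_column*).
    sample_id:
        Label for the sample; defaults to the file stem.

    Rows with identical amino-acid sequences are merged by summing counts.
    """
    path = Path(path)
    if dialect not in ("simple", "mixcr-export"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "simple":
        seq_col = aa_column or "sequence"
        cnt_col = count_column or "count"
        for col in (seq_col, cnt_col):
            if col not in df.columns:
                raise RepertoireFormatError(
                    f"{path.name}: missing required column {col!r} "
                    f"(found {list(df.columns)})"
                )
    else:
        seq_col = aa_column or _pick_column(df, MIXCR_AA_COLUMNS, "amino-acid CDR3")
        cnt_col = count_column or _pick_column(df, MIXCR_COUNT_COLUMNS, "clone count")

    if len(df) == 0:
        raise RepertoireValidationError(f"{path.name}: table contains no clonotypes")

    merged: dict[str, int] = {}
    for i, (seq, cnt) in enumerate(zip(df[seq_col], df[cnt_col])):
        if not isinstance(seq, str):
            raise RepertoireValidationError(f"{path.name} row {i}: missing sequence")
        _validate_sequence(seq, context=f" ({path.name} row {i})")
        try:
            # MiXCR writes clone counts as floats ("12.0")
            c = int(float(cnt))
        except (TypeError, ValueError):
            raise RepertoireValidationError(
                f"{path.name} row {i}: unparseable count {cnt!r}"
            ) from None
        if c < 1:
            raise RepertoireValidationError(
                f"{path.name} row {i}: count must be >= 1, got {c}"
            )
        merged[seq] = merged.get(seq, 0) + c

    return Repertoire.from_counts(sample_id or path.stem, merged)


def write_clonotype_table(rep: Repertoire, path: str | Path) -> None:
    """Serialize a repertoire in the simple dialect (sequence<TAB>count)."""
    df = pd.DataFrame({"sequence": rep.sequences, "count": rep.counts})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------

def subsample_repertoire(rep: Repertoire, n_target: int, seed: int) -> Repertoire:
    """Resample a repertoire to ``n_target`` total reads.

    Draws ``n_target`` reads from the clone relative-frequency distribution
    by inverse-CDF sampling (equivalently, a multinomial draw over clones).
    Clones that receive zero draws are dropped, so the output contains only
    observed unique sequences.  Deterministic given *seed*.
    """
    if n_target < 1:
        raise ValueError(f"n_target must be >= 1, got {n_target}")
    rng = np.random.default_rng(seed)
    drawn = rng.multinomial(n_target, rep.frequencies())
    keep = drawn > 0
    return Repertoire(
        rep.sample_id,
        tuple(
            Clonotype(s, int(c))
            for s, c in zip(np.asarray(rep.sequences)[keep], drawn[keep])
        ),
    )


def equalize_read_depth(reps: Sequence[Repertoire], seed: int) -> list[Repertoire]:
    """Subsample every repertoire down to the minimum total read depth.

    Repertoires already at the minimum depth are returned unchanged; the
    others are resampled with :func:`subsample_repertoire` using
    independent streams derived from *seed*.
    """
    if len(reps) < 2:
        raise ValueError("equalize_read_depth requires at least 2 repertoires")
    depths = [r.total_reads for r in reps]
    n_min = min(depths)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(reps)) % (2**31)
    out = []
    for r, d, s in zip(reps, depths, child_seeds):
        out.append(r if d == n_min else subsample_repertoire(r, n_min, int(s)))
    return out


# ---------------------------------------------------------------------------
# Count-based baseline statistics
# ---------------------------------------------------------------------------

def overlap_fraction(rep_a: Repertoire, rep_b: Repertoire) -> tuple[float, int, int]:
    """Fraction of unique sequences shared by two repertoires.

    Returns ``(n_shared / n_union, n_shared, n_union)`` over the two
    samples' unique sequence sets.
    """
    sa, sb = set(rep_a.sequences), set(rep_b.sequences)
    shared = len(sa & sb)
    union = len(sa | sb)
    return shared / union, shared, union


def bray_curtis(rep_a: Repertoire, rep_b: Repertoire) -> float:
    """Bray-Curtis dissimilarity between two repertoires' count vectors.

    ``BC = 1 - 2 * C / (N_A + N_B)`` where ``C`` sums, over sequences shared
    by both samples, the smaller of the two counts.
    """
    ca, cb = rep_a.as_dict(), rep_b.as_dict()
    c = sum(min(ca[s], cb[s]) for s in ca.keys() & cb.keys())
    return 1.0 - 2.0 * c / (rep_a.total_reads + rep_b.total_reads)


def union_sequences(reps: Iterable[Repertoire]) -> tuple[str, ...]:
    """Sorted union of unique sequences across samples (the pipeline's
    global sequence ordering)."""
    out: set[str] = set()
    for r in reps:
        out.update(r.sequences)
    return tuple(sorted(out))


def membership_table(reps: Sequence[Repertoire], sequences: Sequence[str]) -> pd.DataFrame:
    """Boolean table (sequence x sample) flagging which samples contain
    each sequence."""
    data = {
        r.sample_id: [s in set(r.sequences) for s in sequences] for r in reps
    }
    return pd.DataFrame(data, index=list(sequences))
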