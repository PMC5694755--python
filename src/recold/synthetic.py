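"""Synthetic CDR3 repertoires with controlled motif structure.

Real CDR3 amino-acid sequences share a conserved anatomy — a cysteine-led
prefix and an F/W-containing suffix flanking a hypervariable core — and
samples differ in which motif *families* they draw from and with what
mixture weights.  This generator emulates exactly that: a
:class:`MotifFamily` is a template with designated variable positions that
are stochastically substituted (and optionally hit by a single
insertion/deletion), and a :class:`SyntheticDesign` assigns each sample a
mixture over families, a number of unique sequences, and a heavy-tailed
(discrete power-law) clone-count distribution.

Families with different lengths or fixed regions occupy disjoint sequence
spaces, which gives exact control over inter-sample divergence: samples
sharing mixture weights are statistically exchangeable, while mass moved
onto a family absent from another sample creates a planted, recoverable
difference.  Everything is deterministic given the design seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .repertoire import CANONICAL_AA, Clonotype, Repertoire

__all__ = [
    "MotifFamily",
    "SampleSpec",
    "SyntheticDesign",
    "generate_repertoires",
    "planted_difference_design",
    "hierarchy_design",
    "default_base_family",
    "default_exclusive_family",
]

_MAX_COUNT = 10_000  # truncation of the power-law clone-count draw


@dataclass(frozen=True)
class MotifFamily:
    """A CDR3 motif family: fixed flanks around variable core positions.

    Each variable position is substituted (uniformly among the 19 other
    residues) with probability ``substitution_rate`` per draw; with
    probability ``indel_prob`` a single residue is inserted at or deleted
    from a random interior position, mimicking junctional length
    variation.
    """

    name: str
    template: str
    variable_positions: tuple[int, ...]
    substitution_rate: float = 0.5
    indel_prob: float = 0.0

    def __post_init__(self) -> None:
        if not set(self.template) <= set(CANONICAL_AA):
            raise ValueError(f"template {self.template!r} has non-canonical residues")
        if any(p < 0 or p >= len(self.template) for p in self.variable_positions):
            raise ValueError("variable positions out of template range")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must be in [0, 1]")
        if not 0 <= self.indel_prob <= 1:
            raise ValueError("indel_prob must be in [0, 1]")

    @property
    def space_size(self) -> int:
        """Number of distinct sequences reachable by substitution alone."""
        if self.substitution_rate == 0:
            return 1
        return len(CANONICAL_AA) ** len(self.variable_positions)

    def draw(self, rng: np.random.Generator) -> str:
        seq = list(self.template)
        for p in self.variable_positions:
            if self.substitution_rate and rng.random() < self.substitution_rate:
                alternatives = [a for a in CANONICAL_AA if a != self.template[p]]
                seq[p] = alternatives[rng.integers(len(alternatives))]
        if self.indel_prob and rng.random() < self.indel_prob and len(seq) > 3:
            pos = int(rng.integers(1, len(seq) - 1))
            if rng.random() < 0.5:
                seq.insert(pos, CANONICAL_AA[rng.integers(len(CANONICAL_AA))])
            else:
                del seq[pos]
        return "".join(seq)


@dataclass(frozen=True)
class SampleSpec:
    """One synthetic sample: a family mixture plus count-distribution knobs."""

    sample_id: str
    weights: Mapping[str, float]
    n_unique: int = 200
    count_alpha: float = 2.5  # discrete power-law exponent of clone sizes

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(
                f"mixture weights of {self.sample_id!r} sum to {total}, not 1"
            )
        if self.n_unique < 1:
            raise ValueError("n_unique must be >= 1")
        if self.count_alpha <= 1:
            raise ValueError("count_alpha must exceed 1")


@dataclass(frozen=True)
class SyntheticDesign:
    """Full specification of a synthetic multi-sample experiment."""

    families: tuple[MotifFamily, ...]
    samples: tuple[SampleSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        names = [f.name for f in self.families]
        if len(set(names)) != len(names):
            raise ValueError("family names must be unique")
        for spec in self.samples:
            unknown = set(spec.weights) - set(names)
            if unknown:
                raise ValueError(
                    f"sample {spec.sample_id!r} references unknown families {unknown}"
                )

    def family(self, name: str) -> MotifFamily:
        return next(f for f in self.families if f.name == name)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "families": [
                {
                    "name": f.name,
                    "template": f.template,
                    "variable_positions": list(f.variable_positions),
                    "substitution_rate": f.substitution_rate,
                    "indel_prob": f.indel_prob,
                }
                for f in self.families
            ],
            "samples": [
                {
                    "sample_id": s.sample_id,
                    "weights": dict(s.weights),
                    "n_unique": s.n_unique,
                    "count_alpha": s.count_alpha,
                }
                for s in self.samples
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticDesign":
        return cls(
            families=tuple(
                MotifFamily(
                    f["name"],
                    f["template"],
                    tuple(f["variable_positions"]),
                    f.get("substitution_rate", 0.5),
                    f.get("indel_prob", 0.0),
                )
                for f in data["families"]
            ),
            samples=tuple(
                SampleSpec(
                    s["sample_id"],
                    s["weights"],
                    s.get("n_unique", 200),
                    s.get("count_alpha", 2.5),
                )
                for s in data["samples"]
            ),
            seed=data.get("seed", 0),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticDesign":
        return cls.from_dict(json.loads(text))


def _draw_counts(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    counts = rng.zipf(alpha, size=n)
    return np.minimum(counts, _MAX_COUNT).astype(np.int64)


def generate_repertoires(design: SyntheticDesign) -> list[Repertoire]:
    """Materialize every sample of a design as a :class:`Repertoire`.

    Unique sequences are drawn by rejection from the sample's family
    mixture until ``n_unique`` distinct sequences are collected; counts are
    independent truncated power-law draws.  Deterministic given
    ``design.seed``; samples use independent sub-streams, so samples with
    identical specs are exchangeable but not identical.
    """
    streams = np.random.SeedSequence(design.seed).spawn(len(design.samples))
    out = []
    for spec, ss in zip(design.samples, streams):
        rng = np.random.default_rng(ss)
        names = sorted(spec.weights)
        probs = np.array([spec.weights[n] for n in names])
        capacity = sum(
            design.family(n).space_size
            for n, w in zip(names, probs)
            if w > 0 and design.family(n).indel_prob == 0
        )
        has_indels = any(
            design.family(n).indel_prob > 0 for n, w in zip(names, probs) if w > 0
        )
        if not has_indels and capacity < spec.n_unique:
            raise ValueError(
                f"sample {spec.sample_id!r} requests {spec.n_unique} unique "
                f"sequences but its families can produce only {capacity}"
            )
        seqs: list[str] = []
        seen: set[str] = set()
        attempts = 0
        max_attempts = 500 * spec.n_unique
        while len(seqs) < spec.n_unique:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"sample {spec.sample_id!r}: could not draw {spec.n_unique} "
                    f"distinct sequences in {max_attempts} attempts; the design "
                    "is too close to its family space size"
                )
            fam = design.family(names[rng.choice(len(names), p=probs)])
            s = fam.draw(rng)
            if s not in seen:
                seen.add(s)
                seqs.append(s)
        counts = _draw_counts(rng, spec.n_unique, spec.count_alpha)
        out.append(
            Repertoire(
                spec.sample_id,
                tuple(Clonotype(s, int(c)) for s, c in zip(seqs, counts)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Canonical designs
# ---------------------------------------------------------------------------

def default_base_family() -> MotifFamily:
    """Length-11 family patterned on a conserved C...YQLIWG CDR3 motif.

    Two variable core positions: generated sequences differ from the
    consensus at no more than two residues, the neighborhood structure
    typical of motif-sharing CDR3 groups.
    """
    return MotifFamily("base", "CAASNYQLIWG", (3, 4), substitution_rate=0.5)


def default_exclusive_family() -> MotifFamily:
    """Length-16 family with a distinct suffix, disjoint from the base
    family's sequence space."""
    return MotifFamily("exclusive", "CAASNTGGLSGKLTFG", (4, 5), substitution_rate=0.5)


def planted_difference_design(
    base: MotifFamily | None = None,
    exclusive: MotifFamily | None = None,
    exclusivity: float = 1.0,
    n_unique: int = 200,
    seed: int = 0,
    n_reference: int = 1,
) -> SyntheticDesign:
    """Two-sample design with a planted, sample-exclusive motif family.

    Sample ``planted`` draws an ``exclusivity`` fraction of its sequences
    from the exclusive family, which is absent from the ``reference``
    sample(s); the remaining mass comes from the shared base family.
    Additional exchangeable reference samples can be requested (for null
    comparisons).
    """
    if not 0 < exclusivity <= 1:
        raise ValueError("exclusivity must be in (0, 1]")
    base = base or default_base_family()
    exclusive = exclusive or default_exclusive_family()
    planted_weights = (
        {exclusive.name: exclusivity, base.name: 1.0 - exclusivity}
        if exclusivity < 1
        else {exclusive.name: 1.0}
    )
    samples = [SampleSpec("planted", planted_weights, n_unique)]
    for i in range(n_reference):
        sid = "reference" if n_reference == 1 else f"reference{i + 1}"
        samples.append(SampleSpec(sid, {base.name: 1.0}, n_unique))
    return SyntheticDesign((base, exclusive), tuple(samples), seed)


def hierarchy_design(n_unique: int = 150, seed: int = 0) -> SyntheticDesign:
    """Eight samples in a planted three-level hierarchy.

    Two binary factors of decreasing effect are stacked on a dominant
    genotype-like split: genotype selects which of two disjoint families
    carries 0.55 of the mixture, a cell-type-like factor moves 0.25 onto a
    modifier family, and a donor-site-like factor moves 0.10 onto another.
    The induced pairwise divergences are ordered site < cell type <
    genotype, so cutting the dendrogram at 2, 4, and 8 clusters should
    recover genotype, genotype x cell type, and the individual samples.
    """
    families = (
        MotifFamily("geno1", "CAASNYQLIWG", (3, 4), 0.5),
        MotifFamily("geno2", "CAAMDSNYQLIW", (4, 5), 0.5),
        MotifFamily("celltype", "CAASAWDSNYQLG", (5, 6), 0.5),
        MotifFamily("site", "CAASNTGGLSGKLTF", (6, 7), 0.5),
        MotifFamily("shared", "CAVSAGGSNYKLTFGK", (4, 5), 0.5),
    )
    samples = []
    for geno in ("A", "B"):
        for cell in ("TN", "TR"):
            for site in ("Thy", "Per"):
                w = {
                    "geno1" if geno == "A" else "geno2": 0.55,
                    "celltype": 0.25 if cell == "TR" else 0.0,
                    "site": 0.10 if site == "Per" else 0.0,
                }
                w["shared"] = 1.0 - sum(w.values())
                w = {k: v for k, v in w.items() if v > 0}
                samples.append(SampleSpec(f"{geno}{cell}-{site}", w, n_unique))
    return SyntheticDesign(families, tuple(samples), seed)
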