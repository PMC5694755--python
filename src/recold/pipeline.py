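"""End-to-end orchestration of the repertoire-comparison pipeline.

The five stages — alignment dissimilarity, embedding, density estimation,
divergence/significance, clustering — are run in order from a single
:class:`PipelineConfig`, with every stochastic stage seeded explicitly.
``run_pipeline`` returns all intermediate objects in memory and, when an
output directory is configured, serializes each stage's artifact as
tab-separated text (Newick for the dendrogram) plus a run log of the
effective parameters.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (
    AlignmentParams,
    DissimilarityMatrix,
    dissimilarity_from_scores,
    pairwise_score_matrix,
)
from .clustering import Dendrogram, cophenetic_correlation, to_newick, ward_linkage
from .density import DensityGrid, estimate_pdf, make_grid, optimize_bandwidth
from .divergence import (
    BootstrapResult,
    ContributingSet,
    JsdResult,
    bootstrap_significance,
    contributing_sequences,
    jensen_shannon,
)
from .embedding import EmbeddedPoints, EmbeddingConfig, embed
from .repertoire import (
    Repertoire,
    equalize_read_depth,
    membership_table,
    read_clonotype_table,
    union_sequences,
    write_clonotype_table,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of a pipeline run.

    Defaults follow the method's canonical settings: BLOSUM62 scoring with
    gap penalties 10/1, MDS embedding in two dimensions (deterministic up
    to rigid motion), a 400-bin-per-axis grid, cross-validated exponential
    KDE bandwidth, top-1% contributing bins, and a 100-replicate bootstrap
    judged at the 99th percentile under Ward clustering.
    """

    # stage 1: alignment
    matrix: str = "BLOSUM62"
    gap_open: int = 10
    gap_extend: int = 1
    # stage 2: embedding
    method: str = "mds"
    dim: int = 2
    k_neighbors: int = 10
    perplexity: float = 30.0
    # stage 3: density
    bins: int = 400
    bandwidth: float | None = None  # None -> per-sample ML cross-validation
    cv_folds: int = 5
    weighted: bool = False  # weight KDE points by clone counts
    # stage 4: divergence
    top_frac: float = 0.01
    n_boot: int = 100
    percentile: float = 99.0
    bootstrap_n: str = "match"  # "match" | "reads" | "unique"
    # stage 5: clustering
    linkage: str = "ward"
    # global
    seed: int = 0
    equalize_depth: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.bootstrap_n not in ("match", "reads", "unique"):
            raise ValueError("bootstrap_n must be 'match', 'reads' or 'unique'")

    # flat key=value round-trip ------------------------------------------------

    def to_text(self) -> str:
        lines = []
        for k, v in asdict(self).items():
            lines.append(f"{k} = {'' if v is None else v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PipelineConfig":
        defaults = cls()
        kwargs = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if not hasattr(defaults, key):
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(defaults, key)
            if raw == "":
                kwargs[key] = None
            elif isinstance(default, bool):
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(raw)
            elif isinstance(default, float) or key == "bandwidth":
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Everything a pipeline run computed, stage by stage."""

    config: PipelineConfig
    repertoires: list[Repertoire]
    dissimilarity: DissimilarityMatrix
    points: EmbeddedPoints
    membership: pd.DataFrame
    pdfs: dict[str, DensityGrid]
    jsd_matrix: pd.DataFrame
    jsd_results: dict[tuple[str, str], JsdResult]
    contributing: dict[tuple[str, str], ContributingSet]
    bootstraps: dict[str, BootstrapResult]
    significance: pd.DataFrame
    dendrogram: Dendrogram | None
    cophenetic: float | None

    def sample_points(self, sample_id: str) -> EmbeddedPoints:
        """The embedded points restricted to one sample's sequences."""
        mask = self.membership[sample_id].to_numpy()
        return EmbeddedPoints(
            tuple(np.asarray(self.points.sequences)[mask]),
            self.points.coordinates[mask],
            self.points.method,
            {"sample_id": sample_id},
        )


def _derive_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(
    config: PipelineConfig,
    repertoires: Sequence[Repertoire] | None = None,
    inputs: Sequence[str | Path] | None = None,
) -> PipelineResult:
    """Run all five stages on the given repertoires (or clonotype tables).

    Exactly one of *repertoires* / *inputs* must be provided.  With
    ``config.out_dir`` set, stage artifacts are written there as they are
    produced.
    """
    if (repertoires is None) == (inputs is None):
        raise ValueError("provide exactly one of repertoires or inputs")
    if inputs is not None:
        repertoires = [read_clonotype_table(p) for p in inputs]
    reps = list(repertoires)
    if len(reps) < 2:
        raise ValueError("pipeline needs at least 2 samples")
    ids = [r.sample_id for r in reps]
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")

    seeds = _derive_seeds(config.seed, 4 + len(reps))
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    if config.equalize_depth:
        reps = equalize_read_depth(reps, seed=seeds[0])
        if out:
            for r in reps:
                write_clonotype_table(r, out / f"equalized_{r.sample_id}.tsv")

    # stage 1: dissimilarity ------------------------------------------------
    sequences = union_sequences(reps)
    params = AlignmentParams(config.matrix, config.gap_open, config.gap_extend)
    s = dissimilarity_from_scores(pairwise_score_matrix(sequences, params))
    membership = membership_table(reps, sequences)
    if out:
        pd.DataFrame(s.values, index=sequences, columns=sequences).to_csv(
            out / "dissimilarity.tsv", sep="\t"
        )

    # stage 2: embedding ----------------------------------------------------
    ecfg = EmbeddingConfig(
        method=config.method,
        dim=config.dim,
        k_neighbors=config.k_neighbors,
        perplexity=min(config.perplexity, max(2.0, (len(sequences) - 1) / 3.0)),
        seed=seeds[1],
    )
    points = embed(s, ecfg)
    if out:
        coords = pd.DataFrame(
            points.coordinates,
            index=sequences,
            columns=[f"x{i + 1}" for i in range(config.dim)],
        )
        pd.concat([coords, membership.astype(int)], axis=1).to_csv(
            out / "embedding.tsv", sep="\t"
        )

    # stage 3: densities ----------------------------------------------------
    grid = make_grid(points.coordinates, bins=config.bins)
    pdfs: dict[str, DensityGrid] = {}
    for r, cv_seed in zip(reps, seeds[4:]):
        mask = membership[r.sample_id].to_numpy()
        coords = points.coordinates[mask]
        if config.bandwidth is not None:
            h = config.bandwidth
        else:
            h = optimize_bandwidth(coords, folds=config.cv_folds, seed=cv_seed)
        weights = None
        if config.weighted:
            counts = r.as_dict()
            weights = np.array(
                [counts[q] for q in np.asarray(sequences)[mask]], dtype=float
            )
        pdfs[r.sample_id] = estimate_pdf(coords, grid, h, weights, r.sample_id)
    if out:
        _write_pdfs(pdfs, out / "densities.tsv")

    # stage 4: divergence ---------------------------------------------------
    jsd_results: dict[tuple[str, str], JsdResult] = {}
    n = len(reps)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = jensen_shannon(pdfs[ids[i]], pdfs[ids[j]])
            jsd_results[(ids[i], ids[j])] = res
            mat[i, j] = mat[j, i] = res.global_jsd
    jsd_matrix = pd.DataFrame(mat, index=ids, columns=ids)
    if out:
        jsd_matrix.to_csv(out / "jsd.tsv", sep="\t")

    result = PipelineResult(
        config, reps, s, points, membership, pdfs, jsd_matrix, jsd_results,
        {}, {}, pd.DataFrame(), None, None,
    )

    contributing: dict[tuple[str, str], ContributingSet] = {}
    for (a, b), res in jsd_results.items():
        contributing[(a, b)] = contributing_sequences(
            res, result.sample_points(a), result.sample_points(b), config.top_frac
        )
    result.contributing = contributing
    if out:
        frames = []
        for (a, b), cs in contributing.items():
            f = cs.to_frame()
            f.insert(0, "pair", f"{a}|{b}")
            frames.append(f)
        pd.concat(frames, ignore_index=True).to_csv(
            out / "contributing.tsv", sep="\t", index=False
        )

    bootstraps: dict[str, BootstrapResult] = {}
    if config.n_boot >= 2:
        boot_seeds = _derive_seeds(seeds[2], n)
        for r, bs in zip(reps, boot_seeds):
            if config.bootstrap_n == "reads":
                n_pts = r.total_reads
            elif config.bootstrap_n == "unique":
                n_pts = r.n_unique
            else:  # match the naive estimator's point count
                n_pts = r.total_reads if config.weighted else r.n_unique
            bootstraps[r.sample_id] = bootstrap_significance(
                pdfs[r.sample_id],
                n_points=n_pts,
                n_boot=config.n_boot,
                seed=bs,
                percentile=config.percentile,
            )
        sig = pd.DataFrame(False, index=ids, columns=ids)
        for i in range(n):
            for j in range(n):
                if i != j:
                    thr = max(bootstraps[ids[i]].threshold, bootstraps[ids[j]].threshold)
                    sig.iloc[i, j] = bool(mat[i, j] > thr)
        result.bootstraps = bootstraps
        result.significance = sig
        if out:
            rows = [
                {
                    "sample": sid,
                    "threshold": br.threshold,
                    "percentile": br.percentile,
                    "n_boot": len(br.jsd_samples),
                    "median_null_jsd": float(np.median(br.jsd_samples)),
                }
                for sid, br in bootstraps.items()
            ]
            pd.DataFrame(rows).to_csv(out / "bootstrap.tsv", sep="\t", index=False)
            sig.to_csv(out / "significance.tsv", sep="\t")

    # stage 5: clustering ---------------------------------------------------
    dendrogram = None
    ccc = None
    if n >= 3:
        dendrogram = ward_linkage(jsd_matrix, method=config.linkage)
        try:
            ccc = cophenetic_correlation(jsd_matrix, dendrogram)
        except ValueError:
            ccc = None
        if out:
            pd.DataFrame(
                dendrogram.linkage, columns=["left", "right", "height", "size"]
            ).to_csv(out / "linkage.tsv", sep="\t", index=False)
            (out / "dendrogram.nwk").write_text(to_newick(dendrogram) + "\n")
    result.dendrogram = dendrogram
    result.cophenetic = ccc

    if out:
        log = {
            "recold_version": __version__,
            "config": {k: v for k, v in asdict(config).items()},
            "derived_seeds": seeds,
            "samples": {
                r.sample_id: {"n_unique": r.n_unique, "total_reads": r.total_reads}
                for r in reps
            },
            "n_union_sequences": len(sequences),
            "bandwidths": {sid: p.bandwidth for sid, p in pdfs.items()},
            "cophenetic_correlation": ccc,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2) + "\n")
    return result


def _write_pdfs(pdfs: dict[str, DensityGrid], path: Path) -> None:
    with open(path, "w") as fh:
        first = next(iter(pdfs.values()))
        for ax in range(first.grid.ndim):
            edges = ",".join(f"{e:.10g}" for e in first.grid.edges[ax])
            fh.write(f"# axis{ax}_edges\t{edges}\n")
        for sid, p in pdfs.items():
            fh.write(f"# bandwidth\t{sid}\t{p.bandwidth:.10g}\n")
        df = pd.DataFrame({sid: p.flat for sid, p in pdfs.items()})
        df.to_csv(fh, sep="\t", index_label="bin")
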