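"""Seeded generators of synthetic expression data with planted structure.

The generator emulates the shape of a multi-publication expression
compendium: several experiment blocks of a few conditions each, planted
co-expression clusters shared across blocks, per-gene observation noise,
missing values, and heterogeneous dynamic range across experiments (some
blocks span a wide range of values, others a narrow one), so that every
pipeline stage — normalization, map training, enrichment, spatial tests —
is exercisable without any real dataset.  No attempt is made to reproduce
real measurement values or array physics.

All randomness flows from one seed through named sub-streams
(archetypes / noise / mask / annotation), so adding draws to one stage
never shifts another stage's stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ExprMapError
from .io_formats import AnnotationTable, ExpressionMatrix

_STREAMS = {"archetypes": 0, "noise": 1, "mask": 2, "annotation": 3}

#: Default per-experiment scale factors: a wide-range block, two mid-range
#: blocks and a narrow one, cycling if there are more blocks than factors.
DEFAULT_RANGE_MULTIPLIERS = (2.0, 1.0, 0.5, 1.5)


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, 100 + _STREAMS[name]]))


@dataclass
class SyntheticSpec:
    """Parameters of the generative model.

    Each of ``n_clusters`` archetypes is a condition-length vector of
    independent N(0, cluster_sd²) draws, scaled per experiment block by its
    dynamic-range multiplier; each gene is its cluster's archetype plus
    independent N(0, noise_sd²) noise, with entries masked missing at
    ``missing_rate``.  Genes are assigned to clusters round-robin, so
    cluster sizes are balanced.  Defaults give 2000 genes in 10 clusters
    over 4 experiment blocks totalling 20 conditions, noise at 0.3× the
    archetype spread, and 5% missing values.
    """

    n_genes: int = 2000
    experiment_blocks: tuple[tuple[str, int], ...] = (
        ("exp1", 8), ("exp2", 6), ("exp3", 4), ("exp4", 2),
    )
    n_clusters: int = 10
    cluster_sd: float = 1.0
    noise_sd: float = 0.3
    missing_rate: float = 0.05
    dynamic_range_multipliers: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters > self.n_genes:
            raise ExprMapError("n_clusters must not exceed n_genes")
        if min(self.cluster_sd, self.noise_sd) < 0:
            raise ExprMapError("standard deviations must be non-negative")
        if not (0 <= self.missing_rate < 1):
            raise ExprMapError("missing_rate must be in [0, 1)")
        if not self.experiment_blocks or any(n < 1 for _, n in self.experiment_blocks):
            raise ExprMapError("each experiment block needs ≥ 1 condition")

    @property
    def n_conditions(self) -> int:
        return sum(n for _, n in self.experiment_blocks)

    def multipliers(self) -> list[float]:
        base = self.dynamic_range_multipliers or DEFAULT_RANGE_MULTIPLIERS
        return [base[i % len(base)] for i in range(len(self.experiment_blocks))]


@dataclass
class SyntheticTruth:
    """Planted ground truth: gene → cluster id and the archetype matrix."""

    cluster_of: dict[str, int]
    archetypes: np.ndarray  # (n_clusters, n_conditions)

    def genes_of_cluster(self, cluster: int) -> list[str]:
        return [g for g, c in self.cluster_of.items() if c == cluster]


def generate_matrix(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw an expression matrix with planted clusters. Deterministic per seed."""
    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    condition_ids: list[str] = []
    experiment_of: dict[str, str] = {}
    cond_mult = np.empty(spec.n_conditions)
    j = 0
    for (exp, n_cond), mult in zip(spec.experiment_blocks, spec.multipliers()):
        for i in range(n_cond):
            cond = f"{exp}_c{i}"
            condition_ids.append(cond)
            experiment_of[cond] = exp
            cond_mult[j] = mult
            j += 1

    arch_rng = _stream(spec.seed, "archetypes")
    archetypes = arch_rng.normal(0.0, spec.cluster_sd,
                                 size=(spec.n_clusters, spec.n_conditions))
    archetypes *= cond_mult  # per-experiment dynamic range

    cluster_idx = np.arange(spec.n_genes) % spec.n_clusters
    noise_rng = _stream(spec.seed, "noise")
    values = archetypes[cluster_idx] + noise_rng.normal(
        0.0, spec.noise_sd, size=(spec.n_genes, spec.n_conditions))

    mask_rng = _stream(spec.seed, "mask")
    if spec.missing_rate > 0:
        missing = mask_rng.random(values.shape) < spec.missing_rate
        # no gene may lose every value: redraw fully-masked rows
        bad = np.nonzero(missing.all(axis=1))[0]
        while bad.size:
            missing[bad] = mask_rng.random((bad.size, spec.n_conditions)) < spec.missing_rate
            bad = bad[missing[bad].all(axis=1)]
        values = np.where(missing, np.nan, values)

    df = pd.DataFrame(values, index=gene_ids, columns=condition_ids)
    truth = SyntheticTruth(
        cluster_of={g: int(c) for g, c in zip(gene_ids, cluster_idx)},
        archetypes=archetypes,
    )
    return ExpressionMatrix(df, experiment_of), truth


def generate_annotations(truth: SyntheticTruth, n_terms: int = 10,
                         enrichment_fraction: float = 0.8,
                         background_rate: float = 0.05,
                         seed: int = 0) -> AnnotationTable:
    """Plant cluster-linked annotation terms.

    Term i targets cluster i (cycling over clusters when n_terms exceeds
    the cluster count): each gene of the target cluster carries the term
    with probability ``enrichment_fraction`` and every other gene with
    probability ``background_rate``.  Genes that end up with no term are
    simply absent from the table.  Deterministic given ``seed``.
    """
    if not (0 <= enrichment_fraction <= 1 and 0 <= background_rate <= 1):
        raise ExprMapError("rates must lie in [0, 1]")
    rng = _stream(seed, "annotation")
    n_clusters = truth.archetypes.shape[0]
    genes = list(truth.cluster_of)
    clusters = np.array([truth.cluster_of[g] for g in genes])
    term_of: dict[str, set[str]] = {}
    for t in range(n_terms):
        term = f"TERM:{t:04d}"
        target = t % n_clusters
        p = np.where(clusters == target, enrichment_fraction, background_rate)
        hit = rng.random(len(genes)) < p
        for g, h in zip(genes, hit):
            if h:
                term_of.setdefault(g, set()).add(term)
    if not term_of:
        raise ExprMapError("annotation draw produced no annotations; raise the rates")
    return AnnotationTable(term_of, propagated=False)


def planted_term_of_cluster(term_index: int) -> str:
    """Term id that :func:`generate_annotations` plants at index ``term_index``."""
    return f"TERM:{term_index:04d}"


def write_truth(truth: SyntheticTruth, path, header_comment: str | None = None) -> None:
    """Flat TSV export of the planted gene → cluster labels."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene_id\tcluster\n")
        for g, c in truth.cluster_of.items():
            fh.write(f"{g}\t{c}\n")
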