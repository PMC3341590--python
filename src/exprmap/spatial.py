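"""Spatial statistics on the map grid.

Two questions about a trained map are answered here.

*Is a gene set non-randomly distributed on the map?*  Over-representation
per node misses sets that concentrate in a map region without piling into a
single node.  The empirical test computes the mean city-block distance d
from each set member to its closest other member, then compares d against
the same statistic d′ for repeatedly sampled random gene sets of equal size
drawn (without replacement) from all mapped genes.  The p-value is the
fraction of samples with d′ strictly smaller than d; with multiple sets a
Bonferroni correction multiplies by the number of tests.

*How reproducible is the map given its random initialisation?*  Gene pairs
co-clustered (same node) in a main map are sampled and looked up in
independently re-seeded alternate maps, counting how often they co-cluster
again or land within a small grid distance of each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ExprMapError
from .io_formats import GeneSet
from .som import SomMap

logger = logging.getLogger(__name__)


@dataclass
class SpatialTestResult:
    """Outcome of the non-random-distribution test for one gene set.

    ``p_raw`` counts strictly smaller null values (ties are "not smaller"),
    so 0 is reportable; ``p_conservative`` = (count+1)/(n_samples+1) is the
    add-one estimate, logged alongside as a conservative extension.
    """

    set_name: str
    n: int
    d_observed: float
    n_samples: int
    count_lower: int
    p_raw: float
    p_corrected: float
    p_conservative: float


@dataclass
class ReproducibilityResult:
    n_pairs: int
    n_same: int
    n_near: int
    frac_same: float
    frac_near: float
    near_radius: int


def mean_nn_distance(positions) -> float:
    """Mean city-block distance from each point to its nearest other point.

    ``positions`` is an (n, 2) array of (x, y) grid coordinates, n ≥ 2.
    Co-located points contribute 0.  Invariant to point order and to grid
    translation.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
        raise ExprMapError("mean_nn_distance needs ≥ 2 (x, y) positions")
    d = cdist(pos, pos, metric="cityblock")
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def nonrandom_test(som: SomMap, gene_set: GeneSet, n_samples: int = 100,
                   n_tests: int = 1, seed: int | None = None) -> SpatialTestResult:
    """Empirical test that a gene set clusters spatially on the map.

    Members absent from the map are dropped with a warning; the intersected
    set must keep ≥ 2 genes.  Each of ``n_samples`` null draws takes the
    same number of genes uniformly without replacement from all mapped
    genes.  p_raw = #{d′ < d} / n_samples (strict); p_corrected =
    min(1, p_raw · n_tests).  Deterministic given ``seed``.
    """
    mapped = list(som.assignment)
    members = sorted(gene_set.members & set(mapped))
    dropped = len(gene_set.members) - len(members)
    if dropped:
        logger.warning("gene set %r: %d member(s) not on the map, dropped",
                       gene_set.name, dropped)
    n = len(members)
    if n < 2:
        raise ExprMapError(
            f"gene set {gene_set.name!r} has {n} mapped member(s); need ≥ 2"
        )
    d_obs = mean_nn_distance(som.positions(members))
    all_pos = som.positions(mapped)
    rng = np.random.default_rng(seed)
    count_lower = 0
    for _ in range(n_samples):
        idx = rng.choice(len(mapped), size=n, replace=False)
        if mean_nn_distance(all_pos[idx]) < d_obs:
            count_lower += 1
    p_raw = count_lower / n_samples
    return SpatialTestResult(
        set_name=gene_set.name, n=n, d_observed=d_obs, n_samples=n_samples,
        count_lower=count_lower, p_raw=p_raw,
        p_corrected=min(1.0, p_raw * n_tests),
        p_conservative=(count_lower + 1) / (n_samples + 1),
    )


def _grid_dist(a: np.ndarray, b: np.ndarray, metric: str = "cityblock") -> np.ndarray:
    d = np.abs(a - b)
    if metric == "cityblock":
        return d.sum(axis=-1)
    if metric == "chebyshev":
        return d.max(axis=-1)
    return np.sqrt((d.astype(float) ** 2).sum(axis=-1))


def cocluster_reproducibility(main: SomMap, alternates: list[SomMap],
                              n_pairs: int = 50000, near_radius: int = 5,
                              seed: int | None = None,
                              grid_metric: str = "cityblock") -> ReproducibilityResult:
    """How often do co-clustered gene pairs of ``main`` co-cluster again?

    Pairs are drawn uniformly from the multiset of all within-node pairs of
    the main map (nodes weighted by their pair count, with replacement
    across draws); each pair is looked up in a uniformly chosen alternate
    map and counted as "same" if it lands on one node there and "near" if
    the two assigned nodes are within ``near_radius`` grid units
    (city-block by default).  Deterministic given ``seed``.
    """
    if not alternates:
        raise ExprMapError("need at least one alternate map")
    genes = list(main.assignment)
    gene_index = {g: i for i, g in enumerate(genes)}
    for alt in alternates:
        if set(alt.assignment) != set(genes):
            raise ExprMapError("alternate map has a different gene universe")

    node_members = [np.array([gene_index[g] for g in gs], dtype=int)
                    for gs in main.genes_by_node().values()
                    if len(gs) >= 2]
    if not node_members:
        raise ExprMapError("main map has no node with ≥ 2 genes")
    pair_counts = np.array([len(m) * (len(m) - 1) // 2 for m in node_members], dtype=float)
    node_p = pair_counts / pair_counts.sum()

    alt_pos = [alt.positions(genes) for alt in alternates]  # (n_genes, 2) each

    rng = np.random.default_rng(seed)
    node_draws = rng.choice(len(node_members), size=n_pairs, p=node_p)
    alt_draws = rng.integers(0, len(alternates), size=n_pairs)
    n_same = n_near = 0
    for node_i, alt_i in zip(node_draws, alt_draws):
        members = node_members[node_i]
        i = rng.integers(0, len(members))
        j = rng.integers(0, len(members) - 1)
        if j >= i:
            j += 1
        pos = alt_pos[alt_i]
        d = _grid_dist(pos[members[i]], pos[members[j]], grid_metric)
        if d == 0:
            n_same += 1
        if d <= near_radius:
            n_near += 1
    return ReproducibilityResult(
        n_pairs=n_pairs, n_same=n_same, n_near=n_near,
        frac_same=n_same / n_pairs, frac_near=n_near / n_pairs,
        near_radius=near_radius,
    )


def chance_cocluster_probability(som: SomMap) -> float:
    """Probability two distinct random genes share a node, from occupancies.

    Σ_nodes c_i(c_i − 1) / (G(G − 1)) — the expected frac_same when an
    alternate map's assignments are a random permutation of the originals.
    """
    counts = np.array([len(g) for g in som.genes_by_node().values()], dtype=float)
    total = counts.sum()
    return float((counts * (counts - 1)).sum() / (total * (total - 1)))
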