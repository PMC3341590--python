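"""Self-organizing map training over expression profiles with missing data.

The map is a ``width × height`` grid of condition-length reference vectors
("node vectors").  Training presents gene profiles in random order with
replacement, on average ``presentations_per_gene`` times each; at each
presentation the best matching unit (BMU) — the node whose vector is most
similar to the profile — and its grid neighbours within the current radius
are pulled towards the profile by the current learning rate.  Both the
learning rate and the radius decay linearly to zero over training, and at
the end every gene is assigned to its BMU under the final node vectors.

Similarity defaults to the Pearson correlation computed over jointly
observed components only, so profiles with missing values participate
without imputation.  A comparison with fewer than ``min_overlap`` shared
components, or with zero variance over the overlap, is *incomparable*: it
can never win a BMU search (sentinel score −inf).

Grid conventions: coordinates are 0-based and x-first (x = column,
y = row); node (0, 0) is the top-left corner; edges are hard boundaries
(no toroidal wrap-around).  The neighbourhood is a flat "bubble" on
city-block grid distance by default — all nodes within the radius receive
the full learning-rate update — with Gaussian and alternative grid metrics
available as options.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import ExprMapError, IncomparableGeneError
from .io_formats import ExpressionMatrix

#: Sentinel similarity for incomparable vector pairs; loses every BMU contest.
INCOMPARABLE = -math.inf

_METRICS = ("pearson", "euclidean")
_GRID_METRICS = ("cityblock", "euclidean", "chebyshev")
_KERNELS = ("bubble", "gaussian")


@dataclass(frozen=True)
class SomConfig:
    """Training hyper-parameters.

    Defaults follow the standard whole-transcriptome setup: a 25×20 grid
    (500 clusters), starting learning rate 0.1, starting neighbourhood
    radius 10, and on average 20 presentations per gene, with
    Pearson-correlation similarity.  ``min_overlap`` is the minimum number
    of jointly observed components for a similarity to be defined.
    """

    width: int = 25
    height: int = 20
    lr0: float = 0.1
    radius0: float = 10.0
    presentations_per_gene: int = 20
    metric: str = "pearson"
    seed: int = 0
    min_overlap: int = 3
    grid_metric: str = "cityblock"
    kernel: str = "bubble"

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ExprMapError("map dimensions must be ≥ 1")
        if not (0 < self.lr0 <= 1):
            raise ExprMapError("lr0 must be in (0, 1]")
        if self.radius0 < 0:
            raise ExprMapError("radius0 must be ≥ 0")
        if self.presentations_per_gene < 1:
            raise ExprMapError("presentations_per_gene must be ≥ 1")
        if self.min_overlap < 2:
            raise ExprMapError("min_overlap must be ≥ 2")
        if self.metric not in _METRICS:
            raise ExprMapError(f"metric must be one of {_METRICS}")
        if self.grid_metric not in _GRID_METRICS:
            raise ExprMapError(f"grid_metric must be one of {_GRID_METRICS}")
        if self.kernel not in _KERNELS:
            raise ExprMapError(f"kernel must be one of {_KERNELS}")

    @property
    def n_nodes(self) -> int:
        return self.width * self.height

    def to_dict(self) -> dict:
        return {
            "width": self.width, "height": self.height, "lr0": self.lr0,
            "radius0": self.radius0,
            "presentations_per_gene": self.presentations_per_gene,
            "metric": self.metric, "seed": self.seed,
            "min_overlap": self.min_overlap, "grid_metric": self.grid_metric,
            "kernel": self.kernel,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SomConfig":
        return cls(**d)


def schedule(t: int, total: int, lr0: float, radius0: float) -> tuple[float, float]:
    """Learning rate and radius at presentation ``t`` of ``total``.

    Both decay linearly from their starting values towards zero:
    α(t) = lr0·(1 − t/total), r(t) = radius0·(1 − t/total).
    """
    frac = 1.0 - t / total
    return lr0 * frac, radius0 * frac


@dataclass
class SomMap:
    """A trained (or initialised) map: node vectors plus gene assignments.

    ``weights`` has shape (height, width, n_conditions); ``assignment``
    maps gene_id → (x, y) with x the column and y the row.
    """

    config: SomConfig
    condition_ids: list[str]
    weights: np.ndarray
    assignment: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        expected = (self.config.height, self.config.width, len(self.condition_ids))
        if self.weights.shape != expected:
            raise ExprMapError(
                f"node grid shape {self.weights.shape} does not match {expected}"
            )

    @property
    def width(self) -> int:
        return self.config.width

    @property
    def height(self) -> int:
        return self.config.height

    @property
    def flat_weights(self) -> np.ndarray:
        """(n_nodes, n_conditions) view, row-major: node (x, y) at y*width + x."""
        return self.weights.reshape(self.config.n_nodes, -1)

    def node_vector(self, x: int, y: int) -> np.ndarray:
        return self.weights[y, x]

    def genes_by_node(self) -> dict[tuple[int, int], list[str]]:
        """Member gene lists per node; only occupied nodes appear."""
        out: dict[tuple[int, int], list[str]] = {}
        for gene, xy in self.assignment.items():
            out.setdefault(xy, []).append(gene)
        return out

    def positions(self, gene_ids: Iterable[str]) -> np.ndarray:
        """(n, 2) array of (x, y) node coordinates for the given genes."""
        return np.array([self.assignment[g] for g in gene_ids], dtype=int)


def similarity(u, v, metric: str = "pearson", min_overlap: int = 3) -> float:
    """Similarity between two condition-length vectors, higher = more similar.

    Missing values (NaN) in either vector are excluded: the score is
    computed over the jointly observed components only.  ``pearson`` gives
    the correlation coefficient in [−1, 1]; ``euclidean`` gives the negated
    Euclidean distance divided by √overlap, so that vectors with different
    missingness are on a comparable scale.  Returns :data:`INCOMPARABLE`
    when the overlap is below ``min_overlap`` or either vector is constant
    over the overlap.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ExprMapError(f"vector lengths differ: {u.shape} vs {v.shape}")
    mask = ~(np.isnan(u) | np.isnan(v))
    overlap = int(mask.sum())
    if overlap < min_overlap:
        return INCOMPARABLE
    us, vs = u[mask], v[mask]
    uc, vc = us - us.mean(), vs - vs.mean()
    su2, sv2 = float(uc @ uc), float(vc @ vc)
    if su2 == 0.0 or sv2 == 0.0:
        return INCOMPARABLE
    if metric == "pearson":
        return float(uc @ vc) / math.sqrt(su2 * sv2)
    if metric == "euclidean":
        diff = us - vs
        return -math.sqrt(float(diff @ diff)) / math.sqrt(overlap)
    raise ExprMapError(f"unknown metric {metric!r}")


def _node_scores(x: np.ndarray, flat_w: np.ndarray, metric: str,
                 min_overlap: int) -> np.ndarray:
    """Similarity of profile ``x`` (may contain NaN) to every node vector.

    Node vectors never contain NaN, so the overlap is the set of observed
    components of ``x``.  Incomparable nodes score −inf.
    """
    mask = ~np.isnan(x)
    n_nodes = flat_w.shape[0]
    scores = np.full(n_nodes, INCOMPARABLE)
    overlap = int(mask.sum())
    if overlap < min_overlap:
        return scores
    xs = x[mask]
    xc = xs - xs.mean()
    sx2 = float(xc @ xc)
    if sx2 == 0.0:
        return scores
    ws = flat_w[:, mask]
    wc = ws - ws.mean(axis=1, keepdims=True)
    sw2 = np.einsum("ij,ij->i", wc, wc)
    if metric == "pearson":
        ok = sw2 > 0.0
        num = wc @ xc
        scores[ok] = num[ok] / np.sqrt(sw2[ok] * sx2)
    else:  # euclidean
        ok = sw2 > 0.0  # zero-variance rule applies to both metrics
        diff = ws - xs
        d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        scores[ok] = -d[ok] / math.sqrt(overlap)
    return scores


def _grid_distances(config: SomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-node x and y coordinate arrays in row-major (flat) order."""
    ys, xs = np.divmod(np.arange(config.n_nodes), config.width)
    return xs, ys


def _neighbourhood(xs: np.ndarray, ys: np.ndarray, bmu: int, radius: float,
                   grid_metric: str) -> np.ndarray:
    dx = np.abs(xs - xs[bmu])
    dy = np.abs(ys - ys[bmu])
    if grid_metric == "cityblock":
        d = dx + dy
    elif grid_metric == "chebyshev":
        d = np.maximum(dx, dy)
    else:
        d = np.sqrt(dx * dx + dy * dy)
    return d <= radius


def init_map(config: SomConfig, matrix: ExpressionMatrix) -> SomMap:
    """Randomly initialise node vectors within the range of the data.

    Each node-vector component for condition c is drawn uniformly from the
    observed [min, max] of condition c across all genes.  Deterministic
    given ``config.seed`` (the initialisation uses its own stream, so the
    same seed also fixes the subsequent training draws independently).
    """
    values = matrix.values.to_numpy(dtype=float)
    observed = ~np.isnan(values)
    if not observed.any(axis=0).all():
        bad = [c for c, ok in zip(matrix.condition_ids, observed.any(axis=0)) if not ok]
        raise ExprMapError(f"conditions with no observed values: {bad[:5]}")
    lo = np.nanmin(values, axis=0)
    hi = np.nanmax(values, axis=0)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    weights = rng.uniform(lo, hi, size=(config.height, config.width, len(lo)))
    return SomMap(config=config, condition_ids=list(matrix.condition_ids), weights=weights)


def train(matrix: ExpressionMatrix, config: SomConfig) -> SomMap:
    """Train a map on the matrix and assign every gene to its final BMU.

    T = presentations_per_gene × n_genes presentations are made; at each,
    a gene is drawn uniformly with replacement, its BMU found (ties broken
    towards the smallest (y, x)), and all nodes within the current radius
    of the BMU updated component-wise towards the profile:
    w_j ← w_j + α(t)·(x_j − w_j), skipping components where x_j is missing.
    Bit-for-bit deterministic given (matrix, config).
    """
    som = init_map(config, matrix)
    values = matrix.values.to_numpy(dtype=float)
    gene_ids = matrix.gene_ids
    n_genes = len(gene_ids)
    flat_w = som.flat_weights  # view; updates write through to som.weights
    xs, ys = _grid_distances(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    total = config.presentations_per_gene * n_genes
    gene_draws = rng.integers(0, n_genes, size=total)
    obs_masks = ~np.isnan(values)
    for t in range(total):
        alpha, radius = schedule(t, total, config.lr0, config.radius0)
        g = gene_draws[t]
        x = values[g]
        scores = _node_scores(x, flat_w, config.metric, config.min_overlap)
        if not np.isfinite(scores).any():
            raise IncomparableGeneError(gene_ids[g])
        bmu = int(np.argmax(scores))  # first max = smallest (y, x) row-major
        neigh = _neighbourhood(xs, ys, bmu, radius, config.grid_metric)
        mask = obs_masks[g]
        if config.kernel == "bubble":
            sub = flat_w[np.ix_(neigh, mask)]
            flat_w[np.ix_(neigh, mask)] = sub + alpha * (x[mask] - sub)
        else:  # gaussian: distance-decayed update within the radius
            d = np.abs(xs[neigh] - xs[bmu]) + np.abs(ys[neigh] - ys[bmu])
            sigma = max(radius, 1e-9)
            h = alpha * np.exp(-(d.astype(float) ** 2) / (2 * sigma * sigma))
            sub = flat_w[np.ix_(neigh, mask)]
            flat_w[np.ix_(neigh, mask)] = sub + h[:, None] * (x[mask] - sub)
    som.assignment = assign(matrix, som)
    return som


def assign(matrix: ExpressionMatrix, som: SomMap) -> dict[str, tuple[int, int]]:
    """Assign every gene to its closest node under the map's node vectors.

    Ties break towards the smallest (y, x); identical profiles therefore
    always land on the same node.  A gene incomparable to every node is a
    hard error naming the gene.
    """
    if list(matrix.condition_ids) != list(som.condition_ids):
        raise ExprMapError("matrix and map condition ids differ")
    values = matrix.values.to_numpy(dtype=float)
    flat_w = som.flat_weights
    width = som.config.width
    out: dict[str, tuple[int, int]] = {}
    for i, gene in enumerate(matrix.gene_ids):
        scores = _node_scores(values[i], flat_w, som.config.metric,
                              som.config.min_overlap)
        if not np.isfinite(scores).any():
            raise IncomparableGeneError(gene)
        bmu = int(np.argmax(scores))
        out[gene] = (bmu % width, bmu // width)
    return out


def node_summary(som: SomMap):
    """Per-node occupancy table: one row per grid node, occupied or not.

    Returns a DataFrame with columns x, y, n_genes and a semicolon-joined
    member list, ordered row-major; counts sum to the number of assigned
    genes and each node vector is interpretable as the mean expression
    profile of its members.
    """
    import pandas as pd

    members = som.genes_by_node()
    rows = []
    for y in range(som.height):
        for x in range(som.width):
            genes = sorted(members.get((x, y), []))
            rows.append({"x": x, "y": y, "n_genes": len(genes),
                         "gene_ids": ";".join(genes)})
    return pd.DataFrame(rows)
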