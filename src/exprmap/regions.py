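"""Threshold regions on node vectors and per-node gene-category overlays.

A *region* is the set of map nodes whose node-vector component for one
condition passes a simple inequality (e.g. embryo expression > 0.25) — the
machinery behind the coloured outlines drawn on published maps.  Regions
are plain node sets, so compound regions are ordinary set algebra; an
optional 4-connectivity grouping recovers contiguous blobs for drawing.

An *overlay* counts, per node, how many members of each gene category
(e.g. a paralogous group) map there — the numbers behind per-node pie
charts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ExprMapError
from .io_formats import GeneSet
from .som import SomMap

_COMPARATORS = ("greater_than", "less_than")


@dataclass(frozen=True)
class RegionSpec:
    condition_id: str
    comparator: str  # greater_than | less_than
    threshold: float

    def __post_init__(self):
        if self.comparator not in _COMPARATORS:
            raise ExprMapError(f"comparator must be one of {_COMPARATORS}")


def parse_region_spec(text: str) -> RegionSpec:
    """Parse ``'condition>0.25'`` / ``'condition<-1'`` shorthand."""
    for op, comparator in ((">", "greater_than"), ("<", "less_than")):
        if op in text:
            cond, _, thr = text.partition(op)
            try:
                return RegionSpec(cond.strip(), comparator, float(thr))
            except ValueError as exc:
                raise ExprMapError(f"bad threshold in region spec {text!r}") from exc
    raise ExprMapError(f"region spec {text!r} needs '>' or '<'")


def select_nodes(som: SomMap, spec: RegionSpec) -> set[tuple[int, int]]:
    """Nodes whose component for the spec's condition passes the inequality.

    Monotone in the threshold (raising a greater_than threshold never adds
    nodes); the empty set is a valid result.
    """
    try:
        c = som.condition_ids.index(spec.condition_id)
    except ValueError:
        raise ExprMapError(f"unknown condition {spec.condition_id!r}") from None
    comp = som.weights[:, :, c]
    hit = comp > spec.threshold if spec.comparator == "greater_than" else comp < spec.threshold
    ys, xs = np.nonzero(hit)
    return {(int(x), int(y)) for x, y in zip(xs, ys)}


def connected_components(nodes: Iterable[tuple[int, int]]) -> list[set[tuple[int, int]]]:
    """Group a node set into contiguous blobs under 4-connectivity."""
    remaining = set(nodes)
    out: list[set[tuple[int, int]]] = []
    while remaining:
        seed = remaining.pop()
        blob = {seed}
        frontier = [seed]
        while frontier:
            x, y = frontier.pop()
            for nb in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1)):
                if nb in remaining:
                    remaining.remove(nb)
                    blob.add(nb)
                    frontier.append(nb)
        out.append(blob)
    return out


def overlay_counts(som: SomMap, categories: Sequence[GeneSet]) -> pd.DataFrame:
    """Per-node totals and per-category member counts.

    One row per grid node (row-major), columns x, y, total, then one per
    category.  A gene in several categories counts once in each; category
    counts sum over nodes to the category's mapped-member count.  Empty
    intersections yield an all-zero column (with a logged warning).
    """
    import logging

    mapped = set(som.assignment)
    members = som.genes_by_node()
    rows = []
    for y in range(som.height):
        for x in range(som.width):
            genes = set(members.get((x, y), ()))
            row = {"x": x, "y": y, "total": len(genes)}
            for cat in categories:
                row[cat.name] = len(genes & cat.members)
            rows.append(row)
    for cat in categories:
        if not (cat.members & mapped):
            logging.getLogger(__name__).warning(
                "category %r has no members on the map", cat.name)
    return pd.DataFrame(rows)
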