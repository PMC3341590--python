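"""Per-node GO over-representation analysis.

Each occupied map node is treated as a gene cluster and tested for
over-representation of every informative term with a one-sided Fisher's
exact test (upper hypergeometric tail): the null hypothesis is that genes
carrying the term are randomly distributed between the node and the rest
of the map.  Terms annotating fewer than ten or more than a quarter of the
mapped genes are excluded up front as uninformative.  Raw p-values are
adjusted with the Benjamini–Hochberg step-up procedure pooled over all
(node, term) tests performed, and a term is only *reported* for a node if
its FDR passes the chosen threshold and at least four genes in the node
carry it.  Parent/child term overlap is deliberately not corrected for.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ExprMapError
from .io_formats import AnnotationTable
from .som import SomMap

#: Minimum in-node annotated genes for a term to be reported as enriched.
MIN_GENES_REPORTED = 4

#: Term-size filter: keep terms with MIN_TERM_SIZE ≤ K ≤ N/4 mapped genes.
MIN_TERM_SIZE = 10


@dataclass(frozen=True)
class ContingencyCounts:
    """2×2 counts for one (node, term) test.

    k = annotated genes in the node, K = annotated genes on the map,
    n = genes in the node, N = genes on the map.
    """

    k: int
    K: int
    n: int
    N: int

    def __post_init__(self):
        ok = (0 <= self.k <= min(self.n, self.K)
              and self.K <= self.N and self.n <= self.N)
        if not ok:
            raise ExprMapError(f"invalid contingency counts {self}")


@dataclass
class EnrichmentResult:
    node: tuple[int, int]
    term_id: str
    counts: ContingencyCounts
    p_raw: float
    fdr: float
    reported: bool


def filter_terms(annotations: AnnotationTable, mapped_genes: Iterable[str]) -> set[str]:
    """Informative terms: annotate ≥ 10 and ≤ a quarter of the mapped genes."""
    mapped = set(mapped_genes)
    counts: dict[str, int] = {}
    for gene, terms in annotations.term_of.items():
        if gene in mapped:
            for t in terms:
                counts[t] = counts.get(t, 0) + 1
    n_mapped = len(mapped)
    return {t for t, K in counts.items() if MIN_TERM_SIZE <= K <= n_mapped / 4}


def fisher_upper_tail(c: ContingencyCounts) -> float:
    """One-sided over-representation p-value: P(X ≥ k) for
    X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(c.k - 1, c.N, c.K, c.n))


def bh_fdr(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j ≥ i} (p_(j) · m / j), clipped to 1.  ``m`` is the total
    number of tests performed and may exceed ``len(p_values)`` when only a
    subset of the tested p-values is being adjusted for display.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ExprMapError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ExprMapError(f"m = {m} is smaller than the number of p-values {p.size}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def run_enrichment(som: SomMap, annotations: AnnotationTable,
                   fdr_threshold: float = 0.05) -> list[EnrichmentResult]:
    """Test every (occupied node, informative term) pair for over-representation.

    The gene universe N is the set of mapped genes (unannotated genes stay
    in the universe).  BH adjustment pools over all tests performed.
    """
    members = som.genes_by_node()
    if not members:
        raise ExprMapError("map has no assigned genes")
    mapped = set(som.assignment)
    n_universe = len(mapped)
    terms = sorted(filter_terms(annotations, mapped))
    term_genes = {t: annotations.genes_of_term(t) & mapped for t in terms}
    if not any(term_genes.values()):
        raise ExprMapError("no annotated mapped genes after term filtering")

    results: list[EnrichmentResult] = []
    ks, Ks, ns = [], [], []
    for node in sorted(members, key=lambda xy: (xy[1], xy[0])):
        node_genes = set(members[node])
        n = len(node_genes)
        for t in terms:
            k = len(term_genes[t] & node_genes)
            counts = ContingencyCounts(k=k, K=len(term_genes[t]), n=n, N=n_universe)
            results.append(EnrichmentResult(node, t, counts, np.nan, np.nan, False))
            ks.append(k); Ks.append(counts.K); ns.append(n)

    p_raw = stats.hypergeom.sf(np.asarray(ks) - 1, n_universe,
                               np.asarray(Ks), np.asarray(ns))
    fdr = bh_fdr(p_raw)  # m = number of tests performed
    for r, p, q in zip(results, p_raw, fdr):
        r.p_raw = float(p)
        r.fdr = float(q)
        r.reported = bool(q <= fdr_threshold and r.counts.k >= MIN_GENES_REPORTED)
    return results


def count_enriched_terms(results: list[EnrichmentResult],
                         annotations: AnnotationTable,
                         mapped_genes: Iterable[str],
                         thresholds: Sequence[float]) -> dict[float, int]:
    """Distinct enriched terms per FDR threshold, after redundancy collapse.

    A term counts once however many nodes report it, and terms whose
    annotated mapped-gene sets are identical are collapsed to one
    (redundant GO terms annotate exactly the same genes).  Only results
    whose k ≥ 4 report filter passed are eligible.
    """
    mapped = set(mapped_genes)
    signatures: dict[str, frozenset[str]] = {}

    def signature(term: str) -> frozenset[str]:
        if term not in signatures:
            signatures[term] = frozenset(annotations.genes_of_term(term) & mapped)
        return signatures[term]

    out: dict[float, int] = {}
    for thr in thresholds:
        sigs = {
            signature(r.term_id)
            for r in results
            if r.counts.k >= MIN_GENES_REPORTED and r.fdr <= thr
        }
        out[thr] = len(sigs)
    return out


def results_to_frame(results: list[EnrichmentResult]):
    """Flatten results to a DataFrame (x, y, term_id, k, K, n, N, p_raw, fdr,
    reported), sorted by fdr then p_raw."""
    import pandas as pd

    rows = [
        {"x": r.node[0], "y": r.node[1], "term_id": r.term_id,
         "k": r.counts.k, "K": r.counts.K, "n": r.counts.n, "N": r.counts.N,
         "p_raw": r.p_raw, "fdr": r.fdr, "reported": r.reported}
        for r in results
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(["fdr", "p_raw"], kind="stable").reset_index(drop=True)
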