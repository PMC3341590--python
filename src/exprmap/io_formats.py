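"""Readers and writers for the pipeline's external formats.

Formats handled here:

* expression matrix — TSV, first row condition ids, first column gene ids,
  missing values as empty cells or ``NA``;
* condition→experiment grouping — 2-column TSV;
* gene→GO annotations — 2-column TSV or GAF 2.x (object id and term id
  columns, ``NOT``-qualified rows skipped);
* ontology — OBO, parsed with :mod:`obonet`, ancestor closure along a
  configurable set of relations (default ``is_a`` and ``part_of``);
* gene sets — plain one-gene-per-line lists or GMT;
* trained map — versioned JSON plus a flat ``gene_id, x, y`` TSV export.

Grid coordinates are 0-based, x-first: ``x`` is the column (0..width−1) and
``y`` the row (0..height−1).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

MAP_FORMAT_VERSION = "1"

#: Relations followed during annotation propagation unless overridden.
DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})


@dataclass
class ExpressionMatrix:
    """A gene × condition matrix of normalized expression values.

    ``values`` is a float DataFrame (rows = genes, columns = conditions) with
    ``NaN`` marking missing measurements.  Every condition belongs to exactly
    one experiment via ``experiment_of``; correlation across experiments is
    only meaningful after per-experiment centring (see
    :func:`exprmap.normalize.median_shift`).
    """

    values: pd.DataFrame
    experiment_of: dict[str, str]

    def __post_init__(self):
        self.validate()

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def experiment_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for cond in self.condition_ids:
            seen.setdefault(self.experiment_of[cond], None)
        return list(seen)

    def conditions_of(self, experiment_id: str) -> list[str]:
        return [c for c in self.condition_ids if self.experiment_of[c] == experiment_id]

    def validate(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate condition ids: {dupes[:5]}")
        if len(idx) < 1 or len(cols) < 2:
            raise FormatError(
                f"matrix needs at least 1 gene and 2 conditions, got {self.values.shape}"
            )
        missing = [c for c in cols if c not in self.experiment_of]
        if missing:
            raise FormatError(f"conditions without an experiment assignment: {missing[:5]}")
        if not all(np.issubdtype(dt, np.floating) for dt in self.values.dtypes):
            raise FormatError("matrix contains non-numeric cells")
        all_missing = self.values.isna().all(axis=1)
        if all_missing.any():
            bad = self.values.index[all_missing].tolist()
            raise FormatError(f"genes with no observed value in any condition: {bad[:5]}")


@dataclass
class AnnotationTable:
    """gene_id → set of term ids, optionally closed under ontology ancestors."""

    term_of: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    propagated: bool = False

    def __post_init__(self):
        empty = [g for g, terms in self.term_of.items() if not terms]
        if empty:
            raise FormatError(f"genes with an empty term set: {empty[:5]}")

    def genes_of_term(self, term_id: str) -> set[str]:
        return {g for g, terms in self.term_of.items() if term_id in terms}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self.term_of.values():
            out |= terms
        return out

    def restricted_to(self, genes: Iterable[str]) -> "AnnotationTable":
        keep = set(genes)
        sub = {g: set(t) for g, t in self.term_of.items() if g in keep}
        return AnnotationTable(sub, dict(self.term_names), self.propagated)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids (an overlay category or a spatial-test set)."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


def read_expression_matrix(matrix_path, experiments_path) -> ExpressionMatrix:
    """Read a gene × condition TSV plus its condition→experiment grouping.

    Missing values are empty cells or the literal ``NA``.  Lines starting
    with ``#`` are comments (pipeline outputs carry provenance headers).
    """
    try:
        df = pd.read_csv(
            matrix_path,
            sep="\t",
            index_col=0,
            comment="#",
            na_values=["NA"],
            keep_default_na=False,
            dtype=str,
        )
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"cannot parse expression matrix {matrix_path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        values = df.apply(pd.to_numeric, errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric, non-NA cell in {matrix_path}: {exc}") from exc
    experiment_of = read_experiments(experiments_path)
    absent = [c for c in values.columns if c not in experiment_of]
    if absent:
        raise FormatError(
            f"conditions missing from experiments file {experiments_path}: {absent[:5]}"
        )
    experiment_of = {c: experiment_of[c] for c in values.columns}
    return ExpressionMatrix(values, experiment_of)


def read_experiments(path) -> dict[str, str]:
    """Read the 2-column condition_id → experiment_id TSV."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        cond, exp = parts
        if cond in out and out[cond] != exp:
            raise FormatError(f"{path}:{lineno}: condition {cond!r} listed with two experiments")
        out[cond] = exp
    if not out:
        raise FormatError(f"experiments file {path} is empty")
    return out


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path, experiments_path=None,
                            header_comment: str | None = None) -> None:
    """Write the matrix TSV (missing as ``NA``) and optionally the grouping TSV."""
    with open(matrix_path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        matrix.values.to_csv(fh, sep="\t", na_rep="NA", index_label="gene_id")
    if experiments_path is not None:
        with open(experiments_path, "w") as fh:
            for cond in matrix.condition_ids:
                fh.write(f"{cond}\t{matrix.experiment_of[cond]}\n")


def read_annotations(path, dialect: str = "two_column") -> AnnotationTable:
    """Read gene→term annotations from a 2-column TSV or a GAF 2.x file.

    GAF parsing is deliberately minimal: object id (column 2) and term id
    (column 5) are used, comment lines are skipped, and rows whose qualifier
    contains ``NOT`` are excluded.  Evidence codes are ignored.
    """
    if dialect not in ("two_column", "gaf"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    term_of: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if dialect == "two_column":
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
            gene, term = parts
        else:
            if line.startswith("!"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: GAF row has fewer than 5 columns")
            gene, qualifier, term = parts[1], parts[3], parts[4]
            if not gene or not term:
                raise FormatError(f"{path}:{lineno}: empty object or term id")
            if "NOT" in qualifier.split("|"):
                continue
        term_of.setdefault(gene, set()).add(term)
    if not term_of:
        raise FormatError(f"no annotations parsed from {path}")
    return AnnotationTable(term_of, propagated=False)


def write_annotations(annotations: AnnotationTable, path,
                      header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for gene in sorted(annotations.term_of):
            for term in sorted(annotations.term_of[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_ontology(path) -> nx.MultiDiGraph:
    """Parse an OBO file into a term graph (edges point child → parent).

    Obsolete terms are dropped by obonet; only [Term] stanzas are kept.
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:
        raise FormatError(f"cannot parse OBO file {path}: {exc}") from exc
    return graph


def _ancestors(graph: nx.MultiDiGraph, term: str, relations: frozenset[str]) -> set[str]:
    """All terms reachable from ``term`` along edges of the chosen relations."""
    out: set[str] = set()
    stack = [term]
    while stack:
        node = stack.pop()
        for _, parent, rel in graph.out_edges(node, keys=True):
            if rel in relations and parent not in out:
                out.add(parent)
                stack.append(parent)
    return out


def propagate_annotations(
    annotations: AnnotationTable,
    ontology,
    relations: Iterable[str] = DEFAULT_RELATIONS,
) -> AnnotationTable:
    """Close every gene's term set under ancestor traversal.

    ``ontology`` is an OBO path or an already-parsed term graph.  Terms not
    present in the ontology are kept as-is (with a logged warning) — they
    simply contribute no ancestors.  Idempotent: propagating a propagated
    table is a no-op.
    """
    graph = ontology if isinstance(ontology, nx.MultiDiGraph) else read_ontology(ontology)
    relations = frozenset(relations)
    cache: dict[str, set[str]] = {}
    unknown: set[str] = set()
    term_of: dict[str, set[str]] = {}
    for gene, terms in annotations.term_of.items():
        closed = set(terms)
        for term in terms:
            if term not in graph:
                unknown.add(term)
                continue
            if term not in cache:
                cache[term] = _ancestors(graph, term, relations)
            closed |= cache[term]
        term_of[gene] = closed
    if unknown:
        logger.warning(
            "%d annotated term(s) absent from the ontology, kept without ancestors: %s",
            len(unknown), sorted(unknown)[:5],
        )
    names = dict(annotations.term_names)
    for term, data in graph.nodes(data=True):
        if "name" in data:
            names.setdefault(term, data["name"])
    return AnnotationTable(term_of, names, propagated=True)


def read_gene_sets(path, dialect: str = "plain") -> list[GeneSet]:
    """Read gene sets from a plain list (one gene per line) or a GMT file."""
    path = Path(path)
    if dialect == "plain":
        members = {
            line.strip()
            for line in path.read_text().splitlines()
            if line.strip() and not line.startswith("#")
        }
        if not members:
            raise FormatError(f"gene set file {path} is empty")
        return [GeneSet(path.stem, frozenset(members))]
    if dialect == "gmt":
        sets: list[GeneSet] = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and ≥1 member"
                )
            name, members = parts[0], frozenset(p for p in parts[2:] if p)
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name, members))
        if not sets:
            raise FormatError(f"GMT file {path} is empty")
        return sets
    raise ValueError(f"unknown gene-set dialect {dialect!r}")


def write_map(som_map, path, meta: Mapping[str, object] | None = None) -> None:
    """Serialize a trained map to versioned JSON.

    Node vectors keep full float precision (JSON round-trips Python floats
    exactly).  ``meta`` carries provenance (seed, config hash, version).
    """
    from .som import SomMap  # local import to avoid a cycle

    assert isinstance(som_map, SomMap)
    payload = {
        "format_version": MAP_FORMAT_VERSION,
        "meta": dict(meta or {}),
        "config": som_map.config.to_dict(),
        "condition_ids": list(som_map.condition_ids),
        "node_vectors": som_map.weights.tolist(),  # [y][x][condition]
        "assignment": {g: [int(x), int(y)] for g, (x, y) in som_map.assignment.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
        fh.write("\n")


def read_map(path):
    """Read a map written by :func:`write_map`; rejects version mismatches."""
    from .som import SomConfig, SomMap

    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse map JSON {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != MAP_FORMAT_VERSION:
        raise FormatError(
            f"map file {path} has format version {version!r}, expected {MAP_FORMAT_VERSION!r}"
        )
    config = SomConfig.from_dict(payload["config"])
    weights = np.asarray(payload["node_vectors"], dtype=float)
    condition_ids = list(payload["condition_ids"])
    if weights.shape != (config.height, config.width, len(condition_ids)):
        raise FormatError(f"map file {path}: node grid shape does not match config")
    assignment = {g: (int(x), int(y)) for g, (x, y) in payload["assignment"].items()}
    for g, (x, y) in assignment.items():
        if not (0 <= x < config.width and 0 <= y < config.height):
            raise FormatError(f"map file {path}: gene {g!r} assigned off-grid node ({x},{y})")
    return SomMap(config=config, condition_ids=condition_ids,
                  weights=weights, assignment=assignment)


def write_assignment_tsv(som_map, path, header_comment: str | None = None) -> None:
    """Flat ``gene_id, x, y`` export for downstream tools (one row per gene)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("gene_id\tx\ty\n")
        for gene, (x, y) in som_map.assignment.items():
            fh.write(f"{gene}\t{x}\t{y}\n")
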