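"""Flat-file readers and writers, gene-id resolution, and imputation.

All formats are plain text: a TSV fitness matrix (strain rows, condition
header), two-column TSV annotation tables, a GAF-style association table,
OBO 1.2 ontologies, and a two-column id map. Every writer has a matching
reader and the pair round-trips exactly.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    AnnotationSet,
    ConditionTable,
    DiscreteMatrix,
    FitnessMatrix,
    GeneGoAnnotations,
    IdMap,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Cell contents treated as missing in the fitness table.
DEFAULT_NA_TOKENS = ("", "NA", "NaN")

#: GAF aspect code for each GO namespace.
_NAMESPACE_TO_ASPECT = {
    "biological_process": "P",
    "molecular_function": "F",
    "cellular_component": "C",
}


# ---------------------------------------------------------------------------
# Fitness matrix
# ---------------------------------------------------------------------------

def read_fitness_table(
    path: str | Path,
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
) -> FitnessMatrix:
    """Read a strains x conditions TSV into a :class:`FitnessMatrix`.

    First column holds strain ids, the header row condition ids; cells that
    are empty or equal to an NA token become missing values.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file") from None
        condition_ids = header[1:]
        seen: dict[str, int] = {}
        for cond in condition_ids:
            seen[cond] = seen.get(cond, 0) + 1
        dup_conditions = [c for c, n in seen.items() if n > 1]
        if dup_conditions:
            raise ValidationError(f"{path}: duplicated condition header(s): {dup_conditions}")

        na = set(na_tokens)
        strain_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise ValidationError(
                    f"{path}: ragged row at line {lineno}: "
                    f"expected {len(header)} fields, got {len(row)}"
                )
            strain_ids.append(row[0])
            rows.append([np.nan if cell in na else float(cell) for cell in row[1:]])

    dup_strains = sorted({s for s in strain_ids if strain_ids.count(s) > 1})
    if dup_strains:
        raise ValidationError(f"{path}: duplicate strain ids: {dup_strains}")
    scores = pd.DataFrame(rows, index=strain_ids, columns=condition_ids, dtype=float)
    return FitnessMatrix(scores)


def write_fitness_table(matrix: FitnessMatrix, path: str | Path) -> None:
    """Write a fitness matrix as TSV; missing cells become empty strings."""
    matrix.scores.to_csv(path, sep="\t", index_label="strain", na_rep="")


def impute_population_mean(
    matrix: FitnessMatrix, scope: str = "per_condition"
) -> FitnessMatrix:
    """Replace missing scores with the population mean of their scope.

    ``scope="per_condition"`` (default) uses each condition column's observed
    mean — the natural population for scores standardized within condition —
    while ``scope="global"`` uses the grand mean of all observed cells.
    Observed cells are never altered.
    """
    scores = matrix.scores
    if scope == "per_condition":
        fully_missing = scores.columns[scores.isna().all(axis=0)].tolist()
        if fully_missing:
            raise ValidationError(
                f"conditions with no observed values cannot be imputed per-condition: "
                f"{fully_missing}"
            )
        filled = scores.fillna(scores.mean(axis=0))
    elif scope == "global":
        observed = scores.to_numpy()
        if np.isnan(observed).all():
            raise ValidationError("matrix has no observed values")
        filled = scores.fillna(float(np.nanmean(observed)))
    else:
        raise ValidationError(f"unknown imputation scope: {scope!r}")
    return FitnessMatrix(filled)


# ---------------------------------------------------------------------------
# Condition metadata
# ---------------------------------------------------------------------------

def read_condition_table(path: str | Path) -> ConditionTable:
    frame = pd.read_csv(path, sep="\t", dtype={"condition_id": str, "stress_id": str,
                                               "level_label": str})
    return ConditionTable(frame)


def write_condition_table(table: ConditionTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation sets
# ---------------------------------------------------------------------------

def read_annotation_table(
    path: str | Path,
    name: str | None = None,
    exclude_terms: frozenset[str] | set[str] = frozenset(),
    universe: Iterable[str] | None = None,
) -> AnnotationSet:
    """Read a two-column (term, gene) TSV into an :class:`AnnotationSet`.

    ``exclude_terms`` drops whole terms at read time (e.g. homomeric
    complexes); a ``universe`` restricts genes to those assayed, logging how
    many were dropped.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], dtype=str)
    if frame.empty:
        raise ValidationError(f"{path}: empty annotation table")
    frame = frame[~frame["term"].isin(set(exclude_terms))]
    if universe is not None:
        uni = set(universe)
        dropped = int((~frame["gene"].isin(uni)).sum())
        if dropped:
            logger.info("%s: dropped %d gene rows outside the universe", path, dropped)
        frame = frame[frame["gene"].isin(uni)]
    term_to_genes = {
        term: frozenset(sub["gene"]) for term, sub in frame.groupby("term") if len(sub)
    }
    return AnnotationSet(name=name or path.stem, term_to_genes=term_to_genes)


def write_annotation_table(annotation: AnnotationSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for term in sorted(annotation.term_to_genes):
            for gene in sorted(annotation.term_to_genes[term]):
                fh.write(f"{term}\t{gene}\n")


# ---------------------------------------------------------------------------
# OBO ontology subset
# ---------------------------------------------------------------------------

#: Relations retained from OBO files; the Wang similarity weights only these.
KEPT_RELATIONS = ("is_a", "part_of")


def read_obo_subset(path: str | Path) -> nx.DiGraph:
    """Parse an OBO 1.2 ontology into a typed child->parent DAG.

    Only ``id``, ``name``, ``namespace``, ``is_a``, ``relationship: part_of``
    and ``is_obsolete`` tags are interpreted. Obsolete terms are dropped,
    other relationship types are logged and skipped, and the result is
    validated acyclic. Edges carry a ``relation`` attribute.
    """
    path = Path(path)
    graph = nx.DiGraph()
    pending_edges: list[tuple[str, str, str]] = []

    term: dict | None = None

    def flush(t: dict | None) -> None:
        if not t or "id" not in t or t.get("obsolete"):
            return
        graph.add_node(t["id"], name=t.get("name", ""), namespace=t.get("namespace", ""))
        for parent, relation in t.get("parents", []):
            pending_edges.append((t["id"], parent, relation))

    with path.open() as fh:
        in_term = False
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                flush(term if in_term else None)
                in_term = line == "[Term]"
                term = {"parents": []} if in_term else None
                continue
            if not in_term or not line or term is None:
                continue
            if ":" not in line:
                continue
            tag, _, value = line.partition(":")
            value = value.split("!")[0].strip()
            if tag == "id":
                term["id"] = value
            elif tag == "name":
                term["name"] = value
            elif tag == "namespace":
                term["namespace"] = value
            elif tag == "is_a":
                term["parents"].append((value, "is_a"))
            elif tag == "relationship":
                parts = value.split()
                if len(parts) >= 2:
                    rel, parent = parts[0], parts[1]
                    if rel in KEPT_RELATIONS:
                        term["parents"].append((parent, rel))
                    else:
                        logger.warning("%s: skipping relationship type %r", path, rel)
            elif tag == "is_obsolete" and value.lower() == "true":
                term["obsolete"] = True
        flush(term if in_term else None)

    for child, parent, relation in pending_edges:
        if parent in graph and child in graph:
            graph.add_edge(child, parent, relation=relation)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValidationError(f"{path}: ontology graph has a cycle: {cycle}")
    return graph


def write_obo(graph: nx.DiGraph, path: str | Path) -> None:
    """Write a minimal OBO 1.2 file for a typed child->parent DAG."""
    with Path(path).open("w") as fh:
        fh.write("format-version: 1.2\n")
        for node in sorted(graph.nodes):
            data = graph.nodes[node]
            fh.write("\n[Term]\n")
            fh.write(f"id: {node}\n")
            fh.write(f"name: {data.get('name', node)}\n")
            fh.write(f"namespace: {data.get('namespace', 'biological_process')}\n")
            for _, parent, edata in sorted(graph.out_edges(node, data=True)):
                if edata.get("relation", "is_a") == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {edata['relation']} {parent}\n")


# ---------------------------------------------------------------------------
# Gene -> GO associations (GAF-like)
# ---------------------------------------------------------------------------

def read_gene_associations(
    path: str | Path,
    graph: nx.DiGraph,
    namespace: str = "biological_process",
    exclude_iea: bool = False,
) -> GeneGoAnnotations:
    """Read a GAF-like (gene, term, evidence, aspect) TSV.

    Rows outside the requested namespace are ignored; ``exclude_iea`` drops
    electronically inferred (IEA) annotations; terms absent from ``graph``
    are dropped with a logged count.
    """
    aspect = _NAMESPACE_TO_ASPECT[namespace]
    frame = pd.read_csv(
        path, sep="\t", header=None,
        names=["gene", "term", "evidence", "aspect"], dtype=str,
    )
    frame = frame[frame["aspect"] == aspect]
    if exclude_iea:
        frame = frame[frame["evidence"] != "IEA"]
    known = frame["term"].isin(graph.nodes)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with terms absent from the ontology", path, n_dropped)
    frame = frame[known]
    gene_to_terms: dict[str, frozenset[str]] = {
        gene: frozenset(sub["term"]) for gene, sub in frame.groupby("gene")
    }
    evidence = {
        (row.gene, row.term): row.evidence for row in frame.itertuples(index=False)
    }
    return GeneGoAnnotations(gene_to_terms=gene_to_terms, evidence=evidence)


def write_gene_associations(annotations: GeneGoAnnotations, path: str | Path,
                            namespace: str = "biological_process") -> None:
    aspect = _NAMESPACE_TO_ASPECT[namespace]
    with Path(path).open("w") as fh:
        for gene in sorted(annotations.gene_to_terms):
            for term in sorted(annotations.gene_to_terms[gene]):
                ev = annotations.evidence.get((gene, term), "IDA")
                fh.write(f"{gene}\t{term}\t{ev}\t{aspect}\n")


# ---------------------------------------------------------------------------
# Gene-id mapping
# ---------------------------------------------------------------------------

def read_id_map(path: str | Path) -> IdMap:
    """Read a two-column (primary, alias) TSV into an :class:`IdMap`."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["primary", "alias"], dtype=str)
    records = [(p, list(sub["alias"])) for p, sub in frame.groupby("primary")]
    return IdMap.from_records(records)


def resolve_ids(ids: Sequence[str], id_map: IdMap) -> tuple[list[str], list[str]]:
    """Map aliases to primary ids.

    Returns the resolved list (same length and order as the input: aliases
    replaced, primaries unchanged, unknown ids passed through) together with
    the list of unresolved ids — unknowns are reported, never silently
    dropped.
    """
    resolved: list[str] = []
    unresolved: list[str] = []
    for identifier in ids:
        if identifier in id_map.primaries:
            resolved.append(identifier)
        elif identifier in id_map.alias_to_primary:
            resolved.append(id_map.alias_to_primary[identifier])
        else:
            resolved.append(identifier)
            unresolved.append(identifier)
    return resolved, unresolved


# ---------------------------------------------------------------------------
# Discrete matrices and pair tables (pipeline intermediates)
# ---------------------------------------------------------------------------

def write_discrete_matrix(matrix: DiscreteMatrix, path: str | Path) -> None:
    matrix.calls.to_csv(path, sep="\t", index_label="strain")


def read_discrete_matrix(path: str | Path, n_bins: int = 3) -> DiscreteMatrix:
    calls = pd.read_csv(path, sep="\t", index_col="strain")
    return DiscreteMatrix(calls=calls, n_bins=n_bins)


def write_pair_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_pair_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str, "metric": str})
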