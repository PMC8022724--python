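"""Graph-based (Wang) semantic similarity of GO terms and genes.

Each term A defines a semantic profile over its ancestor sub-DAG: the
S-value of A itself is 1 and every ancestor t receives
``S_A(t) = max over children t' of t in DAG_A of w(t' -> t) * S_A(t')``,
where the edge weight depends on the relation (is_a: 0.8, part_of: 0.6 by
default). Two terms are compared by the S-values of their shared ancestors
relative to the total semantic value of each term, and genes by the
best-match average (BMA) over their annotated term sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    GeneGoAnnotations,
    UndefinedSimilarityError,
    ValidationError,
)

#: Default semantic-contribution weights of the two retained relation types.
DEFAULT_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class TermSemanticProfile:
    """S-values of one term over its ancestor DAG, and their sum SV."""

    term: str
    s_values: dict[str, float]
    sv: float = field(init=False)

    def __post_init__(self) -> None:
        self.sv = float(sum(self.s_values.values()))


def _weights(weights: dict[str, float] | None) -> dict[str, float]:
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    for rel, val in w.items():
        if not (0.0 < val < 1.0):
            raise ValidationError(f"semantic weight for {rel!r} must be in (0,1), got {val}")
    return w


def s_values(
    term: str,
    graph: nx.DiGraph,
    weights: dict[str, float] | None = None,
) -> TermSemanticProfile:
    """Semantic profile of ``term``: S-values over it and all its ancestors.

    Computed by dynamic programming in topological order over the ancestor
    sub-DAG (edges run child -> parent, so ancestors are graph descendants).
    """
    if term not in graph:
        raise ValidationError(f"unknown term: {term}")
    w = _weights(weights)
    dag_nodes = {term} | nx.descendants(graph, term)
    sub = graph.subgraph(dag_nodes)
    s: dict[str, float] = {term: 1.0}
    for node in nx.topological_sort(sub):
        if node == term:
            continue
        best = 0.0
        for child, _, data in sub.in_edges(node, data=True):
            relation = data.get("relation", "is_a")
            weight = w.get(relation)
            if weight is None:
                continue
            best = max(best, weight * s[child])
        s[node] = best
    return TermSemanticProfile(term=term, s_values=s)


def term_similarity(
    a: str,
    b: str,
    graph: nx.DiGraph,
    weights: dict[str, float] | None = None,
    _cache: dict | None = None,
) -> float:
    """Wang similarity of two terms in [0, 1]; 1 when ``a == b``.

    ``sim(a,b) = sum over shared t of (S_a(t) + S_b(t)) / (SV(a) + SV(b))``.
    Terms must share a namespace.
    """
    ns_a = graph.nodes[a].get("namespace") if a in graph else None
    ns_b = graph.nodes[b].get("namespace") if b in graph else None
    if a not in graph or b not in graph:
        missing = [t for t in (a, b) if t not in graph]
        raise ValidationError(f"unknown term(s): {missing}")
    if ns_a and ns_b and ns_a != ns_b:
        raise ValidationError(
            f"cross-namespace comparison: {a} ({ns_a}) vs {b} ({ns_b})"
        )
    if _cache is not None:
        prof_a = _cache.setdefault(a, s_values(a, graph, weights))
        prof_b = _cache.setdefault(b, s_values(b, graph, weights))
    else:
        prof_a = s_values(a, graph, weights)
        prof_b = s_values(b, graph, weights)
    shared = prof_a.s_values.keys() & prof_b.s_values.keys()
    if not shared:
        return 0.0
    num = sum(prof_a.s_values[t] + prof_b.s_values[t] for t in shared)
    return float(num / (prof_a.sv + prof_b.sv))


def gene_similarity(
    gene_a: str,
    gene_b: str,
    annotations: GeneGoAnnotations,
    graph: nx.DiGraph,
    combine: str = "bma",
    weights: dict[str, float] | None = None,
    _profile_cache: dict | None = None,
    _term_sim_cache: dict | None = None,
) -> float:
    """Best-match-average semantic similarity of two annotated genes.

    For each term of one gene take the maximal similarity against the other
    gene's terms; average all row and column maxima. Genes without any term
    raise :class:`UndefinedSimilarityError` (the caller filters to annotated
    genes).
    """
    if combine != "bma":
        raise ValidationError(f"unknown combine method: {combine!r}")
    terms_a = sorted(annotations.gene_to_terms.get(gene_a, frozenset()))
    terms_b = sorted(annotations.gene_to_terms.get(gene_b, frozenset()))
    if not terms_a or not terms_b:
        missing = [g for g, t in ((gene_a, terms_a), (gene_b, terms_b)) if not t]
        raise UndefinedSimilarityError(f"gene(s) without GO terms: {missing}")
    prof_cache = _profile_cache if _profile_cache is not None else {}

    def tsim(t1: str, t2: str) -> float:
        if _term_sim_cache is not None:
            key = (t1, t2) if t1 <= t2 else (t2, t1)
            if key not in _term_sim_cache:
                _term_sim_cache[key] = term_similarity(t1, t2, graph, weights, _cache=prof_cache)
            return _term_sim_cache[key]
        return term_similarity(t1, t2, graph, weights, _cache=prof_cache)

    sims = np.array([[tsim(ta, tb) for tb in terms_b] for ta in terms_a])
    row_max = sims.max(axis=1)
    col_max = sims.max(axis=0)
    return float((row_max.sum() + col_max.sum()) / (len(terms_a) + len(terms_b)))


def gene_pair_table(
    genes: list[str],
    annotations: GeneGoAnnotations,
    graph: nx.DiGraph,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Semantic similarity of every annotated gene pair as a tidy pair table.

    Unannotated genes are dropped (mirroring the restriction of semantic
    analysis to the annotated fraction of a strain collection); the result
    uses the same schema as the profile-similarity tables, with metric
    ``go_wang_bma``.
    """
    annotated = [g for g in genes if annotations.gene_to_terms.get(g)]
    profile_cache: dict = {}
    term_sim_cache: dict = {}
    rows = []
    for ga, gb in itertools.combinations(annotated, 2):
        value = gene_similarity(
            ga, gb, annotations, graph, weights=weights,
            _profile_cache=profile_cache, _term_sim_cache=term_sim_cache,
        )
        a, b = (ga, gb) if ga < gb else (gb, ga)
        rows.append((a, b, "go_wang_bma", value))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "metric", "value"])
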