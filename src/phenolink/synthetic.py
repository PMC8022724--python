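"""Synthetic chemical-genomics datasets with planted functional structure.

The generator emulates the statistical shape of a genome-scale fitness
screen: per-condition standard-normal scores, a large majority of
no-phenotype cells, disjoint gene modules whose members share a latent
condition response (so their profiles correlate), an auxotroph block with
extreme negative scores confined to minimal-media conditions, concentration
series grouped into stresses, a small missing-value fraction, and a toy GO
DAG. Ground-truth tables make every downstream stage testable without the
original published dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    AnnotationSet,
    ConditionTable,
    ConfigurationError,
    FitnessMatrix,
    GeneGoAnnotations,
)

# Fixed spawn keys so each generation stage has its own RNG stream and can be
# regenerated independently of the others.
_STREAM_FITNESS = 0
_STREAM_ANNOTATIONS = 1
_STREAM_GO = 2
_STREAM_MISSING = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the stated synthetic world.

    Defaults are a desk-scale analogue of a 3979-strain x 324-condition
    screen (114 stresses, 10 minimal-media conditions, 0.17% missing):
    400 strains x 40 stresses x 3 concentrations, 12 planted modules.
    """

    n_strains: int = 400
    n_stresses: int = 40
    reps_per_stress: int = 3
    n_modules: int = 12
    module_size_range: tuple[int, int] = (4, 8)
    within_module_correlation: float = 0.8
    signal_fraction: float = 0.75
    n_auxotrophs: int = 30
    n_minimal_conditions: int = 10
    auxotroph_score: float = -6.0
    missing_rate: float = 0.0017
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ConfigurationError("n_strains must be >= 1")
        if self.n_stresses < 1 or self.reps_per_stress < 1:
            raise ConfigurationError("n_stresses and reps_per_stress must be >= 1")
        if self.n_minimal_conditions > self.n_conditions:
            raise ConfigurationError(
                f"n_minimal_conditions ({self.n_minimal_conditions}) exceeds total "
                f"conditions ({self.n_conditions})"
            )
        if not (0.0 <= self.within_module_correlation <= 1.0):
            raise ConfigurationError("within_module_correlation must be in [0, 1]")
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise ConfigurationError("signal_fraction must be in [0, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        lo, hi = self.module_size_range
        if lo < 2 or hi < lo:
            raise ConfigurationError("module_size_range must satisfy 2 <= min <= max")
        if self.n_modules * hi > self.n_strains:
            raise ConfigurationError(
                "module_size_range: maximal total module size exceeds n_strains"
            )
        if self.n_auxotrophs > self.n_strains:
            raise ConfigurationError("n_auxotrophs exceeds n_strains")

    @property
    def n_conditions(self) -> int:
        return self.n_stresses * self.reps_per_stress


@dataclass
class GroundTruth:
    """Truth tables for parameter-recovery tests."""

    module_membership: dict[str, int]
    auxotroph_flags: dict[str, bool]
    responsive_conditions: dict[int, frozenset[str]]

    def module_genes(self, module: int) -> list[str]:
        return sorted(g for g, m in self.module_membership.items() if m == module)

    @property
    def modules(self) -> list[int]:
        return sorted(set(self.module_membership.values()))

    def comembership_pairs(self) -> frozenset[tuple[str, str]]:
        pairs: set[tuple[str, str]] = set()
        for module in self.modules:
            genes = self.module_genes(module)
            for i, a in enumerate(genes):
                for b in genes[i + 1:]:
                    pairs.add((a, b))
        return frozenset(pairs)


def _condition_table(config: SyntheticConfig) -> ConditionTable:
    rows = []
    idx = 0
    total = config.n_conditions
    width = len(str(total))
    for s in range(config.n_stresses):
        for r in range(config.reps_per_stress):
            idx += 1
            rows.append({
                "condition_id": f"c{idx:0{width}d}",
                "stress_id": f"s{s + 1:03d}",
                "level_label": f"L{r + 1}",
                # the last n_minimal_conditions columns are minimal media
                "is_minimal": idx > total - config.n_minimal_conditions,
            })
    return ConditionTable(pd.DataFrame(rows))


def generate_fitness_matrix(
    config: SyntheticConfig,
) -> tuple[FitnessMatrix, ConditionTable, GroundTruth]:
    """Generate background + planted-module fitness scores.

    Background cells are i.i.d. standard normal. Members of a module share a
    latent per-condition response on that module's responsive conditions:
    ``score = sqrt(rho) * z_module + sqrt(1 - rho) * noise`` so the expected
    within-module Pearson correlation on those conditions is ``rho``. Every
    column is re-standardized to mean 0, sd 1 afterwards. Deterministic given
    ``config.seed``.
    """
    rng = _rng(config.seed, _STREAM_FITNESS)
    conditions = _condition_table(config)
    n, m = config.n_strains, config.n_conditions
    strain_ids = [f"g{i + 1:04d}" for i in range(n)]
    cond_ids = conditions.condition_ids

    scores = rng.standard_normal((n, m))

    # Plant modules on contiguous strain blocks; responsive conditions are
    # drawn from the non-minimal columns so the auxotroph block stays the
    # only minimal-media signal.
    sizes = rng.integers(config.module_size_range[0], config.module_size_range[1] + 1,
                         size=config.n_modules)
    if int(sizes.sum()) > n:
        raise ConfigurationError("sum of module sizes exceeds n_strains")
    non_minimal = np.array(
        [i for i, c in enumerate(cond_ids) if c not in set(conditions.minimal_conditions)]
    )
    n_responsive = int(round(config.signal_fraction * m))
    n_responsive = min(n_responsive, len(non_minimal))

    rho = config.within_module_correlation
    membership: dict[str, int] = {}
    responsive: dict[int, frozenset[str]] = {}
    cursor = 0
    for module, size in enumerate(sizes, start=1):
        members = list(range(cursor, cursor + int(size)))
        cursor += int(size)
        for i in members:
            membership[strain_ids[i]] = module
        if n_responsive == 0:
            responsive[module] = frozenset()
            continue
        resp_idx = np.sort(rng.choice(non_minimal, size=n_responsive, replace=False))
        responsive[module] = frozenset(cond_ids[j] for j in resp_idx)
        latent = rng.standard_normal(n_responsive)
        for i in members:
            noise = rng.standard_normal(n_responsive)
            scores[i, resp_idx] = math.sqrt(rho) * latent + math.sqrt(1.0 - rho) * noise

    # Re-standardize every condition column (population sd).
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0)

    matrix = FitnessMatrix(pd.DataFrame(scores, index=strain_ids, columns=cond_ids))
    truth = GroundTruth(
        module_membership=membership,
        auxotroph_flags={s: False for s in strain_ids},
        responsive_conditions=responsive,
    )
    return matrix, conditions, truth


def inject_auxotroph_block(
    matrix: FitnessMatrix,
    conditions: ConditionTable,
    truth: GroundTruth,
    config: SyntheticConfig,
) -> FitnessMatrix:
    """Overwrite minimal-media cells of selected strains with an extreme score.

    Auxotroph strains are picked round-robin across the planted modules first
    (one member per module per round), then from background strains, so pairs
    of auxotrophs are mostly NOT co-annotated — reproducing the biosynthetic-
    gene artefact where unrelated mutants share huge negative minimal-media
    scores. The score overwrites the background draw so the outlier magnitude
    is guaranteed. ``truth.auxotroph_flags`` is updated in place.
    """
    if config.n_auxotrophs > len(matrix.strain_ids):
        raise ConfigurationError("n_auxotrophs exceeds the number of strains")
    if config.n_auxotrophs == 0:
        return matrix.copy()
    minimal = conditions.minimal_conditions
    if not minimal:
        raise ConfigurationError(
            "n_auxotrophs > 0 requires at least one is_minimal condition"
        )

    by_module: dict[int, list[str]] = {}
    for gene in matrix.strain_ids:
        mod = truth.module_membership.get(gene)
        if mod is not None:
            by_module.setdefault(mod, []).append(gene)
    background = [g for g in matrix.strain_ids if g not in truth.module_membership]

    order: list[str] = []
    round_idx = 0
    while any(len(v) > round_idx for v in by_module.values()):
        for mod in sorted(by_module):
            if len(by_module[mod]) > round_idx:
                order.append(by_module[mod][round_idx])
        round_idx += 1
    order.extend(background)
    chosen = order[: config.n_auxotrophs]

    out = matrix.scores.copy()
    out.loc[chosen, minimal] = config.auxotroph_score
    for gene in chosen:
        truth.auxotroph_flags[gene] = True
    return FitnessMatrix(out)


def generate_annotation_sets(
    truth: GroundTruth,
    n_sets: int,
    coverage: float,
    seed: int,
) -> list[AnnotationSet]:
    """Derive annotation sets from module membership.

    Each set gives every module one term annotating a random ``coverage``
    fraction of its members; independent subsampling per set emulates how
    pathway, complex, and operon annotations partially disagree.
    """
    if n_sets < 1:
        raise ConfigurationError("n_sets must be >= 1")
    if not (0.0 < coverage <= 1.0):
        raise ConfigurationError("coverage must be in (0, 1]")
    rng = _rng(seed, _STREAM_ANNOTATIONS)
    sets = []
    for s in range(1, n_sets + 1):
        term_to_genes: dict[str, frozenset[str]] = {}
        for module in truth.modules:
            genes = truth.module_genes(module)
            k = int(round(coverage * len(genes)))
            if k == 0:
                continue
            picked = sorted(rng.choice(genes, size=k, replace=False).tolist())
            term_to_genes[f"SET{s}:M{module:03d}"] = frozenset(picked)
        sets.append(AnnotationSet(name=f"set{s}", term_to_genes=term_to_genes))
    return sets


def generate_toy_go(
    depth: int,
    branching: int,
    part_of_fraction: float,
    seed: int,
    truth: GroundTruth | None = None,
    genes: list[str] | None = None,
    annotated_fraction: float = 0.66,
) -> tuple[nx.DiGraph, GeneGoAnnotations]:
    """Build a rooted biological-process toy DAG and gene annotations.

    A complete ``branching``-ary tree of the given depth, each child->parent
    edge typed ``part_of`` with probability ``part_of_fraction`` and ``is_a``
    otherwise. When a :class:`GroundTruth` is given, every module's genes are
    annotated to the same leaf (so module mates share terms); background
    genes are annotated to a random leaf with probability
    ``annotated_fraction``, emulating a screen where about two thirds of
    strains carry a biological-process annotation.
    """
    if depth < 1 or branching < 1:
        raise ConfigurationError("depth and branching must be >= 1")
    if not (0.0 <= part_of_fraction <= 1.0):
        raise ConfigurationError("part_of_fraction must be in [0, 1]")
    rng = _rng(seed, _STREAM_GO)

    graph = nx.DiGraph()
    counter = 1
    root = f"GO:{counter:07d}"
    graph.add_node(root, name="biological_process", namespace="biological_process")
    level = [root]
    for _ in range(depth):
        nxt = []
        for parent in level:
            for _ in range(branching):
                counter += 1
                term = f"GO:{counter:07d}"
                relation = "part_of" if rng.random() < part_of_fraction else "is_a"
                graph.add_node(term, name=f"process {counter}",
                               namespace="biological_process")
                graph.add_edge(term, parent, relation=relation)
                nxt.append(term)
        level = nxt
    leaves = level

    gene_to_terms: dict[str, frozenset[str]] = {}
    if truth is not None:
        module_leaf = {
            module: leaves[i % len(leaves)] for i, module in enumerate(truth.modules)
        }
        for gene, module in truth.module_membership.items():
            gene_to_terms[gene] = frozenset({module_leaf[module]})
        pool = [g for g in (genes or []) if g not in truth.module_membership]
        for gene in pool:
            if rng.random() < annotated_fraction:
                gene_to_terms[gene] = frozenset({leaves[int(rng.integers(len(leaves)))]})
    evidence = {
        (g, t): "IDA" for g, terms in gene_to_terms.items() for t in terms
    }
    return graph, GeneGoAnnotations(gene_to_terms=gene_to_terms, evidence=evidence)


def inject_missing_values(matrix: FitnessMatrix, rate: float, seed: int) -> FitnessMatrix:
    """Mask exactly ``round(rate * n_cells)`` cells, uniformly without replacement."""
    if not (0.0 <= rate < 1.0):
        raise ConfigurationError("missing rate must be in [0, 1)")
    out = matrix.scores.copy()
    n_cells = out.size
    k = int(round(rate * n_cells))
    if k:
        rng = _rng(seed, _STREAM_MISSING)
        flat = rng.choice(n_cells, size=k, replace=False)
        values = out.to_numpy()
        values[np.unravel_index(flat, values.shape)] = np.nan
        out = pd.DataFrame(values, index=out.index, columns=out.columns)
    return FitnessMatrix(out)


def generate_dataset(
    config: SyntheticConfig,
    n_annotation_sets: int = 2,
    coverage: float = 0.8,
    go_depth: int = 3,
    go_branching: int = 3,
    part_of_fraction: float = 0.2,
) -> dict:
    """Convenience wrapper running every generation stage in order.

    Returns a dict with keys ``matrix`` (missing values injected),
    ``conditions``, ``truth``, ``annotation_sets``, ``go_graph``,
    ``go_annotations``.
    """
    matrix, conditions, truth = generate_fitness_matrix(config)
    matrix = inject_auxotroph_block(matrix, conditions, truth, config)
    matrix = inject_missing_values(matrix, config.missing_rate, config.seed)
    annotation_sets = generate_annotation_sets(
        truth, n_sets=n_annotation_sets, coverage=coverage, seed=config.seed
    )
    go_graph, go_annotations = generate_toy_go(
        depth=go_depth, branching=go_branching, part_of_fraction=part_of_fraction,
        seed=config.seed, truth=truth, genes=matrix.strain_ids,
    )
    return {
        "matrix": matrix,
        "conditions": conditions,
        "truth": truth,
        "annotation_sets": annotation_sets,
        "go_graph": go_graph,
        "go_annotations": go_annotations,
    }
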