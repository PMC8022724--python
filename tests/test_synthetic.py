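"""Generator contracts: standardization, planted correlation, determinism."""

import dataclasses

import networkx as nx
import numpy as np
import pytest

import phenolink as pl
from phenolink.containers import ConfigurationError
from phenolink.synthetic import (
    SyntheticConfig,
    generate_annotation_sets,
    generate_fitness_matrix,
    generate_toy_go,
    inject_auxotroph_block,
    inject_missing_values,
)


@pytest.mark.parametrize("bad", [
    {"n_strains": 0},
    {"within_module_correlation": 1.5},
    {"missing_rate": 1.0},
    {"n_minimal_conditions": 10_000},
    {"module_size_range": (1, 3)},
    {"module_size_range": (40, 50)},   # 12 modules x 50 > 400 strains
    {"n_auxotrophs": 401},
])
def test_config_invariants_rejected(bad):
    with pytest.raises(ConfigurationError):
        SyntheticConfig(**bad)


def test_null_model_columns_standard():
    cfg = SyntheticConfig(n_modules=0, n_auxotrophs=0, within_module_correlation=0.0,
                          missing_rate=0.0, seed=3)
    matrix, _, truth = generate_fitness_matrix(cfg)
    vals = matrix.scores.to_numpy()
    assert np.allclose(vals.mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(vals.std(axis=0), 1.0, atol=1e-9)
    assert truth.module_membership == {}


def test_column_standardization_with_modules(dataset):
    # before missing injection / auxotroph overwrite the columns are standard
    cfg = SyntheticConfig(seed=1)
    matrix, _, _ = generate_fitness_matrix(cfg)
    vals = matrix.scores.to_numpy()
    assert np.allclose(vals.mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(vals.std(axis=0), 1.0, atol=1e-9)


def test_perfect_correlation_limit():
    cfg = SyntheticConfig(
        n_strains=30, n_stresses=10, reps_per_stress=3, n_modules=1,
        module_size_range=(3, 3), within_module_correlation=1.0,
        signal_fraction=1.0, n_auxotrophs=0, n_minimal_conditions=0,
        missing_rate=0.0, seed=5,
    )
    matrix, _, truth = generate_fitness_matrix(cfg)
    genes = truth.module_genes(1)
    assert len(genes) == 3
    for i in range(3):
        for j in range(i + 1, 3):
            assert pl.abs_pcc(matrix.scores.loc[genes[i]], matrix.scores.loc[genes[j]]) \
                == pytest.approx(1.0, abs=1e-12)


def test_planted_correlation_recovers_rho():
    """Monte-Carlo check of the mixture: mean within-module |PCC| ~= rho.

    The module must be a small fraction of the strain population, otherwise
    per-column re-standardization absorbs part of the shared latent and
    attenuates the observed correlation.
    """
    cfg = SyntheticConfig(
        n_strains=400, n_stresses=100, reps_per_stress=3, n_modules=1,
        module_size_range=(10, 10), within_module_correlation=0.8,
        signal_fraction=1.0, n_auxotrophs=0, n_minimal_conditions=0,
        missing_rate=0.0, seed=1,
    )
    matrix, _, truth = generate_fitness_matrix(cfg)
    genes = truth.module_genes(1)
    sims = [
        pl.abs_pcc(matrix.scores.loc[a], matrix.scores.loc[b])
        for i, a in enumerate(genes) for b in genes[i + 1:]
    ]
    assert abs(np.mean(sims) - 0.8) < 0.05


def test_seed_determinism(default_config):
    m1, c1, t1 = generate_fitness_matrix(default_config)
    m2, c2, t2 = generate_fitness_matrix(default_config)
    assert m1.scores.equals(m2.scores)
    assert c1.frame.equals(c2.frame)
    assert t1.module_membership == t2.module_membership
    assert t1.responsive_conditions == t2.responsive_conditions


class TestAuxotrophBlock:
    def test_noop_when_zero(self, default_config):
        cfg = dataclasses.replace(default_config, n_auxotrophs=0)
        matrix, conds, truth = generate_fitness_matrix(cfg)
        out = inject_auxotroph_block(matrix, conds, truth, cfg)
        assert out.scores.equals(matrix.scores)
        assert not any(truth.auxotroph_flags.values())

    def test_block_overwrites_minimal_cells(self, default_config):
        matrix, conds, truth = generate_fitness_matrix(default_config)
        out = inject_auxotroph_block(matrix, conds, truth, default_config)
        aux = [g for g, f in truth.auxotroph_flags.items() if f]
        assert len(aux) == default_config.n_auxotrophs
        minimal = conds.minimal_conditions
        assert len(minimal) == default_config.n_minimal_conditions
        block = out.scores.loc[aux, minimal].to_numpy()
        assert (block == default_config.auxotroph_score).all()
        # non-minimal cells untouched
        other = [c for c in out.condition_ids if c not in set(minimal)]
        assert out.scores[other].equals(matrix.scores[other])

    def test_outlier_dominates_pcc(self, default_config):
        """Two auxotrophs from distinct modules correlate more strongly with
        minimal-media conditions included than excluded."""
        matrix, conds, truth = generate_fitness_matrix(default_config)
        out = inject_auxotroph_block(matrix, conds, truth, default_config)
        aux = [g for g, f in truth.auxotroph_flags.items() if f]
        a, b = next(
            (x, y) for i, x in enumerate(aux) for y in aux[i + 1:]
            if truth.module_membership.get(x) != truth.module_membership.get(y)
        )
        minimal = set(conds.minimal_conditions)
        nonmin = [c for c in out.condition_ids if c not in minimal]
        full = pl.abs_pcc(out.scores.loc[a], out.scores.loc[b])
        partial = pl.abs_pcc(out.scores.loc[a, nonmin], out.scores.loc[b, nonmin])
        assert full > partial

    def test_too_many_auxotrophs(self, default_config):
        matrix, conds, truth = generate_fitness_matrix(default_config)
        truncated = pl.FitnessMatrix(matrix.scores.iloc[:10])  # 10 strains < 30 auxotrophs
        with pytest.raises(ConfigurationError):
            inject_auxotroph_block(truncated, conds, truth, default_config)


class TestAnnotationSets:
    def test_full_coverage_equals_comembership(self, dataset):
        truth = dataset["truth"]
        (aset,) = generate_annotation_sets(truth, n_sets=1, coverage=1.0, seed=2)
        assert aset.coannotated_pairs() == truth.comembership_pairs()

    def test_union_monotonicity(self, dataset):
        truth = dataset["truth"]
        s1, s2 = generate_annotation_sets(truth, n_sets=2, coverage=0.5, seed=2)
        union = s1.coannotated_pairs() | s2.coannotated_pairs()
        assert union >= s1.coannotated_pairs()
        assert union >= s2.coannotated_pairs()

    def test_combinatorial_pair_count(self, dataset):
        truth = dataset["truth"]
        (aset,) = generate_annotation_sets(truth, n_sets=1, coverage=1.0, seed=2)
        for term, genes in aset.term_to_genes.items():
            module = int(term.rsplit("M", 1)[1])
            size = len(truth.module_genes(module))
            assert len(genes) == size
        n_pairs = sum(
            len(g) * (len(g) - 1) // 2 for g in aset.term_to_genes.values()
        )
        assert len(aset.coannotated_pairs()) == n_pairs

    def test_coverage_validation(self, dataset):
        with pytest.raises(ConfigurationError):
            generate_annotation_sets(dataset["truth"], n_sets=1, coverage=0.0, seed=2)
        with pytest.raises(ConfigurationError):
            generate_annotation_sets(dataset["truth"], n_sets=0, coverage=1.0, seed=2)


class TestToyGo:
    def test_smallest_dag(self):
        graph, _ = generate_toy_go(depth=1, branching=2, part_of_fraction=0.0, seed=1)
        assert graph.number_of_nodes() == 3
        assert graph.number_of_edges() == 2

    def test_all_is_a_when_fraction_zero(self):
        graph, _ = generate_toy_go(depth=3, branching=2, part_of_fraction=0.0, seed=1)
        assert all(d["relation"] == "is_a" for _, _, d in graph.edges(data=True))

    @pytest.mark.parametrize("depth,branching,pf", [(1, 1, 0.5), (3, 3, 0.2), (4, 2, 1.0)])
    def test_acyclic(self, depth, branching, pf):
        graph, _ = generate_toy_go(depth, branching, pf, seed=9)
        assert nx.is_directed_acyclic_graph(graph)
        list(nx.topological_sort(graph))  # raises on a cycle

    def test_module_mates_share_terms(self, dataset):
        truth = dataset["truth"]
        ann = dataset["go_annotations"]
        for module in truth.modules:
            genes = truth.module_genes(module)
            terms = {ann.gene_to_terms[g] for g in genes}
            assert len(terms) == 1  # one shared leaf per module


class TestMissingValues:
    def test_rate_zero_noop(self, matrix_factory):
        m = matrix_factory(np.arange(12.0).reshape(3, 4))
        out = inject_missing_values(m, rate=0.0, seed=1)
        assert out.scores.equals(m.scores)

    def test_exact_count(self):
        rng = np.random.default_rng(0)
        import pandas as pd
        m = pl.FitnessMatrix(pd.DataFrame(rng.standard_normal((1000, 300))))
        out = inject_missing_values(m, rate=0.0017, seed=1)
        assert out.n_missing == 510  # round(0.0017 * 300000)

    def test_determinism(self, matrix_factory):
        m = matrix_factory(np.random.default_rng(2).standard_normal((50, 40)))
        a = inject_missing_values(m, rate=0.05, seed=11)
        b = inject_missing_values(m, rate=0.05, seed=11)
        assert a.missing_mask.equals(b.missing_mask)

    def test_rate_validation(self, matrix_factory):
        m = matrix_factory(np.zeros((2, 3)))
        with pytest.raises(ConfigurationError):
            inject_missing_values(m, rate=1.0, seed=1)
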