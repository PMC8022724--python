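"""Labels, rankings, precision curves, controls, and rank-sum tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phenolink as pl
from phenolink import evaluation as ev
from phenolink.containers import ConfigurationError, ValidationError


def aset(name, **terms):
    return pl.AnnotationSet(name=name, term_to_genes={
        t: frozenset(g) for t, g in terms.items()})


def ranked_frame(labels_or_values):
    """A ranked table from a descending value list (gene ids v1, v2, ...)."""
    n = len(labels_or_values)
    return pd.DataFrame({
        "gene_a": [f"a{i}" for i in range(n)],
        "gene_b": [f"b{i}" for i in range(n)],
        "metric": "m",
        "value": np.linspace(1, 0, n),
        "rank": np.arange(1, n + 1),
    })


def labels_for(ranked, flags):
    positives = frozenset(
        (a, b) for a, b, f in zip(ranked["gene_a"], ranked["gene_b"], flags) if f
    )
    universe = tuple(ranked["gene_a"]) + tuple(ranked["gene_b"])
    return pl.CoAnnotationLabels(universe=universe, positive_pairs=positives)


class TestCoannotationLabels:
    def test_single_set_single_pair(self):
        labels = pl.coannotation_labels(["g1", "g2", "g3"], [aset("s", T=["g1", "g2"])])
        assert labels.label("g1", "g2")
        assert not labels.label("g1", "g3")

    def test_union_is_logical_or(self):
        s1 = aset("s1", T1=["g1", "g2"], T2=["g3", "g4"])
        s2 = aset("s2", T3=["g2", "g3"])
        universe = ["g1", "g2", "g3", "g4"]
        union = pl.coannotation_labels(universe, [s1, s2], mode="union")
        l1 = pl.coannotation_labels(universe, [s1])
        l2 = pl.coannotation_labels(universe, [s2])
        for a in universe:
            for b in universe:
                if a < b:
                    assert union.label(a, b) == (l1.label(a, b) or l2.label(a, b))

    def test_intersection_requires_every_set(self):
        s1 = aset("s1", T1=["g1", "g2"])
        s2 = aset("s2", T2=["g3", "g4"])
        inter = pl.coannotation_labels(["g1", "g2", "g3", "g4"], [s1, s2],
                                       mode="intersection")
        assert len(inter.positive_pairs) == 0

    def test_empty_universe_errors(self):
        with pytest.raises(ValidationError):
            pl.coannotation_labels([], [aset("s", T=["g1", "g2"])])


class TestRankPairs:
    def _table(self, values):
        return pd.DataFrame({
            "gene_a": [f"x{i}" for i in range(len(values))],
            "gene_b": [f"y{i}" for i in range(len(values))],
            "metric": "abs_pcc",
            "value": values,
        })

    def test_rank_order(self):
        ranked = pl.rank_pairs(self._table([0.9, 0.1, 0.5]), "abs_pcc")
        assert ranked["value"].tolist() == [0.9, 0.5, 0.1]
        assert ranked["rank"].tolist() == [1, 2, 3]

    def test_tie_break_deterministic(self):
        t = self._table([0.5, 0.5, 0.5])
        r1 = pl.rank_pairs(t, "abs_pcc")
        r2 = pl.rank_pairs(t.sample(frac=1, random_state=0), "abs_pcc")
        assert r1["gene_a"].tolist() == r2["gene_a"].tolist() == ["x0", "x1", "x2"]

    def test_sorted_nonincreasing(self):
        rng = np.random.default_rng(2)
        ranked = pl.rank_pairs(self._table(rng.uniform(size=100)), "abs_pcc")
        assert (np.diff(ranked["value"].to_numpy()) <= 0).all()

    def test_missing_metric_errors(self):
        with pytest.raises(ValidationError):
            pl.rank_pairs(self._table([0.5]), "mi_cont")


class TestPrecisionCurve:
    def test_hand_example(self):
        ranked = ranked_frame([1, 0, 1, 1])
        labels = labels_for(ranked, [1, 0, 1, 1])
        curve = pl.precision_curve(ranked, labels, max_rank=4)
        assert curve["precision"].tolist() == pytest.approx([1, 0.5, 2 / 3, 0.75])

    @pytest.mark.parametrize("flag,expected", [(True, 1.0), (False, 0.0)])
    def test_constant_labels(self, flag, expected):
        ranked = ranked_frame(range(10))
        labels = labels_for(ranked, [flag] * 10)
        curve = pl.precision_curve(ranked, labels)
        assert (curve["precision"] == expected).all()

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(st.lists(st.booleans(), min_size=1, max_size=1000))
    def test_running_count_oracle(self, flags):
        ranked = ranked_frame(flags)
        labels = labels_for(ranked, flags)
        curve = pl.precision_curve(ranked, labels)
        running = 0
        for n, f in enumerate(flags, start=1):
            running += int(f)
            assert curve["precision"].iloc[n - 1] == pytest.approx(running / n)


class TestPrecisionRecallTopk:
    def test_hand_example(self):
        ranked = ranked_frame([1, 0, 1, 1])
        labels = labels_for(ranked, [1, 0, 1, 1])
        pr = pl.precision_recall_topk(ranked, labels, k=4)
        assert not pr.zero_positives
        assert pr.frame["recall"].tolist() == pytest.approx([1 / 3, 1 / 3, 2 / 3, 1.0])

    def test_recall_exhausts_at_k(self):
        flags = [0, 1, 0, 1, 1, 0]
        ranked = ranked_frame(flags)
        labels = labels_for(ranked, flags)
        pr = pl.precision_recall_topk(ranked, labels, k=6)
        assert pr.frame["recall"].iloc[-1] == pytest.approx(1.0)

    def test_zero_positives_flagged(self):
        ranked = ranked_frame([0, 0, 0])
        labels = labels_for(ranked, [0, 0, 0])
        pr = pl.precision_recall_topk(ranked, labels, k=3)
        assert pr.zero_positives
        assert (pr.frame["recall"] == 0).all()


class TestControls:
    def test_permuted_determinism(self, union_labels):
        c1 = ev.permuted_ranking_control(union_labels, n_pairs=100, seed=5)
        c2 = ev.permuted_ranking_control(union_labels, n_pairs=100, seed=5)
        assert c1.equals(c2)

    def test_zero_base_rate_flat(self):
        labels = pl.CoAnnotationLabels(universe=tuple(f"g{i}" for i in range(20)),
                                       positive_pairs=frozenset())
        curve = ev.permuted_ranking_control(labels, n_pairs=50, seed=1)
        assert (curve["precision"] == 0).all()

    def test_sampled_pairs_full_and_unique(self):
        labels = pl.CoAnnotationLabels(universe=("a", "b", "c", "d"),
                                       positive_pairs=frozenset({("a", "b")}))
        full = ev.sampled_pairs_control(labels, n=6, seed=0)
        assert len(full) == 6
        sample = ev.sampled_pairs_control(labels, n=4, seed=0)
        assert len(set(zip(sample["gene_a"], sample["gene_b"]))) == 4
        again = ev.sampled_pairs_control(labels, n=4, seed=0)
        assert sample.equals(again)
        with pytest.raises(ValidationError):
            ev.sampled_pairs_control(labels, n=7, seed=0)


class TestGroupPermutation:
    def _table(self, genes, rng):
        rows = []
        for i, a in enumerate(genes):
            for b in genes[i + 1:]:
                rows.append((a, b, "abs_pcc", rng.uniform()))
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "metric", "value"])

    def test_validation(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(6)]
        table = self._table(genes, rng)
        with pytest.raises(ValidationError):
            pl.group_permutation_test(["g0"], table, genes)
        with pytest.raises(ConfigurationError):
            pl.group_permutation_test(["g0", "g1"], table, genes, n_perm=0)

    def test_strict_inequality_counts_only_greater(self):
        # every pair has identical similarity -> no null mean exceeds observed
        genes = [f"g{i}" for i in range(8)]
        rows = [(a, b, "abs_pcc", 0.5) for i, a in enumerate(genes) for b in genes[i + 1:]]
        table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "metric", "value"])
        res = pl.group_permutation_test(genes[:3], table, genes, n_perm=50, seed=1)
        assert res.p_value == 0.0

    def test_planted_group_significant(self, dataset, imputed):
        truth = dataset["truth"]
        minimal = set(dataset["conditions"].minimal_conditions)
        table = pl.pairwise_table(imputed, "abs_pcc", exclude_conditions=minimal)
        module = truth.module_genes(truth.modules[0])
        res = pl.group_permutation_test(module, table, imputed.strain_ids,
                                        n_perm=200, seed=3)
        assert res.observed > np.mean(res.null_means)
        assert res.p_value <= 0.005


class TestDistributionSummary:
    def test_cutoff_fraction(self):
        s = pl.distribution_summary([0.0, 0.15], cutoff=0.1)
        assert s["frac_above_cutoff"] == pytest.approx(0.5)

    def test_log_transform_constant(self):
        s = pl.distribution_summary([0.0], cutoff=0.5, log_transform=True)
        assert s["mean"] == pytest.approx(-6.0)

    def test_type7_quantiles(self):
        s = pl.distribution_summary([1, 2, 3, 4], cutoff=0)
        assert s["median"] == pytest.approx(2.5)
        assert s["q1"] == pytest.approx(1.75)
        assert s["q3"] == pytest.approx(3.25)

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            pl.distribution_summary([], cutoff=0)


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = pl.mann_whitney_one_sided([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(1 / 20)

    def test_identical_samples_not_significant(self):
        _, p = pl.mann_whitney_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.5

    def test_far_shift_tiny_p(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(100)
        b = rng.standard_normal(100) + 100
        _, p = pl.mann_whitney_one_sided(a, b)
        assert p < 1e-10


class TestCompareToplists:
    def test_identical_rankings_no_discordance(self):
        r = ranked_frame([1, 1, 0, 0])
        report = pl.compare_metric_toplists(r, r.copy(), k=2, threshold=0.5)
        assert report.counts == (0, 0)

    def test_matches_brute_force_sets(self):
        rng = np.random.default_rng(11)
        n = 100
        pairs = [(f"a{i}", f"b{i}") for i in range(n)]
        va, vb = rng.uniform(size=n), rng.uniform(size=n)

        def mk(vals):
            f = pd.DataFrame({"gene_a": [p[0] for p in pairs],
                              "gene_b": [p[1] for p in pairs],
                              "metric": "m", "value": vals})
            return pl.rank_pairs(f, "m")

        ra, rb = mk(va), mk(vb)
        k, thr = 30, 0.7
        report = pl.compare_metric_toplists(ra, rb, k=k, threshold=thr)
        top_b = set(zip(rb["gene_a"][:k], rb["gene_b"][:k]))
        expected_a = sorted(
            (a, b) for a, b, v in zip(ra["gene_a"], ra["gene_b"], ra["value"])
            if v >= thr and (a, b) not in top_b
        )
        assert report.a_above_threshold_not_in_b_topk == expected_a

    def test_mismatched_universe_errors(self):
        ra = ranked_frame([1, 0])
        rb = ranked_frame([1, 0, 1])
        with pytest.raises(ValidationError):
            pl.compare_metric_toplists(ra, rb, k=1, threshold=0.5)
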