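"""Precision-versus-rank evaluation of similarity metrics against co-annotation.

Ranks all gene pairs by each metric, labels pairs that share an annotation
term, and compares precision curves with and without the minimal-media
conditions — reproducing, on synthetic data, the finding that |PCC| precision
collapses under auxotroph outliers while |SRCC| and MI are stable.
"""

import phenolink as pl
from phenolink.evaluation import (
    group_permutation_test,
    permuted_ranking_control,
    precision_curve,
    rank_pairs,
)
from phenolink.io import impute_population_mean

data = pl.generate_dataset(pl.SyntheticConfig(seed=1))
matrix = impute_population_mean(data["matrix"])
minimal = set(data["conditions"].minimal_conditions)
labels = pl.coannotation_labels(matrix.strain_ids, data["annotation_sets"],
                                mode="union")
print(f"pair universe: {labels.n_pairs}, co-annotation base rate "
      f"{labels.base_rate:.4f}\n")

print(f"{'metric':10s} {'conditions':18s} mean precision @ ranks 1-200")
for metric in ("abs_pcc", "abs_srcc", "mi_cont"):
    for name, excl in (("all", set()), ("minimal excluded", minimal)):
        table = pl.pairwise_table(matrix, metric, exclude_conditions=excl)
        curve = precision_curve(rank_pairs(table, metric), labels, max_rank=200)
        print(f"{metric:10s} {name:18s} {curve['precision'].mean():.3f}")
control = permuted_ranking_control(labels, n_pairs=200, seed=1)
print(f"{'permuted':10s} {'(negative control)':18s} "
      f"{control['precision'].mean():.3f}")
print("-> only |PCC| depends strongly on the minimal-media block; the permuted")
print("   control sits at the base rate.\n")

# group permutation test: are a module's profiles more alike than random sets?
table = pl.pairwise_table(matrix, "abs_pcc", exclude_conditions=minimal)
truth = data["truth"]
module = truth.module_genes(truth.modules[0])
res = group_permutation_test(module, table, matrix.strain_ids,
                             n_perm=1000, seed=1, group_id="module 1")
print(f"module 1 ({len(module)} genes): observed mean |PCC| = {res.observed:.3f}, "
      f"null mean = {res.null_means.mean():.3f}, p = {res.p_value:.3g}")
print("-> none of 1000 random same-size gene sets matches the planted module's "
      "coherence.")
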