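"""Compare |PCC|, |SRCC|, and mutual information as profile-similarity metrics.

Shows the headline methodological result: Pearson correlation is dominated by
the shared extreme scores of auxotrophic mutants on minimal media, while the
rank-based Spearman correlation and binned mutual information are robust to
those outliers.
"""

import phenolink as pl
from phenolink.io import impute_population_mean

data = pl.generate_dataset(pl.SyntheticConfig(seed=1))
matrix = impute_population_mean(data["matrix"])
conditions = data["conditions"]
truth = data["truth"]
minimal = set(conditions.minimal_conditions)

# two auxotrophs from different modules: not functionally related
aux = [g for g, f in truth.auxotroph_flags.items() if f]
a, b = next((x, y) for i, x in enumerate(aux) for y in aux[i + 1:]
            if truth.module_membership.get(x) != truth.module_membership.get(y))
x_all, y_all = matrix.scores.loc[a], matrix.scores.loc[b]
keep = [c for c in matrix.condition_ids if c not in minimal]
x_ex, y_ex = matrix.scores.loc[a, keep], matrix.scores.loc[b, keep]

print(f"unrelated auxotroph pair ({a}, {b}):")
print(f"  |PCC|  all conditions {pl.abs_pcc(x_all, y_all):.3f}   "
      f"minimal excluded {pl.abs_pcc(x_ex, y_ex):.3f}")
print(f"  |SRCC| all conditions {pl.abs_srcc(x_all, y_all):.3f}   "
      f"minimal excluded {pl.abs_srcc(x_ex, y_ex):.3f}")
print(f"  MI     all conditions {pl.mi_continuous(x_all, y_all):.3f}   "
      f"minimal excluded {pl.mi_continuous(x_ex, y_ex):.3f}")
print("-> 10 shared extreme scores inflate |PCC| several-fold but barely move")
print("   the rank-based metrics: correlation without shared function.\n")

# a genuinely co-functional module pair for contrast
mod = truth.module_genes(truth.modules[0])
x, y = matrix.scores.loc[mod[0]], matrix.scores.loc[mod[1]]
print(f"module pair ({mod[0]}, {mod[1]}):")
print(f"  |PCC| {pl.abs_pcc(x, y):.3f}  |SRCC| {pl.abs_srcc(x, y):.3f}  "
      f"MI {pl.mi_continuous(x, y):.3f}")
print("-> real functional signal registers on every metric.")

# the all-pairs table used downstream
table = pl.pairwise_table(matrix, "abs_pcc")
print(f"\npairwise table: {len(table)} unordered strain pairs, "
      f"mean |PCC| = {table['value'].mean():.3f}")
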