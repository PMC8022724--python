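"""Wang graph-based semantic similarity on a toy biological-process DAG.

Walks through the S-value recursion on a hand-built ontology fragment, then
scores gene pairs on the synthetic dataset's toy GO annotations with the
best-match average.
"""

import networkx as nx

import phenolink as pl
from phenolink.gosim import gene_pair_table, s_values, term_similarity

# A small typed DAG: A is_a B is_a R, and A part_of C is_a R.
graph = nx.DiGraph()
for t in ("R", "B", "C", "A"):
    graph.add_node(t, name=t, namespace="biological_process")
graph.add_edge("A", "B", relation="is_a")
graph.add_edge("B", "R", relation="is_a")
graph.add_edge("A", "C", relation="part_of")
graph.add_edge("C", "R", relation="is_a")

profile = s_values("A", graph)
print("S-values of term A over its ancestor DAG:")
for term, s in sorted(profile.s_values.items()):
    print(f"  S_A({term}) = {s:.3f}")
print(f"  SV(A) = {profile.sv:.3f}")
print("-> each ancestor's contribution decays with the weighted path from A;")
print("   the root is reached via is_a x is_a (0.8 x 0.8 = 0.64), beating the")
print("   part_of route (0.6 x 0.8 = 0.48).\n")

print(f"sim(A, B) = {term_similarity('A', 'B', graph):.4f} (parent-child)")
print(f"sim(B, C) = {term_similarity('B', 'C', graph):.4f} (siblings)")
print(f"sim(A, A) = {term_similarity('A', 'A', graph):.4f} (identity)\n")

# Gene-level similarity on the synthetic dataset.
data = pl.generate_dataset(pl.SyntheticConfig(seed=1))
annotations = data["go_annotations"]
table = gene_pair_table(list(data["matrix"].strain_ids), annotations,
                        data["go_graph"])
truth = data["truth"]
labels = pl.coannotation_labels(
    list(data["matrix"].strain_ids), data["annotation_sets"], mode="union")
lab = labels.series(table["gene_a"], table["gene_b"])
print(f"annotated genes: {len(annotations.genes)} of {len(data['matrix'].strain_ids)}")
print(f"mean semantic similarity, all annotated pairs: "
      f"{table['value'].mean():.3f}")
print(f"mean semantic similarity, co-annotated pairs:  "
      f"{table['value'][lab].mean():.3f}")
print("-> genes sharing pathway/complex-style annotations also sit close in "
      "the ontology, mirroring the enrichment seen for real annotation sets.")
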