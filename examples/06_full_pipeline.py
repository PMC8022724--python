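"""Run the whole pipeline from one config and inspect the manifest.

Every stage writes TSV intermediates plus a JSON manifest with config,
per-stage log, and output checksums; the same config and seed reproduce
bit-identical outputs.
"""

import json
from pathlib import Path

import phenolink as pl

outdir = Path("phenolink_example_run")
config = pl.PipelineConfig(
    synthetic=pl.SyntheticConfig(seed=1),
    seed=1,
    exclude_minimal=False,
    n_perm=200,           # keep the example quick
    outdir=str(outdir),
)
manifest = pl.run(config)

print("stages executed:")
for stage in manifest["stages"]:
    extras = {k: v for k, v in stage.items() if k not in ("stage", "elapsed_s")}
    print(f"  {stage['stage']:14s} {stage['elapsed_s']:6.2f}s  {extras}")

print("\noutputs written:")
for name in sorted(manifest["checksums"]):
    print(f"  {outdir / name}")

summaries = (outdir / "distribution_summaries.tsv").read_text().splitlines()
print("\ndistribution summaries (one row per metric):")
print("\n".join(summaries[:3]) + "\n...")

groups = json.loads(json.dumps(manifest["stages"][-1]))
print(f"\nevaluation: {groups['n_pairs']} gene pairs, co-annotation base rate "
      f"{groups['base_rate']}, {groups['n_groups']} annotation groups "
      "permutation-tested.")
print("rerunning with the same seed reproduces identical checksums.")
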