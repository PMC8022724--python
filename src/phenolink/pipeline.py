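"""End-to-end orchestration: generate/load -> impute -> similarity ->
discretize -> GO similarity -> labels -> curves and tests.

Every intermediate is written as TSV under the output directory together
with a JSON manifest (config, seed, stage log, sha256 checksums). A rerun
with the same config and seed writes bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discretize as disc
from . import evaluation as ev
from . import gosim
from . import io as plio
from . import similarity as sim
from .containers import ConfigurationError, FitnessMatrix
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

QUANT_METRICS = ("abs_pcc", "abs_srcc", "mi_cont")


@dataclass
class PipelineConfig:
    """Run parameters for a full analysis.

    Exactly one of ``synthetic`` or ``input_paths`` must be set.
    ``input_paths`` names the flat files (keys: fitness, conditions,
    annotations [list], obo, gaf). Defaults mirror the published analysis:
    precision over the first 500 ranked pairs, PR over the top 5000, 5% FDR
    discretization, |PCC| cutoff 0.75 and MI cutoffs 0.15/0.32 for the
    distribution summaries, 1000 permutations for group tests.
    """

    synthetic: SyntheticConfig | None = None
    input_paths: dict | None = None
    metrics: tuple[str, ...] = QUANT_METRICS
    exclude_minimal: bool = False
    exclude_strains: tuple[str, ...] = ()
    annotation_mode: str = "union"
    alpha: float = 0.05
    n_bins: int = 3
    collapse: bool = True
    go_weights: dict | None = None
    exclude_iea: bool = False
    max_rank: int = 500
    pr_k: int = 5000
    pcc_cutoff: float = 0.75
    mi_cutoff: float = 0.15
    mi_collapsed_cutoff: float = 0.32
    n_perm: int = 1000
    seed: int = 1
    outdir: str = "phenolink_run"
    include_go: bool = True

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_paths is None):
            raise ConfigurationError(
                "exactly one of 'synthetic' or 'input_paths' must be provided"
            )
        bad = [m for m in self.metrics if m not in QUANT_METRICS]
        if bad:
            raise ConfigurationError(f"unknown quantitative metrics: {bad}")
        if self.input_paths is not None:
            missing = [
                k for k, v in self.input_paths.items()
                if k != "annotations" and not Path(v).exists()
            ] + [
                p for p in self.input_paths.get("annotations", []) if not Path(p).exists()
            ]
            if missing:
                raise ConfigurationError(f"input files not found: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        synth = raw.pop("synthetic", None)
        if synth is not None:
            if "module_size_range" in synth:
                synth["module_size_range"] = tuple(synth["module_size_range"])
            synth = SyntheticConfig(**synth)
        for key in ("metrics", "exclude_strains"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(synthetic=synth, **raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    t0 = time.perf_counter()

    def log_stage(name: str, **info) -> None:
        elapsed = round(time.perf_counter() - t0, 3)
        stages.append({"stage": name, "elapsed_s": elapsed, **info})
        logger.info("stage %s done (%.2fs): %s", name, elapsed, info)

    # --- stage 1: generate or load ---------------------------------------
    if config.synthetic is not None:
        synth = dataclasses.replace(config.synthetic, seed=config.seed)
        data = generate_dataset(synth)
        plio.write_fitness_table(data["matrix"], outdir / "fitness.tsv")
        plio.write_condition_table(data["conditions"], outdir / "conditions.tsv")
        ann_paths = []
        for aset in data["annotation_sets"]:
            p = outdir / f"annotations_{aset.name}.tsv"
            plio.write_annotation_table(aset, p)
            ann_paths.append(p)
        plio.write_obo(data["go_graph"], outdir / "ontology.obo")
        plio.write_gene_associations(data["go_annotations"], outdir / "associations.tsv")
        paths = {
            "fitness": outdir / "fitness.tsv",
            "conditions": outdir / "conditions.tsv",
            "annotations": ann_paths,
            "obo": outdir / "ontology.obo",
            "gaf": outdir / "associations.tsv",
        }
    else:
        paths = dict(config.input_paths)

    # Even synthetic data goes through the real readers.
    matrix = plio.read_fitness_table(paths["fitness"])
    conditions = plio.read_condition_table(paths["conditions"])
    annotation_sets = [plio.read_annotation_table(p) for p in paths["annotations"]]
    go_graph = plio.read_obo_subset(paths["obo"]) if config.include_go else None
    go_ann = (
        plio.read_gene_associations(paths["gaf"], go_graph, exclude_iea=config.exclude_iea)
        if config.include_go else None
    )
    log_stage("load", n_strains=len(matrix.strain_ids),
              n_conditions=len(matrix.condition_ids),
              n_missing=matrix.n_missing)

    # --- stage 2: impute ---------------------------------------------------
    matrix = plio.impute_population_mean(matrix, scope="per_condition")
    log_stage("impute")

    # --- stage 3: exclusions ----------------------------------------------
    excluded_conditions: set[str] = set()
    if config.exclude_minimal:
        excluded_conditions = set(conditions.minimal_conditions)
    excluded_strains = set(config.exclude_strains)
    log_stage("exclusions", excluded_conditions=sorted(excluded_conditions),
              n_excluded_strains=len(excluded_strains))

    # --- stage 4: quantitative similarity tables ---------------------------
    pair_tables = []
    for metric in config.metrics:
        table = sim.pairwise_table(
            matrix, metric,
            exclude_conditions=excluded_conditions,
            exclude_strains=excluded_strains,
        )
        pair_tables.append(table)
    log_stage("similarity", metrics=list(config.metrics),
              n_pairs=0 if not pair_tables else len(pair_tables[0]))

    # --- stage 5: discretization -------------------------------------------
    calls = disc.condition_fdr_calls(matrix, alpha=config.alpha)
    ternary = (disc.ternarize(matrix, calls) if config.n_bins == 3
               else disc.nbin_discretize(matrix, calls, config.n_bins))
    plio.write_discrete_matrix(ternary, outdir / "discretized.tsv")
    calls.to_tidy().to_csv(outdir / "significant_calls.tsv", sep="\t", index=False)
    pair_tables.append(sim.pairwise_table(
        ternary, "mi_disc",
        exclude_conditions=excluded_conditions, exclude_strains=excluded_strains,
    ))
    collapsed = None
    if config.collapse:
        collapsed = disc.collapse_to_stresses(matrix, calls, conditions)
        plio.write_discrete_matrix(collapsed, outdir / "discretized_collapsed.tsv")
        ctab = sim.pairwise_table(collapsed, "mi_disc",
                                  exclude_strains=excluded_strains)
        ctab["metric"] = "mi_disc_collapsed"
        pair_tables.append(ctab)
    log_stage("discretize", alpha=config.alpha, n_bins=config.n_bins,
              n_significant=calls.n_significant, collapsed=config.collapse)

    # --- stage 6: GO semantic similarity ------------------------------------
    if config.include_go and go_graph is not None and go_ann is not None:
        universe_for_go = [s for s in matrix.strain_ids if s not in excluded_strains]
        go_table = gosim.gene_pair_table(universe_for_go, go_ann, go_graph,
                                         weights=config.go_weights)
        pair_tables.append(go_table)
        log_stage("go_similarity", n_annotated=len(
            [g for g in universe_for_go if go_ann.gene_to_terms.get(g)]))

    pair_table = sim.concat_pair_tables(pair_tables)
    plio.write_pair_table(pair_table, outdir / "pair_similarity.tsv")

    # --- stage 7: labels, curves, summaries, tests --------------------------
    universe = [s for s in matrix.strain_ids if s not in excluded_strains]
    labels = ev.coannotation_labels(universe, annotation_sets, mode=config.annotation_mode)

    curves = []
    summaries = []
    cutoffs = {
        "abs_pcc": config.pcc_cutoff, "abs_srcc": config.pcc_cutoff,
        "mi_cont": config.mi_cutoff, "mi_disc": config.mi_cutoff,
        "mi_disc_collapsed": config.mi_collapsed_cutoff, "go_wang_bma": config.pcc_cutoff,
    }
    for metric in pair_table["metric"].unique():
        ranked = ev.rank_pairs(pair_table, metric)
        curve = ev.precision_curve(ranked, labels, max_rank=config.max_rank)
        curve.insert(0, "metric", metric)
        curves.append(curve)
        values = ranked["value"].to_numpy()
        lab = labels.series(ranked["gene_a"], ranked["gene_b"])
        summary = ev.distribution_summary(values, cutoff=cutoffs.get(metric, 0.75))
        summary["metric"] = metric
        if lab.any() and (~lab).any():
            _, p = ev.mann_whitney_one_sided(values, values[lab])
            summary["mw_p_coannotated_greater"] = p
        summaries.append(summary)
    control = ev.permuted_ranking_control(labels, n_pairs=config.max_rank,
                                          seed=config.seed)
    control.insert(0, "metric", "permuted_control")
    curves.append(control)
    pd.concat(curves, ignore_index=True).to_csv(
        outdir / "precision_curves.tsv", sep="\t", index=False)
    pd.DataFrame(summaries).to_csv(outdir / "distribution_summaries.tsv",
                                   sep="\t", index=False)

    pr_k = min(config.pr_k, labels.n_pairs)
    first_metric = config.metrics[0] if config.metrics else "mi_disc"
    pr = ev.precision_recall_topk(ev.rank_pairs(pair_table, first_metric),
                                  labels, k=pr_k)
    pr.frame.to_csv(outdir / f"pr_top{pr_k}_{first_metric}.tsv", sep="\t", index=False)

    group_rows = []
    if annotation_sets:
        lookup_metric = first_metric
        for term, genes in sorted(annotation_sets[0].term_to_genes.items()):
            members = [g for g in genes if g in set(universe)]
            if len(members) < 2:
                continue
            res = ev.group_permutation_test(
                members, pair_table, universe, n_perm=config.n_perm,
                seed=config.seed, metric=lookup_metric, group_id=term,
            )
            group_rows.append({
                "group": term, "n_genes": len(members),
                "observed_mean": res.observed, "p_value": res.p_value,
            })
    pd.DataFrame(group_rows).to_csv(outdir / "group_permutation.tsv",
                                    sep="\t", index=False)
    log_stage("evaluate", n_pairs=labels.n_pairs,
              base_rate=round(labels.base_rate, 6), n_groups=len(group_rows))

    # --- manifest ------------------------------------------------------------
    outputs = sorted(p for p in outdir.glob("*.tsv")) + [outdir / "ontology.obo"]
    manifest = {
        "config": json.loads(json.dumps(config.to_dict(), default=str)),
        "seed": config.seed,
        "stages": stages,
        "checksums": {p.name: _sha256(p) for p in outputs if p.exists()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
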