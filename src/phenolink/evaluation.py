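"""Co-annotation labelling, ranked-pair precision/recall, and controls.

The central question is evaluated here: do gene pairs with similar
phenotypic profiles share a function? Pairs are ranked by similarity, each
pair carries a boolean co-annotation label (shares >= 1 term in the chosen
annotation sets), and precision at rank n = (co-annotated pairs among the
top n) / n. Negative controls permute the ranking or sample pairs at random;
a permutation test scores whole gene groups (pathways, complexes) against
random same-size groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .containers import (
    AnnotationSet,
    CoAnnotationLabels,
    ConfigurationError,
    ValidationError,
)


def all_pairs(universe: list[str]) -> list[tuple[str, str]]:
    """All unordered pairs of the universe as sorted tuples, in sorted order."""
    return [tuple(sorted(p)) for p in itertools.combinations(universe, 2)]


def coannotation_labels(
    universe: list[str],
    sets: list[AnnotationSet],
    mode: str = "union",
) -> CoAnnotationLabels:
    """Label every universe pair as co-annotated or not.

    ``union``: a pair is positive if it shares a term in ANY set;
    ``intersection``: only if it shares a term in EVERY set. Pairs involving
    unannotated genes are negative.
    """
    if not universe:
        raise ValidationError("gene universe is empty")
    if not sets:
        raise ValidationError("need at least one annotation set")
    if mode not in ("union", "intersection"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    per_set = [s.coannotated_pairs() for s in sets]
    if mode == "union":
        positives = frozenset().union(*per_set)
    else:
        positives = frozenset.intersection(*per_set)
    provenance = f"{mode}({', '.join(s.name for s in sets)})"
    return CoAnnotationLabels(
        universe=tuple(universe), positive_pairs=positives, provenance=provenance
    )


def rank_pairs(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Sort one metric's pairs by similarity, descending, with dense ranks 1..N.

    Ties are broken lexicographically by (gene_a, gene_b) so the ranking is
    deterministic.
    """
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ValidationError(f"no rows for metric {metric!r}")
    ranked = sub.sort_values(
        ["value", "gene_a", "gene_b"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


def _attach_labels(ranked: pd.DataFrame, labels: CoAnnotationLabels) -> np.ndarray:
    return labels.series(ranked["gene_a"], ranked["gene_b"])


def precision_curve(
    ranked: pd.DataFrame,
    labels: CoAnnotationLabels,
    max_rank: int | None = None,
) -> pd.DataFrame:
    """Precision at every rank 1..max_rank: TP(n)/n with TP = co-annotated."""
    lab = _attach_labels(ranked, labels).astype(int)
    n = len(lab) if max_rank is None else min(max_rank, len(lab))
    tp = np.cumsum(lab[:n])
    ranks = np.arange(1, n + 1)
    return pd.DataFrame({"rank": ranks, "tp": tp, "precision": tp / ranks})


@dataclass
class PrecisionRecallCurve:
    """Precision and recall over a top-k window; flags a zero-positive window."""

    frame: pd.DataFrame
    zero_positives: bool = False


def precision_recall_topk(
    ranked: pd.DataFrame,
    labels: CoAnnotationLabels,
    k: int = 5000,
    global_positives: bool = False,
) -> PrecisionRecallCurve:
    """Precision-recall inside the top-k ranked pairs.

    By default the recall denominator is the positives within the top-k
    window (recall(k) = 1); ``global_positives=True`` switches the
    denominator to all positives in the pair universe. A window with zero
    positives returns an all-zero recall with ``zero_positives`` set, so
    batch runs complete.
    """
    if k > len(ranked):
        raise ValidationError(f"k={k} exceeds the {len(ranked)} ranked pairs")
    lab = _attach_labels(ranked.iloc[:k], labels).astype(int)
    tp = np.cumsum(lab)
    ranks = np.arange(1, k + 1)
    denom = len(labels.positive_pairs) if global_positives else int(tp[-1]) if k else 0
    zero = denom == 0
    recall = np.zeros(k) if zero else tp / denom
    frame = pd.DataFrame({
        "rank": ranks, "tp": tp, "precision": tp / ranks, "recall": recall,
    })
    return PrecisionRecallCurve(frame=frame, zero_positives=zero)


def permuted_ranking_control(
    labels: CoAnnotationLabels,
    n_pairs: int,
    seed: int,
) -> pd.DataFrame:
    """Precision curve of a uniformly permuted ranking of all universe pairs."""
    pairs = all_pairs(list(labels.universe))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n = min(n_pairs, len(pairs))
    lab = np.array(
        [pairs[i] in labels.positive_pairs for i in order[:n]], dtype=int
    )
    tp = np.cumsum(lab)
    ranks = np.arange(1, n + 1)
    return pd.DataFrame({"rank": ranks, "tp": tp, "precision": tp / ranks})


def sampled_pairs_control(
    labels: CoAnnotationLabels,
    n: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample n pairs uniformly without replacement, with their labels."""
    pairs = all_pairs(list(labels.universe))
    if n > len(pairs):
        raise ValidationError(f"n={n} exceeds the {len(pairs)} possible pairs")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n, replace=False)
    sampled = [pairs[i] for i in idx]
    return pd.DataFrame({
        "gene_a": [p[0] for p in sampled],
        "gene_b": [p[1] for p in sampled],
        "label": [p in labels.positive_pairs for p in sampled],
    })


@dataclass
class GroupPermutationResult:
    """Observed within-group mean similarity against a random-group null."""

    group_id: str
    observed: float
    n_permutations: int
    null_means: np.ndarray
    p_value: float


def similarity_lookup(
    table: pd.DataFrame, genes: list[str], metric: str = "abs_pcc"
) -> pd.DataFrame:
    """Symmetric gene x gene similarity matrix from a tidy pair table."""
    index = {g: i for i, g in enumerate(genes)}
    mat = np.full((len(genes), len(genes)), np.nan)
    np.fill_diagonal(mat, 1.0)
    sub = table[table["metric"] == metric]
    ia = sub["gene_a"].map(index)
    ib = sub["gene_b"].map(index)
    ok = ia.notna() & ib.notna()
    ia = ia[ok].astype(int).to_numpy()
    ib = ib[ok].astype(int).to_numpy()
    vals = sub.loc[ok, "value"].to_numpy()
    mat[ia, ib] = vals
    mat[ib, ia] = vals
    return pd.DataFrame(mat, index=genes, columns=genes)


def _mean_pairwise(sim: np.ndarray, idx: np.ndarray) -> float:
    sub = sim[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(np.nanmean(sub[iu]))


def group_permutation_test(
    group_genes: list[str],
    table: pd.DataFrame,
    all_genes: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "abs_pcc",
    group_id: str = "",
    lookup: pd.DataFrame | None = None,
) -> GroupPermutationResult:
    """Permutation p-value for a gene group's mean pairwise similarity.

    The null draws ``n_perm`` random same-size gene sets from ``all_genes``
    and records each mean pairwise similarity; ``p = (# null means strictly
    greater than observed) / n_perm`` — ties count for the null. A
    precomputed ``similarity_lookup`` matrix (indexed exactly by
    ``all_genes``) can be passed when testing many groups against one table.
    """
    if len(group_genes) < 2:
        raise ValidationError("group must contain at least 2 genes")
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    missing = [g for g in group_genes if g not in set(all_genes)]
    if missing:
        raise ValidationError(f"group genes outside the universe: {missing}")
    if lookup is None:
        lookup = similarity_lookup(table, all_genes, metric=metric)
    elif list(lookup.index) != list(all_genes):
        raise ValidationError("precomputed lookup does not match all_genes")
    sim = lookup.to_numpy()
    index = {g: i for i, g in enumerate(all_genes)}
    group_idx = np.array([index[g] for g in group_genes])
    observed = _mean_pairwise(sim, group_idx)
    rng = np.random.default_rng(seed)
    size = len(group_genes)
    null_means = np.array([
        _mean_pairwise(sim, rng.choice(len(all_genes), size=size, replace=False))
        for _ in range(n_perm)
    ])
    p = float((null_means > observed).sum() / n_perm)
    return GroupPermutationResult(
        group_id=group_id or ",".join(group_genes[:3]),
        observed=observed,
        n_permutations=n_perm,
        null_means=null_means,
        p_value=p,
    )


def distribution_summary(
    values,
    cutoff: float,
    log_transform: bool = False,
    log_const: float = 1e-6,
) -> dict:
    """Box-plot style summary plus the fraction of raw values above a cutoff.

    Quantiles use linear interpolation (type 7). With ``log_transform`` the
    location statistics are computed on ``log10(value + log_const)`` (the
    small constant eliminates zeros) but the cutoff fraction always uses the
    raw values.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("empty input")
    frac_above = float((values > cutoff).mean())
    stats_values = np.log10(values + log_const) if log_transform else values
    q1, med, q3 = np.quantile(stats_values, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    return {
        "n": int(values.size),
        "mean": float(stats_values.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
        "frac_above_cutoff": frac_above,
        "cutoff": float(cutoff),
        "log_transform": bool(log_transform),
    }


def mann_whitney_one_sided(sample_a, sample_b, alternative: str = "greater"):
    """One-sided Mann-Whitney U: is ``sample_b`` stochastically greater than
    ``sample_a``? Exact for small tie-free samples, tie-corrected normal
    approximation otherwise. Returns ``(U, p_value)``.
    """
    if alternative != "greater":
        raise ConfigurationError("only the 'greater' alternative is supported")
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    res = mannwhitneyu(b, a, alternative="greater", method="auto")
    return float(res.statistic), float(res.pvalue)


@dataclass
class DiscordanceReport:
    """Pairs scoring high in one metric but absent from the other's top-k."""

    a_above_threshold_not_in_b_topk: list[tuple[str, str]]
    b_above_threshold_not_in_a_topk: list[tuple[str, str]]

    @property
    def counts(self) -> tuple[int, int]:
        return (len(self.a_above_threshold_not_in_b_topk),
                len(self.b_above_threshold_not_in_a_topk))


def compare_metric_toplists(
    ranked_a: pd.DataFrame,
    ranked_b: pd.DataFrame,
    k: int,
    threshold: float,
) -> DiscordanceReport:
    """Cross-metric discordance of highly ranked pairs.

    Lists pairs with similarity >= ``threshold`` in metric A that are absent
    from metric B's top-k, and vice versa.
    """
    def pairset(frame: pd.DataFrame) -> set[tuple[str, str]]:
        return set(zip(frame["gene_a"], frame["gene_b"]))

    if pairset(ranked_a) != pairset(ranked_b):
        raise ValidationError("rankings cover different pair universes")

    def discordant(src: pd.DataFrame, other: pd.DataFrame) -> list[tuple[str, str]]:
        top_other = pairset(other.iloc[:k])
        high = src[src["value"] >= threshold]
        return sorted(
            (a, b) for a, b in zip(high["gene_a"], high["gene_b"])
            if (a, b) not in top_other
        )

    return DiscordanceReport(
        a_above_threshold_not_in_b_topk=discordant(ranked_a, ranked_b),
        b_above_threshold_not_in_a_topk=discordant(ranked_b, ranked_a),
    )
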