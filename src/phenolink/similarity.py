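"""Phenotypic-profile similarity metrics: |PCC|, |SRCC|, and mutual information.

Correlations are reported as absolute values in [0, 1] because the sign of a
fitness correlation is not informative for shared function. Mutual
information is a plug-in estimate in nats; the continuous variant discretizes
each profile into equal-frequency bins first (rank-based, hence invariant
under strictly monotone transforms of either profile).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import (
    ConfigurationError,
    DiscreteMatrix,
    FitnessMatrix,
    UndefinedSimilarityError,
    ValidationError,
)

METRICS = ("abs_pcc", "abs_srcc", "mi_cont", "mi_disc")

PAIR_TABLE_COLUMNS = ("gene_a", "gene_b", "metric", "value")


def _check_vectors(x: np.ndarray, y: np.ndarray, min_len: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be 1-d vectors of equal length")
    if len(x) < min_len:
        raise ValidationError(f"vectors must have length >= {min_len}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("inputs contain missing values; impute first")
    return x, y


def abs_pcc(x, y) -> float:
    """Absolute Pearson product-moment correlation in [0, 1]."""
    x, y = _check_vectors(x, y)
    if x.std() == 0 or y.std() == 0:
        raise UndefinedSimilarityError("Pearson correlation undefined for zero-variance input")
    r = np.corrcoef(x, y)[0, 1]
    return min(abs(float(r)), 1.0)


def abs_srcc(x, y) -> float:
    """Absolute Spearman rank correlation (ties get average ranks)."""
    x, y = _check_vectors(x, y)
    rx = rankdata(x)  # average ranks
    ry = rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise UndefinedSimilarityError("Spearman correlation undefined: all values tied")
    r = np.corrcoef(rx, ry)[0, 1]
    return min(abs(float(r)), 1.0)


def mi_discrete(x, y) -> float:
    """Plug-in mutual information of two categorical vectors, in nats.

    ``MI = sum_{a,b} p(a,b) ln [ p(a,b) / (p(a) p(b)) ]`` over empirical joint
    frequencies; zero-probability cells contribute 0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValidationError("inputs must be 1-d vectors of equal, positive length")
    n = len(x)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    kx = int(xi.max()) + 1
    ky = int(yi.max()) + 1
    joint = np.bincount(xi * ky + yi, minlength=kx * ky).reshape(kx, ky) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log(joint[nz] / outer[nz])))


def auto_bins(n: int) -> int:
    """Default equal-frequency bin count for continuous MI: floor(sqrt(n/5)), min 2."""
    return max(2, int(math.floor(math.sqrt(n / 5))))


def equal_frequency_codes(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign each value an equal-frequency bin code 0..n_bins-1 by rank.

    Ordinal ranks (stable for ties) make the coding depend only on the order
    of values, so any strictly monotone transform yields identical codes.
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    n = len(x)
    order = rankdata(x, method="ordinal") - 1
    return (order * n_bins // n).astype(np.int64)


def mi_continuous(x, y, n_bins: int | str = "auto") -> float:
    """Mutual information of two quantitative vectors via equal-frequency binning."""
    x, y = _check_vectors(x, y, min_len=10)
    bins = auto_bins(len(x)) if n_bins == "auto" else int(n_bins)
    return mi_discrete(equal_frequency_codes(x, bins), equal_frequency_codes(y, bins))


# ---------------------------------------------------------------------------
# All-pairs computation
# ---------------------------------------------------------------------------

def _mi_matrix(codes: np.ndarray, n_classes: int) -> np.ndarray:
    """Pairwise plug-in MI (nats) between all rows of an integer code matrix.

    Joint counts for every row pair are accumulated one class pair at a time
    via indicator-matrix products, so the whole computation is dense linear
    algebra rather than a Python loop over ~n^2/2 pairs.
    """
    n_rows, n = codes.shape
    indicators = [
        (codes == k).astype(np.float64) for k in range(n_classes)
    ]
    counts_k = np.stack([ind.sum(axis=1) for ind in indicators])  # K x n_rows
    p_k = counts_k / n
    mi = np.zeros((n_rows, n_rows))
    for a in range(n_classes):
        for b in range(n_classes):
            joint = indicators[a] @ indicators[b].T / n
            outer = np.outer(p_k[a], p_k[b])
            with np.errstate(divide="ignore", invalid="ignore"):
                term = joint * np.log(joint / outer)
            mi += np.where(joint > 0, term, 0.0)
    return np.maximum(mi, 0.0)


def _pairs_frame(ids: list[str], values: np.ndarray, metric: str) -> pd.DataFrame:
    iu, ju = np.triu_indices(len(ids), k=1)
    ids_arr = np.asarray(ids, dtype=object)
    a = ids_arr[iu]
    b = ids_arr[ju]
    # fixed total order: gene_a < gene_b lexicographically
    swap = a > b
    a2 = np.where(swap, b, a)
    b2 = np.where(swap, a, b)
    return pd.DataFrame({
        "gene_a": a2, "gene_b": b2, "metric": metric, "value": values[iu, ju],
    })


def pairwise_table(
    matrix: FitnessMatrix | DiscreteMatrix,
    metric: str,
    exclude_conditions: set[str] | frozenset[str] = frozenset(),
    exclude_strains: set[str] | frozenset[str] = frozenset(),
    n_bins: int | str = "auto",
) -> pd.DataFrame:
    """Similarity of every unordered strain pair, as a tidy pair table.

    Exclusions (e.g. minimal-media conditions, known auxotroph strains) are
    applied before any metric computation. For ``metric="mi_disc"`` the input
    must be a :class:`DiscreteMatrix`; the other metrics consume a complete
    (imputed) :class:`FitnessMatrix`.
    """
    if metric not in METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; choose from {METRICS}")
    frame = matrix.calls if isinstance(matrix, DiscreteMatrix) else matrix.scores
    if isinstance(matrix, DiscreteMatrix) and metric != "mi_disc":
        raise ConfigurationError(f"metric {metric!r} requires quantitative scores")
    if not isinstance(matrix, DiscreteMatrix) and metric == "mi_disc":
        raise ConfigurationError("mi_disc requires a DiscreteMatrix input")

    keep_rows = [s for s in frame.index if s not in set(exclude_strains)]
    keep_cols = [c for c in frame.columns if c not in set(exclude_conditions)]
    if len(keep_rows) < 2:
        raise ValidationError("fewer than 2 strains remain after exclusions")
    if len(keep_cols) < 3:
        raise ValidationError("fewer than 3 conditions remain after exclusions")
    sub = frame.loc[keep_rows, keep_cols]
    values = sub.to_numpy()
    if metric in ("abs_pcc", "abs_srcc", "mi_cont") and np.isnan(values).any():
        raise ValidationError("matrix contains missing values; impute first")

    if metric == "abs_pcc":
        if (values.std(axis=1) == 0).any():
            bad = [keep_rows[i] for i in np.nonzero(values.std(axis=1) == 0)[0]]
            raise UndefinedSimilarityError(f"zero-variance strain profiles: {bad}")
        sim = np.abs(np.corrcoef(values))
    elif metric == "abs_srcc":
        ranks = rankdata(values, axis=1)
        if (ranks.std(axis=1) == 0).any():
            bad = [keep_rows[i] for i in np.nonzero(ranks.std(axis=1) == 0)[0]]
            raise UndefinedSimilarityError(f"all-tied strain profiles: {bad}")
        sim = np.abs(np.corrcoef(ranks))
    elif metric == "mi_cont":
        bins = auto_bins(values.shape[1]) if n_bins == "auto" else int(n_bins)
        codes = np.vstack([equal_frequency_codes(row, bins) for row in values])
        sim = _mi_matrix(codes, bins)
    else:  # mi_disc
        vals = values.astype(np.int64)
        offset = int(vals.min())
        codes = vals - offset
        sim = _mi_matrix(codes, int(codes.max()) + 1)

    if metric in ("abs_pcc", "abs_srcc"):
        sim = np.clip(sim, 0.0, 1.0)
    return _pairs_frame(keep_rows, sim, metric)


def concat_pair_tables(tables: list[pd.DataFrame]) -> pd.DataFrame:
    return pd.concat(tables, ignore_index=True)
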