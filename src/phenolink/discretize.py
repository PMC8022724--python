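"""Quantitative-to-qualitative conversion of fitness scores.

Scores are z-scores (standard-normal scaled within each condition), so a
two-sided normal p-value and per-condition Benjamini-Hochberg control at 5%
FDR identify significant phenotypes. Significant cells become +1/-1 calls
(ternary discretization); a concentration series can be collapsed to one
call per stress by keeping each strain's most significant concentration; and
an n-bin variant grades each significant tail into equal-frequency sub-bins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from .containers import (
    ConditionTable,
    ConfigurationError,
    DiscreteMatrix,
    FitnessMatrix,
    SignificanceCalls,
    ValidationError,
)


def condition_fdr_calls(matrix: FitnessMatrix, alpha: float = 0.05) -> SignificanceCalls:
    """Per-condition FDR-controlled significance calls.

    For every condition: two-sided p-values ``p = 2 * Phi(-|z|)`` and
    Benjamini-Hochberg step-up at level ``alpha`` within that condition.
    Significant strains carry ``sign(z)``; everything else is 0.
    """
    if not (0 < alpha < 1):
        raise ConfigurationError(f"alpha must be in (0,1), got {alpha}")
    z = matrix.scores.to_numpy()
    if np.isnan(z).any():
        raise ValidationError("matrix contains missing values; impute first")
    p = 2.0 * norm.sf(np.abs(z))
    signs = np.zeros_like(z, dtype=int)
    q = np.empty_like(p)
    for j in range(z.shape[1]):
        reject, qvals, _, _ = multipletests(p[:, j], alpha=alpha, method="fdr_bh")
        q[:, j] = qvals
        signs[reject, j] = np.sign(z[reject, j]).astype(int)
    idx, cols = matrix.scores.index, matrix.scores.columns
    return SignificanceCalls(
        alpha=alpha,
        signs=pd.DataFrame(signs, index=idx, columns=cols),
        pvalues=pd.DataFrame(p, index=idx, columns=cols),
        qvalues=pd.DataFrame(q, index=idx, columns=cols),
    )


def _check_aligned(matrix: FitnessMatrix, calls: SignificanceCalls) -> None:
    if (list(calls.signs.index) != matrix.strain_ids
            or list(calls.signs.columns) != matrix.condition_ids):
        raise ValidationError("significance calls do not match the matrix dimensions")


def ternarize(matrix: FitnessMatrix, calls: SignificanceCalls) -> DiscreteMatrix:
    """Ternary {-1, 0, +1} phenotype calls: sign where significant, else 0."""
    _check_aligned(matrix, calls)
    return DiscreteMatrix(calls=calls.signs.copy(), n_bins=3)


def collapse_to_stresses(
    matrix: FitnessMatrix,
    calls: SignificanceCalls,
    conditions: ConditionTable,
) -> DiscreteMatrix:
    """Collapse each concentration series to one ternary call per stress.

    For each (strain, stress) the member condition with maximal ``|z|`` (the
    most significant concentration; ties broken by column order) supplies the
    call: its sign if significant for that strain, else 0.
    """
    _check_aligned(matrix, calls)
    known = set(conditions.condition_ids)
    unknown = [c for c in matrix.condition_ids if c not in known]
    if unknown:
        raise ValidationError(f"conditions without metadata: {unknown}")
    z = matrix.scores
    out = {}
    for stress, members in conditions.stress_groups().items():
        members = [c for c in members if c in z.columns]
        if not members:
            continue
        absz = z[members].abs().to_numpy()
        best = np.argmax(absz, axis=1)  # first max wins ties
        sign_block = calls.signs[members].to_numpy()
        out[stress] = sign_block[np.arange(len(z)), best]
    collapsed = pd.DataFrame(out, index=z.index)
    return DiscreteMatrix(calls=collapsed, n_bins=3)


def nbin_discretize(
    matrix: FitnessMatrix,
    calls: SignificanceCalls,
    n_bins: int,
) -> DiscreteMatrix:
    """Grade significant calls into symmetric integer bins.

    Non-significant cells stay in the center bin 0. Within each condition,
    the significant cells of each sign are split into ``(n_bins - 1) / 2``
    equal-frequency sub-bins by ``|z|``: more extreme scores get larger
    magnitudes (labels -k..-1, 0, +1..+k). ``n_bins=3`` reproduces the
    ternary calls exactly.
    """
    if n_bins % 2 == 0 or n_bins < 3:
        raise ConfigurationError(f"n_bins must be odd and >= 3, got {n_bins}")
    _check_aligned(matrix, calls)
    k = (n_bins - 1) // 2
    z = matrix.scores.to_numpy()
    signs = calls.signs.to_numpy()
    out = np.zeros_like(signs)
    for j in range(z.shape[1]):
        for sign in (-1, 1):
            rows = np.nonzero(signs[:, j] == sign)[0]
            m = len(rows)
            if m == 0:
                continue
            # average rank of |z| ascending -> sub-bin 1..k (extreme -> k);
            # average ranks keep exactly tied scores in the same sub-bin
            ranks = rankdata(np.abs(z[rows, j]), method="average")
            sub = np.ceil(ranks * k / m).astype(int)
            out[rows, j] = sign * np.clip(sub, 1, k)
    frame = pd.DataFrame(out, index=matrix.scores.index, columns=matrix.scores.columns)
    return DiscreteMatrix(calls=frame, n_bins=n_bins)
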