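"""Core in-memory containers for fitness matrices, annotations, and calls.

The primary substrate is a strains x conditions matrix of fitness z-scores
(each condition scaled to a standard normal, negative = growth defect).
Everything downstream — profile similarity, discretization, co-annotation
labelling — consumes these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class PhenolinkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PhenolinkError, ValueError):
    """A configuration value violates its documented invariant."""


class ValidationError(PhenolinkError, ValueError):
    """An input file or container violates its documented invariant."""


class UndefinedSimilarityError(PhenolinkError, ValueError):
    """A similarity is mathematically undefined for the given input
    (e.g. zero-variance profile, gene with no GO terms)."""


@dataclass
class FitnessMatrix:
    """Strains x conditions quantitative fitness scores.

    ``scores`` is a float DataFrame indexed by strain id with condition ids
    as columns; ``NaN`` marks a missing measurement. Row and column labels
    must be unique.
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.scores, pd.DataFrame):
            raise ValidationError("scores must be a pandas DataFrame")
        if self.scores.index.has_duplicates:
            dups = self.scores.index[self.scores.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate strain ids: {dups}")
        if self.scores.columns.has_duplicates:
            dups = self.scores.columns[self.scores.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate condition ids: {dups}")
        self.scores = self.scores.astype(float)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.scores.isna()

    @property
    def n_missing(self) -> int:
        return int(self.scores.isna().to_numpy().sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def copy(self) -> "FitnessMatrix":
        return FitnessMatrix(self.scores.copy())


_CONDITION_COLUMNS = ("condition_id", "stress_id", "level_label", "is_minimal")


@dataclass
class ConditionTable:
    """Per-condition metadata: stress identity, dose label, minimal-media flag.

    A *stress* groups the conditions that probe the same treatment at
    different concentrations; collapsing a concentration series operates on
    these groups.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CONDITION_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"condition table missing columns: {missing}")
        if self.frame["condition_id"].duplicated().any():
            dups = self.frame.loc[self.frame["condition_id"].duplicated(), "condition_id"]
            raise ValidationError(f"duplicate condition ids: {dups.tolist()}")
        if self.frame["stress_id"].isna().any():
            raise ValidationError("every condition must have a stress_id")
        self.frame = self.frame.reset_index(drop=True)
        self.frame["is_minimal"] = self.frame["is_minimal"].astype(bool)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.frame["condition_id"])

    @property
    def stress_ids(self) -> list[str]:
        """Distinct stress ids in first-appearance order."""
        return list(dict.fromkeys(self.frame["stress_id"]))

    @property
    def minimal_conditions(self) -> list[str]:
        return list(self.frame.loc[self.frame["is_minimal"], "condition_id"])

    def stress_groups(self) -> dict[str, list[str]]:
        """Map stress id -> its member condition ids, in table order."""
        groups: dict[str, list[str]] = {}
        for cond, stress in zip(self.frame["condition_id"], self.frame["stress_id"]):
            groups.setdefault(stress, []).append(cond)
        return groups


@dataclass
class AnnotationSet:
    """A named term -> gene-set map (pathways, complexes, operons, ...)."""

    name: str
    term_to_genes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.term_to_genes = {
            term: frozenset(genes) for term, genes in self.term_to_genes.items()
        }
        empty = [t for t, g in self.term_to_genes.items() if not g]
        if empty:
            raise ValidationError(f"annotation set {self.name!r} has empty terms: {empty}")

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.term_to_genes.values():
            out |= genes
        return frozenset(out)

    def coannotated_pairs(self) -> frozenset[tuple[str, str]]:
        """All unordered gene pairs sharing at least one term, as sorted tuples."""
        pairs: set[tuple[str, str]] = set()
        for genes in self.term_to_genes.values():
            members = sorted(genes)
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    pairs.add((a, b))
        return frozenset(pairs)


@dataclass
class GeneGoAnnotations:
    """Per-gene GO term sets (one namespace) with evidence codes."""

    gene_to_terms: dict[str, frozenset[str]]
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_to_terms = {
            g: frozenset(ts) for g, ts in self.gene_to_terms.items() if ts
        }

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.gene_to_terms)


@dataclass
class IdMap:
    """Alias -> primary gene-id resolution map.

    Built from (primary, aliases) records; an alias mapping to two distinct
    primaries is rejected at construction.
    """

    alias_to_primary: dict[str, str]
    primaries: frozenset[str]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, Iterable[str]]]) -> "IdMap":
        alias_to_primary: dict[str, str] = {}
        primaries: set[str] = set()
        for primary, aliases in records:
            primaries.add(primary)
            for alias in aliases:
                prev = alias_to_primary.get(alias)
                if prev is not None and prev != primary:
                    raise ValidationError(
                        f"ambiguous alias {alias!r}: maps to both {prev!r} and {primary!r}"
                    )
                alias_to_primary[alias] = primary
        return cls(alias_to_primary=alias_to_primary, primaries=frozenset(primaries))


@dataclass
class SignificanceCalls:
    """Per-condition FDR-significant phenotype calls.

    ``signs`` holds -1/0/+1 per (strain, condition); ``pvalues``/``qvalues``
    the two-sided normal p-values and BH-adjusted q-values they came from.
    """

    alpha: float
    signs: pd.DataFrame
    pvalues: pd.DataFrame
    qvalues: pd.DataFrame

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must be in (0,1), got {self.alpha}")
        for name in ("pvalues", "qvalues"):
            other = getattr(self, name)
            if other.shape != self.signs.shape:
                raise ValidationError(f"{name} shape {other.shape} != signs shape {self.signs.shape}")

    @property
    def n_significant(self) -> int:
        return int((self.signs.to_numpy() != 0).sum())

    def to_tidy(self) -> pd.DataFrame:
        """Significant calls as a tidy (condition, strain, sign, p, q) frame."""
        rows = []
        signs = self.signs.to_numpy()
        p = self.pvalues.to_numpy()
        q = self.qvalues.to_numpy()
        strains = list(self.signs.index)
        conds = list(self.signs.columns)
        ii, jj = np.nonzero(signs)
        for i, j in zip(ii, jj):
            rows.append((conds[j], strains[i], int(signs[i, j]), p[i, j], q[i, j]))
        return pd.DataFrame(rows, columns=["condition", "strain", "sign", "p", "q"])


@dataclass
class DiscreteMatrix:
    """Discretized phenotype calls: integer labels symmetric around 0.

    ``n_bins = 3`` is the ternary {-1, 0, +1} case; larger odd ``n_bins``
    split each significant tail into graded sub-bins.
    """

    calls: pd.DataFrame
    n_bins: int = 3

    def __post_init__(self) -> None:
        if self.n_bins % 2 == 0 or self.n_bins < 3:
            raise ConfigurationError(f"n_bins must be odd and >= 3, got {self.n_bins}")
        k = (self.n_bins - 1) // 2
        vals = self.calls.to_numpy()
        if not np.isin(vals, np.arange(-k, k + 1)).all():
            raise ValidationError(f"calls contain labels outside [-{k}, {k}]")
        self.calls = self.calls.astype(int)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.calls.columns)


# Ternary {-1,0,+1} matrices are DiscreteMatrix with the default n_bins=3.
TernaryMatrix = DiscreteMatrix


@dataclass
class CoAnnotationLabels:
    """Boolean shares-an-annotation labels over all pairs of a gene universe."""

    universe: tuple[str, ...]
    positive_pairs: frozenset[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValidationError("gene universe is empty")
        uni = set(self.universe)
        self.positive_pairs = frozenset(
            tuple(sorted(p)) for p in self.positive_pairs
            if p[0] in uni and p[1] in uni and p[0] != p[1]
        )

    def label(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.positive_pairs

    def series(self, gene_a: Iterable[str], gene_b: Iterable[str]) -> np.ndarray:
        """Vectorized labels for aligned gene_a / gene_b sequences."""
        return np.array(
            [tuple(sorted((a, b))) in self.positive_pairs for a, b in zip(gene_a, gene_b)],
            dtype=bool,
        )

    @property
    def n_pairs(self) -> int:
        n = len(self.universe)
        return n * (n - 1) // 2

    @property
    def base_rate(self) -> float:
        """Fraction of all universe pairs that are co-annotated."""
        return len(self.positive_pairs) / self.n_pairs
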