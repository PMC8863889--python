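"""Core containers shared across the package.

Matrices are plain pandas DataFrames (genes as rows, cell lines as columns);
the classes here wrap them only where an invariant has to be carried around
(alignment, annotation, null-model parameters, synthetic ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellAnnotation",
    "AlignedDataset",
    "PairList",
    "NullModel",
    "SyntheticConfig",
    "SyntheticTruth",
    "PairRegression",
]


@dataclass(frozen=True)
class CellAnnotation:
    """One cell line and its tissue / cancer-type label."""

    cell_line: str
    tissue_type: str


class AlignedDataset:
    """Dependency and expression panels sharing one cell-line axis.

    Parameters
    ----------
    dependency : DataFrame
        Gene x cell-line CERES-style dependency scores (more negative =
        more essential).  No missing values after alignment.
    expression : DataFrame
        Gene x cell-line log2(TPM+1) expression, all values >= 0.
    annotation : Series
        Tissue label per cell line, indexed by cell line.

    Both matrices must carry the cell lines in identical order; the gene
    universes may differ.
    """

    def __init__(self, dependency: pd.DataFrame, expression: pd.DataFrame,
                 annotation: pd.Series):
        if list(dependency.columns) != list(expression.columns):
            raise ValueError("dependency and expression must share the same "
                             "cell-line order")
        missing = [c for c in dependency.columns if c not in annotation.index]
        if missing:
            raise ValueError(f"cell lines lacking a tissue label: {missing[:5]}")
        if dependency.index.has_duplicates or expression.index.has_duplicates:
            raise ValueError("duplicate gene IDs in aligned matrices")
        self.dependency = dependency
        self.expression = expression
        self.annotation = annotation.reindex(dependency.columns)

    @property
    def cell_lines(self) -> list[str]:
        return list(self.dependency.columns)

    @property
    def n_cell_lines(self) -> int:
        return self.dependency.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"AlignedDataset({self.dependency.shape[0]} dependency genes, "
                f"{self.expression.shape[0]} expression genes, "
                f"{self.n_cell_lines} cell lines, "
                f"{self.annotation.nunique()} tissues)")


class PairList:
    """A list of gene pairs with optional per-row payload.

    For annotation-style lists (duplicated pairs, pathway co-membership,
    PPI) membership is unordered: (a, b) and (b, a) are the same pair.
    Genetic-interaction (GI) lists additionally carry a cell line and a
    score per row and stay directional rows in ``table``.
    """

    SYMMETRIC_KINDS = {"duplicated", "annotation", "ppi"}

    def __init__(self, table: pd.DataFrame, kind: str = "annotation"):
        if not {"gene_a", "gene_b"}.issubset(table.columns):
            raise ValueError("pair table requires gene_a and gene_b columns")
        self.table = table.reset_index(drop=True)
        self.kind = kind
        self._members: set[tuple[str, str]] = set()
        symmetric = kind in self.SYMMETRIC_KINDS
        for a, b in zip(table["gene_a"], table["gene_b"]):
            key = (min(a, b), max(a, b)) if symmetric else (a, b)
            self._members.add(key)
        self.symmetric = symmetric

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        key = (min(a, b), max(a, b)) if self.symmetric else (a, b)
        return key in self._members

    def __len__(self) -> int:
        return len(self._members)

    def pairs(self) -> set[tuple[str, str]]:
        """Normalized membership set (sorted tuples when symmetric)."""
        return set(self._members)


@dataclass
class NullModel:
    """Normal fit to C-scores computed after shuffling expression.

    ``mu``/``sigma`` are the pooled moments over all shuffles; per-shuffle
    moments are retained for inspection.
    """

    mu: float
    sigma: float
    n_shuffles: int
    n_samples: int
    per_shuffle: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("null sigma must be positive")

    def sf(self, c: np.ndarray | float) -> np.ndarray | float:
        """Upper-tail probability of a C-score under the null."""
        from scipy import stats

        return stats.norm.sf(c, loc=self.mu, scale=self.sigma)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic DepMap-like generator.

    Defaults are the package's reference conditions: 200 cell lines in 10
    tissue blocks, a 100 x 100 (G1 x G2) pair universe with 50 planted
    buffering pairs of slope 0.01 log2 TPM per dependency unit, dependency
    noise 0.1 and expression noise 0.5.
    """

    n_cell_lines: int = 200
    n_tissues: int = 10
    n_g1: int = 100
    n_g2: int = 100
    n_planted_pairs: int = 50
    planted_slope: float = 0.01
    dependency_noise_sd: float = 0.1
    expression_noise_sd: float = 0.5
    tissue_effect_sd: float = 1.0
    expression_baseline: float = 4.0
    baseline_dependency: float = -0.5
    tissue_boost: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_pairs > min(self.n_g1, self.n_g2):
            raise ValueError("n_planted_pairs exceeds min(n_g1, n_g2)")
        for name in ("dependency_noise_sd", "expression_noise_sd",
                     "tissue_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_dependency >= 0:
            raise ValueError("baseline_dependency must be negative")
        if self.planted_slope == 0:
            raise ValueError("planted_slope must be nonzero")
        if (self.dependency_noise_sd == 0 and self.expression_noise_sd == 0
                and self.tissue_effect_sd == 0):
            raise ValueError("degenerate config: zero variance everywhere")
        if self.n_tissues < 1 or self.n_cell_lines < self.n_tissues:
            raise ValueError("need at least one cell line per tissue")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset.

    ``planted`` has one row per planted pair: g1, g2, true_slope,
    true_intercept.  ``tissue_of`` maps cell line -> tissue and
    ``tissue_means`` holds each expression gene's per-tissue mean, which is
    sufficient to recompute the expected regression parameters.
    """

    planted: pd.DataFrame
    tissue_of: pd.Series
    tissue_means: pd.DataFrame
    boosted_tissue: str | None = None

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.planted["g1"], self.planted["g2"]))


@dataclass(frozen=True)
class PairRegression:
    """Per-pair regression of G2 expression on G1 dependency."""

    g1: str
    g2: str
    rho: float
    slope: float
    p_rho: float
    n: int
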