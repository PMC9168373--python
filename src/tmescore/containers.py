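"""Core in-memory containers shared across the pipeline.

Expression data travels as an :class:`ExpressionMatrix` (genes x samples),
deconvolution results as a :class:`CellFractionTable` (samples x cell types),
and survival data as a plain pandas DataFrame with ``time``/``event`` columns
(see :mod:`tmescore.survstats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd


class Unit(str, Enum):
    """Scale of an expression matrix; transitions only via declared ops."""

    FPKM = "FPKM"
    TPM = "TPM"
    LOG2TPM = "LOG2TPM"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with an optional missingness mask.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    unit
        One of ``FPKM``, ``TPM``, ``LOG2TPM``.
    mask
        Optional boolean DataFrame, same shape; True marks a missing entry.
    """

    values: pd.DataFrame
    unit: Unit = Unit.TPM
    mask: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.unit = Unit(self.unit)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if self.mask is not None:
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape does not match values")
            self.mask = self.mask.astype(bool)
            self.mask.index = self.values.index
            self.mask.columns = self.values.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(),
            self.unit,
            None if self.mask is None else self.mask.copy(),
        )

    def with_values(self, values: pd.DataFrame, unit: Unit | None = None,
                    mask: Optional[pd.DataFrame] = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, unit or self.unit, mask)


@dataclass
class SignatureMatrix:
    """Reference expression of marker genes across immune cell types."""

    values: pd.DataFrame  # genes x cell types

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate cell types in signature matrix")
        if self.values.shape[1] < 2:
            raise ValueError("signature matrix needs at least 2 cell types")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("signature matrix contains non-finite values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_type_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class CellFractionTable:
    """Per-sample immune cell fractions with reconstruction diagnostics."""

    fractions: pd.DataFrame  # samples x cell types
    rmse: pd.Series
    pearson_r: pd.Series

    @property
    def sample_ids(self) -> pd.Index:
        return self.fractions.index

    @property
    def cell_type_ids(self) -> pd.Index:
        return self.fractions.columns


@dataclass
class ConsensusResult:
    """Consensus clustering output across a range of cluster numbers."""

    k_range: list[int]
    consensus_matrices: dict[int, np.ndarray]
    cdf_areas: dict[int, float]
    chosen_k: int
    labels: pd.Series  # item id -> cluster id (1-based, ordered by size)


@dataclass
class GeneClusterSet:
    """Gene clusters with their per-sample metagene (PC1) scores and Cox signs."""

    members: dict[str, list[str]]          # cluster id -> gene ids
    pc1_scores: pd.DataFrame               # samples x cluster ids
    cox_signs: dict[str, int] = field(default_factory=dict)  # cluster id -> +1/-1


@dataclass
class TMEscoreTable:
    """Per-sample TMEscore with the dichotomizing cutoff and group labels."""

    scores: pd.Series                      # sample id -> score
    cutoff: Optional[float] = None
    groups: Optional[pd.Series] = None     # "high" / "low"


@dataclass
class GroundTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    true_fractions: pd.DataFrame           # samples x cell types
    true_subtype: pd.Series                # sample -> subtype label (1-based)
    true_latent_score: pd.Series
    module_membership: dict[str, str]      # gene -> module id
    batch: pd.Series
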