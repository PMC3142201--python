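"""Protein-profile construction: peptide-to-protein aggregation and imputation.

Differential testing runs at the peptide level, but cluster analysis needs one
value per protein and condition.  Each cell of the profile matrix is the
arithmetic mean (optionally median or trimmed mean) of all peptide abundance
ratios observed for that protein under that condition.  Cells backed by fewer
than ``min_support`` measurements are flagged missing; the primary pipeline
simply drops proteins with any missing cell, while mean-imputation of a small
number of missing cells per protein is available as an opt-in alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model_io import PeptideQuantTable

__all__ = ["ProfileMatrix", "aggregate", "impute"]


@dataclass
class ProfileMatrix:
    """Protein x condition matrix of mean abundance ratios.

    ``support`` counts the peptide measurements behind each cell;
    ``missing_mask`` marks cells whose support fell below the minimum at
    build time; ``imputed_mask`` marks cells later filled by imputation.
    """

    protein_ids: list[str]
    conditions: list[str]
    values: np.ndarray
    support: np.ndarray
    missing_mask: np.ndarray
    imputed_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    min_support: int = 2
    n_dropped_all_missing: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.support = np.asarray(self.support, dtype=int)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.imputed_mask is None:
            self.imputed_mask = np.zeros_like(self.missing_mask)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        shape = (len(self.protein_ids), len(self.conditions))
        for name in ("values", "support", "missing_mask", "imputed_mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, expected {shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def complete(self) -> "ProfileMatrix":
        """Sub-matrix of proteins with no missing (non-imputed) cell.

        This is the default clustering input: proteins with at least
        ``min_support`` peptide measurements in every condition.
        """
        unresolved = self.missing_mask & ~self.imputed_mask
        keep = ~unresolved.any(axis=1)
        return self._take(np.flatnonzero(keep))

    def _take(self, idx: np.ndarray) -> "ProfileMatrix":
        return ProfileMatrix(
            protein_ids=[self.protein_ids[i] for i in idx],
            conditions=list(self.conditions),
            values=self.values[idx],
            support=self.support[idx],
            missing_mask=self.missing_mask[idx],
            imputed_mask=self.imputed_mask[idx],
            min_support=self.min_support,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide-format DataFrame (``protein`` + one column per condition)."""
        df = pd.DataFrame(self.values, columns=self.conditions)
        df.insert(0, "protein", self.protein_ids)
        return df

    def support_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.support, columns=self.conditions)
        df.insert(0, "protein", self.protein_ids)
        return df


def _cell_statistic(values: np.ndarray, statistic: str, trim: float) -> float:
    if statistic == "mean":
        return float(np.mean(values))
    if statistic == "median":
        return float(np.median(values))
    if statistic == "trimmed":
        from scipy.stats import trim_mean

        return float(trim_mean(values, trim))
    raise ValueError(f"unknown statistic {statistic!r}")


def aggregate(
    table: PeptideQuantTable,
    min_support: int = 2,
    statistic: str = "mean",
    trim: float = 0.1,
) -> ProfileMatrix:
    """Aggregate peptide ratios into a protein x condition profile matrix.

    Every protein appearing in the table is retained (the *extended* matrix);
    cells with fewer than ``min_support`` measurements are flagged missing and
    carry the mean of whatever was observed (NaN for support zero).  Use
    :meth:`ProfileMatrix.complete` for the filtered matrix that the primary
    clustering pipeline consumes.

    Aggregation is permutation-invariant: record order never affects cells.
    """
    if len(table) == 0:
        empty = np.zeros((0, len(table.conditions)))
        return ProfileMatrix([], list(table.conditions), empty, empty.astype(int),
                             empty.astype(bool), min_support=min_support)
    proteins = list(dict.fromkeys(table.data["protein"].astype(str)))
    conditions = list(table.conditions)
    p_index = {p: i for i, p in enumerate(proteins)}
    c_index = {c: j for j, c in enumerate(conditions)}

    values = np.full((len(proteins), len(conditions)), np.nan)
    support = np.zeros((len(proteins), len(conditions)), dtype=int)
    grouped = table.data.groupby(["protein", "condition"], sort=False)["ratio"]
    for (prot, cond), vals in grouped:
        i, j = p_index[str(prot)], c_index[str(cond)]
        arr = vals.to_numpy(dtype=float)
        support[i, j] = arr.size
        values[i, j] = _cell_statistic(arr, statistic, trim)
    missing = support < min_support
    return ProfileMatrix(proteins, conditions, values, support, missing,
                         min_support=min_support)


def impute(matrix: ProfileMatrix, max_missing_per_protein: int = 1) -> ProfileMatrix:
    """Mean-impute missing profile cells, protein by protein.

    A missing cell receives the protein's mean ratio over its observed
    conditions.  Proteins with more than ``max_missing_per_protein`` missing
    cells, or with no observed cell at all, are dropped; the count of
    all-missing proteins is recorded on the result.  Observed cells are never
    altered, and a matrix without missing cells is returned unchanged.
    """
    unresolved = matrix.missing_mask & ~matrix.imputed_mask
    if not unresolved.any():
        return matrix
    n_missing = unresolved.sum(axis=1)
    n_observed = (~unresolved).sum(axis=1)
    keep = (n_missing <= max_missing_per_protein) & (n_observed >= 1)
    n_all_missing = int((n_observed == 0).sum())

    out = matrix._take(np.flatnonzero(keep))
    unresolved = out.missing_mask & ~out.imputed_mask
    values = out.values.copy()
    # a missing cell may still hold a single-measurement value; imputation
    # replaces it by the protein mean over fully supported cells
    observed_vals = np.where(unresolved, np.nan, values)
    row_means = np.nanmean(observed_vals, axis=1)
    rows, cols = np.nonzero(unresolved)
    values[rows, cols] = row_means[rows]
    imputed = out.imputed_mask | unresolved
    return replace(out, values=values, imputed_mask=imputed,
                   n_dropped_all_missing=n_all_missing)
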