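"""Core data types and tab-separated I/O shared by every analysis stage.

The pipeline's unit of raw data is one relative abundance measurement: the
ratio of the stable-isotope-labeled (e.g. 15N) to the unlabeled (14N) signal
of a single peptide pair, tagged with a protein accession, a condition label
(time point or carbon source) and a replicate label.  Long tables of such
records are the input to the differential-regulation stage and, after
aggregation, to cluster analysis.

All tabular artifacts are plain TSV with a single header line; lines starting
with ``#`` are treated as provenance comments.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "REQUIRED_COLUMNS",
    "TableFormatError",
    "RowValueError",
    "PeptideQuantRecord",
    "PeptideQuantTable",
    "AnalysisConfig",
    "read_peptide_table",
    "write_peptide_table",
    "write_table",
    "apply_log2",
]

#: canonical column names of a peptide quantification table
REQUIRED_COLUMNS = ("protein", "peptide", "condition", "replicate", "ratio")


class TableFormatError(ValueError):
    """The file does not conform to the expected tabular layout."""


class RowValueError(ValueError):
    """A single row holds an invalid value (e.g. a non-positive ratio)."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class PeptideQuantRecord:
    """One peptide-level abundance-ratio measurement."""

    protein_id: str
    peptide_id: str
    condition: str
    replicate: str
    ratio: float

    def __post_init__(self) -> None:
        if not self.condition or not self.replicate:
            raise ValueError("condition and replicate labels must be non-empty")
        if not math.isfinite(self.ratio):
            raise ValueError(f"ratio must be finite, got {self.ratio!r}")


@dataclass
class PeptideQuantTable:
    """Long-format table of peptide abundance ratios.

    Parameters
    ----------
    data
        DataFrame with columns ``protein, peptide, condition, replicate,
        ratio``.  Row order is meaningful and preserved.
    conditions
        The fixed condition order used by every downstream artifact
        (profile-matrix columns, test groupings).  Defaults to first
        appearance in ``data``.
    log_transformed
        True when ratios have been replaced by their log2 at load time, in
        which case the positivity requirement no longer applies.
    """

    data: pd.DataFrame
    conditions: list[str] = field(default_factory=list)
    log_transformed: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise TableFormatError(f"missing required column(s): {', '.join(missing)}")
        self.data = self.data.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
        if not self.conditions:
            self.conditions = list(dict.fromkeys(self.data["condition"].astype(str)))
        else:
            extra = set(self.data["condition"].astype(str)) - set(self.conditions)
            if extra:
                raise TableFormatError(
                    f"records use condition(s) not in the condition list: {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def protein_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["protein"].astype(str)))

    def records(self) -> Iterator[PeptideQuantRecord]:
        for row in self.data.itertuples(index=False):
            yield PeptideQuantRecord(
                str(row.protein), str(row.peptide), str(row.condition),
                str(row.replicate), float(row.ratio),
            )


@dataclass
class AnalysisConfig:
    """Run-level settings shared across stages.

    alpha is the family-wise significance level for all four test families
    (common choices are 0.05 or 0.01); ``min_peptides_per_condition`` is the
    support filter applied before profile clustering; ``k_min``/``k_max``
    bound cluster-number sweeps; ``seed`` feeds every stochastic stage.
    """

    alpha: float = 0.05
    log_transform: bool = False
    min_peptides_per_condition: int = 2
    k_min: int = 2
    k_max: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.min_peptides_per_condition < 1:
            raise ValueError("min_peptides_per_condition must be >= 1")
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in mapping.items() if k in known})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, Mapping):
            raise TableFormatError(f"config file {path} is not a key-value mapping")
        return cls.from_mapping(payload.get("analysis", payload))


def _resolve_dialect(columns: Sequence[str], dialect: Mapping[str, str] | None) -> dict:
    """Map canonical column names to the names present in the file."""
    dialect = dict(dialect or {})
    rename = {}
    for canonical in REQUIRED_COLUMNS:
        source = dialect.get(canonical, canonical)
        if source not in columns:
            raise TableFormatError(
                f"required column '{source}' (for '{canonical}') not found in header"
            )
        rename[source] = canonical
    return rename


def read_peptide_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    condition_order: Sequence[str] | None = None,
    log_transform: bool = False,
) -> PeptideQuantTable:
    """Read a peptide quantification TSV.

    Parameters
    ----------
    dialect
        Optional map from canonical column names (``protein``, ``peptide``,
        ``condition``, ``replicate``, ``ratio``) to the header names actually
        used in the file, so external exports need no rewriting.
    condition_order
        Overrides the default first-appearance condition order.
    log_transform
        Apply a log2 transform to the ratios once, at load time.

    Raises
    ------
    TableFormatError
        A required column is missing from the header.
    RowValueError
        A ratio is non-numeric, non-positive or non-finite; the error carries
        the 1-based line number of the offending row.
    """
    path = Path(path)
    # locate the header line so row errors can report true line numbers
    header_line = 1
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#") and line.strip():
                header_line = lineno
                break
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    raw = raw.rename(columns=_resolve_dialect(raw.columns, dialect))

    ratios = pd.to_numeric(raw["ratio"], errors="coerce")
    bad = ~np.isfinite(ratios.to_numpy(dtype=float))
    if not log_transform:
        bad |= ratios.to_numpy(dtype=float) <= 0
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise RowValueError(
            f"invalid ratio {raw['ratio'].iloc[i]!r} at line {header_line + 1 + i} "
            f"(must be a positive finite number)",
            line=header_line + 1 + i,
        )
    data = raw.assign(ratio=ratios.astype(float))
    table = PeptideQuantTable(data, conditions=list(condition_order or []))
    if log_transform:
        table = apply_log2(table)
    return table


def apply_log2(table: PeptideQuantTable) -> PeptideQuantTable:
    """Return a copy of the table with ratios replaced by log2(ratio).

    Applied at most once; the flag is recorded so provenance headers and
    result tables can state the scale of the analyzed values.
    """
    if table.log_transformed:
        return table
    if (table.data["ratio"] <= 0).any():
        raise RowValueError("cannot log-transform non-positive ratios")
    data = table.data.assign(ratio=np.log2(table.data["ratio"].to_numpy()))
    return PeptideQuantTable(data, conditions=list(table.conditions), log_transformed=True)


def write_table(
    records: pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write any tabular result as a deterministic TSV.

    One header line, fixed column order (as given), floats serialized with 6
    significant digits.  Two writes of the same data produce byte-identical
    files.  Optional provenance is emitted as leading ``# key: value`` lines.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        records.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def write_peptide_table(
    table: PeptideQuantTable,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write a peptide table (optionally with provenance header comments)."""
    meta = dict(provenance or {})
    if table.log_transformed:
        meta.setdefault("ratio_scale", "log2")
    write_table(table.data, path, provenance=meta)
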