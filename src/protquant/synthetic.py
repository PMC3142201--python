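"""Synthetic data with the statistical structure of isotope-ratio proteomics.

Real stable-isotope experiments deliver, per protein, dozens to thousands of
peptide-level abundance ratios spread over a handful of conditions (time
points after a stress, or alternative carbon sources) and a few biological
replicates.  The generator reproduces the features the downstream statistics
care about:

* unregulated proteins fluctuate around a protein-specific baseline ratio;
* regulated proteins carry condition-dependent mean shifts shaped as a step,
  a monotone ramp, or a transient pulse — the patterns seen in stress and
  starvation time courses;
* a fraction of proteins violates the ANOVA prerequisites, either through one
  condition with inflated variance or through heavy-tailed (t, df=3)
  residuals;
* some protein x condition cells receive too few measurements and trip the
  minimum-support filter;
* contaminant proteins (e.g. keratins entering during sample handling) show
  label-swap artifacts: both very high and very low ratios, hence extreme
  pooled variance.

Every draw flows from one :class:`numpy.random.Generator` seeded from the
config, so identical configs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model_io import PeptideQuantTable
from .profiles import ProfileMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_peptide_table",
    "simulate_profile_matrix",
]

#: default condition labels: minutes after stress induction, five time points
DEFAULT_CONDITIONS = ("t0", "t10", "t30", "t60", "t120")


@dataclass
class SimulationConfig:
    """Parameters of the peptide-table simulation.

    ``effect_size`` is the peak mean shift (in ratio units) a regulated
    protein shows between its most extreme conditions; with the default
    ``noise_sd`` of 0.1 (a ~10% coefficient of variation around a baseline
    near 1, typical of well-behaved isotope-pair quantification) the default
    effect of 0.5 is a strong, clearly detectable regulation.
    """

    n_proteins: int = 200
    conditions: Sequence[str] = DEFAULT_CONDITIONS
    replicates: int = 3
    peptides_per_condition: int = 12
    frac_regulated: float = 0.2
    effect_size: float = 0.5
    frac_heteroscedastic: float = 0.1
    frac_heavy_tailed: float = 0.1
    missing_rate: float = 0.0
    frac_contaminant: float = 0.0
    noise_sd: float = 0.1
    baseline_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 0 or self.replicates < 1 or self.peptides_per_condition < 1:
            raise ValueError("counts must be non-negative (replicates/peptides >= 1)")
        for name in ("frac_regulated", "frac_heteroscedastic", "frac_heavy_tailed",
                     "missing_rate", "frac_contaminant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if len(self.conditions) < 2 and self.n_proteins > 0:
            raise ValueError("need at least two conditions")
        self.conditions = tuple(str(c) for c in self.conditions)


@dataclass
class GroundTruth:
    """Per-protein simulation truth for parameter-recovery tests.

    ``assumption_violation`` is one of ``none``/``variance``/``normality``;
    ``true_cluster`` holds contiguous labels for profile simulations and -1
    where no cluster structure was simulated.
    """

    table: pd.DataFrame

    COLUMNS = ("protein", "regulated", "assumption_violation", "contaminant", "true_cluster")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"ground truth missing column(s): {missing}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def regulated(self) -> np.ndarray:
        return self.table["regulated"].to_numpy(dtype=bool)

    @property
    def contaminant(self) -> np.ndarray:
        return self.table["contaminant"].to_numpy(dtype=bool)

    @property
    def true_cluster(self) -> np.ndarray:
        return self.table["true_cluster"].to_numpy(dtype=int)


def _regulated_offsets(rng: np.random.Generator, n_cond: int, effect: float) -> tuple[np.ndarray, str]:
    """Condition-wise mean offsets for one regulated protein."""
    shape = rng.choice(("step", "ramp", "pulse"))
    sign = rng.choice((-1.0, 1.0))
    offsets = np.zeros(n_cond)
    if shape == "step":
        offsets[n_cond // 2:] = effect
    elif shape == "ramp":
        offsets[:] = np.linspace(0.0, effect, n_cond)
    else:  # transient pulse
        offsets[n_cond // 2] = effect
    return sign * offsets, str(shape)


def simulate_peptide_table(cfg: SimulationConfig) -> tuple[PeptideQuantTable, GroundTruth]:
    """Simulate a peptide quantification table plus its ground truth.

    Contaminants, regulated proteins and the two assumption-violation classes
    are disjoint protein sets drawn without replacement.  Cells selected for
    missingness receive 0 or 1 measurements (below the default support
    minimum of 2); all other cells receive ``peptides_per_condition``
    measurements distributed round-robin over the replicates.
    """
    rng = np.random.default_rng(cfg.seed)
    n, n_cond = cfg.n_proteins, len(cfg.conditions)
    proteins = np.array([f"P{i:05d}" for i in range(n)])

    if n == 0:
        empty = pd.DataFrame(columns=["protein", "peptide", "condition", "replicate", "ratio"])
        truth = GroundTruth(pd.DataFrame(columns=list(GroundTruth.COLUMNS)))
        return PeptideQuantTable(empty, conditions=list(cfg.conditions)), truth

    order = rng.permutation(n)
    n_contam = int(round(cfg.frac_contaminant * n))
    contaminant = np.zeros(n, dtype=bool)
    contaminant[order[:n_contam]] = True
    clean = order[n_contam:]

    regulated = np.zeros(n, dtype=bool)
    n_reg = int(round(cfg.frac_regulated * n))
    regulated[rng.choice(clean, size=min(n_reg, clean.size), replace=False)] = True

    violation = np.full(n, "none", dtype=object)
    n_var = int(round(cfg.frac_heteroscedastic * n))
    n_norm = int(round(cfg.frac_heavy_tailed * n))
    viol_pool = rng.permutation(clean)
    violation[viol_pool[:n_var]] = "variance"
    violation[viol_pool[n_var:n_var + n_norm]] = "normality"

    baseline = rng.uniform(*cfg.baseline_range, size=n)
    offsets = np.zeros((n, n_cond))
    shape_tag = np.full(n, "flat", dtype=object)
    for i in np.flatnonzero(regulated):
        offsets[i], shape_tag[i] = _regulated_offsets(rng, n_cond, cfg.effect_size)

    cell_mu = baseline[:, None] + offsets  # (n, n_cond)
    cell_sd = np.full((n, n_cond), cfg.noise_sd)
    for i in np.flatnonzero(violation == "variance"):
        cell_sd[i, rng.integers(n_cond)] *= 4.0

    counts = np.full((n, n_cond), cfg.peptides_per_condition, dtype=int)
    if cfg.missing_rate > 0:
        miss = rng.random((n, n_cond)) < cfg.missing_rate
        counts[miss] = rng.integers(0, 2, size=int(miss.sum()))

    # expand cells to rows
    flat_counts = counts.ravel()
    cell_ids = np.repeat(np.arange(n * n_cond), flat_counts)
    row_protein = cell_ids // n_cond
    row_cond = cell_ids % n_cond
    n_rows = cell_ids.size

    # within-cell measurement index -> replicate (round-robin)
    within = np.concatenate([np.arange(c) for c in flat_counts]) if n_rows else np.array([], int)
    replicate = within % cfg.replicates + 1

    mu = cell_mu[row_protein, row_cond]
    sd = cell_sd[row_protein, row_cond]
    heavy = np.isin(row_protein, np.flatnonzero(violation == "normality"))
    contam_row = contaminant[row_protein]

    eps = rng.standard_normal(n_rows)
    if heavy.any():
        # t(3) rescaled to unit variance keeps the nominal noise_sd
        eps[heavy] = rng.standard_t(3, size=int(heavy.sum())) / np.sqrt(3.0)
    ratio = mu + sd * eps
    if contam_row.any():
        # label swaps yield both very high and very low ratios
        ratio[contam_row] = mu[contam_row] * np.exp2(rng.normal(0.0, 3.0, size=int(contam_row.sum())))
    # ratios are physical quantities: redraw the (vanishingly rare) non-positive values
    for _ in range(100):
        bad = ratio <= 0
        if not bad.any():
            break
        ratio[bad] = mu[bad] + sd[bad] * rng.standard_normal(int(bad.sum()))
    np.clip(ratio, 1e-9, None, out=ratio)

    data = pd.DataFrame({
        "protein": proteins[row_protein],
        "peptide": "",
        "condition": np.asarray(cfg.conditions, dtype=object)[row_cond],
        "replicate": np.char.add("r", replicate.astype(str)),
        "ratio": ratio,
    })
    pep_idx = data.groupby("protein", sort=False).cumcount()
    data["peptide"] = np.char.add("pep", pep_idx.to_numpy().astype(str))

    truth = GroundTruth(pd.DataFrame({
        "protein": proteins,
        "regulated": regulated,
        "assumption_violation": violation,
        "contaminant": contaminant,
        "true_cluster": -1,
        "profile_shape": shape_tag,
    }))
    return PeptideQuantTable(data, conditions=list(cfg.conditions)), truth


def simulate_profile_matrix(
    n_per_cluster: Sequence[int],
    n_conditions: int,
    centers: np.ndarray,
    sd: float,
    seed: int = 0,
    condition_labels: Sequence[str] | None = None,
) -> tuple[ProfileMatrix, GroundTruth]:
    """Gaussian-blob protein profiles with known cluster membership.

    Each row is its cluster center plus iid N(0, sd^2) noise — the standard
    fixture for clustering and validity-index recovery tests.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n_per_cluster = [int(c) for c in n_per_cluster]
    if len(n_per_cluster) < 1:
        raise ValueError("need at least one cluster")
    if sd <= 0:
        raise ValueError("sd must be > 0")
    if centers.shape != (len(n_per_cluster), n_conditions):
        raise ValueError(
            f"centers shape {centers.shape} does not match "
            f"({len(n_per_cluster)}, {n_conditions})"
        )
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(n_per_cluster)), n_per_cluster)
    values = centers[labels] + rng.normal(0.0, sd, size=(labels.size, n_conditions))
    conditions = list(condition_labels or [f"c{j + 1}" for j in range(n_conditions)])
    proteins = [f"P{i:05d}" for i in range(labels.size)]
    matrix = ProfileMatrix(
        protein_ids=proteins,
        conditions=conditions,
        values=values,
        support=np.full(values.shape, 2, dtype=int),
        missing_mask=np.zeros(values.shape, dtype=bool),
    )
    truth = GroundTruth(pd.DataFrame({
        "protein": proteins,
        "regulated": True,
        "assumption_violation": "none",
        "contaminant": False,
        "true_cluster": labels,
    }))
    return matrix, truth
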