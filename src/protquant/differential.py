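"""Detection of differentially regulated proteins from peptide-level ratios.

Given the limited number of biological replicates in typical isotope-labeling
experiments, every peptide abundance ratio is treated as an independent
measurement of its protein's quantity.  For each protein the series of ratios
x_i with condition assignments t_i is submitted to

* a one-way fixed-effects ANOVA (x_i = mu + tau_{t_i} + eps_i),
* the non-parametric Kruskal-Wallis rank-sum test,
* a Shapiro-Wilk test on the pooled within-group residuals (normality
  prerequisite of the ANOVA), and
* a Fligner-Killeen test of variance homogeneity across conditions,

and each test's p-values are corrected across proteins with Holm's step-down
procedure to control the family-wise error rate.  A protein counts as
*strictly* significant when the adjusted ANOVA p-value falls below alpha while
neither assumption check rejects at the same level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .model_io import AnalysisConfig, PeptideQuantTable

__all__ = [
    "AbundanceSeries",
    "ConcordanceSummary",
    "BoxplotSummary",
    "CLASSIFICATIONS",
    "anova_oneway",
    "kruskal_wallis",
    "shapiro_wilk_residuals",
    "fligner_killeen",
    "holm_adjust",
    "run_differential",
    "concordance",
    "boxplot_summary",
]

CLASSIFICATIONS = (
    "strict_significant",
    "both_lenient",
    "anova_only_assumptions_violated",
    "kw_only",
    "not_significant",
    "untestable",
)

#: result-table column layout (mirrors the published result tables, with raw
#: p-values and the classification added)
RESULT_COLUMNS = (
    "protein", "n_peptide_hits",
    "anova_p", "kw_p", "shapiro_p", "fligner_p",
    "anova_p_adj", "kw_p_adj", "shapiro_p_adj", "fligner_p_adj",
    "classification",
)


@dataclass
class AbundanceSeries:
    """A protein's abundance-ratio series with its condition assignments."""

    values: np.ndarray
    groups: np.ndarray
    protein_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.values.shape != self.groups.shape:
            raise ValueError("values and groups must have equal length")
        if self.values.size and np.unique(self.groups).size < 1:
            raise ValueError("need at least one group")

    def split(self) -> list[np.ndarray]:
        """Values per group, in first-appearance group order."""
        order = list(dict.fromkeys(self.groups.tolist()))
        return [self.values[self.groups == g] for g in order]


def is_testable(series: AbundanceSeries) -> bool:
    """Weakest rule making all four tests well-defined.

    At least two conditions, every observed condition measured at least
    twice, and at least two residual degrees of freedom (N >= k + 2).
    """
    groups = series.split()
    k = len(groups)
    n = series.values.size
    return k >= 2 and all(g.size >= 2 for g in groups) and n >= k + 2


def anova_oneway(series: AbundanceSeries) -> tuple[float, float]:
    """One-way fixed-effects ANOVA F statistic and p-value.

    F = (SS_between / (k-1)) / (SS_within / (N-k)), with the p-value from the
    F(k-1, N-k) distribution.  Returns (nan, nan) for untestable series.  A
    series with zero within-group variance but distinct group means yields
    (inf, 0.0).
    """
    if not is_testable(series):
        return (np.nan, np.nan)
    groups = series.split()
    n, k = series.values.size, len(groups)
    grand = series.values.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssw <= 0.0:
        return (0.0, 1.0) if ssb <= 1e-300 else (np.inf, 0.0)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return float(f), float(st.f.sf(f, k - 1, n - k))


def kruskal_wallis(series: AbundanceSeries) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p-value.

    All-identical values give (0.0, 1.0); untestable series give NaNs.
    """
    if not is_testable(series):
        return (np.nan, np.nan)
    if np.ptp(series.values) == 0.0:  # all values identical: no evidence
        return (0.0, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            h, p = st.kruskal(*series.split())
        except ValueError:
            return (0.0, 1.0)
    return float(h), float(p)


def shapiro_wilk_residuals(series: AbundanceSeries) -> float:
    """Shapiro-Wilk p-value on pooled within-group residuals.

    Residuals are each value minus its group mean, pooled across groups
    (the ANOVA's normality prerequisite concerns deviations from the group
    mean).  NaN outside the test's 3..5000 sample range or for degenerate
    (zero-range) residuals.
    """
    residuals = np.concatenate([g - g.mean() for g in series.split()]) if series.values.size else np.array([])
    if not 3 <= residuals.size <= 5000 or np.ptp(residuals) == 0.0:
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(st.shapiro(residuals).pvalue)


def fligner_killeen(series: AbundanceSeries) -> float:
    """Fligner-Killeen p-value for homogeneity of group variances.

    Median-centered normal-scores rank test; chi-square with k-1 df.  NaN for
    degenerate input (fewer than two usable groups, or all median-centered
    residuals zero).
    """
    groups = [g for g in series.split() if g.size >= 2]
    if len(groups) < 2:
        return np.nan
    if all(np.ptp(g) == 0.0 for g in groups):
        return np.nan
    abs_resid = np.concatenate([np.abs(g - np.median(g)) for g in groups])
    if np.ptp(abs_resid) == 0.0:
        return 1.0  # identical spread patterns: statistic 0 by definition
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            p = float(st.fligner(*groups).pvalue)
        except (ValueError, ZeroDivisionError):
            return np.nan
    return p if np.isfinite(p) else np.nan


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm's step-down FWER adjustment, NA-aware.

    NaNs are excluded from the family size m and stay NaN.  The i-th smallest
    p-value is multiplied by (m - i + 1), the running maximum is enforced and
    results are capped at 1.  The output is invariant to input order.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return out
    m = idx.size
    order = idx[np.argsort(p[idx], kind="stable")]
    adj = p[order] * (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out[order] = adj
    return out


def _classify(row: Mapping[str, float], alpha: float) -> str:
    """Decision rule on Holm-adjusted p-values.

    Precedence: strict (ANOVA significant, both assumption checks pass) >
    both_lenient (ANOVA and KW significant, assumptions violated) >
    anova_only_assumptions_violated > kw_only > not_significant.  A missing
    assumption p-value counts as unverified, hence never strict.
    """
    anova_sig = row["anova_p_adj"] < alpha
    kw_sig = row["kw_p_adj"] < alpha
    assumptions_ok = (row["fligner_p_adj"] >= alpha) and (row["shapiro_p_adj"] >= alpha)
    if anova_sig and assumptions_ok:
        return "strict_significant"
    if anova_sig and kw_sig:
        return "both_lenient"
    if anova_sig:
        return "anova_only_assumptions_violated"
    if kw_sig:
        return "kw_only"
    return "not_significant"


def run_differential(table: PeptideQuantTable, cfg: AnalysisConfig) -> pd.DataFrame:
    """Per-protein testing with Holm correction and classification.

    Returns one row per protein (columns in :data:`RESULT_COLUMNS`).  Each of
    the four tests is Holm-adjusted as its own family across all proteins for
    which that test produced a p-value; untestable proteins are reported but
    excluded from every family.
    """
    if len(table) == 0:
        raise ValueError("peptide table is empty")
    rows = []
    for protein, sub in table.data.groupby("protein", sort=False):
        # conditions measured fewer than twice cannot contribute a variance
        # estimate and are excluded from this protein's series
        counts = sub["condition"].value_counts()
        usable = counts.index[counts >= 2]
        sub_used = sub[sub["condition"].isin(usable)]
        series = AbundanceSeries(
            sub_used["ratio"].to_numpy(dtype=float),
            sub_used["condition"].to_numpy(),
            protein_id=str(protein),
        )
        if not is_testable(series):
            rows.append({"protein": str(protein), "n_peptide_hits": len(sub),
                         "anova_p": np.nan, "kw_p": np.nan,
                         "shapiro_p": np.nan, "fligner_p": np.nan})
            continue
        _, anova_p = anova_oneway(series)
        _, kw_p = kruskal_wallis(series)
        rows.append({
            "protein": str(protein),
            "n_peptide_hits": len(sub),
            "anova_p": anova_p,
            "kw_p": kw_p,
            "shapiro_p": shapiro_wilk_residuals(series),
            "fligner_p": fligner_killeen(series),
        })
    results = pd.DataFrame(rows)
    for test in ("anova", "kw", "shapiro", "fligner"):
        results[f"{test}_p_adj"] = holm_adjust(results[f"{test}_p"].to_numpy())

    untestable = results["anova_p"].isna() & results["kw_p"].isna()
    classifications = []
    for i, row in results.iterrows():
        if untestable.iloc[i]:
            classifications.append("untestable")
        else:
            classifications.append(_classify(row, cfg.alpha))
    results["classification"] = classifications
    return results.loc[:, list(RESULT_COLUMNS)]


@dataclass
class ConcordanceSummary:
    """Agreement between the parametric and the rank-based test."""

    spearman_rho: float
    n_anova_sig: int
    n_kw_sig: int
    n_strict: int
    n_overlap_lenient: int

    def __post_init__(self) -> None:
        if not np.isnan(self.spearman_rho) and not -1.0 <= self.spearman_rho <= 1.0:
            raise ValueError("spearman_rho out of [-1, 1]")
        if self.n_overlap_lenient > min(self.n_anova_sig, self.n_kw_sig):
            raise ValueError("overlap cannot exceed either significant count")


def concordance(results: pd.DataFrame, cfg: AnalysisConfig) -> ConcordanceSummary:
    """Spearman rank correlation of raw ANOVA vs KW p-values, plus counts.

    Raw p-values are compared (the Holm adjustment is a heavily tied
    monotone transform that would distort ranks).  Requires at least three
    proteins with both p-values; otherwise rho is NaN.
    """
    paired = results.dropna(subset=["anova_p", "kw_p"])
    if len(paired) >= 3:
        rho = float(st.spearmanr(paired["anova_p"], paired["kw_p"]).statistic)
    else:
        rho = np.nan
    alpha = cfg.alpha
    anova_sig = results["anova_p_adj"] < alpha
    kw_sig = results["kw_p_adj"] < alpha
    return ConcordanceSummary(
        spearman_rho=rho,
        n_anova_sig=int(anova_sig.sum()),
        n_kw_sig=int(kw_sig.sum()),
        n_strict=int((results["classification"] == "strict_significant").sum()),
        n_overlap_lenient=int((anova_sig & kw_sig).sum()),
    )


@dataclass
class BoxplotSummary:
    """Five-number summary of one condition's ratios, plus outliers.

    Quartiles use linear interpolation between order statistics; whiskers
    reach the most extreme data point within 1.5 IQR of the quartiles.
    """

    group: str
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not (self.whisker_low <= self.q1 <= self.median <= self.q3 <= self.whisker_high):
            raise ValueError("box summary ordering violated")


def boxplot_summary(series: AbundanceSeries) -> list[BoxplotSummary]:
    """Box-and-whisker summaries per condition, in group order."""
    out = []
    for group in dict.fromkeys(series.groups.tolist()):
        vals = np.sort(series.values[series.groups == group])
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_limit, hi_limit = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = vals[(vals >= lo_limit) & (vals <= hi_limit)]
        out.append(BoxplotSummary(
            group=str(group),
            median=float(med), q1=float(q1), q3=float(q3),
            whisker_low=float(inside.min()),
            whisker_high=float(inside.max()),
            outliers=vals[(vals < lo_limit) | (vals > hi_limit)],
        ))
    return out
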