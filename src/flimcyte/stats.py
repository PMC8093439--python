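"""Population-level heterogeneity statistics for single-cell feature tables.

Between-condition comparisons use the two-sided Mann-Whitney U test
(exact enumeration for small tie-free samples, normal approximation with
continuity and tie correction otherwise). Heterogeneity is quantified as
the percent coefficient of variation, CV = sd/mean * 100, tabulated per
variable and condition as the data behind a CV heatmap. Macrophage
phenotype composition (CD86+/CD206+/double-negative among mCherry+ cells)
is summarized per condition as mean percentage across fields of view with
an across-FOV standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PopulationSummary",
    "TestResult",
    "ProportionSummary",
    "summarize_population",
    "mann_whitney",
    "cv_heatmap",
    "phenotype_proportions",
    "VARIABLE_ORDER",
    "CONDITION_ORDER",
]

PHENOTYPES = ("CD86+", "CD206+", "double-negative")

#: Row order of the CV heatmap: redox ratio first, then mean lifetimes,
#: then component lifetimes and fractions per channel.
VARIABLE_ORDER = [
    "redox_ratio",
    "nadh_taum",
    "fad_taum",
    "nadh_tau1",
    "nadh_tau2",
    "nadh_alpha1",
    "fad_tau1",
    "fad_tau2",
    "fad_alpha1",
]
CONDITION_ORDER = ["tumor", "dermis"]

#: Exact Mann-Whitney enumeration is used up to this combined sample size
#: (tie-free samples only); beyond it the normal approximation applies.
EXACT_MAX_N = 20


@dataclass
class PopulationSummary:
    """Mean, sample SD, 95% CI half-width, and %CV for one variable."""

    variable: str
    condition: str | None
    n_cells: int
    mean: float
    sd: float
    ci95_half_width: float
    cv_percent: float


def summarize_population(
    records, variable: str, condition: str | None = None
) -> PopulationSummary:
    """Summarize one variable over a cell table (or a plain value array).

    Uses the sample (n-1) standard deviation; the 95% CI half-width is
    ``t_{0.975, n-1} * sd / sqrt(n)``. With fewer than two finite values
    the SD, CI and CV are absent (NaN).
    """
    if isinstance(records, pd.DataFrame):
        values = records[variable].to_numpy(dtype=float)
        if condition is None and "condition" in records and len(records):
            uniq = records["condition"].dropna().unique()
            condition = uniq[0] if len(uniq) == 1 else None
    else:
        values = np.asarray(records, dtype=float)
    values = values[np.isfinite(values)]
    n = values.size
    if n == 0:
        return PopulationSummary(variable, condition, 0, np.nan, np.nan, np.nan, np.nan)
    mean = float(values.mean())
    if n < 2:
        return PopulationSummary(variable, condition, n, mean, np.nan, np.nan, np.nan)
    sd = float(values.std(ddof=1))
    ci = float(sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n))
    cv = sd / mean * 100.0 if mean != 0 else np.nan
    return PopulationSummary(variable, condition, n, mean, sd, ci, cv)


@dataclass
class TestResult:
    """Two-sided Mann-Whitney U comparison of two unpaired samples."""

    variable: str
    u_statistic: float
    p_value: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int


def mann_whitney(a, b, variable: str = "") -> TestResult:
    """Two-sided Mann-Whitney U test (U reported for the first sample).

    Exact p by enumeration of rank arrangements when the combined sample
    is small (<= EXACT_MAX_N) and tie-free; otherwise the normal
    approximation with continuity and tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and a.size + b.size <= EXACT_MAX_N:
        method, scipy_method = "exact", "exact"
    else:
        method, scipy_method = "normal_approx", "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=scipy_method, use_continuity=True
    )
    return TestResult(
        variable=variable,
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        n1=int(a.size),
        n2=int(b.size),
    )


def cv_heatmap(summaries) -> pd.DataFrame:
    """%CV matrix, variables (rows) by conditions (columns).

    Rows/columns follow VARIABLE_ORDER / CONDITION_ORDER where applicable,
    then any extra labels in first-seen order. Missing cells are NaN with
    a warning.
    """
    variables, conditions = [], []
    for s in summaries:
        if s.variable not in variables:
            variables.append(s.variable)
        if s.condition not in conditions:
            conditions.append(s.condition)
    variables.sort(key=lambda v: (VARIABLE_ORDER.index(v) if v in VARIABLE_ORDER else len(VARIABLE_ORDER), v))
    conditions.sort(key=lambda c: (CONDITION_ORDER.index(c) if c in CONDITION_ORDER else len(CONDITION_ORDER), str(c)))
    mat = pd.DataFrame(np.nan, index=variables, columns=conditions)
    for s in summaries:
        mat.at[s.variable, s.condition] = s.cv_percent
    if mat.isna().any().any():
        warnings.warn("cv_heatmap: some variable/condition cells are missing")
    return mat


@dataclass
class ProportionSummary:
    """Phenotype composition of mCherry+ cells in one condition.

    Fractions are mean percentages across fields of view; SEMs are
    across-FOV standard errors. Totals need not informally reach 100% in
    real data (cells staining for neither marker are double-negative).
    """

    condition: str
    frac_cd206_pos: float
    frac_cd86_pos: float
    frac_double_negative: float
    n_fov: int
    sem_cd206_pos: float
    sem_cd86_pos: float
    sem_double_negative: float


def phenotype_proportions(cells: pd.DataFrame) -> list:
    """Per-condition phenotype percentages among mCherry+ cells.

    ``cells`` needs columns ``condition``, ``fov`` and ``phenotype`` (one
    row per cell). Percentages are computed per FOV and averaged; the SEM
    is the across-FOV standard error.
    """
    unknown = set(cells["phenotype"].dropna().unique()) - set(PHENOTYPES)
    if unknown:
        raise ValueError(f"unknown phenotype labels: {sorted(unknown)}")
    out = []
    for condition, grp in cells.groupby("condition", sort=False):
        per_fov = {ph: [] for ph in PHENOTYPES}
        for _, fov_grp in grp.groupby("fov", sort=False):
            n = len(fov_grp)
            for ph in PHENOTYPES:
                per_fov[ph].append((fov_grp["phenotype"] == ph).sum() / n * 100.0)
        n_fov = len(next(iter(per_fov.values())))
        means = {ph: float(np.mean(v)) for ph, v in per_fov.items()}
        sems = {
            ph: float(np.std(v, ddof=1) / np.sqrt(n_fov)) if n_fov > 1 else np.nan
            for ph, v in per_fov.items()
        }
        out.append(
            ProportionSummary(
                condition=condition,
                frac_cd206_pos=means["CD206+"],
                frac_cd86_pos=means["CD86+"],
                frac_double_negative=means["double-negative"],
                n_fov=n_fov,
                sem_cd206_pos=sems["CD206+"],
                sem_cd86_pos=sems["CD86+"],
                sem_double_negative=sems["double-negative"],
            )
        )
    return out
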