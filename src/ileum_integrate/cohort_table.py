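"""Cohort-characteristics summary table.

Between-phenotype tests for the per-sample covariates: Pearson chi-square
(no continuity correction) for categorical variables, Kruskal-Wallis for
age and BMI, and a Benjamini-Hochberg FDR column over the table's tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correlation_screen import bh_adjust

#: (column, display name, kind) in display order; 12 tests in total
COHORT_VARIABLES = (
    ("nod2", "NOD2 genotype", "categorical"),
    ("atg16l1", "ATG16L1 genotype", "categorical"),
    ("gender", "Gender (male)", "categorical"),
    ("race", "Race (Caucasian)", "categorical"),
    ("age", "Median age (range) y", "numeric"),
    ("smoker", "Current smoker", "categorical"),
    ("cdiff", "Positive fecal C. difficile toxin", "categorical"),
    ("bmi", "Median BMI (range) kg/m^2", "numeric"),
    ("asa5", "5-ASA", "categorical"),
    ("steroids", "Steroids", "categorical"),
    ("immunomod", "Immunomodulators", "categorical"),
    ("anti_tnf", "Anti-TNFa biologics", "categorical"),
)


@dataclass
class CohortSummary:
    """Table-shaped cohort report: one row per tested variable."""

    table: pd.DataFrame  # variable, test, statistic, df, p, q, significant
    descriptives: pd.DataFrame  # variable x phenotype formatted cells


def contingency_chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square for an r x c count table, without continuity
    correction; df = (r-1)(c-1)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (t.sum(axis=0) <= 0).any() or (t.sum(axis=1) <= 0).any():
        raise ValueError("degenerate margins (zero row or column total)")
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def kruskal_wallis(values, groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square P on (groups-1) df."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if np.ptp(values) == 0:
        return 0.0, len(levels) - 1, 1.0
    h, p = stats.kruskal(*samples)
    return float(h), len(levels) - 1, float(p)


def summarize_cohort(
    metadata: pd.DataFrame, phenotype_col: str = "phenotype"
) -> CohortSummary:
    """Build the cohort-characteristics report from per-sample metadata.

    Categorical variables get per-phenotype percentage cells and a
    chi-square P; numeric ones get median (range) cells and a
    Kruskal-Wallis P.  The q column is BH over all performed tests;
    variables with q <= 0.05 are marked significant.  Missing covariates
    are skipped with a warning.
    """
    if phenotype_col not in metadata.columns:
        raise ValueError(f"metadata lacks a {phenotype_col!r} column")
    phen = metadata[phenotype_col]
    phen_levels = list(pd.unique(phen))
    if len(phen_levels) < 2:
        raise ValueError("only one phenotype present; between-group tests undefined")

    rows, desc_rows = [], []
    for col, label, kind in COHORT_VARIABLES:
        if col not in metadata.columns:
            warnings.warn(f"covariate {col!r} missing; skipped", stacklevel=2)
            continue
        v = metadata[col]
        cells = {}
        if kind == "categorical":
            ct = pd.crosstab(v, phen).reindex(columns=phen_levels, fill_value=0)
            stat, df, p = contingency_chi_square(ct.to_numpy())
            test = "chi-square"
            for ph in phen_levels:
                pct = 100.0 * ct[ph] / ct[ph].sum()
                cells[ph] = "; ".join(
                    f"{lev}: {x:.0f}%" for lev, x in pct.items()
                )
        else:
            stat, df, p = kruskal_wallis(v.to_numpy(dtype=float), phen.to_numpy())
            test = "kruskal-wallis"
            for ph in phen_levels:
                sub = v[phen == ph].astype(float)
                cells[ph] = f"{sub.median():.0f} ({sub.min():.0f}-{sub.max():.0f})"
        rows.append(
            {"variable": label, "test": test, "statistic": stat, "df": df, "p": p}
        )
        desc_rows.append({"variable": label, **cells})

    if not rows:
        raise ValueError("no testable covariates found")
    table = pd.DataFrame(rows)
    table["q"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["q"] <= 0.05
    return CohortSummary(
        table=table.set_index("variable"),
        descriptives=pd.DataFrame(desc_rows).set_index("variable"),
    )
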