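"""Phenotype-stratified gene-transcript x bacterial-genus correlation screen.

Within each phenotype stratum, every selected transcript is correlated
against every selected genus relative frequency (Pearson by default, on
pairwise-complete observations).  Two-sided P values come from the
t-transform ``t = r sqrt((n-2)/(1-r^2))`` on n-2 df; signed significance
flags (+1 positive / -1 negative at P < alpha) mirror the red/green square
display, and Benjamini-Hochberg q values are computed over the whole
screen by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationGrid:
    """Long-format correlation screen results.

    ``table`` has one row per (gene, genus, stratum) with columns
    r, n, p, q, flag, available.
    """

    table: pd.DataFrame
    alpha: float
    method: str

    def flag_matrix(self) -> pd.DataFrame:
        """Gene x (stratum, genus) signed flag table mirroring the heatmap."""
        return self.table.pivot_table(
            index="gene", columns=["stratum", "genus"], values="flag", fill_value=0
        ).astype(int)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided P for a correlation via the t-transform on n-2 df."""
    if n < 3:
        return float("nan")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def bh_adjust(p, m: Optional[int] = None):
    """Benjamini-Hochberg step-up adjusted values.

    q_(i) = min_{j >= i} p_(j) * m / j on the ascending-sorted p, capped
    at 1 and mapped back to input order.  ``m`` defaults to the number of
    p values (supply a larger m to adjust within a wider family).
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    k = arr.size
    if m is None:
        m = k
    if m < k:
        raise ValueError("family size m cannot be smaller than the number of p values")
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(k)
    q[order] = q_sorted
    return q


def _pair_r(x: np.ndarray, y: np.ndarray, method: str):
    """(r, n) on pairwise-complete observations; (nan, n) if undefined."""
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        return float("nan"), n
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        return float("nan"), n
    if method == "spearman":
        xs = stats.rankdata(xs)
        ys = stats.rankdata(ys)
    r = float(np.corrcoef(xs, ys)[0, 1])
    return r, n


def stratified_correlations(
    expression: pd.DataFrame,
    frequencies: pd.DataFrame,
    strata: pd.Series,
    method: str = "pearson",
    alpha: float = 0.05,
    family: str = "joint",
    transform: str = "none",
) -> CorrelationGrid:
    """Correlate selected transcripts with selected genus frequencies per stratum.

    Parameters
    ----------
    expression : genes x samples log2 ratios
    frequencies : genera x samples relative frequencies
    strata : sample -> phenotype label
    family : {"joint", "per_stratum"}
        BH family for the q values (the whole grid by default).
    transform : {"none", "clr", "arcsine_sqrt"}
        Optional variance-stabilizing transform of the frequencies.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    samples = expression.columns.intersection(frequencies.columns).intersection(
        strata.index
    )
    if len(samples) == 0:
        raise ValueError("no shared samples between the three inputs")
    expr = expression[samples]
    freq = frequencies[samples].astype(float)
    if transform == "clr":
        vals = freq.to_numpy() + 1e-9
        logv = np.log(vals)
        freq = pd.DataFrame(
            logv - logv.mean(axis=0, keepdims=True), index=freq.index, columns=freq.columns
        )
    elif transform == "arcsine_sqrt":
        freq = np.arcsin(np.sqrt(freq.clip(0, 1)))
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    strata = strata.loc[samples]

    rows = []
    for stratum in sorted(strata.unique()):
        cols = strata.index[strata == stratum]
        for gene in expr.index:
            x = expr.loc[gene, cols].to_numpy(dtype=float)
            for genus in freq.index:
                y = freq.loc[genus, cols].to_numpy(dtype=float)
                r, n = _pair_r(x, y, method)
                p = correlation_pvalue(r, n) if np.isfinite(r) else float("nan")
                rows.append(
                    {
                        "gene": gene,
                        "genus": genus,
                        "stratum": stratum,
                        "r": r,
                        "n": n,
                        "p": p,
                        "available": np.isfinite(r),
                    }
                )
    table = pd.DataFrame(rows)

    table["q"] = np.nan
    if family == "joint":
        ok = table["available"] & table["p"].notna()
        if ok.any():
            table.loc[ok, "q"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    elif family == "per_stratum":
        for stratum in table["stratum"].unique():
            ok = (table["stratum"] == stratum) & table["available"] & table["p"].notna()
            if ok.any():
                table.loc[ok, "q"] = bh_adjust(table.loc[ok, "p"].to_numpy())
    else:
        raise ValueError(f"unknown family {family!r}")

    table["flag"] = 0
    sig = table["available"] & (table["p"] < alpha)
    table.loc[sig, "flag"] = np.sign(table.loc[sig, "r"]).astype(int)
    return CorrelationGrid(table=table, alpha=alpha, method=method)


def flag_grid(grid: CorrelationGrid, alpha: Optional[float] = None) -> pd.DataFrame:
    """Signed flag matrix (+1 pos / -1 neg at P < alpha, else 0)."""
    t = grid.table
    if alpha is None:
        return grid.flag_matrix()
    out = t.copy()
    out["flag"] = 0
    sig = out["available"] & (out["p"] < alpha)
    out.loc[sig, "flag"] = np.sign(out.loc[sig, "r"]).astype(int)
    return CorrelationGrid(out, alpha, grid.method).flag_matrix()
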