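"""Two-class unpaired SAM differential expression.

Implements the moderated relative-difference statistic
``d_i = (mean_B - mean_A) / (s_i + s0)`` with the fudge factor s0 chosen to
minimize the coefficient of variation of d across the spread of s, the
permutation-derived expected order statistics d-bar, asymmetric delta
cutoffs, and an FDR computed as the median number of falsely-called probes
across label permutations divided by the number called.  Probes are finally
gated jointly on FDR and linear fold change (expression values are log2
test/reference ratios, so fold change is ``2**(mean_B - mean_A)``).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class SamConfig:
    """Settings for one two-class SAM comparison."""

    fold_change_min: float = 1.5
    fdr_max: float = 0.05
    n_permutations: int = 200
    s0_method: str = "tusher_cv_minimizing"  # or "fixed_percentile", "zero"
    s0_percentile: Optional[float] = None
    seed: Optional[int] = None
    #: gate the permuted (null) calls on fold change as well
    fold_gate_permutations: bool = True
    #: use one symmetric delta cut instead of separate up/down slabs
    symmetric_delta: bool = False
    #: apply the later-SAM pi0 (proportion of true nulls) multiplier
    pi0_correction: bool = False

    def __post_init__(self) -> None:
        if self.fold_change_min < 1:
            raise ValueError("fold_change_min must be >= 1")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must be in (0, 1)")


@dataclass
class SamResult:
    """Per-probe SAM output plus the threshold bookkeeping."""

    table: pd.DataFrame  # columns: d, s, fold_change, q, call
    s0: float
    delta: float  # delta actually used for calling (nan if nothing called)
    dbar: np.ndarray  # expected order statistics, ascending
    delta_table: pd.DataFrame  # delta, n_called, median_false_positives, fdr
    n_permutations_used: int
    exhaustive: bool

    @property
    def called(self) -> pd.Index:
        return self.table.index[self.table["call"] != 0]


def _split_classes(labels: Sequence, classes: Optional[Sequence] = None):
    labels = np.asarray(labels)
    if classes is None:
        classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    mask_a = labels == classes[0]
    mask_b = labels == classes[1]
    if not (mask_a | mask_b).all():
        raise ValueError("labels contain values outside the two classes")
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    return mask_a, mask_b, tuple(classes)


def _d_components(values: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray):
    """Per-probe (mean difference, pooled scale s) for one class assignment."""
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    mean_a = values[:, mask_a].mean(axis=1)
    mean_b = values[:, mask_b].mean(axis=1)
    ss_a = ((values[:, mask_a] - mean_a[:, None]) ** 2).sum(axis=1)
    ss_b = ((values[:, mask_b] - mean_b[:, None]) ** 2).sum(axis=1)
    a = (1.0 / na + 1.0 / nb) / (na + nb - 2)
    s = np.sqrt(a * (ss_a + ss_b))
    return mean_b - mean_a, s


def sam_statistic(
    values, labels: Sequence, s0: float = 0.0, classes: Optional[Sequence] = None
):
    """Compute per-probe (d, s, fold_change) for a two-class comparison.

    ``values`` is a probes x samples matrix of log2 ratios (DataFrame or
    ndarray).  ``d = (mean_B - mean_A)/(s + s0)`` with the Tusher pooled
    scale ``s``; ``fold_change = 2**(mean_B - mean_A)``.  With ``s0 = 0``
    and zero within-class variance, d is +/-inf when the means differ and
    0 when they coincide.
    """
    vals = np.asarray(values, dtype=float)
    mask_a, mask_b, _ = _split_classes(labels, classes)
    diff, s = _d_components(vals, mask_a, mask_b)
    denom = s + s0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(
            denom > 0, diff / np.where(denom > 0, denom, 1.0), np.sign(diff) * np.inf
        )
    d = np.where((denom == 0) & (diff == 0), 0.0, d)
    fold = 2.0 ** diff
    return d, s, fold


def estimate_s0(
    diff: np.ndarray,
    s: np.ndarray,
    method: str = "tusher_cv_minimizing",
    percentile: Optional[float] = None,
    n_windows: int = 20,
) -> float:
    """Choose the fudge factor s0 from the per-probe numerators and scales.

    The default evaluates candidate s0 values at the 0,5,...,100th
    percentiles of s and picks the candidate minimizing the coefficient of
    variation of the median absolute deviation of ``diff/(s+s0)`` computed
    within equal-count windows of s.
    """
    s = np.asarray(s, dtype=float)
    if method == "zero":
        return 0.0
    if method == "fixed_percentile":
        if percentile is None:
            raise ValueError("s0_percentile required for fixed_percentile")
        return float(np.percentile(s, 100.0 * percentile))
    if method != "tusher_cv_minimizing":
        raise ValueError(f"unknown s0 method {method!r}")

    if np.ptp(s) == 0:
        warnings.warn("degenerate scale values (all equal); s0 set to 0", stacklevel=2)
        return 0.0

    candidates = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, n_windows)
    best, best_cv = 0.0, np.inf
    for alpha in candidates:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = diff / (s + alpha)
        mads = []
        for idx in bins:
            di = d[idx]
            di = di[np.isfinite(di)]
            if di.size == 0:
                continue
            mads.append(np.median(np.abs(di - np.median(di))))
        mads = np.asarray(mads)
        if mads.size < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv - 1e-15:
            best_cv, best = cv, float(alpha)
    return best


def _permutation_masks(labels, mask_a, n_permutations, seed):
    """Class-A indicator masks for label permutations.

    Enumerate all distinct assignments when there are no more of them than
    requested permutations; otherwise sample label permutations.
    Returns (masks, exhaustive).
    """
    n = len(labels)
    na = int(mask_a.sum())
    n_distinct = math.comb(n, na)
    if n_distinct <= n_permutations:
        masks = np.zeros((n_distinct, n), dtype=bool)
        for i, pos in enumerate(itertools.combinations(range(n), na)):
            masks[i, list(pos)] = True
        return masks, True
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_permutations, n), dtype=bool)
    for i in range(n_permutations):
        masks[i, rng.permutation(n)[:na]] = True
    return masks, False


def sam_fdr(
    values,
    labels: Sequence,
    config: SamConfig,
    classes: Optional[Sequence] = None,
    s0: Optional[float] = None,
) -> SamResult:
    """Full SAM procedure: d, d-bar, delta grid, FDR and per-probe q.

    For each delta the up (down) cut point is the smallest (largest)
    observed d among probes whose sorted d exceeds its expected order
    statistic by at least delta (the "slab" rule); every probe beyond the
    cut is called, subject to the fold-change gate.  ``FDR(delta)`` is the
    median across permutations of the number of permuted d values falling
    beyond the cuts (fold-gated likewise when configured), divided by the
    number called.  ``q_i`` is the smallest FDR at which probe i is called.
    """
    if isinstance(values, pd.DataFrame):
        index = values.index
        vals = values.to_numpy(dtype=float)
    else:
        vals = np.asarray(values, dtype=float)
        index = pd.RangeIndex(vals.shape[0])
    mask_a, mask_b, classes = _split_classes(labels, classes)
    n = vals.shape[1]

    diff, s = _d_components(vals, mask_a, mask_b)
    if s0 is None:
        if config.s0_method == "fixed_percentile":
            s0 = estimate_s0(diff, s, "fixed_percentile", config.s0_percentile)
        else:
            s0 = estimate_s0(diff, s, config.s0_method)
    d, _, fold = sam_statistic(vals, labels, s0=s0, classes=classes)
    log_fold_min = np.log2(config.fold_change_min)
    gate_obs = np.abs(np.log2(fold)) >= log_fold_min - 1e-12

    masks, exhaustive = _permutation_masks(labels, mask_a, config.n_permutations, config.seed)
    n_perm = masks.shape[0]
    na = int(mask_a.sum())

    # vectorized permuted d*: means/SS via mask matrix products
    M = masks.astype(float)  # n_perm x n
    Mc = 1.0 - M
    nb = n - na
    sum_a = vals @ M.T  # probes x n_perm
    sum_b = vals @ Mc.T
    mean_a = sum_a / na
    mean_b = sum_b / nb
    sq = vals ** 2
    ss_a = sq @ M.T - na * mean_a ** 2
    ss_b = sq @ Mc.T - nb * mean_b ** 2
    a = (1.0 / na + 1.0 / nb) / (na + nb - 2)
    s_perm = np.sqrt(np.clip(a * (ss_a + ss_b), 0.0, None))
    diff_perm = mean_b - mean_a
    with np.errstate(divide="ignore", invalid="ignore"):
        d_perm = diff_perm / (s_perm + s0)
    d_perm = np.nan_to_num(d_perm, nan=0.0, posinf=np.inf, neginf=-np.inf)
    gate_perm = (
        np.abs(diff_perm) >= log_fold_min - 1e-12
        if config.fold_gate_permutations
        else np.ones_like(d_perm, dtype=bool)
    )

    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    dbar = np.sort(d_perm, axis=0).mean(axis=1)  # ascending expected order stats

    resid = d_sorted - dbar
    # the slab scan starts at the origin and moves outward on each side
    mid = int(np.searchsorted(dbar, 0.0))
    upper_half = np.arange(len(d_sorted)) >= mid
    deltas = np.unique(np.abs(resid))
    deltas = deltas[deltas > 0]
    if deltas.size > 100:
        deltas = np.unique(np.quantile(deltas, np.linspace(0, 1, 100)))

    if config.pi0_correction:
        q25, q75 = np.percentile(d_perm, [25, 75])
        pi0 = min(1.0, np.mean((d > q25) & (d < q75)) / 0.5)
    else:
        pi0 = 1.0

    rows = []
    called_at = np.zeros((vals.shape[0], deltas.size), dtype=bool)
    sign_at = np.zeros(vals.shape[0], dtype=int)
    for j, delta in enumerate(deltas):
        up = (resid >= delta) & upper_half
        down = (resid <= -delta) & ~upper_half
        cut_up = d_sorted[up].min() if up.any() else np.inf
        cut_down = d_sorted[down].max() if down.any() else -np.inf
        if config.symmetric_delta:
            # one symmetric cut in d instead of separate up/down slabs
            c = min(cut_up, -cut_down)
            cut_up, cut_down = c, -c
        call_up = (d >= cut_up) & gate_obs
        call_down = (d <= cut_down) & gate_obs
        called = call_up | call_down
        n_called = int(called.sum())
        fp = ((d_perm >= cut_up) | (d_perm <= cut_down)) & gate_perm
        median_fp = float(np.median(fp.sum(axis=0)))
        fdr = 0.0 if n_called == 0 else min(1.0, pi0 * median_fp / n_called)
        rows.append((delta, n_called, median_fp, fdr))
        called_at[:, j] = called
        sign_at[call_up] = 1
        sign_at[call_down] = -1

    delta_table = pd.DataFrame(
        rows, columns=["delta", "n_called", "median_false_positives", "fdr"]
    )

    q = np.ones(vals.shape[0])
    for j in range(deltas.size):
        fdr_j = delta_table["fdr"].iloc[j]
        idx = called_at[:, j]
        q[idx] = np.minimum(q[idx], fdr_j)

    ok = delta_table[(delta_table["fdr"] <= config.fdr_max) & (delta_table["n_called"] > 0)]
    if len(ok):
        jstar = int(ok.index[0])
        delta_star = float(deltas[jstar])
        call = np.where(called_at[:, jstar], sign_at, 0)
    else:
        delta_star = float("nan")
        call = np.zeros(vals.shape[0], dtype=int)

    table = pd.DataFrame(
        {"d": d, "s": s, "fold_change": fold, "q": q, "call": call}, index=index
    )
    return SamResult(
        table=table,
        s0=float(s0),
        delta=delta_star,
        dbar=dbar,
        delta_table=delta_table,
        n_permutations_used=n_perm,
        exhaustive=exhaustive,
    )


def sam_analyze(
    values, labels: Sequence, config: Optional[SamConfig] = None,
    classes: Optional[Sequence] = None,
) -> SamResult:
    """Run the full SAM comparison with default or supplied settings."""
    return sam_fdr(values, labels, config or SamConfig(), classes=classes)


def pairwise_union(selected: Mapping[str, Iterable]):
    """Union of the probes called in the pairwise comparisons + Venn counts.

    Parameters
    ----------
    selected : mapping comparison-name -> iterable of probe ids
        Typically the three pairwise phenotype comparisons.

    Returns
    -------
    (union, venn_counts) where ``venn_counts`` maps each nonempty
    combination of comparison names (as a sorted tuple) to the number of
    probes belonging to exactly those comparisons.
    """
    names = list(selected)
    sets = {k: set(v) for k, v in selected.items()}
    union = set().union(*sets.values()) if sets else set()
    venn: dict[tuple, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo)) if combo else set()
            outside = set().union(*(sets[c] for c in names if c not in combo), set())
            venn[tuple(combo)] = len(inside - outside)
    return union, venn
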