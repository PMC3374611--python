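"""Permutational MANCOVA with sequential SS and forward stepwise selection.

The response is a samples x q real matrix (here: CLR-transformed
six-category compositions).  Variation is partitioned by sequential
(Type I) sums of squares of the trace of the residual cross-product
matrix: for term t entering after terms 1..t-1,

    SS_t   = tr(Y' (H_t - H_{t-1}) Y),        H_t the hat matrix of the
                                              design including terms <= t,
    pseudo-F_t = (SS_t / df_t) / (SS_res / df_res),

with SS_res from the full entered model.  For Euclidean geometry this
trace form coincides with the pairwise-distance form of permutational
MANOVA, and for a univariate response it reduces to the classical ANOVA F.
Significance is assessed by permutation: either raw permutation of the
response rows, or Freedman-Lane permutation of the residuals of the
reduced model (terms before t), the default, which keeps the test exact
in the presence of covariates.

Forward stepwise selection repeatedly offers each remaining candidate as
the last term of the current model, enters the candidate with the
smallest permutation P (ties: larger F, then name), and stops when no
candidate reaches the entry threshold.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

SCHEMES = ("raw", "freedman_lane")

_F_TOL = 1e-9


class AliasedTermError(ValueError):
    """A term's design columns add no rank to the model."""


@dataclass
class DesignVariable:
    """One model term: a continuous covariate or a categorical factor.

    Categorical terms are dummy-coded against their first (sorted) level
    and contribute levels-1 degrees of freedom pooled into a single term.
    """

    name: str
    kind: str  # "continuous" | "categorical"
    values: pd.Series

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values)
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown kind {self.kind!r} for {self.name!r}")
        if self.values.isna().any():
            raise ValueError(f"missing values in design variable {self.name!r}")
        if self.kind == "categorical" and self.values.nunique() < 2:
            raise ValueError(f"categorical {self.name!r} has fewer than 2 levels")

    @property
    def df(self) -> int:
        if self.kind == "continuous":
            return 1
        return int(self.values.nunique()) - 1

    def design_columns(self) -> np.ndarray:
        """n x df design block (dummy coding, first level as reference)."""
        if self.kind == "continuous":
            return np.asarray(self.values, dtype=float).reshape(-1, 1)
        levels = sorted(self.values.unique())
        cols = [
            (self.values.to_numpy() == lev).astype(float) for lev in levels[1:]
        ]
        return np.column_stack(cols)

    @staticmethod
    def from_series(name: str, s: pd.Series, max_levels: int = 10) -> "DesignVariable":
        """Infer kind: numeric with many distinct values -> continuous."""
        if pd.api.types.is_numeric_dtype(s) and s.nunique() > max_levels:
            return DesignVariable(name, "continuous", s.astype(float))
        return DesignVariable(name, "categorical", s.astype(str))


@dataclass
class MancovaResult:
    """Sequential MANCOVA table plus residual/total bookkeeping."""

    table: pd.DataFrame  # index: term; columns: df, ss, r2, pseudo_f, p
    residual_df: int
    residual_ss: float
    total_ss: float
    n_perm: int
    scheme: str


@dataclass
class StepwiseTrace:
    """Entry-order record of a forward stepwise selection run."""

    entries: pd.DataFrame  # step, term, df, pseudo_f, p, cumulative_r2, forced
    candidates: list
    alpha_enter: float
    n_perm: int
    seed: Optional[int]

    @property
    def selected(self) -> list:
        return list(self.entries["term"])


def _orthobasis(x: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of the column space of x (via SVD)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    rank = int((s > tol * max(x.shape) * (s[0] if s.size else 1.0)).sum())
    return u[:, :rank]


def _quad_traces(ystar: np.ndarray, a: np.ndarray) -> np.ndarray:
    """tr(Y*' A Y*) for a stack of responses ystar (B, n, q)."""
    ay = np.einsum("ij,bjk->bik", a, ystar, optimize=True)
    return np.einsum("bik,bik->b", ay, ystar, optimize=True)


def permutation_indices(
    n: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n) array of sampled row permutations."""
    return np.array([rng.permutation(n) for _ in range(n_perm)])


def permuted_responses(
    y: np.ndarray,
    perms: np.ndarray,
    scheme: str = "freedman_lane",
    h_reduced: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Stack of permuted responses under the chosen scheme.

    raw: rows of y permuted wholesale.  freedman_lane: residuals of the
    reduced-model fit permuted and added back onto its fitted values.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    if scheme == "raw":
        return y[perms]
    if h_reduced is None:
        raise ValueError("freedman_lane requires the reduced-model hat matrix")
    fitted = h_reduced @ y
    resid = y - fitted
    return fitted[None, :, :] + resid[perms]


def _as_matrix(y) -> tuple[np.ndarray, pd.Index]:
    if isinstance(y, pd.DataFrame):
        return y.to_numpy(dtype=float), y.index
    arr = np.asarray(y, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    return arr, pd.RangeIndex(arr.shape[0])


def _exhaustive_perms(n: int, limit: int = 9) -> np.ndarray:
    if n > limit:
        raise ValueError(
            f"exhaustive enumeration limited to n <= {limit} samples ({n} given)"
        )
    return np.array(list(itertools.permutations(range(n))))


def sequential_mancova(
    y,
    terms: Sequence[DesignVariable],
    n_perm: int = 999,
    seed: Optional[int] = None,
    scheme: str = "freedman_lane",
    exhaustive: bool = False,
) -> MancovaResult:
    """Sequential-SS permutational MANCOVA of y on an ordered term list.

    With ``exhaustive=True`` all n! row permutations are enumerated
    (small n only) and P = #{F* >= F}/n! including the identity;
    otherwise P = (1 + #{F* >= F})/(1 + n_perm), never zero.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    yv, index = _as_matrix(y)
    n = yv.shape[0]
    if not terms:
        raise ValueError("no terms supplied")
    for t in terms:
        if len(t.values) != n:
            raise ValueError(f"term {t.name!r} length differs from response")

    total_df = sum(t.df for t in terms)
    if n <= total_df + 1:
        raise ValueError(
            f"{n} samples cannot support {total_df} model df plus intercept"
        )

    # cumulative designs and hat matrices
    x = np.ones((n, 1))
    bases = [_orthobasis(x)]
    ranks = [1]
    for t in terms:
        x = np.column_stack([x, t.design_columns()])
        b = _orthobasis(x)
        if b.shape[1] - ranks[-1] < t.df:
            raise AliasedTermError(
                f"term {t.name!r} is aliased with preceding terms "
                f"(adds rank {b.shape[1] - ranks[-1]}, df {t.df})"
            )
        bases.append(b)
        ranks.append(b.shape[1])
    hats = [b @ b.T for b in bases]

    yc = yv - yv.mean(axis=0)
    total_ss = float((yc ** 2).sum())
    h_full = hats[-1]
    resid_full = yv - h_full @ yv
    residual_ss = float((resid_full ** 2).sum())
    residual_df = n - ranks[-1]
    if residual_df <= 0:
        raise ValueError("saturated model: no residual degrees of freedom")

    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2 ** 31))

    rows = []
    for t_idx, t in enumerate(terms):
        h_red, h_t = hats[t_idx], hats[t_idx + 1]
        m_num = h_t - h_red
        ss_t = float(np.einsum("ik,ij,jk->", yv, m_num, yv))
        f_obs = (ss_t / t.df) / (residual_ss / residual_df)

        if exhaustive:
            perms = _exhaustive_perms(n)
        else:
            rng = np.random.default_rng([seed, t_idx])
            perms = permutation_indices(n, n_perm, rng)
        ystar = permuted_responses(yv, perms, scheme=scheme, h_reduced=h_red)
        num = _quad_traces(ystar, m_num) / t.df
        den = (
            _quad_traces(ystar, np.eye(n) - h_full)
        ) / residual_df
        with np.errstate(divide="ignore", invalid="ignore"):
            f_star = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
        hits = int((f_star >= f_obs - _F_TOL * max(1.0, abs(f_obs))).sum())
        if exhaustive:
            p = hits / perms.shape[0]
        else:
            p = (1 + hits) / (1 + perms.shape[0])

        rows.append(
            {
                "term": t.name,
                "df": t.df,
                "ss": ss_t,
                "r2": ss_t / total_ss if total_ss > 0 else 0.0,
                "pseudo_f": f_obs,
                "p": p,
            }
        )

    table = pd.DataFrame(rows).set_index("term")
    return MancovaResult(
        table=table,
        residual_df=residual_df,
        residual_ss=residual_ss,
        total_ss=total_ss,
        n_perm=n_perm,
        scheme=scheme,
    )


def _conditional_tests(
    yv: np.ndarray,
    entered: Sequence[DesignVariable],
    candidates: Sequence[DesignVariable],
    n_perm: int,
    rng_seed: Sequence[int],
    scheme: str,
) -> pd.DataFrame:
    """Permutation test of each candidate appended last to the entered model.

    All candidates in one round share the same permutations (and, under
    Freedman-Lane, the same reduced model), so their P values are directly
    comparable.  Aliased candidates get F=0, P=1.
    """
    n, q = yv.shape
    x_red = np.ones((n, 1))
    for t in entered:
        x_red = np.column_stack([x_red, t.design_columns()])
    b_red = _orthobasis(x_red)
    rank_red = b_red.shape[1]
    h_red = b_red @ b_red.T

    rng = np.random.default_rng(list(rng_seed))
    perms = permutation_indices(n, n_perm, rng)
    ystar = permuted_responses(yv, perms, scheme=scheme, h_reduced=h_red)
    tr_red_star = _quad_traces(ystar, h_red)
    tr_tot_star = np.einsum("bik,bik->b", ystar, ystar, optimize=True)
    tr_red = float(np.einsum("ik,ij,jk->", yv, h_red, yv))
    tr_tot = float((yv ** 2).sum())

    rows = []
    for c in candidates:
        x_full = np.column_stack([x_red, c.design_columns()])
        b_full = _orthobasis(x_full)
        added = b_full.shape[1] - rank_red
        df_res = n - b_full.shape[1]
        if added < c.df or df_res <= 0:
            rows.append({"term": c.name, "df": c.df, "pseudo_f": 0.0, "p": 1.0, "ss": 0.0})
            continue
        h_full = b_full @ b_full.T
        tr_full = float(np.einsum("ik,ij,jk->", yv, h_full, yv))
        ss_c = tr_full - tr_red
        ss_res = tr_tot - tr_full
        f_obs = (ss_c / c.df) / (ss_res / df_res)

        tr_full_star = _quad_traces(ystar, h_full)
        num = (tr_full_star - tr_red_star) / c.df
        den = (tr_tot_star - tr_full_star) / df_res
        with np.errstate(divide="ignore", invalid="ignore"):
            f_star = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.inf)
        hits = int((f_star >= f_obs - _F_TOL * max(1.0, abs(f_obs))).sum())
        p = (1 + hits) / (1 + n_perm)
        rows.append({"term": c.name, "df": c.df, "pseudo_f": f_obs, "p": p, "ss": ss_c})
    return pd.DataFrame(rows)


def stepwise_select(
    y,
    candidates: Sequence[DesignVariable],
    alpha_enter: float = 0.05,
    n_perm: int = 999,
    seed: Optional[int] = None,
    scheme: str = "freedman_lane",
    forced_first: Optional[Sequence[str]] = None,
    max_steps: Optional[int] = None,
    backward: bool = False,
) -> tuple[StepwiseTrace, Optional[MancovaResult]]:
    """Forward stepwise permutational MANCOVA variable selection.

    Parameters
    ----------
    candidates : sequence of DesignVariable
        The candidate pool (e.g. gene-cluster centroids plus clinical and
        genotype covariates).
    forced_first : optional sequence of candidate names
        Entered unconditionally, in order, before free selection; their
        entry P is still computed and recorded.
    max_steps : optional int
        Cap on freely-selected entries (forced entries not counted).
    backward : bool
        After forward selection, repeatedly drop the entered term with the
        largest conditional-last P above ``alpha_enter`` and re-check.

    Returns
    -------
    (StepwiseTrace, MancovaResult or None)
        The final model re-reported in entry order, or None when nothing
        entered.
    """
    if not candidates:
        raise ValueError("candidate pool is empty")
    yv, _ = _as_matrix(y)
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2 ** 31))
    by_name = {c.name: c for c in candidates}
    if len(by_name) != len(candidates):
        raise ValueError("duplicate candidate names")

    forced = list(forced_first or [])
    for f in forced:
        if f not in by_name:
            raise ValueError(f"forced_first variable {f!r} not among candidates")

    yc = yv - yv.mean(axis=0)
    total_ss = float((yc ** 2).sum())

    entered: list[DesignVariable] = []
    entry_rows = []
    remaining = [c for c in candidates]
    step = 0

    def model_r2(model: Sequence[DesignVariable]) -> float:
        x = np.ones((yv.shape[0], 1))
        for t in model:
            x = np.column_stack([x, t.design_columns()])
        b = _orthobasis(x)
        fitted = b @ (b.T @ yv)
        ss_model = float(((fitted - yv.mean(axis=0)) ** 2).sum())
        return ss_model / total_ss if total_ss > 0 else 0.0

    # forced entries
    for f in forced:
        c = by_name[f]
        tests = _conditional_tests(yv, entered, [c], n_perm, [seed, step, 0], scheme)
        row = tests.iloc[0]
        entered.append(c)
        remaining = [r for r in remaining if r.name != f]
        entry_rows.append(
            {
                "step": step,
                "term": c.name,
                "df": c.df,
                "pseudo_f": float(row["pseudo_f"]),
                "p": float(row["p"]),
                "cumulative_r2": model_r2(entered),
                "forced": True,
            }
        )
        step += 1

    n_free = 0
    while remaining:
        if max_steps is not None and n_free >= max_steps:
            break
        tests = _conditional_tests(
            yv, entered, remaining, n_perm, [seed, step, 0], scheme
        )
        tests = tests.sort_values(
            by=["p", "pseudo_f", "term"], ascending=[True, False, True],
            kind="stable",
        )
        best = tests.iloc[0]
        if best["p"] > alpha_enter:
            break
        c = by_name[best["term"]]
        entered.append(c)
        remaining = [r for r in remaining if r.name != c.name]
        entry_rows.append(
            {
                "step": step,
                "term": c.name,
                "df": c.df,
                "pseudo_f": float(best["pseudo_f"]),
                "p": float(best["p"]),
                "cumulative_r2": model_r2(entered),
                "forced": False,
            }
        )
        step += 1
        n_free += 1

        if backward and len(entered) > 1:
            changed = True
            while changed and len(entered) > 1:
                changed = False
                worst_name, worst_p = None, alpha_enter
                for t in entered:
                    if t.name in forced:
                        continue
                    others = [e for e in entered if e.name != t.name]
                    tt = _conditional_tests(
                        yv, others, [t], n_perm, [seed, step, 1], scheme
                    )
                    pt = float(tt.iloc[0]["p"])
                    if pt > worst_p:
                        worst_name, worst_p = t.name, pt
                if worst_name is not None:
                    entered = [e for e in entered if e.name != worst_name]
                    remaining.append(by_name[worst_name])
                    changed = True

    trace = StepwiseTrace(
        entries=pd.DataFrame(
            entry_rows,
            columns=["step", "term", "df", "pseudo_f", "p", "cumulative_r2", "forced"],
        ),
        candidates=[c.name for c in candidates],
        alpha_enter=alpha_enter,
        n_perm=n_perm,
        seed=seed,
    )
    if not entered:
        return trace, None
    final = sequential_mancova(
        y, entered, n_perm=n_perm, seed=seed + 1, scheme=scheme
    )
    return trace, final
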