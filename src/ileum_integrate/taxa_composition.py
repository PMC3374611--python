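"""Phylum/subphylum binning of genus counts and the centered log-ratio transform.

Genus-level 16S counts are collapsed into seven broad phyla/subphyla
categories.  The first six form the compositional response vector of the
downstream multivariate analysis; the seventh ("Other") absorbs everything
else and is excluded from the response.  The CLR transform maps the
six-part composition from the simplex onto the zero-sum hyperplane, where
Euclidean geometry (and hence cross-product sums of squares) is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

#: Fixed category order used by every table in the package.
CATEGORIES = (
    "Actinobacteria",
    "Bacteroidetes",
    "Firmicutes.ClostridiumIV",
    "Firmicutes.ClostridiumXIVa",
    "Firmicutes.Bacilli",
    "Proteobacteria",
    "Other",
)

#: The six categories forming the MANCOVA response ("Other" excluded).
RESPONSE_CATEGORIES = CATEGORIES[:6]


@dataclass
class CompositionTable:
    """Per-sample category counts and relative frequencies.

    Attributes
    ----------
    counts : pandas.DataFrame
        samples x 7 integer (or real, after pseudocounting) category counts,
        columns in :data:`CATEGORIES` order.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(columns=list(CATEGORIES))

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def frequencies(self) -> pd.DataFrame:
        """Row-closed relative frequencies over all seven categories."""
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)

    def response_counts(self) -> pd.DataFrame:
        """Counts over the six response categories (Other dropped)."""
        return self.counts[list(RESPONSE_CATEGORIES)]


def bin_to_categories(
    genus_counts: pd.DataFrame, taxonomy: Mapping[str, str]
) -> CompositionTable:
    """Collapse a genus x sample count table into the seven categories.

    Parameters
    ----------
    genus_counts : pandas.DataFrame
        Genera as rows, samples as columns, nonnegative counts.
    taxonomy : mapping genus -> category
        Category names must be members of :data:`CATEGORIES`.  Genera
        missing from the map are routed to "Other" with a warning.

    Returns
    -------
    CompositionTable

    Raises
    ------
    ValueError
        If a mapped category is unknown, or any sample has zero total reads.
    """
    unmapped = [g for g in genus_counts.index if g not in taxonomy]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} genera missing from the taxonomy map routed to "
            f"'Other': {', '.join(map(str, unmapped[:10]))}",
            stacklevel=2,
        )
    cats = []
    for g in genus_counts.index:
        c = taxonomy.get(g, "Other")
        if c not in CATEGORIES:
            raise ValueError(f"unknown category {c!r} for genus {g!r}")
        cats.append(c)

    grouped = genus_counts.groupby(pd.Index(cats, name="category")).sum()
    counts = grouped.T.reindex(columns=list(CATEGORIES), fill_value=0).fillna(0)
    totals = counts.sum(axis=1)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValueError(
            f"samples with zero total reads: {', '.join(map(str, empty.index))}"
        )
    return CompositionTable(counts=counts)


def clr_transform(
    composition: CompositionTable | pd.DataFrame,
    pseudocount_mode: str = "add_half_read",
) -> pd.DataFrame:
    """Centered log-ratio transform of the six-category response vector.

    clr_c = ln(p_c) - mean_c ln(p_c), taken over the six response
    categories only.  The result is invariant to rescaling of each row
    (closure invariance), so whether or not the six frequencies are
    renormalized after dropping "Other" is immaterial.

    Parameters
    ----------
    composition :
        A :class:`CompositionTable`, or a samples x 6 (or x 7, "Other"
        dropped) DataFrame of counts or frequencies.
    pseudocount_mode : {"add_half_read", "add_min_nonzero_fraction", "none"}
        Zero-replacement policy.  ``add_half_read`` adds 0.5 (reads) to
        every category entry before closing; ``add_min_nonzero_fraction``
        adds half the smallest nonzero entry of the table; ``none`` raises
        on zeros.

    Returns
    -------
    pandas.DataFrame
        samples x 6 CLR coordinates; each row sums to zero.
    """
    if isinstance(composition, CompositionTable):
        x = composition.response_counts()
    else:
        x = composition.reindex(columns=list(RESPONSE_CATEGORIES))
        if x.isna().any().any():
            raise ValueError(
                "input must contain the six response categories: "
                + ", ".join(RESPONSE_CATEGORIES)
            )
    vals = x.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative entries in composition")

    if pseudocount_mode == "add_half_read":
        vals = vals + 0.5
    elif pseudocount_mode == "add_min_nonzero_fraction":
        nz = vals[vals > 0]
        if nz.size == 0:
            raise ValueError("all-zero composition table")
        vals = vals + 0.5 * nz.min()
    elif pseudocount_mode == "none":
        if (vals == 0).any():
            raise ValueError(
                "zero frequencies present; choose a pseudocount_mode other "
                "than 'none'"
            )
    else:
        raise ValueError(f"unknown pseudocount_mode {pseudocount_mode!r}")

    logx = np.log(vals)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=x.index, columns=list(RESPONSE_CATEGORIES))


def clr_inverse(clr: pd.DataFrame) -> pd.DataFrame:
    """Map CLR coordinates back to the closed composition (softmax rows)."""
    z = np.exp(clr.to_numpy(dtype=float))
    z /= z.sum(axis=1, keepdims=True)
    return pd.DataFrame(z, index=clr.index, columns=clr.columns)
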