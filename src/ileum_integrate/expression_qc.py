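"""Expression-matrix quality control.

Two light-weight pre-processing steps applied to a normalized log2
test/reference ratio matrix: removal of probes absent on every array
(by scanner quality flag), and averaging of technical replicate arrays.
Normalization itself is expected to have been done upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 ratio matrix with optional quality flags.

    ``values`` and ``flags`` (when present) share index and columns.
    """

    values: pd.DataFrame
    flags: Optional[pd.DataFrame] = field(default=None)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicated probe ids: {', '.join(map(str, dups[:5]))}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicated sample ids: {', '.join(map(str, dups[:5]))}")
        if self.flags is not None:
            if not self.flags.index.equals(self.values.index) or not self.flags.columns.equals(
                self.values.columns
            ):
                raise ValueError("flags matrix shape/labels differ from values")

    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)


def filter_absent_probes(m: ExpressionMatrix, threshold: int = -50) -> ExpressionMatrix:
    """Drop probes whose quality flags are below ``threshold`` on every array.

    A probe is treated as absent — and removed — only when *all* of its
    per-array flags are strictly less than the threshold; a single array
    flagging it at or above the threshold retains it.  Probe order is
    preserved.  Idempotent.
    """
    if m.flags is None:
        raise ValueError(
            "no flag matrix attached; skip the absent-probe filter for "
            "flag-free inputs"
        )
    keep = (m.flags >= threshold).any(axis=1)
    return ExpressionMatrix(values=m.values.loc[keep], flags=m.flags.loc[keep])


def average_technical_duplicates(
    m: ExpressionMatrix, duplicate_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Average technical replicate arrays into one column per sample.

    Parameters
    ----------
    duplicate_map : mapping array-id -> replicate-group id
        Arrays absent from the map form singleton groups under their own
        id.  Output columns are ordered by first appearance of each group.
        Missing values propagate as the mean of the non-missing replicates.
    """
    unknown = [s for s in duplicate_map if s not in m.values.columns]
    if unknown:
        raise ValueError(
            f"duplicate_map references unknown samples: {', '.join(map(str, unknown))}"
        )
    groups: dict[str, list[str]] = {}
    for s in m.values.columns:
        g = duplicate_map.get(s, s)
        groups.setdefault(g, []).append(s)

    out = {}
    for g, members in groups.items():
        out[g] = m.values[members].mean(axis=1, skipna=True)
    values = pd.DataFrame(out)

    flags = None
    if m.flags is not None:
        # keep the most-present (largest) flag across replicates
        flags = pd.DataFrame(
            {g: m.flags[members].max(axis=1) for g, members in groups.items()}
        )
    return ExpressionMatrix(values=values, flags=flags)
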