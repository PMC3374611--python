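"""Readers and writers for the tab-separated analysis inputs.

All tables are UTF-8 tab-separated text with a header row and a row
identifier in the first column.  Numeric tables are parsed strictly:
non-numeric cells and duplicated identifiers raise descriptive errors
with the offending label and (1-based) line number.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd

from .expression_qc import ExpressionMatrix

logger = logging.getLogger("ileum_integrate")


class TableParseError(ValueError):
    pass


def _check_unique(index: pd.Index, what: str, path) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()].unique()
        positions = [int(index.get_indexer_for([d])[0]) + 2 for d in dup[:5]]
        raise TableParseError(
            f"{path}: duplicated {what}: "
            + ", ".join(f"{d!r} (line {ln})" for d, ln in zip(dup[:5], positions))
        )


def read_numeric_table(path) -> pd.DataFrame:
    """Strictly numeric table: id column first, numeric cells elsewhere."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "row identifiers", path)
    _check_unique(df.columns, "column identifiers", path)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = next(zip(*bad.to_numpy().nonzero()))
        raise TableParseError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r} "
            f"(line {r + 2}), column {df.columns[c]!r}"
        )
    return numeric


def read_expression(path, flags_path=None) -> ExpressionMatrix:
    """Probe x sample log2-ratio matrix, with optional companion flag table."""
    values = read_numeric_table(path)
    flags = None
    if flags_path is not None:
        flags = read_numeric_table(flags_path).astype(int)
        flags = flags.reindex(index=values.index, columns=values.columns)
        if flags.isna().any().any():
            raise TableParseError(
                f"{flags_path}: flag matrix does not cover the expression matrix"
            )
    return ExpressionMatrix(values=values, flags=flags)


def read_counts(path) -> pd.DataFrame:
    """Genus x sample count table (nonnegative integers)."""
    df = read_numeric_table(path)
    if (df.to_numpy() < 0).any():
        raise TableParseError(f"{path}: negative counts present")
    return df.round().astype(int)


def read_taxonomy(path) -> pd.Series:
    """Two-column genus -> category map."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise TableParseError(f"{path}: expected a genus and a category column")
    _check_unique(df.index, "genus identifiers", path)
    return df.iloc[:, 0].astype(str)


def read_metadata(path) -> pd.DataFrame:
    """Per-sample covariate table (mixed types allowed)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    _check_unique(df.index, "sample identifiers", path)
    return df


def align_samples(
    expression: ExpressionMatrix,
    taxa_counts: pd.DataFrame,
    metadata: pd.DataFrame,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Restrict all three tables to their shared samples, logging exclusions.

    Mirrors the analysis-set construction of paired designs: only samples
    present in expression, microbiome and metadata enter the analysis.
    """
    shared = (
        pd.Index(expression.sample_ids)
        .intersection(taxa_counts.columns)
        .intersection(metadata.index)
    )
    if len(shared) == 0:
        raise ValueError("no samples shared across the three inputs")
    for name, ids in (
        ("expression", pd.Index(expression.sample_ids)),
        ("taxa_counts", pd.Index(taxa_counts.columns)),
        ("metadata", metadata.index),
    ):
        dropped = ids.difference(shared)
        if len(dropped):
            logger.warning(
                "%s: %d samples outside the analysis set: %s",
                name,
                len(dropped),
                ", ".join(map(str, dropped[:10])),
            )
    expr = ExpressionMatrix(
        values=expression.values[shared],
        flags=None if expression.flags is None else expression.flags[shared],
    )
    return expr, taxa_counts[shared], metadata.loc[shared]


def write_table(df: pd.DataFrame, path, index_label: Optional[str] = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label)
    return path
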