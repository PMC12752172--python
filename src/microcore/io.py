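"""TSV / Newick / JSON readers and writers for the pipeline's data types.

All tabular formats are tab-delimited UTF-8 with '.' as the decimal mark.
Count tables are written with OTU rows and sample columns; distance
matrices as square tables with matching header row and index column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .containers import (
    CONTINUOUS_COVARIATES,
    DEFAULT_CATEGORICAL_LEVELS,
    RANKS,
    CountTable,
    Phylogeny,
    SampleMetadata,
    TaxonomyTable,
)

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_distance_matrix",
    "write_distance_matrix",
]


def read_count_table(path: str | Path) -> CountTable:
    """Read an OTU x sample count table from TSV.

    The first column holds OTU identifiers; the header row holds sample
    identifiers.  Cells must be non-negative integers; non-numeric or
    fractional cells are rejected with the offending row/column named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate OTU identifier: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate sample identifier: {dup!r}")
    mat = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        try:
            vals = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric cell in sample column {col!r}: {exc}") from None
        arr = vals.to_numpy()
        if np.any(arr != np.floor(arr)):
            i = int(np.argmax(arr != np.floor(arr)))
            raise ValueError(
                f"non-integer count at OTU {df.index[i]!r}, sample {col!r}: {arr[i]}"
            )
        if np.any(arr < 0):
            i = int(np.argmax(arr < 0))
            raise ValueError(f"negative count at OTU {df.index[i]!r}, sample {col!r}")
        mat[:, j] = arr.astype(np.int64)
    return CountTable(mat, list(df.index), list(df.columns))


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_frame().rename_axis("otu_id").to_csv(path, sep="\t")


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read per-OTU lineages from TSV (columns: otu_id + ranks domain..genus)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path: str | Path) -> None:
    tax.lineages.rename_axis("otu_id").to_csv(path, sep="\t")


def read_metadata(
    path: str | Path,
    levels: dict[str, tuple[str, ...]] | None = None,
) -> SampleMetadata:
    """Read sample metadata from TSV keyed by sample identifier.

    ``levels`` declares categorical level sets (first entry = reference
    level); unknown levels in the file raise.  Defaults cover the
    amendment and texture factors; continuous soil-chemistry columns are
    parsed as floats.
    """
    # keep_default_na: "None" is a genuine amendment level, not missing data
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if levels is None:
        levels = {k: v for k, v in DEFAULT_CATEGORICAL_LEVELS.items() if k in df.columns}
    for col in df.columns:
        if col in CONTINUOUS_COVARIATES or col.startswith("z_"):
            df[col] = pd.to_numeric(df[col], errors="raise")
    return SampleMetadata(df, dict(levels))


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.rename_axis("sample_id").to_csv(path, sep="\t")


def read_tree(path: str | Path) -> Phylogeny:
    """Read a rooted Newick tree with branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    return Phylogeny(tree)


def write_tree(phy: Phylogeny, path: str | Path) -> None:
    phy.tree.write(str(path), format="newick")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=list(df.index))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_data_frame().to_csv(path, sep="\t")
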