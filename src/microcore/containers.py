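"""Core data containers: count table, taxonomy, sample metadata, phylogeny.

Conventions
-----------
* Count tables are OTUs x samples, matching the on-disk orientation
  (OTU rows, sample columns).  Indexing contracts are always
  ``(otu, sample)``.
* Distance matrices are :class:`skbio.DistanceMatrix` instances keyed by
  sample identifiers.
* Phylogenies wrap a rooted :class:`skbio.TreeNode` with branch lengths;
  the patristic (tip-to-tip) distance matrix is computed lazily and cached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "CountTable",
    "TaxonomyTable",
    "SampleMetadata",
    "Phylogeny",
    "RANKS",
    "DEFAULT_CATEGORICAL_LEVELS",
    "CONTINUOUS_COVARIATES",
]

#: Taxonomic ranks, coarsest to finest.  Empty string = unassigned at a rank.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: Declared level sets for the categorical covariates of the study design.
#: First element of each tuple list is the reference level.
DEFAULT_CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "amendment": ("None", "FYM", "Digestate", "Slurry"),
    "texture": ("sandy_loam", "sandy_silt_loam", "silty_clay_loam", "clay_loam"),
}

#: Continuous soil-chemistry covariates carried by sample metadata.
CONTINUOUS_COVARIATES = ("pH", "P", "K", "Mg", "Ca", "Na", "LOI")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


class CountTable:
    """Integer OTU x sample abundance matrix with aligned identifiers.

    Parameters
    ----------
    counts
        Non-negative integer matrix of shape ``(n_otus, n_samples)``.
    otu_ids, sample_ids
        Unique identifier sequences matching the matrix dimensions.
    """

    def __init__(self, counts, otu_ids: Sequence[str], sample_ids: Sequence[str]):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix (OTUs x samples)")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            i, j = np.argwhere(counts < 0)[0]
            raise ValueError(f"negative count at OTU {otu_ids[i]!r}, sample {sample_ids[j]!r}")
        otu_ids = [str(x) for x in otu_ids]
        sample_ids = [str(x) for x in sample_ids]
        _check_unique(otu_ids, "OTU")
        _check_unique(sample_ids, "sample")
        if counts.shape != (len(otu_ids), len(sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(otu_ids)} OTUs x {len(sample_ids)} samples"
            )
        self.counts = counts.astype(np.int64)
        self.otu_ids = list(otu_ids)
        self.sample_ids = list(sample_ids)

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Per-sample read totals (column sums)."""
        return pd.Series(self.counts.sum(axis=0), index=self.sample_ids, name="library_size")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.otu_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def relative_abundances(self) -> np.ndarray:
        """Per-sample proportions (TSS).  Columns sum to 1."""
        sizes = self.counts.sum(axis=0)
        if np.any(sizes == 0):
            j = int(np.argmin(sizes))
            raise ValueError(f"sample {self.sample_ids[j]!r} has zero total count")
        return self.counts / sizes

    def select_otus(self, otus: Iterable[str]) -> "CountTable":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        keep = [idx[o] for o in otus]
        return CountTable(self.counts[keep], [self.otu_ids[i] for i in keep], self.sample_ids)

    def select_samples(self, samples: Iterable[str]) -> "CountTable":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        keep = [idx[s] for s in samples]
        return CountTable(self.counts[:, keep], self.otu_ids, [self.sample_ids[j] for j in keep])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CountTable)
            and self.otu_ids == other.otu_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"CountTable({self.n_otus} OTUs x {self.n_samples} samples)"


class TaxonomyTable:
    """Per-OTU ranked lineages (domain..genus); empty string = unassigned."""

    def __init__(self, lineages: pd.DataFrame):
        missing = [r for r in RANKS if r not in lineages.columns]
        if missing:
            raise ValueError(f"taxonomy missing rank columns: {missing}")
        _check_unique(list(lineages.index), "taxonomy OTU")
        self.lineages = lineages.loc[:, list(RANKS)].fillna("").astype(str)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.lineages.index)

    def lineage_string(self, otu_id: str) -> str:
        """Semicolon-joined lineage, used for contaminant substring matching."""
        return ";".join(self.lineages.loc[otu_id])

    def unassigned_at_all_ranks(self) -> pd.Series:
        return (self.lineages == "").all(axis=1)

    def unassigned_at_any_rank(self) -> pd.Series:
        return (self.lineages == "").any(axis=1)

    def __repr__(self) -> str:
        return f"TaxonomyTable({len(self.lineages)} OTUs)"


@dataclass
class SampleMetadata:
    """Sample covariates: categorical design factors plus soil chemistry.

    ``levels`` declares the allowed level set per categorical column, with
    the first entry taken as the reference level for design matrices.
    """

    data: pd.DataFrame
    levels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(list(self.data.index), "sample")
        for col, lv in self.levels.items():
            if col not in self.data.columns:
                raise ValueError(f"declared categorical column {col!r} absent from metadata")
            observed = set(self.data[col].astype(str))
            unknown = observed - set(lv)
            if unknown:
                raise ValueError(
                    f"unknown level(s) {sorted(unknown)} in column {col!r}; "
                    f"declared levels are {list(lv)}"
                )
        for col in self.continuous_columns():
            vals = pd.to_numeric(self.data[col], errors="coerce")
            if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
                bad = self.data.index[~np.isfinite(vals.to_numpy(dtype=float))][0]
                raise ValueError(f"non-finite value in continuous column {col!r}, sample {bad!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def categorical_columns(self) -> list[str]:
        return [c for c in self.data.columns if c in self.levels or self.data[c].dtype == object]

    def continuous_columns(self) -> list[str]:
        return [
            c
            for c in self.data.columns
            if c not in self.levels and np.issubdtype(self.data[c].dtype, np.number)
        ]

    def reference_level(self, col: str) -> str:
        if col in self.levels:
            return self.levels[col][0]
        return sorted(self.data[col].astype(str).unique())[0]

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)].copy(), dict(self.levels))

    def __repr__(self) -> str:
        return f"SampleMetadata({len(self.data)} samples, {len(self.data.columns)} covariates)"


class Phylogeny:
    """Rooted tree with non-negative branch lengths over OTU tips."""

    def __init__(self, tree: TreeNode):
        self.tree = tree
        tips = list(tree.tips())
        names = [t.name for t in tips]
        if any(n is None for n in names):
            raise ValueError("all tips must be named")
        _check_unique(names, "tip")
        for node in tree.traverse(include_self=False):
            if node.length is None:
                raise ValueError(f"branch above {node.name or 'internal node'} has no length")
            if node.length < 0:
                raise ValueError(f"negative branch length above {node.name or 'internal node'}")
        self.tip_names = names
        self._patristic: DistanceMatrix | None = None

    @property
    def n_tips(self) -> int:
        return len(self.tip_names)

    def patristic(self) -> DistanceMatrix:
        """Tip-to-tip (patristic) distance matrix; cached."""
        if self._patristic is None:
            self._patristic = self.tree.tip_tip_distances()
        return self._patristic

    def depth(self, tip_name: str) -> float:
        """Root-to-tip path length."""
        tip = self.tree.find(tip_name)
        return tip.accumulate_to_ancestor(self.tree)

    def to_newick(self) -> str:
        return str(self.tree)

    def __repr__(self) -> str:
        return f"Phylogeny({self.n_tips} tips)"
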