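"""Alpha diversity on rarefied counts, beta-diversity distances, and PCoA.

Alpha diversity (Shannon entropy in nats, bias-corrected Chao1 richness)
is conventionally computed after rarefying every sample to a common depth;
:func:`rarefy` subsamples without replacement so the per-taxon expectation
is hypergeometric.  Beta diversity offers Bray-Curtis dissimilarity on
counts or proportions and unweighted UniFrac on presence/absence over a
rooted phylogeny.  :func:`pcoa` is classical metric scaling with explicit
negative-eigenvalue reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity as _skbio_beta_diversity

from .containers import CountTable, Phylogeny

__all__ = [
    "rarefy",
    "shannon",
    "chao1",
    "bray_curtis",
    "unweighted_unifrac",
    "pcoa",
    "OrdinationResult",
    "alpha_diversity_table",
]


def rarefy(
    table: CountTable,
    depth: int | None = None,
    seed: int = 0,
    drop_small: bool = False,
) -> CountTable:
    """Subsample every sample to ``depth`` reads without replacement.

    ``depth`` defaults to the minimum library size.  Samples shallower
    than ``depth`` raise unless ``drop_small`` is set, in which case they
    are removed.  Reproducible from ``seed``.
    """
    sizes = table.library_sizes()
    if depth is None:
        depth = int(sizes.min())
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    shallow = [s for s in table.sample_ids if sizes[s] < depth]
    if shallow:
        if not drop_small:
            raise ValueError(
                f"samples below rarefaction depth {depth}: {shallow}; "
                "pass drop_small=True to remove them"
            )
        table = table.select_samples([s for s in table.sample_ids if sizes[s] >= depth])
    rng = np.random.default_rng(seed)
    out = np.zeros_like(table.counts)
    for j in range(table.n_samples):
        col = table.counts[:, j]
        # multivariate hypergeometric = draw `depth` reads without replacement
        out[:, j] = rng.multivariate_hypergeometric(col, depth)
    return CountTable(out, table.otu_ids, table.sample_ids)


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy H = -sum p ln p (nats) over nonzero proportions."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon entropy undefined for an all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts: np.ndarray) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    counts = np.asarray(counts)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity_table(table: CountTable) -> pd.DataFrame:
    """Shannon and Chao1 per sample (rows = samples)."""
    rows = {
        s: {"shannon": shannon(table.counts[:, j]), "chao1": chao1(table.counts[:, j])}
        for j, s in enumerate(table.sample_ids)
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def bray_curtis(table: CountTable, use_proportions: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples.

    d(j,k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik).  By default
    computed on total-sum-scaled proportions so library size does not
    masquerade as composition; set ``use_proportions=False`` for raw
    counts.
    """
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    x = table.counts.T.astype(float)
    if np.any(x.sum(axis=1) == 0):
        j = int(np.argmin(x.sum(axis=1)))
        raise ValueError(f"sample {table.sample_ids[j]!r} is all zeros; Bray-Curtis undefined")
    if use_proportions:
        x = x / x.sum(axis=1, keepdims=True)
    condensed = pdist(x, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def unweighted_unifrac(table: CountTable, tree: Phylogeny) -> DistanceMatrix:
    """Unweighted UniFrac: unshared / total branch length on presence sets."""
    missing = [o for o in table.otu_ids if o not in set(tree.tip_names)]
    if missing:
        raise ValueError(f"OTU(s) missing from tree: {missing[:5]}")
    presence = (table.counts > 0).astype(int).T  # samples x OTUs
    return _skbio_beta_diversity(
        "unweighted_unifrac",
        presence,
        ids=table.sample_ids,
        taxa=table.otu_ids,
        tree=tree.tree,
        validate=True,
    )


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a distance matrix.

    ``proportion_explained`` uses only the positive eigenvalues in its
    denominator; negative eigenvalues are reported, not corrected away
    (``correction = "none"``).
    """

    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes (positive-eigenvalue axes only)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray
    correction: str = "none"

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dm: DistanceMatrix, eps: float = 1e-9) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centres -D^2/2, eigendecomposes, and returns coordinates for
    axes with eigenvalues > ``eps`` * max eigenvalue.  Negative eigenvalues
    (non-Euclidean distances) are reported in ``eigenvalues`` and excluded
    from the proportion-explained denominator.
    """
    d = dm.data
    if np.any(~np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite values")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(vals.max(), 0.0)
    keep = vals > eps * max(scale, 1.0)
    coords = vecs[:, keep] * np.sqrt(vals[keep])
    pos_sum = vals[vals > 0].sum()
    prop = np.where(vals > 0, vals / pos_sum, 0.0) if pos_sum > 0 else np.zeros_like(vals)
    return OrdinationResult(
        sample_ids=list(dm.ids),
        coordinates=coords,
        eigenvalues=vals,
        proportion_explained=prop,
    )
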