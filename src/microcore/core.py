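"""Abundance-occupancy core microbiome selection.

Taxa are ranked by an occupancy index that averages (i) group-averaged
occupancy ("site-specific occupancy": the mean over groups of the fraction
of that group's samples containing the taxon) and (ii) replication
consistency (the fraction of groups in which the taxon occurs in every
replicate).  Ranked taxa are added to a prospective core until their
cumulative contribution to between-sample Bray-Curtis dissimilarity grows
by less than a stopping increment (default 2 percentage points).

The contribution curve ``E(k)`` is the ratio of the mean pairwise
Bray-Curtis numerator restricted to the top-k taxa (with full-table sample
sums in the denominator) to the full-table mean Bray-Curtis, so E rises
from 0 to 1 as taxa are added.  The complementary form ``C(k) = 1 - E(k)``
is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CountTable, SampleMetadata
from .assembly import NeutralFit

logger = logging.getLogger(__name__)

__all__ = [
    "occupancy_index",
    "bc_contribution_curve",
    "select_core",
    "occupancy_models",
    "core_overlap",
    "neutral_overlay",
    "CoreResult",
    "OverlapResult",
]


def occupancy_index(table: CountTable, groups: pd.Series | dict) -> pd.DataFrame:
    """Rank taxa by the averaged occupancy / replication-consistency index.

    Parameters
    ----------
    table
        Count table; detection is ``count > 0``.
    groups
        Mapping sample id -> group label ("site").  Every sample must be
        grouped and every group must contain at least one sample.

    Returns
    -------
    DataFrame indexed by OTU, sorted by descending index (ties broken by
    total abundance, then OTU id), with columns ``site_occupancy``,
    ``replication_consistency``, ``index``, ``occupancy`` (overall),
    ``mean_abundance`` and ``rank`` (1-based).
    """
    groups = pd.Series(groups)
    missing = [s for s in table.sample_ids if s not in groups.index]
    if missing:
        raise ValueError(f"samples without a group label: {missing[:5]}")
    groups = groups.loc[table.sample_ids]
    present = table.counts > 0
    labels = groups.to_numpy()
    uniq = pd.unique(labels)
    site_occ = np.zeros(table.n_otus)
    rep_cons = np.zeros(table.n_otus)
    for g in uniq:
        cols = labels == g
        if cols.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        sub = present[:, cols]
        site_occ += sub.mean(axis=1)
        rep_cons += sub.all(axis=1)
    site_occ /= len(uniq)
    rep_cons /= len(uniq)
    index = (site_occ + rep_cons) / 2.0
    props = table.counts / np.maximum(table.counts.sum(axis=0, keepdims=True), 1)
    df = pd.DataFrame(
        {
            "site_occupancy": site_occ,
            "replication_consistency": rep_cons,
            "index": index,
            "occupancy": present.mean(axis=1),
            "mean_abundance": props.mean(axis=1),
            "total_count": table.counts.sum(axis=1),
        },
        index=table.otu_ids,
    )
    df = df.sort_values(
        ["index", "total_count"], ascending=[False, False], kind="mergesort"
    )
    # stable mergesort + pre-sorted index makes the OTU-id tiebreak deterministic
    df = df.loc[
        sorted(df.index, key=lambda o: (-df.at[o, "index"], -df.at[o, "total_count"], o))
    ]
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="total_count")


def bc_contribution_curve(table: CountTable, ranking: list[str]) -> pd.DataFrame:
    """Cumulative Bray-Curtis contribution of the top-k ranked taxa.

    ``BC_all`` is the mean pairwise Bray-Curtis of the full table;
    ``BC_core(k)`` keeps only the top-k taxa in the numerator while the
    denominator retains full-table sample sums, so ``E(k) =
    BC_core(k) / BC_all`` climbs from 0 to 1.  Returns a frame with one
    row per rank k: ``otu``, ``E`` and ``C = 1 - E``.
    """
    unknown = set(ranking) - set(table.otu_ids)
    if unknown:
        raise ValueError(f"ranking contains unknown OTUs: {sorted(unknown)[:5]}")
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    counts = table.to_frame().loc[ranking].to_numpy(dtype=float)
    totals = table.counts.sum(axis=0).astype(float)
    if np.any(totals == 0):
        raise ValueError("all-zero sample: Bray-Curtis undefined")
    n = table.n_samples
    iu, jl = np.triu_indices(n, k=1)
    denom = totals[iu] + totals[jl]  # full-table sums for every prefix
    diffs = np.abs(counts[:, iu] - counts[:, jl])  # taxa x pairs
    cum_num = np.cumsum(diffs, axis=0)
    bc_k = (cum_num / denom).mean(axis=1)
    # BC_all over *all* taxa (ranking may be a prefix of the full set)
    all_counts = table.counts.astype(float)
    bc_all = (np.abs(all_counts[:, iu] - all_counts[:, jl]).sum(axis=0) / denom).mean()
    e = bc_k / bc_all
    return pd.DataFrame(
        {"otu": ranking, "E": e, "C": 1.0 - e}, index=pd.RangeIndex(1, len(ranking) + 1, name="k")
    )


@dataclass
class CoreResult:
    """Ranked taxa, contribution curve, and the selected core set."""

    ranking: pd.DataFrame  # occupancy_index output
    curve: pd.DataFrame  # bc_contribution_curve output
    core: list[str]
    stopping_rank: int
    delta: float
    label: str = "all"

    @property
    def min_core_occupancy(self) -> float:
        """Lowest overall occupancy among selected core taxa."""
        return float(self.ranking.loc[self.core, "occupancy"].min())

    def per_otu_table(self) -> pd.DataFrame:
        out = self.ranking.copy()
        out["in_core"] = out.index.isin(self.core)
        return out


def select_core(
    ranking: pd.DataFrame,
    curve: pd.DataFrame,
    delta: float = 0.02,
    label: str = "all",
    tol: float = 1e-9,
) -> CoreResult:
    """Apply the diminishing-returns stopping rule to a contribution curve.

    Taxa are added in rank order; selection stops at the smallest k where
    the next taxon's increment ``E(k+1) - E(k)`` falls below ``delta``
    (absolute, on the [0, 1] explanatory-value scale).  At least one taxon
    is always selected; if every increment clears ``delta`` the core is
    the whole ranking.
    """
    e = curve["E"].to_numpy()
    if np.any(np.diff(e) < -tol):
        raise ValueError("contribution curve is not non-decreasing; ranking/curve mismatch")
    increments = np.diff(e)
    below = np.nonzero(increments < delta)[0]
    k = int(below[0]) + 1 if len(below) else len(e)
    k = max(k, 1)
    core = list(curve["otu"].iloc[:k])
    return CoreResult(
        ranking=ranking, curve=curve, core=core, stopping_rank=k, delta=delta, label=label
    )


def occupancy_models(
    table: CountTable,
    meta: SampleMetadata,
    model_var: str = "amendment",
    group_var: str = "farm_id",
    delta: float = 0.02,
    min_samples: int = 2,
) -> dict[str, CoreResult]:
    """Per-level occupancy models plus the pooled model.

    For each level of ``model_var`` with at least ``min_samples`` samples,
    runs the index -> curve -> selection pipeline on that level's samples
    (grouped by ``group_var`` for the occupancy index), and once on all
    samples.  Returns a map ``level -> CoreResult`` with key ``"all"`` for
    the pooled model.
    """
    if model_var not in meta.data.columns:
        raise ValueError(f"model variable {model_var!r} not in metadata")
    results: dict[str, CoreResult] = {}

    def run(sub: CountTable, label: str) -> CoreResult:
        groups = meta.data.loc[sub.sample_ids, group_var]
        nonzero = [o for o, t in zip(sub.otu_ids, sub.counts.sum(axis=1)) if t > 0]
        sub = sub.select_otus(nonzero)
        ranking = occupancy_index(sub, groups)
        curve = bc_contribution_curve(sub, list(ranking.index))
        return select_core(ranking, curve, delta=delta, label=label)

    results["all"] = run(table, "all")
    for level, rows in meta.data.groupby(model_var):
        samples = [s for s in table.sample_ids if s in set(rows.index)]
        if len(samples) < min_samples:
            logger.warning(
                "skipping occupancy model %r: only %d sample(s)", level, len(samples)
            )
            continue
        results[str(level)] = run(table.select_samples(samples), str(level))
    return results


@dataclass
class OverlapResult:
    """Venn counts and sharing percentages between per-level core sets."""

    venn: dict[str, int]  # "+"-joined sorted level combination -> exclusive count
    pairwise: dict[tuple[str, str], float]  # Jaccard sharing percentage
    total_sharing: float  # |intersection of all| / |union of all| * 100
    filtered_sets: dict[str, set]


def core_overlap(
    cores: dict[str, CoreResult] | dict[str, set],
    prevalence_filter: float = 1.0,
) -> OverlapResult:
    """Overlap of per-level core sets restricted to high-prevalence taxa.

    Each level's core is first restricted to taxa with occupancy >=
    ``prevalence_filter`` within that level (1.0 = taxa observed in every
    sample of the level).  Emits exclusive Venn-region counts for every
    level combination and pairwise/total sharing percentages
    ``|intersection| / |union| * 100``.
    """
    levels = [l for l in cores if l != "all"]
    if len(levels) < 2:
        raise ValueError("need at least two levels to overlap")
    sets: dict[str, set] = {}
    for level in levels:
        entry = cores[level]
        if isinstance(entry, CoreResult):
            occ = entry.ranking["occupancy"]
            sets[level] = {o for o in entry.core if occ[o] >= prevalence_filter}
        else:
            sets[level] = set(entry)
        if not sets[level]:
            logger.warning("core set for level %r is empty after prevalence filter", level)

    venn: dict[str, int] = {}
    n_levels = len(levels)
    for mask in range(1, 2**n_levels):
        inside = [levels[i] for i in range(n_levels) if mask >> i & 1]
        outside = [levels[i] for i in range(n_levels) if not mask >> i & 1]
        region = set.intersection(*(sets[l] for l in inside)) if inside else set()
        for l in outside:
            region -= sets[l]
        venn["+".join(sorted(inside))] = len(region)

    pairwise: dict[tuple[str, str], float] = {}
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            union = sets[a] | sets[b]
            inter = sets[a] & sets[b]
            pairwise[(a, b)] = 100.0 * len(inter) / len(union) if union else 0.0
    union_all = set.union(*sets.values()) if sets else set()
    inter_all = set.intersection(*sets.values()) if sets else set()
    total = 100.0 * len(inter_all) / len(union_all) if union_all else 0.0
    return OverlapResult(venn=venn, pairwise=pairwise, total_sharing=total, filtered_sets=sets)


def neutral_overlay(core: CoreResult, fit: NeutralFit) -> pd.Series:
    """Join neutral-model partition labels onto the selected core taxa."""
    labels = fit.per_otu["partition"]
    missing = [o for o in core.core if o not in labels.index]
    if missing:
        raise ValueError(f"core OTU(s) missing from neutral fit: {missing[:5]}")
    return labels.loc[core.core].copy()
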