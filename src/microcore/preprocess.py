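"""Preprocessing: sample/contaminant filtering and compositional transforms.

The filtering convention follows common 16S practice for agricultural soil
surveys: samples must exceed a minimum library size (strict inequality),
organellar contaminant lineages (mitochondria, chloroplasts) are removed by
case-insensitive substring match over the full lineage string, and OTUs
without any taxonomic assignment can be dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import CountTable, TaxonomyTable

logger = logging.getLogger(__name__)

__all__ = ["filter_dataset", "tss_clr", "FilterReport", "DEFAULT_CONTAMINANTS"]

DEFAULT_CONTAMINANTS = ("mitochondria", "chloroplast")


@dataclass
class FilterReport:
    """Counts of what filtering removed, for logging/provenance."""

    samples_removed: list[str] = field(default_factory=list)
    contaminant_otus_removed: int = 0
    unassigned_otus_removed: int = 0

    def __str__(self) -> str:
        return (
            f"removed {len(self.samples_removed)} shallow samples, "
            f"{self.contaminant_otus_removed} contaminant OTUs, "
            f"{self.unassigned_otus_removed} unassigned OTUs"
        )


def filter_dataset(
    table: CountTable,
    taxonomy: TaxonomyTable | None = None,
    min_reads: int = 5000,
    exclude: tuple[str, ...] = DEFAULT_CONTAMINANTS,
    drop_unassigned: bool = True,
    unassigned_mode: str = "all",
    return_report: bool = False,
) -> CountTable | tuple[CountTable, FilterReport]:
    """Apply the standard sample- and OTU-level filters.

    Parameters
    ----------
    table
        Raw count table.
    taxonomy
        Lineages used for contaminant and unassigned screening.  Required
        when ``exclude`` is non-empty or ``drop_unassigned`` is set.
    min_reads
        Samples with library size <= ``min_reads`` are removed (strict
        ``> min_reads`` retention).
    exclude
        Case-insensitive substrings; an OTU whose joined lineage contains
        any of them is removed.
    drop_unassigned
        Remove OTUs lacking taxonomic assignment.
    unassigned_mode
        ``"all"``: drop OTUs unassigned at every rank (default);
        ``"any"``: drop OTUs unassigned at any single rank.
    return_report
        Also return a :class:`FilterReport`.
    """
    report = FilterReport()

    sizes = table.library_sizes()
    keep_samples = [s for s in table.sample_ids if sizes[s] > min_reads]
    report.samples_removed = [s for s in table.sample_ids if sizes[s] <= min_reads]
    if not keep_samples:
        raise ValueError("no samples survive filtering")
    out = table.select_samples(keep_samples)

    if (exclude or drop_unassigned) and taxonomy is None:
        raise ValueError("taxonomy required for contaminant/unassigned screening")

    if taxonomy is not None:
        keep_otus = []
        needles = tuple(e.lower() for e in exclude)
        tax_otus = set(taxonomy.otu_ids)
        if unassigned_mode not in ("all", "any"):
            raise ValueError(f"unassigned_mode must be 'all' or 'any', got {unassigned_mode!r}")
        unassigned = (
            taxonomy.unassigned_at_all_ranks()
            if unassigned_mode == "all"
            else taxonomy.unassigned_at_any_rank()
        )
        for otu in out.otu_ids:
            if otu not in tax_otus:
                raise ValueError(f"OTU {otu!r} missing from taxonomy")
            lineage = taxonomy.lineage_string(otu).lower()
            if any(n in lineage for n in needles):
                report.contaminant_otus_removed += 1
                continue
            if drop_unassigned and bool(unassigned[otu]):
                report.unassigned_otus_removed += 1
                continue
            keep_otus.append(otu)
        if not keep_otus:
            raise ValueError("no OTUs survive filtering")
        out = out.select_otus(keep_otus)

    logger.info("filter_dataset: %s", report)
    if return_report:
        return out, report
    return out


def tss_clr(table: CountTable, pseudocount: float = 0.5) -> np.ndarray:
    """Total-sum scaling followed by the centred log-ratio transform.

    Per sample: ``p = (x + pseudocount) / sum(x + pseudocount)`` then
    ``clr = log p - mean(log p)``.  Each sample's clr values sum to zero.

    Returns an (OTUs x samples) float matrix aligned with the table.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    sizes = table.counts.sum(axis=0)
    if np.any(sizes == 0):
        j = int(np.argmin(sizes))
        raise ValueError(f"sample {table.sample_ids[j]!r} is all zeros")
    shifted = table.counts + pseudocount
    props = shifted / shifted.sum(axis=0)
    logs = np.log(props)
    return logs - logs.mean(axis=0)
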