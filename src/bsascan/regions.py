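"""Candidate-region calling: merge significant windows, find peaks, add genes."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

from .io import GeneRecord
from .windows import WindowStat

logger = logging.getLogger(__name__)

__all__ = ["CandidateRegion", "merge_significant", "overlap_genes"]


@dataclass(frozen=True)
class CandidateRegion:
    """A maximal run of significant windows, 0-based half-open.

    ``peak_pos`` is the start of the member window with the highest mean
    ΔSNP index (ties broken toward the smaller start); ``genes`` lists the
    identifiers of annotated genes overlapping the region, in start order.
    """

    chrom: str
    start: int
    end: int
    n_windows: int
    peak_pos: int
    peak_delta: float
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("region must have start < end")
        if not self.start <= self.peak_pos < self.end:
            raise ValueError("peak_pos must lie within the region")
        if self.n_windows < 1:
            raise ValueError("a region contains at least one window")


def merge_significant(
    windows: Sequence[WindowStat], max_gap: int = 0
) -> list[CandidateRegion]:
    """Union significant windows that overlap or lie within ``max_gap`` bp.

    Only windows flagged significant participate.  Merging is per
    chromosome; region bounds are the union of member intervals; the peak
    is recomputed within each region.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    sig = sorted(
        (w for w in windows if w.significant), key=lambda w: (w.chrom, w.start)
    )
    regions: list[CandidateRegion] = []
    cluster: list[WindowStat] = []

    def close(cluster: list[WindowStat]) -> CandidateRegion:
        peak = max(cluster, key=lambda w: (w.mean_delta, -w.start))
        return CandidateRegion(
            chrom=cluster[0].chrom,
            start=min(w.start for w in cluster),
            end=max(w.end for w in cluster),
            n_windows=len(cluster),
            peak_pos=peak.start,
            peak_delta=peak.mean_delta,
        )

    for w in sig:
        if cluster and (w.chrom != cluster[-1].chrom or w.start > max(c.end for c in cluster) + max_gap):
            regions.append(close(cluster))
            cluster = []
        cluster.append(w)
    if cluster:
        regions.append(close(cluster))
    return regions


def overlap_genes(
    regions: Sequence[CandidateRegion], genes: Sequence[GeneRecord]
) -> list[CandidateRegion]:
    """Attach overlapping gene identifiers to each region.

    Gene coordinates are 1-based inclusive; a gene overlaps a region iff
    its 0-based half-open interval ``[start-1, end)`` intersects the
    region's.  A disjoint set of chromosome names between the two inputs
    is logged as a warning (likely a naming-convention mismatch).
    """
    region_chroms = {r.chrom for r in regions}
    gene_chroms = {g.chrom for g in genes}
    if regions and genes and not (region_chroms & gene_chroms):
        logger.warning(
            "no chromosome names shared between regions and annotation; "
            "regions only: %s; annotation only: %s",
            sorted(region_chroms - gene_chroms),
            sorted(gene_chroms - region_chroms),
        )
    out = []
    for r in regions:
        hits = [
            g
            for g in genes
            if g.chrom == r.chrom and g.start - 1 < r.end and r.start < g.end
        ]
        hits.sort(key=lambda g: g.start)
        out.append(replace(r, genes=tuple(g.gene_id for g in hits)))
    return out
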