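"""Per-site SNP index and ΔSNP index with depth/quality filtering.

The SNP index of a pool at a site is the fraction of reads carrying the
mutant (ALT) allele: ``alt / (ref + alt)``.  The ΔSNP index subtracts the
wild-type pool's index from the mutant pool's.  In an F2-type recessive
bulk design the mutant bulk is homozygous mutant at the causal locus
(index 1) while the wild-type bulk is 1 AA : 2 Aa (expected index 1/3),
so Δ approaches 2/3 at full linkage and 0 at unlinked loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import VariantSite

__all__ = [
    "FilterSpec",
    "SnpIndexRecord",
    "snp_index",
    "delta_snp_index",
    "filter_sites",
    "compute_site_stats",
]

EMS_PAIRS = {("G", "A"), ("C", "T")}


@dataclass(frozen=True)
class FilterSpec:
    """Site filters applied before index computation.

    min_depth_per_pool : int
        Keep a site only if ref+alt reads reach this depth in *both* pools
        (default 8, common BSA-seq practice).
    min_site_quality : float
        Minimum caller quality; applied only to sites that carry a quality
        score (default 20).
    restrict_to_ems_spectrum : bool
        If set, keep only G→A / C→T substitutions — the canonical EMS
        alkylation spectrum (default off).
    min_index_floor : float
        Optional floor: drop sites whose SNP index is below this value in
        both pools, as some published bulk-scan protocols do. Default 0.0
        (disabled).
    """

    min_depth_per_pool: int = 8
    min_site_quality: float = 20.0
    restrict_to_ems_spectrum: bool = False
    min_index_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.min_depth_per_pool < 0 or self.min_site_quality < 0:
            raise ValueError("filter thresholds must be >= 0")
        if not 0.0 <= self.min_index_floor <= 1.0:
            raise ValueError("min_index_floor must lie in [0, 1]")


@dataclass(frozen=True)
class SnpIndexRecord:
    """Per-site indices of both pools and their difference."""

    chrom: str
    pos: int
    depth_mut: int
    depth_wt: int
    index_mut: float
    index_wt: float
    delta: float


def snp_index(ref_count: int, alt_count: int) -> float:
    """Fraction of reads carrying the mutant allele at one site in one pool.

    Raises :class:`ZeroDivisionError` on zero total depth: the index is
    undefined there and callers are expected to filter uncovered sites
    first.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    total = ref_count + alt_count
    if total == 0:
        raise ZeroDivisionError("SNP index undefined at zero depth; filter uncovered sites")
    return alt_count / total


def delta_snp_index(index_mut: float, index_wt: float) -> float:
    """ΔSNP index: mutant-pool index minus wild-type-pool index."""
    for v in (index_mut, index_wt):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"SNP index {v} outside [0, 1]")
    return index_mut - index_wt


def filter_sites(
    sites: Iterable[VariantSite], spec: FilterSpec = FilterSpec()
) -> tuple[list[VariantSite], dict[str, int]]:
    """Apply the filters of ``spec``; report per-rule rejection counts.

    A rejected site is attributed to the *first* failing rule, checked in
    the order depth → quality → spectrum → index floor.
    """
    kept: list[VariantSite] = []
    counts = {"depth": 0, "quality": 0, "spectrum": 0, "index_floor": 0}
    for s in sites:
        if s.mut_depth < spec.min_depth_per_pool or s.wt_depth < spec.min_depth_per_pool:
            counts["depth"] += 1
            continue
        if s.quality is not None and s.quality < spec.min_site_quality:
            counts["quality"] += 1
            continue
        if spec.restrict_to_ems_spectrum and (s.ref, s.alt) not in EMS_PAIRS:
            counts["spectrum"] += 1
            continue
        if spec.min_index_floor > 0.0:
            # only meaningful for covered sites; uncovered ones fail depth above
            if (
                snp_index(s.mut_ref, s.mut_alt) < spec.min_index_floor
                and snp_index(s.wt_ref, s.wt_alt) < spec.min_index_floor
            ):
                counts["index_floor"] += 1
                continue
        kept.append(s)
    return kept, counts


def compute_site_stats(sites: Sequence[VariantSite]) -> list[SnpIndexRecord]:
    """Compute SNP indices and Δ for every (already filtered) site.

    Order is preserved.  A site with zero depth in either pool reaching
    this stage is a filter-contract violation and raises.
    """
    records: list[SnpIndexRecord] = []
    for s in sites:
        if not s.covered():
            raise ValueError(
                f"{s.chrom}:{s.pos} has zero depth in a pool; filter before computing indices"
            )
        im = snp_index(s.mut_ref, s.mut_alt)
        iw = snp_index(s.wt_ref, s.wt_alt)
        records.append(
            SnpIndexRecord(
                chrom=s.chrom,
                pos=s.pos,
                depth_mut=s.mut_depth,
                depth_wt=s.wt_depth,
                index_mut=im,
                index_wt=iw,
                delta=delta_snp_index(im, iw),
            )
        )
    return records


def write_site_table(records: Sequence[SnpIndexRecord], path) -> None:
    """Per-site TSV: chrom, pos, depths, indices, delta."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("chrom\tpos\tdepth_mut\tdepth_wt\tindex_mut\tindex_wt\tdelta\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.depth_mut}\t{r.depth_wt}\t"
                f"{r.index_mut:.6g}\t{r.index_wt:.6g}\t{r.delta:.6g}\n"
            )
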