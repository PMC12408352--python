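"""Readers and writers for the formats a two-pool genome scan touches.

Coordinate conventions are explicit throughout the package:

* VCF, the allele-count TSV, GFF3 and all in-memory positions are **1-based**
  (``pos`` is the position of the SNP itself; gene ``start``/``end`` are
  1-based inclusive, as in GFF3).
* Every exported *interval* file — the window table, region TSV and BED —
  uses **0-based half-open** intervals, the BED convention.

The atomic input record is :class:`VariantSite`: one biallelic SNP with
ref/alt read counts in each of the two phenotype-contrasted pools.  By
convention the ALT allele is the mutant (EMS-induced) allele: the reference
genome is assumed to be the non-mutagenized parent of the cross, so every
called SNP's alternate base is the mutagen's doing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "VariantSite",
    "GeneRecord",
    "read_variants_vcf",
    "read_variants_tsv",
    "write_variants_tsv",
    "read_genes_gff3",
    "write_window_table",
    "write_region_table",
    "write_region_bed",
]

TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "mut_ref", "mut_alt", "wt_ref", "wt_alt"]

WINDOW_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_sites",
    "mean_delta",
    "band_lo",
    "band_hi",
    "significant",
]

REGION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_windows",
    "peak_pos",
    "peak_delta",
    "genes",
]


@dataclass(frozen=True)
class VariantSite:
    """One biallelic SNP with per-pool allele depths.

    ``mut_ref``/``mut_alt`` are reference- and alternate-allele read counts in
    the mutant-phenotype pool, ``wt_ref``/``wt_alt`` in the wild-type pool.
    ``pos`` is 1-based. ``quality`` is the caller's site quality when the
    source format carries one (VCF QUAL), else ``None``.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    mut_ref: int
    mut_alt: int
    wt_ref: int
    wt_alt: int
    quality: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if min(self.mut_ref, self.mut_alt, self.wt_ref, self.wt_alt) < 0:
            raise ValueError("read counts must be non-negative")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref})")

    @property
    def mut_depth(self) -> int:
        return self.mut_ref + self.mut_alt

    @property
    def wt_depth(self) -> int:
        return self.wt_ref + self.wt_alt

    def covered(self) -> bool:
        """True iff the site has at least one read in *both* pools."""
        return self.mut_depth > 0 and self.wt_depth > 0


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval in GFF3 convention: 1-based, both ends inclusive."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


def read_variants_vcf(
    path: str | Path, mut_sample: str, wt_sample: str
) -> tuple[list[VariantSite], dict[str, int]]:
    """Read biallelic SNPs with per-sample allele depth (AD) from a VCF.

    Parameters
    ----------
    path
        A VCF 4.x text file with at least the two named samples, each
        carrying the standard ``AD`` FORMAT field.
    mut_sample, wt_sample
        Sample names of the mutant-phenotype and wild-type-phenotype pools.

    Returns
    -------
    sites, skipped
        Sites in file order, and a counter of skipped records keyed by
        reason (``multiallelic``, ``not_snp``, ``missing_ad``).

    Raises
    ------
    ValueError
        If either sample name is absent (the message lists the samples the
        file does carry).
    """
    skipped = {"multiallelic": 0, "not_snp": 0, "missing_ad": 0}
    sites: list[VariantSite] = []
    with pysam.VariantFile(str(path)) as vcf:
        available = list(vcf.header.samples)
        for name in (mut_sample, wt_sample):
            if name not in available:
                raise ValueError(
                    f"sample {name!r} not in VCF; available samples: {available}"
                )
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped["multiallelic"] += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or alt == "*":
                skipped["not_snp"] += 1
                continue
            try:
                mut_ad = rec.samples[mut_sample]["AD"]
                wt_ad = rec.samples[wt_sample]["AD"]
            except KeyError:
                skipped["missing_ad"] += 1
                continue
            if mut_ad is None or wt_ad is None or None in mut_ad[:2] or None in wt_ad[:2]:
                skipped["missing_ad"] += 1
                continue
            sites.append(
                VariantSite(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    mut_ref=int(mut_ad[0]),
                    mut_alt=int(mut_ad[1]),
                    wt_ref=int(wt_ad[0]),
                    wt_alt=int(wt_ad[1]),
                    quality=rec.qual,
                )
            )
    if any(skipped.values()):
        logger.info("VCF read: skipped records by reason: %s", skipped)
    return sites, skipped


def read_variants_tsv(path: str | Path) -> list[VariantSite]:
    """Read the package's plain allele-count table.

    Expected header (tab-separated):
    ``chrom pos ref alt mut_ref mut_alt wt_ref wt_alt`` with an optional
    trailing ``quality`` column.
    """
    sites: list[VariantSite] = []
    with open(path, encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise ValueError(f"{path}: empty file; expected header {TSV_COLUMNS}")
        header = header_line.rstrip("\n").split("\t")
        if header[: len(TSV_COLUMNS)] != TSV_COLUMNS:
            raise ValueError(
                f"{path}: malformed header {header}; expected columns {TSV_COLUMNS}"
            )
        has_quality = len(header) > len(TSV_COLUMNS) and header[len(TSV_COLUMNS)] == "quality"
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                quality = None
                if has_quality and len(parts) > 8 and parts[8] not in ("", "NA", "."):
                    quality = float(parts[8])
                sites.append(
                    VariantSite(
                        chrom=parts[0],
                        pos=int(parts[1]),
                        ref=parts[2],
                        alt=parts[3],
                        mut_ref=int(parts[4]),
                        mut_alt=int(parts[5]),
                        wt_ref=int(parts[6]),
                        wt_alt=int(parts[7]),
                        quality=quality,
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}: line {lineno}: cannot parse {line!r}: {exc}") from exc
    return sites


def write_variants_tsv(sites: Iterable[VariantSite], path: str | Path) -> None:
    """Write sites in the allele-count TSV schema (inverse of the reader)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TSV_COLUMNS + ["quality"]) + "\n")
        for s in sites:
            q = "NA" if s.quality is None else repr(float(s.quality))
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t"
                f"{s.mut_ref}\t{s.mut_alt}\t{s.wt_ref}\t{s.wt_alt}\t{q}\n"
            )


def read_genes_gff3(path: str | Path) -> list[GeneRecord]:
    """Read ``gene``-type features from a GFF3 file.

    Coordinates are kept 1-based inclusive as GFF3 defines them. The gene
    identifier is taken from the ``ID`` attribute (falling back to
    ``gene_id``/``Name``); lines that cannot be parsed are skipped and
    counted in a log message.
    """
    genes: list[GeneRecord] = []
    n_bad = 0
    for feature in gffutils.DataIterator(str(path)):
        if feature.featuretype != "gene":
            continue
        try:
            attrs = feature.attributes
            gene_id = (
                attrs.get("ID", attrs.get("gene_id", attrs.get("Name", [None])))[0]
            )
            if gene_id is None:
                raise ValueError("no ID/gene_id/Name attribute")
            genes.append(
                GeneRecord(
                    chrom=feature.seqid,
                    start=int(feature.start),
                    end=int(feature.end),
                    strand=feature.strand or ".",
                    gene_id=gene_id,
                )
            )
        except (ValueError, TypeError):
            n_bad += 1
    if n_bad:
        logger.warning("GFF3 read: skipped %d unparseable gene lines", n_bad)
    return genes


def _fmt(value: float | None) -> str:
    if value is None:
        return "NA"
    import math

    if isinstance(value, float) and math.isnan(value):
        return "NA"
    if value == float("-inf"):
        return "-inf"
    return format(value, ".6g")


def write_window_table(windows: Sequence, path: str | Path) -> None:
    """Write windows as a TSV sorted by (chrom, start).

    Window intervals are 0-based half-open.  ``mean_delta``/``band_lo``/
    ``band_hi`` print ``NA`` when missing (empty windows).
    """
    rows = sorted(windows, key=lambda w: (w.chrom, w.start))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(WINDOW_COLUMNS) + "\n")
        for w in rows:
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_sites}\t"
                f"{_fmt(w.mean_delta)}\t{_fmt(w.band_lo)}\t{_fmt(w.band_hi)}\t"
                f"{int(bool(w.significant))}\n"
            )


def write_region_table(regions: Sequence, path: str | Path) -> None:
    """Write candidate regions as TSV (0-based half-open, genes ;-joined)."""
    rows = sorted(regions, key=lambda r: (r.chrom, r.start))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(REGION_COLUMNS) + "\n")
        for r in rows:
            genes = ";".join(r.genes) if r.genes else "NA"
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.n_windows}\t"
                f"{r.peak_pos}\t{_fmt(r.peak_delta)}\t{genes}\n"
            )


def write_region_bed(regions: Sequence, path: str | Path) -> None:
    """Write candidate regions as 4-column BED (name = peak delta)."""
    rows = sorted(regions, key=lambda r: (r.chrom, r.start))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in rows:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tdelta={_fmt(r.peak_delta)}\n")
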