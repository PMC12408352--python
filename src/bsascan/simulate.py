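"""Forward simulation of an EMS mutant-mapping cross with pooled sequencing.

The emulated experiment: an EMS-mutagenized recessive mutant is backcrossed
to its (non-mutagenized) parent; the heterozygous BC1F1 is selfed, giving a
BC1F2 population in which genotypes at every induced variant segregate
1 AA : 2 Aa : 1 aa and the recessive phenotype segregates 3:1.  Two bulks
are formed — mutant-phenotype lines (all ``aa`` at the causal locus) and
wild-type-phenotype lines (1 AA : 2 Aa there) — and each bulk is sequenced
as a pool, observed only through per-site read counts.

Genetics model ("star" topology): each individual's genotype at a marker is
derived from its causal-locus genotype gamete-by-gamete, with an
independent recombination event at rate ``r`` per gamete given by the
Haldane map function; markers on other chromosomes assort freely
(``r = 0.5``).  Crossover interference and marker-marker linkage beyond the
causal locus are not modelled — sufficient for the sampling distribution of
per-site pool allele frequencies, which is what the scan statistics see.

Read model: per site and pool, depth ~ Poisson(λ) and mutant-allele count ~
Binomial(depth, f(1−ε) + (1−f)ε) with per-read miscall rate ε.

Defaults state the emulated experiment: bulks of 44 mutant-phenotype and
50 wild-type-phenotype lines; variant density 1/50 kb; 95% of EMS changes
G:C→A:T; 4 cM/Mb; mean depth 30×; ε = 0.002.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import VariantSite

__all__ = [
    "CrossDesign",
    "SimConfig",
    "recomb_fraction",
    "place_variants",
    "simulate_population",
    "simulate_reads",
    "simulate_experiment",
    "generate_dataset",
]

BASES = ("A", "C", "G", "T")
EMS_PAIRS = (("G", "A"), ("C", "T"))
NON_EMS_PAIRS = tuple(
    (r, a) for r in BASES for a in BASES if r != a and (r, a) not in EMS_PAIRS
)

TRUTH_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "distance_morgans",
    "recomb_fraction",
    "f_mut",
    "f_wt",
    "is_causal",
]

_MAX_DRAW_ATTEMPTS = 10**6


@dataclass(frozen=True)
class CrossDesign:
    """The mapping cross: bulk sizes and the (hidden) causal locus."""

    causal_chrom: str
    causal_pos: int
    mut_bulk_size: int = 44
    wt_bulk_size: int = 50
    segregation_model: str = "F2_SELFED"

    def __post_init__(self) -> None:
        if self.mut_bulk_size < 1 or self.wt_bulk_size < 1:
            raise ValueError("bulk sizes must be >= 1")
        if self.causal_pos < 1:
            raise ValueError("causal_pos must be >= 1")
        if self.segregation_model != "F2_SELFED":
            raise ValueError(
                f"unsupported segregation model {self.segregation_model!r}; "
                "only F2_SELFED (selfed heterozygote, 3:1 phenotypes) is implemented"
            )


@dataclass(frozen=True)
class SimConfig:
    """Genome, mutagenesis, genetic-map and sequencing parameters."""

    chrom_lengths: Mapping[str, int]
    variant_density: float = 1.0 / 50_000
    ems_gc_to_at_fraction: float = 0.95
    cm_per_mb: float = 4.0
    depth_mean: float = 30.0
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must not be empty")
        if any(length < 1 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be >= 1")
        if self.variant_density < 0 or self.depth_mean < 0 or self.cm_per_mb < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.ems_gc_to_at_fraction <= 1.0:
            raise ValueError("ems_gc_to_at_fraction must lie in [0, 1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")


def recomb_fraction(distance_bp: float, cm_per_mb: float) -> float:
    """Haldane map function: r = (1 − e^(−2d)) / 2 for distance d in Morgans.

    ``d = (distance_bp / 1e6) * cm_per_mb / 100``; an infinite distance
    (another chromosome) gives the free-assortment limit r = 0.5.
    """
    if distance_bp < 0:
        raise ValueError("distance must be >= 0")
    if math.isinf(distance_bp):
        return 0.5
    d = distance_bp * cm_per_mb * 1e-8
    return 0.5 * (1.0 - math.exp(-2.0 * d))


def _spawn(seed: int, *key: str) -> np.random.Generator:
    """Deterministic child stream named by ``key``, derived from the root seed."""
    digest = np.frombuffer(",".join(key).encode("utf-8"), dtype=np.uint8)
    entropy = [int(seed)] + [int(b) for b in digest]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def place_variants(
    config: SimConfig, design: CrossDesign, rng: np.random.Generator | None = None
) -> list[tuple[str, int, str, str]]:
    """Scatter EMS-induced SNPs on the genome; always include the causal site.

    Per chromosome the variant count is Poisson(density × length) and
    positions are uniform without duplicates.  With probability
    ``ems_gc_to_at_fraction`` a variant is a canonical EMS transition
    (G→A or C→T); otherwise one of the ten other substitutions, uniformly.
    The causal site is forced at ``(design.causal_chrom, design.causal_pos)``
    as a G→A transition.
    """
    if design.causal_chrom not in config.chrom_lengths:
        raise ValueError(f"causal chromosome {design.causal_chrom!r} not in chrom_lengths")
    if design.causal_pos > config.chrom_lengths[design.causal_chrom]:
        raise ValueError("causal_pos beyond its chromosome length")
    if rng is None:
        rng = _spawn(config.seed, "place_variants")

    variants: list[tuple[str, int, str, str]] = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        n = int(rng.poisson(config.variant_density * length))
        if n > 0.5 * length:
            raise ValueError(
                f"{chrom}: {n} variants on {length} bp cannot be placed without duplicates"
            )
        taken: set[int] = set()
        causal_here = chrom == design.causal_chrom
        if causal_here:
            taken.add(design.causal_pos)
        positions: list[int] = []
        while len(positions) < n:
            batch = rng.integers(1, length + 1, size=n - len(positions))
            for p in batch:
                p = int(p)
                if p not in taken:
                    taken.add(p)
                    positions.append(p)
        positions.sort()
        for pos in positions:
            if rng.random() < config.ems_gc_to_at_fraction:
                ref, alt = EMS_PAIRS[int(rng.integers(2))]
            else:
                ref, alt = NON_EMS_PAIRS[int(rng.integers(len(NON_EMS_PAIRS)))]
            variants.append((chrom, pos, ref, alt))
        if causal_here:
            variants.append((chrom, design.causal_pos, "G", "A"))
    variants.sort(key=lambda v: (v[0], v[1]))
    return variants


def _draw_bulk_composition(
    design: CrossDesign, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Draw BC1F2 individuals until both bulks fill.

    Each individual's causal genotype is AA/Aa/aa with probability
    ¼/½/¼; the phenotype is mutant iff aa (fully penetrant recessive).
    Returns (n_mut, n_wt_AA, n_wt_Aa) — the wild-type bulk's genotype
    split is the quantity that matters downstream.
    """
    n_mut = 0
    n_aa_wt = 0
    n_wt = 0
    for _ in range(_MAX_DRAW_ATTEMPTS):
        if n_mut >= design.mut_bulk_size and n_wt >= design.wt_bulk_size:
            break
        u = rng.random()
        if u < 0.25:  # aa — mutant phenotype
            if n_mut < design.mut_bulk_size:
                n_mut += 1
        else:  # AA (p=1/4) or Aa (p=1/2) — wild-type phenotype
            if n_wt < design.wt_bulk_size:
                n_wt += 1
                if u < 0.5:  # AA given wild-type: ¼ of total mass
                    n_aa_wt += 1
    else:
        raise RuntimeError("bulks not filled within the attempt cap")
    return n_mut, n_aa_wt, n_wt - n_aa_wt


def simulate_population(
    design: CrossDesign,
    variants: Sequence[tuple[str, int, str, str]],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate bulk allele frequencies at every variant — the truth table.

    Marker genotypes follow the star-topology linkage model: per gamete the
    marker allele equals the causal-locus allele unless a recombination
    event (probability ``r`` from the Haldane function) flips it.  Pool
    frequencies are mutant-allele counts over ``2 × bulk size``.

    Returns a DataFrame with one row per variant: position, genetic distance
    to the causal locus (Morgans; inf across chromosomes), ``r``, the true
    frequencies ``f_mut``/``f_wt`` and an ``is_causal`` flag.
    """
    if rng is None:
        rng = _spawn(config.seed, "simulate_population")
    n_mut, n_aa, n_het = _draw_bulk_composition(design, rng)
    n_wt = n_aa + n_het

    rows = []
    for chrom, pos, ref, alt in variants:
        if chrom == design.causal_chrom:
            dist_bp: float = abs(pos - design.causal_pos)
            d_morgan = dist_bp * config.cm_per_mb * 1e-8
        else:
            dist_bp = math.inf
            d_morgan = math.inf
        r = recomb_fraction(dist_bp, config.cm_per_mb)

        # Mutant bulk: every individual is aa, so each of its 2*n_mut
        # gametes carries the mutant marker allele with probability 1-r.
        mut_count = rng.binomial(2 * n_mut, 1.0 - r)
        # Wild-type bulk: AA individuals contribute two "recombine-to-mutant"
        # gametes (prob r each); Aa individuals one 1-r gamete and one r gamete.
        wt_count = (
            rng.binomial(2 * n_aa, r)
            + rng.binomial(n_het, 1.0 - r)
            + rng.binomial(n_het, r)
        )
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "distance_morgans": d_morgan,
                "recomb_fraction": r,
                "f_mut": mut_count / (2 * n_mut),
                "f_wt": wt_count / (2 * n_wt),
                "is_causal": chrom == design.causal_chrom and pos == design.causal_pos,
            }
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def simulate_reads(
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[VariantSite]:
    """Sample pooled short-read allele counts from the true frequencies.

    Depth is Poisson(λ) per site per pool; the mutant-read count is
    binomial with success probability f(1−ε) + (1−f)ε.  Zero-depth sites
    are still emitted — downstream depth filters decide their fate.
    """
    if rng is None:
        rng = _spawn(config.seed, "simulate_reads")
    n = len(truth)
    eps = config.error_rate
    sites: list[VariantSite] = []
    depth_mut = rng.poisson(config.depth_mean, size=n)
    depth_wt = rng.poisson(config.depth_mean, size=n)
    p_mut = truth["f_mut"].to_numpy() * (1 - eps) + (1 - truth["f_mut"].to_numpy()) * eps
    p_wt = truth["f_wt"].to_numpy() * (1 - eps) + (1 - truth["f_wt"].to_numpy()) * eps
    alt_mut = rng.binomial(depth_mut, p_mut)
    alt_wt = rng.binomial(depth_wt, p_wt)
    for i, row in enumerate(truth.itertuples(index=False)):
        sites.append(
            VariantSite(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                mut_ref=int(depth_mut[i] - alt_mut[i]),
                mut_alt=int(alt_mut[i]),
                wt_ref=int(depth_wt[i] - alt_wt[i]),
                wt_alt=int(alt_wt[i]),
            )
        )
    return sites


def simulate_experiment(
    design: CrossDesign, config: SimConfig
) -> tuple[list[VariantSite], pd.DataFrame]:
    """Run the full simulation: variants → population → reads.

    All randomness derives from ``config.seed`` through named child
    streams, so a fixed seed reproduces the dataset exactly.
    """
    variants = place_variants(config, design)
    truth = simulate_population(design, variants, config)
    sites = simulate_reads(truth, config)
    return sites, truth


def generate_dataset(
    design: CrossDesign,
    config: SimConfig,
    out_prefix: str | Path,
    write_vcf: bool = False,
) -> dict[str, Path]:
    """Write the observable data and the hidden truth to disk.

    Produces ``<prefix>.variants.tsv`` (allele-count table),
    ``<prefix>.truth.tsv`` and optionally ``<prefix>.vcf`` (two samples,
    ``mut_pool`` and ``wt_pool``, with AD fields).  Byte-identical for a
    fixed seed.
    """
    from .io import write_variants_tsv

    sites, truth = simulate_experiment(design, config)
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": prefix.with_suffix(".variants.tsv"),
        "truth": prefix.with_suffix(".truth.tsv"),
    }
    write_variants_tsv(sites, paths["variants"])
    truth_out = truth.copy()
    truth_out["is_causal"] = truth_out["is_causal"].astype(int)
    truth_out.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    if write_vcf:
        paths["vcf"] = prefix.with_suffix(".vcf")
        _write_minimal_vcf(sites, config, paths["vcf"])
    return paths


def _write_minimal_vcf(
    sites: Sequence[VariantSite], config: SimConfig, path: Path
) -> None:
    """Two-sample sites-only VCF carrying GT (./.) and AD per pool."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bsascan-simulator\n")
        for chrom in sorted(config.chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={config.chrom_lengths[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tmut_pool\twt_pool\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT:AD\t"
                f"./.:{s.mut_ref},{s.mut_alt}\t./.:{s.wt_ref},{s.wt_alt}\n"
            )
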