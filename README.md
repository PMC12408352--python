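# bsascan

Bulked-segregant analysis (BSA-seq) for mapping monogenic mutations from
pooled whole-genome sequencing, with a built-in forward simulator for
validating every stage against known ground truth.

## The problem

A recessive mutant recovered from an EMS screen is backcrossed to its
parent; the F1 is selfed; the resulting F2-type population segregates
3 wild-type : 1 mutant. DNA from a bulk of mutant-phenotype lines and a
bulk of wild-type-phenotype lines is pool-sequenced. At each induced SNP,
the **SNP index** of a pool is the fraction of reads carrying the mutant
(ALT) allele, and the **ΔSNP index** is

```
Δ(site) = index_mutant_pool − index_wildtype_pool
```

At unlinked sites both pools sample the mutant allele at frequency ½, so
E[Δ] ≈ 0. At the causal locus the mutant bulk is fixed (index 1) while the
wild-type bulk is 1 AA : 2 Aa (index ⅓), so E[Δ] → ⅔; intermediate sites
decay between the two with the recombination fraction. Scanning the
smoothed Δ profile along the genome therefore points at the causal locus.

`bsascan` implements the full scan:

- per-site SNP-index / ΔSNP-index statistics with depth and quality filters;
- sliding-window smoothing (default 25-kb windows, 5-kb step);
- Monte-Carlo confidence bands under the no-linkage null (default α = 0.01),
  resampling both bulk composition — Binomial(2N, ½) chromosomes per bulk
  of N lines — and read counts at the observed depths, with full linkage
  assumed within a window;
- merging of significant windows into candidate regions with peak
  statistics and GFF3 gene overlap;
- the χ² goodness-of-fit test for Mendelian segregation ratios;
- a forward simulator of the whole experiment (EMS variant placement,
  Haldane-map linkage to the causal locus, 3:1 segregation, bulk
  formation, Poisson depth / binomial allele read sampling).

Inputs are a two-sample VCF with per-sample `AD` fields or a plain
allele-count TSV, plus chromosome lengths and an optional GFF3 annotation.

## Worked example

```python
import bsascan as b

# simulate a mapping experiment: 10-Mb chromosome, causal locus at 5 Mb,
# bulks of 44 mutant-phenotype and 50 wild-type-phenotype lines, 30x pools
config = b.SimConfig(chrom_lengths={"chr1": 10_000_000}, seed=7)
design = b.CrossDesign(causal_chrom="chr1", causal_pos=5_000_000)
sites, truth = b.simulate_experiment(design, config)
print(f"{len(sites)} simulated variant sites")

result = b.run_scan(
    sites,
    chrom_lengths=config.chrom_lengths,
    band_spec=b.BandSpec(alpha=0.01, n_sims=2_000, seed=8),
    design=design,
)
top = max(result.regions, key=lambda r: r.peak_delta)
print(f"{sum(w.significant for w in result.windows)} significant windows, "
      f"{len(result.regions)} regions")
print(f"top region {top.chrom}:{top.start:,}-{top.end:,} "
      f"peak ΔSNP-index {top.peak_delta:.2f}")

seg = b.chi_square_segregation((135, 44), (3, 1))
print(f"chi2={seg.chi2:.3f} df={seg.df} p={seg.p_value:.3f}")
```

prints

```
206 simulated variant sites
725 significant windows, 77 regions
top region chr1:3,805,000-3,870,000 peak ΔSNP-index 0.84
chi2=0.017 df=1 p=0.897
```

The top-peak region sits ~1.1 Mb from the true causal position — typical
resolution for single-site 30× windows, where read-sampling noise (sd ≈ 0.1
per site) is comparable to the linkage decay of E[Δ] over a megabase. The
peak Δ of 0.84 exceeds the theoretical ⅔ for the same reason: the maximum
over many noisy windows is upward-biased. The segregation line is the
classic single-gene check: 135:44 observed against 3:1 expected gives
χ² = 0.017, far from rejection.

The same pipeline is available from the shell:

```
bsascan simulate --config sim.yaml --seed 1 --out data/run
bsascan scan data/run.variants.tsv --chrom-lengths lengths.tsv \
    --gff genes.gff3 --seed 2 --out scan/run
bsascan segtest 135 44 --ratio 3:1
```

`scan` writes per-site, window and region TSVs (window and region
intervals in 0-based half-open/BED convention), a BED file of candidate
regions, and a YAML run manifest with the seed and all parameters.

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` runs the complete
computation end-to-end — simulates a 40-Mb mapping experiment from the
given seed, executes the full scan, reports the top candidate region and
the 3:1 segregation test on stderr — and writes its JSON result file to
`--out`.
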