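# Methods

## Statistical model

### SNP index and ΔSNP index

For one biallelic SNP and one pool, the SNP index is `alt / (ref + alt)`
over the reads covering the site; the ΔSNP index subtracts the wild-type
pool's index from the mutant pool's. The ALT allele is taken to be the
mutagen-induced allele throughout: the reference genome is assumed to be
the non-mutagenized parent of the cross, so in a backcross-derived
population every segregating SNP's alternate base is EMS-induced. The
index is undefined at zero depth and the code refuses to compute it there;
uncovered sites must be removed by the depth filter first, and a site
uncovered in either pool is dropped entirely (Δ needs both indices).

Under the selfed-heterozygote (F2-type) design with a fully penetrant
recessive phenotype, the expected ΔSNP index at a site with recombination
fraction `r` to the causal locus is

```
E[index_mut] = 1 − r          (mutant bulk: all aa)
E[index_wt]  = ⅓ + r/3        (wild-type bulk: 1 AA : 2 Aa)
E[Δ]         = ⅔ − (4/3) r
```

so Δ runs from ⅔ at full linkage to 0 at `r = ½`. A pure backcross (1:1)
design is deliberately out of scope; the design type is validated and
anything but `F2_SELFED` is rejected.

### Sliding windows

Windows of `size` bp advance by `step` bp from coordinate 0 of each
chromosome; the final windows are clipped to the chromosome end rather
than dropped, so the tiling is deterministic and covers every base. A
1-based site position `p` belongs to the 0-based half-open window `[a, b)`
iff `a ≤ p − 1 < b`. The window statistic is the *unweighted* arithmetic
mean of member Δ values — no depth weighting, no kernel — and empty
windows carry a missing mean. Defaults are 25 kb / 5 kb, the standard
geometry for this kind of scan; each interior site then contributes to
exactly five windows.

### Monte-Carlo null bands

The null hypothesis is no linkage: the mutant allele sits at frequency ½
in the gamete pool of both bulks. Two sampling layers separate that from
an observed window mean, and the null replay reproduces both:

1. **Bulk composition.** Per replicate, one frequency per pool per window:
   `f = X / (2N)` with `X ~ Binomial(2N, ½)` for a bulk of `N` lines.
   Binomial rather than hypergeometric sampling of gametes is exact for an
   unbounded F2 population and errs only at O(1/N²). The draw is shared by
   every site in the window: a 25-kb window spans ≪ 1 cM, so its sites are
   effectively completely linked, and resampling them independently would
   understate the variance of the window mean.
2. **Read sampling.** Per site, `alt ~ Binomial(D, f)` at the *observed*
   depth `D` of that site in that pool, so the band automatically widens
   in thin regions. Sequencing error is not added in the null (its effect
   at f = ½ is symmetric and second-order).

For a single site this gives `Var(Δ̄) ≈ ¼(1/(2N_mut) + 1/D_mut) +
¼(1/(2N_wt) + 1/D_wt)` — the analytic approximation used as an
independent oracle in the tests (≈ 0.148 at 30×/30× and 44/50-line bulks).

Bands are empirical nearest-rank quantiles of the simulated window means
(`ceil(q·n)`-th order statistic; no interpolation, hence platform-exact
reproducibility): α/2 and 1−α/2 for a two-sided band, or an upper 1−α
bound with a −∞ floor for one-sided peak calls. Significance is
*pointwise* — window mean strictly outside its own band — matching the
single-window criterion such scans conventionally report; a genome-wide
max-statistic band is available behind `genome_wide=True` but is off by
default. Each window receives a child random stream spawned from the band
seed, so flags are deterministic and order-independent. Empty windows are
reported but never flagged.

### Candidate regions

Significant windows on one chromosome merge when they overlap or lie
within `max_gap` bp (default 0: adjacent-or-overlapping only). A region's
peak is the member window with the largest mean Δ, ties broken toward the
smaller start — the peak is reported at window resolution, not an
interpolated summit. Gene overlap converts GFF3's 1-based inclusive
intervals to 0-based half-open before intersecting, so a gene ending
exactly at a region boundary does not overlap it.

### Segregation test

`chi2 = Σ (obs − exp)² / exp` against expected counts `total ·
ratio_i / Σratio`, df = classes − 1, upper-tail χ² p-value. No continuity
correction by default — for the canonical 135:44 vs 3:1 example the
uncorrected statistic reproduces the conventionally printed 0.017, while
the Yates-corrected value would be ≈ 0.0006 — but the correction is
available behind a flag.

## The simulator: what it emulates and what it does not

The generator states the emulated experiment once, as defaults:
a BC1F2-type population from selfing a heterozygous backcross F1;
bulks of 44 mutant-phenotype and 50 wild-type-phenotype lines;
EMS variants at density 1/50 kb with 95% G:C→A:T transitions;
a uniform genetic map of 4 cM/Mb (rice-typical); mean pool depth λ = 30
with per-read miscall rate ε = 0.002. Variant density and depth are not
quantities the emulated study reports, so these are stated assumptions —
chosen so that 25-kb windows average ~0.5 sites (smoothing matters) and
depth noise is realistic for pooled resequencing.

Individuals are drawn (capped at 10⁶ attempts) until both bulks fill;
the mutant bulk takes mutant-phenotype (aa) individuals, the wild-type
bulk the others, whose causal genotypes are 1 AA : 2 Aa in expectation.
Marker genotypes then follow a **star topology**: each gamete's allele at
a marker equals its causal-locus allele flipped with probability `r`
(Haldane), independently per marker; markers on other chromosomes assort
freely. Given the drawn bulk composition this makes per-site allele
counts independent binomials, which is how they are sampled. Consequences
a user should know:

- per-individual draws are exchangeable, so given bulk composition the
  per-site frequency *distributions* are exact for the star model;
- cross-site *correlation* of frequencies (shared recombination
  breakpoints along a real chromosome) is not reproduced — adjacent sites'
  bulk frequencies fluctuate independently. This leaves each site's
  marginal sampling distribution (what the per-window statistics see)
  correct, but real scans would show smoother site-to-site profiles;
- crossover interference, polygenic effects, incomplete penetrance,
  mapping bias and indels are not modelled.

A green simulation-based test therefore establishes the statistics'
behaviour under the stated marginal model, not under a full meiosis.

All randomness derives from the single `SimConfig.seed` through named
`SeedSequence` child streams (variant placement, population, reads), so a
fixed seed reproduces datasets byte-for-byte.

## Numerical and design choices

- Window means are computed by sorted-position binary search, but the sum
  over a window's member Δ values is taken over the contiguous slice in
  position order, so results are bit-identical to a brute-force
  per-window scan (verified exhaustively in the tests).
- Default filters: depth ≥ 8 in both pools; site quality ≥ 20 when the
  input carries a quality score (the TSV dialect may not). Common pooled
  resequencing practice; both are configuration, not science. An optional
  SNP-index floor (drop sites below a threshold index in both pools,
  as some published protocols do) exists but is off by default.
- `n_sims` defaults to 10,000 per window and is bounded below at 100;
  at α = 0.01 at least ~2,000 replicates are advisable for a stable
  upper quantile.
- Positions are 1-based internally (VCF/GFF3 convention); every exported
  interval (window, region, BED) is 0-based half-open. The off-by-one
  contracts are pinned by tests at the boundaries.

## Known limitations

- Localization accuracy at the default stated world is bounded by read
  noise: with ~0.5 sites per 25-kb window at 30×, the per-window noise
  sd (~0.1) is comparable to the linkage decay of E[Δ] across ±1–2 Mb,
  so the highest-peak region frequently sits 1–3 Mb from the causal
  locus even though the surrounding signal is unambiguous. Deeper
  sequencing, denser variants or wider smoothing would tighten this;
  all three are configuration.
- Pointwise α = 0.01 on thousands of windows flags ~1% of null windows
  by construction; candidate regions should be read alongside the
  genome-wide option or the peak's magnitude.
- The Monte-Carlo band is one faithful realization of a no-linkage null;
  closed-form band approximations from the BSA-seq literature are used
  only as test oracles, never as the significance path.
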