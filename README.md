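# herdsweep

Selection-signature scans for pedigreed, SNP-array-genotyped livestock
populations — built for the question "which genomic regions changed under
the last few decades of artificial selection?", the situation of modern
dairy and beef breeds where a handful of AI sires fathers most of each
cohort and genome-wide autozygosity rises steadily.

It implements four complementary analyses on one marker panel:

1. **ROH and locus autozygosity.**  Runs of homozygosity (≥ 50 consecutive
   homozygous SNPs spanning > 1 Mb) per animal, and per-SNP locus
   autozygosity `F_L = (Σ_l roh_l) / N` — the fraction of animals whose ROH
   cover the SNP.  ROH-based (`f_roh`) and pedigree (Wright's `F`, tabular
   method) inbreeding coefficients come with it.
2. **Change of autozygosity (ΔF_L).**  Per SNP, logistic regression of ROH
   state on birth year, `logit P(roh_l = 1) = α + βb`, with experiment-wise
   5% / 1% significance thresholds from 1,000 permutations of birth year and
   merging of significant SNPs into candidate regions.
3. **Most-frequent-haplotype analyses.**  50-SNP sliding windows over phased
   haplotypes; carriage of each window's most frequent haplotype regressed
   on birth year (same permutation machinery), and the additive GLM
   `y = μ + βG + e` of trait PTAs on copies `G ∈ {0,1,2}` of the top
   haplotype (all other haplotypes set to 0).
4. **Extended-haplotype statistics.**  iHS — standardised
   `ln(iHH_ancestral / iHH_derived)` per core SNP, binned by derived-allele
   frequency, with the supported-peak filter (|iHS| > 3 plus ≥ 10 neighbours
   > 2 within 0.5 Mb); and Rsb — standardised `ln(iES_ancestral /
   iES_contemporary)` between an old and a recent birth cohort, for nearly
   fixed sweeps.

A forward-in-time breeding simulator (`herdsweep.synthetic_data`) generates
pedigreed populations with half-sib family structure, birth years, trait
values and known selected loci, so every stage can be validated against
ground truth.  Simulated data round-trip through the same files the real
analyses read: VCF, phased VCF, and TSV tables for pedigree, traits and
ancestral alleles.

## Worked example

```python
import numpy as np
import herdsweep as hs

# a 2,280-animal population, 1953-2007, with one selected QTL on chromosome 1
pop = hs.simulate_breeding(hs.sweep_preset(seed=1))

g = hs.qc_filter(pop.genotypes)                 # MAF > 0.01, call rate > 0.8
segs = hs.detect_roh(g)                         # >= 50 SNPs and > 1 Mb
track = hs.locus_autozygosity(segs, g, pop.pedigree)
print(f"mean F_L = {track.fl.mean():.3f}")

cov = hs.coverage_matrix(segs, g)
years = pop.pedigree.birth_years(g.animals)
scan = hs.scan_genome(cov, years, g.markers)
thr = hs.permutation_thresholds(cov, years, n_perm=1000, rng_seed=1)
peak = int(np.nanargmax(np.where(scan.estimable, scan.neg_log10_p, -np.inf)))
print(f"thresholds 5%/1%: {thr.threshold_5pct:.1f} / {thr.threshold_1pct:.1f}")
print(f"peak -log10 p = {scan.neg_log10_p[peak]:.1f} at "
      f"chr{g.markers.chromosome[peak]}:{g.markers.position_bp[peak]:,}")
print(f"true QTL at chr1:{pop.qtl_trajectory(0)['position_bp'].iloc[0]:,}")
```

prints (seed 1):

```
mean F_L = 0.196
thresholds 5%/1%: 2.8 / 3.5
peak -log10 p = 143.7 at chr1:6,481,019
true QTL at chr1:6,256,244
```

Read: background autozygosity averages ~0.20 across the genome; any SNP
whose birth-year trend exceeds −log10 p ≈ 2.8 is genome-wide significant at
the 5% level; the strongest trend in this replicate lands 225 kb from the
simulated selected locus.

The same pipeline runs from the shell on files:

```bash
herdsweep simulate --preset sweep --seed 1 --out simdata/
herdsweep report --genotypes simdata/genotypes.vcf \
    --phased-vcf simdata/haplotypes.vcf --pedigree simdata/pedigree.tsv \
    --traits simdata/traits.tsv --ancestral simdata/ancestral_alleles.tsv \
    --seed 1 --out results/
```

`report` writes per-SNP tracks (F_L, scan, iHS, Rsb), candidate-region
tables, the high-F_L cross-tabulation, optional Manhattan plots and a run
manifest that reproduces the run byte-for-byte.

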