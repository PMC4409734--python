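# Methods

`herdsweep` detects recent directional (artificial) selection in a pedigreed,
SNP-array-genotyped livestock population by tracking how autozygosity and
haplotype frequency change with animal birth year, and by contrasting
extended-haplotype homozygosity within and between birth cohorts.  This note
records the models, the parameter choices that matter, what the bundled
simulator does and does not emulate, and the numerical conventions.

## Study design the package assumes

The target data are a half-century of genotyped animals from one intensively
selected breed: diploid autosomal SNP genotypes (a few tens of thousands of
markers), phased haplotypes for the same panel, a multi-generation pedigree
with birth years, per-SNP ancestral-allele assignments, and per-animal
predicted transmitting abilities (PTAs) for yield traits.  Breeding in such
populations is dominated by artificial insemination: a modest number of elite
sires fathers large paternal half-sib families each year, so favourable
haplotypes both rise in frequency (selection) and spread identically by
descent (inbreeding).  The package's job is to separate locus-specific
selection signals from that genome-wide autozygosity drift.

## Marker QC

SNPs are kept when they are autosomal, have minor allele frequency strictly
above `maf_min` (default 0.01, computed on non-missing calls only) and call
rate strictly above `call_rate_min` (default 0.8).  Genotypes are coded 0/1/2
as counts of `allele_b`; missing calls are a sentinel and are never imputed.
Map coordinates are 1-based bp; written interval files are BED-style 0-based
half-open and say so in their headers.

## Runs of homozygosity and locus autozygosity

An ROH is a maximal run of consecutive homozygous calls containing at least
`min_snps` SNPs (default 50) **and** spanning more than `min_length_bp`
(default 1 Mb); both clauses bind jointly and heterozygote tolerance is zero.
Missing calls break a run by default; an optional bridge policy
(`missing_policy="skip"`, `bridge_k`) tolerates up to k consecutive missing
calls without counting them, because array data have sporadic missingness.
Segment length is the distance between its first and last SNP, not padded to
neighbouring midpoints, so coverage is unambiguous.

Locus autozygosity at SNP l is F_L(l) = (number of animals whose ROH cover
l) / N, with N the number of genotyped animals in the input (never a fixed
constant).  Per-animal genomic inbreeding f_roh divides total ROH length by
the SNP-spanned (mapped) autosome length — the panel defines what is
observable.  Pedigree inbreeding is Wright's F by the tabular
additive-relationship method, F_x = a(sire, dam)/2, with unknown parents
treated as unrelated founders.  The dense tabular matrix is exact and fast to
a few thousand animals; very large national pedigrees would need the sparse
recursive algorithm, which is out of scope here.

## Temporal change of autozygosity (the birth-year scan)

Each SNP's 0/1 coverage status is modelled as
logit P(covered) = alpha + beta·b with b the animal's birth year; beta > 0
means autozygosity at the locus increased over the study period.  Birth year
is centred before fitting (numerical stability; alpha is reported back on the
original scale).  Estimation is maximum likelihood by Newton/IRLS, vectorised
across loci because all loci share the same two-column design; the per-locus
2x2 Newton systems are solved in closed form.  Implementation detail that
matters for budgets: the iterations run in float32 on a locus-major copy
(the computation is memory-bandwidth-bound at genome scale), then a float64
Newton polish drives every estimable locus to |step| < 1e-10, so reported
statistics are full precision.  Permutation rescans skip the polish and stay
in float32 end to end: thresholds are empirical percentiles and the float32
path agrees with the full path to ~1e-6 in -log10 p.  Loci with constant status, fewer than two animals in either
class, or complete separation (|beta| x year-range > 30) are flagged
non-estimable and excluded from thresholds.

p-values are two-sided Wald tests of beta = 0 (cheap enough to recompute
inside a thousand permutation rescans; a per-locus likelihood-ratio test is
available for peak follow-up).  Experiment-wise thresholds shuffle birth
years across animals — preserving the spatial correlation of ROH coverage,
which is the exchangeability the model assumes — rescan the genome, record
the maximum -log10 p, and take the 95th/99th percentiles of `n_perm`
(default 1,000) maxima as the 5% and 1% thresholds.  The permutation seed is
a required, logged parameter.  Candidate regions merge above-threshold SNPs
within `merge_gap_bp` (default 250 kb, chosen below the 0.5 Mb reporting
floor) and discard regions at or below `min_size_bp` (default 0.5 Mb).

One calibration subtlety, verified empirically: a threshold estimated by
permutation conditions on the observed coverage matrix, so fresh null
datasets exceed it slightly more often than the nominal 5% (about 6% in our
checks).  This is a property of conditional thresholds generally, not of the
implementation.

## Haplotype windows, birth-year trend, trait GLM

Phased haplotypes are catalogued in sliding windows of `window_snps`
(default 50) with step `step_snps` (default 1; windows never span
chromosomes).  Haplotype identity is exact string equality; an animal with
any missing phased allele in a window is dropped from that window's
catalogue.  Ties for the most frequent haplotype break lexicographically and
are flagged.

The birth-year trend per window reuses the logistic machinery with response
"carries the most frequent haplotype" (G >= 1) — carriage rather than copy
count keeps the response binary; a count-based option exists.  The trait
association fits y = mu + beta·G + e per window by least squares, where y is
the animal's PTA, G in {0,1,2} counts copies of the most frequent haplotype
and every other haplotype's effect is set to 0.  Experiment-wise thresholds
permute trait values across animals (1% level by default).  Both analyses
are marginal per window; no multi-window model is fitted.

beta-hat estimates the effect of carrying the top *haplotype string*, which
is an eroded tag of any causal allele inside the window: recombination moves
allele copies onto other strings, attenuating beta-hat relative to the
causal effect by roughly (1-x)/(1-g) within a cohort (x the allele
frequency, g the tag frequency).  On the simulator's sweep scenario this
attenuation is about 7% — visible in the parameter-recovery check and
documented there; it is a property of the estimand, not an estimation error.

## Extended haplotype homozygosity: EHH, iHS

EHH at distance x from a core SNP is the probability that two random carrier
haplotypes are identical over the whole stretch from the core to x, computed
as sum_h C(n_h,2)/C(n,2) over distinct extended haplotypes.  Haplotypes
leave the risk set at their first missing allele.  iHH integrates the EHH
curve against physical distance (trapezoid rule) outward to the first point
where EHH < `truncation_ehh` (default 0.05, the usual convention), the
bracket edge (`max_bracket_bp`, default 5 Mb), or a map gap larger than
`gap_bp` (default 500 kb), whichever comes first.  Integration is over bp —
the array panel carries no genetic map; a cM map can be supplied by scaling
positions.

iHS is ln(iHH_ancestral / iHH_derived) standardised to mean 0, variance 1
(ddof = 1) within 20 equal-width derived-allele-frequency bins over [0, 1];
cores need a known ancestral allele and MAF >= 0.03.  Cores with fewer than
two carriers of either allele, zero iHH, or a bin with fewer than
`min_bin_count` scored cores are flagged and left unstandardised.  Negative
iHS marks unusually long *derived*-allele haplotypes (recent selection on
the derived allele).  The false-positive filter retains cores with
|iHS| > 3 supported by at least 10 other scored SNPs with |iHS| > 2 within
0.5 Mb; retained cores and their supports merge into regions (cores within
1 Mb share a region).

## Between-cohort contrast: EHHS, iES, Rsb

Site-EHH (EHHS) is the same homozygosity decay computed over *all*
haplotypes of a group, anchored at the SNP irrespective of its allele (so
EHHS(0) = 1 by construction).  iES integrates EHHS per cohort; the statistic
is ln(iES_ancestral / iES_contemporary), standardised genome-wide (single
bin).  It is exactly antisymmetric under swapping the cohorts and
identically zero when they hold identical haplotypes — both are tested.
The cohort split takes the `n_ancestral` oldest genotyped animals born
before a cutoff year, and a seeded equal-size random sample from a recent
birth-year window.  Scored SNPs need pooled MAF >= 0.02, a lower bar than
iHS because the contrast targets nearly fixed alleles.  The sign convention
follows the definition: a sweep concentrated in the contemporary cohort
lengthens contemporary homozygosity and drives the ratio *negative*; both
signs are reported and no interpretive flip is applied.  Candidate windows
(200 kb, >= 20 SNPs with |Rsb| >= 2 including one >= 3, overlaps merged)
follow the region-reporting convention; because the statistic is regional by
construction, sweep recovery is judged at this 200-kb resolution in the
acceptance suite.

## The forward breeding simulator

Ground truth comes from a forward-in-time simulator, not a coalescent:
the signal of interest is five decades of sire selection in an
overlapping-generation pedigree, which forward breeding reproduces directly.

*Founders.*  Each founder gamete is a mosaic of `n_ancestral_haplotypes`
template haplotypes (each template an independent Bernoulli(f_j) sequence
with f_j ~ U(0.1, 0.9)); template switches are a Poisson process along the
genetic map at `mosaic_switch_rate` per Morgan.  The mosaics induce
block-wise LD, which is what makes ROH and EHH non-degenerate.  The
ancestral allele at each SNP is the allele carried by the majority of
templates, exported to the ancestral-allele table.

*Breeding.*  Each year, males and females of breeding age (2-10 years) are
eligible; candidate sires are ranked by trait value and `n_sires_per_year`
sires are drawn at random from the top `sire_selection_fraction` (dams are
drawn at random).  Every offspring picks its sire uniformly among the year's
sires — large paternal half-sib families — and gametes recombine with
crossovers as a Poisson process (Haldane, no interference, uniform
`recombination_rate` = 1 cM/Mb).  Trait value = sum of QTL allele counts x
effects + Normal(0, `trait_noise_sd`); setting `heritability_target`
rescales the noise against founder genetic variance instead.  A QTL can be
seeded on a fixed number of founder templates (`origin_templates`), which
controls both its initial frequency and how cleanly a 50-SNP haplotype tags
it.  Selection can be switched on mid-study (`selection_start_year`) to
model the onset of systematic quantitative-genetic selection.

*Scale.*  The default preset compresses the genome to 2 chromosomes x 1,000
SNPs x 12.5 Mb (12.5 kb spacing), 40 animals/year over 1953-2007, 80
founders, 10 sires/year from the top half.  Two interactions drove the
compressed map, explored before the preset was frozen: the 50-SNP ROH rule
sets the minimum detectable segment at 50 x spacing, and at 100 kb spacing
that is ~4.9 Mb — so broad that the birth-year scan cannot localise a sweep
to 1 Mb; and a very small elite (3 extreme-top sires/year) fixes a strongly
selected allele within a decade and throws off drift peaks that can outrank
the true locus.  With 12.5 kb spacing the minimum ROH span is 0.625 Mb
(the > 1 Mb clause then binds at 80 SNPs), and with 10 sires drawn from the
top half the favoured allele rises from ~0.06 to near fixation across the
five decades — an ongoing, multi-decade partial sweep, which is the regime
the method targets.  Mean F_L on this preset is ~0.2 with a rising
birth-year trend, the same order as real intensively selected dairy panels.

The cohort-contrast preset (`recent_sweep_preset`) differs deliberately:
4 chromosomes x 500 SNPs (three neutral), 48 templates with 1 cM blocks,
80 animals/year with 40 sires, selection from 1965.  The between-cohort
statistic compares homozygosity *turnover* between old and recent cohorts,
so it needs the oldest cohort unswept, a background not dominated by
drift turnover (hence the larger Ne and founder diversity), and enough
neutral genome that the extreme 1% tail is defined by background rather
than by the sweep's own flanks.

*What the simulator does not emulate.*  No mutation; no genotyping error
beyond optional uniform missingness; a single selected trait with fully
additive loci (PTAs are the trait values themselves — no BLUP evaluation);
uniform recombination with no hotspots or interference; evenly spaced
markers; random mating apart from sire truncation.  Passing tests therefore
show the statistics behave correctly under half-sib pedigree structure,
drift and truncation selection — they do not certify behaviour under array
ascertainment bias, phasing error (haplotypes are phase-known), or
population admixture.

## Numerical conventions and degenerate inputs

QC thresholds are strict inequalities.  MAF uses non-missing calls only.
Logistic fits report NaN (flagged) rather than raising for degenerate loci.
The EHH group-splitting step compacts labels with a bincount (O(n) per SNP,
no sort).  Percentiles use the linear-interpolation default of the numeric
stack.  Ties for the most frequent haplotype break toward the
lexicographically smallest string, deterministically.  Seeds: every
stochastic entry point (simulation, permutations, cohort sampling) takes an
explicit seed and is reproducible byte-for-byte from (config, seed).

## Known limitations

- Wald p-values can be anticonservative at small cohort sizes; the
  permutation thresholds, not single-locus p-values, carry inference.
- The trait GLM estimates a haplotype-tag effect; see the attenuation note.
- The dense tabular relationship matrix is quadratic in pedigree size.
- The conditional permutation threshold under-covers fresh datasets by about
  one percentage point at the 5% level (measured; see above).
- Problem sizes in the test-suite and acceptance runs (replicate counts,
  permutation counts at 150-1,000, window steps of 10-25 SNPs) are the
  package's own desk-scale choices and are stated in the tests that use them.
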