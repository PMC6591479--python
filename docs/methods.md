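# Methods

`popsel` re-implements, as a tested library and pipeline, the analytic
machinery of a genome-wide population-structure and positive-selection
study on SNP-array cohorts: quality control and LD pruning, kinship and
inbreeding screening, PCA with projection of held-out samples, outgroup
f3 drift sharing, per-SNP Weir–Cockerham F_ST, XP-EHH haplotype scans,
sliding-window Tajima's D, and a composite candidate-region caller with
cross-comparison overlap. Because such studies hinge on array data that
cannot be bundled, every stage is validated on synthetic cohorts with
analytic ground truth; this note records the models, the defaults, and
the choices made where the design was genuinely open.

## Statistical procedures

**QC cascade.** Filters run in the order sample missingness → SNP
missingness → minor-allele frequency → Hardy–Weinberg, with MAF and HWE
computed on the samples retained by the first step (the order matters and
is documented because downstream frequencies depend on the retained
sample set). Defaults: missingness > 0.10 (either axis) removed, MAF
< 0.01 removed, HWE exact p < 1e-4 removed. The HWE test is the plain
exact conditional test on the heterozygote count (two-sided by
probability mass, no mid-p correction), evaluated by a numerically stable
log-space recurrence; it is tested against full enumeration. HWE is
tested on the pooled sample by default with a flag to stratify by
population (pooling is the common tool default; stratification avoids
Wahlund-driven rejections in mixed cohorts).

**LD pruning** mirrors the `indep-pairwise` procedure: windows of 50
SNPs advancing by 5, dropping one member of any pair with squared
genotype-dosage correlation above 0.5. r² is composite (dosage)
correlation, not haplotype r², because pruning precedes phasing in the
emulated workflow. When a pair exceeds the threshold the lower-MAF member
is dropped; ties drop the later-positioned one.

**Kinship** uses the KING-robust between-family estimator,
φ = (N_both-het − 2·N_opposite-hom) / (N_het,i + N_het,j), over pairwise
jointly observed SNPs; it needs no allele frequencies and is therefore
robust to exactly the structure the package is meant to study. Pairs with
fewer than 100 joint SNPs are reported undefined. **Inbreeding** is the
method-of-moments F = (O_hom − E_hom)/(L − E_hom) with the 2n/(2n−1)
small-sample correction and cohort-estimated frequencies; negative values
are clamped to zero (flagged), as such values ordinarily reflect sampling
error. Default exclusion thresholds are the emulated study's printed
values: kinship > 0.0084 (one member per pair, dropping the higher
missingness, ties by later sample id) and F ≥ 0.0156 = 1/64, the expected
inbreeding of a second-cousin mating's offspring. The 0.0084 cutoff is
preserved as printed even though it matches neither the second-degree
kinship expectation (0.125) nor the conventional KING second-degree
inference bound (0.0884); both thresholds are configurable. Note that
these thresholds presume an outbred cohort: in a sample drawn from a
small simulated population, background cryptic relatedness sits far above
0.0084 and a screen at that level empties the cohort, so the bundled
demo pipeline raises the cutoffs to duplicate scale.

**PCA** normalizes each variant by centering on its mean observed dosage
and scaling by sqrt(p̂(1−p̂)) with the shrunk estimate
p̂ = (1 + Σdosage)/(2 + 2·n_obs); missing entries contribute zero after
centering. Components come from the SVD of the normalized matrix; signs
are fixed by making each component's largest-magnitude loading positive.
Projection applies the *model's* normalization to new samples over the
shared variant subset and divides by the shared-variant fraction, so a
fitted sample projects onto its own score and half-masked panels stay on
scale. Group separation on scores is tested by one-way ANOVA per
component.

**Outgroup f3(O; A, B)** is the mean over SNPs of
(o − p_A)(o − p_B) − o(1−o)/(n_O − 1), the last term correcting for the
finite outgroup sample (counts, not just frequencies, are required).
Standard errors use a weighted delete-one-block jackknife over contiguous
SNP-count blocks (default 500 SNPs); fixed SNP-count blocks are used
because no genetic map is in scope. Pseudo-haploid outgroup calls simply
halve n_O; the estimator takes counts agnostically.

**Weir–Cockerham F_ST** computes the 1984 two-population variance
components a (among populations), b (among individuals within), and
c (within individuals) per SNP with per-SNP observed sample sizes,
heterozygosity-aware. Per-SNP estimates θ = a/(a+b+c) are clamped to zero
for reporting when negative; pairwise population means are the ratio of
sums Σa / Σ(a+b+c) over unclamped components — never a mean of per-SNP
ratios. SNPs monomorphic across both populations are excluded from the
mean.

**EHH / XP-EHH.** EHH at distance d from a core SNP is the probability
that two haplotypes drawn from the set are identical at every SNP
strictly between the core and d inclusive (Σ C(k_g,2)/C(n,2) over
identity groups); it is 1 at the core and non-increasing outward. iHH
integrates the decay curve by trapezoid over *physical* distance — the
dialect appropriate to array data without a genetic map. For XP-EHH, iHH
is computed per population over all of that population's haplotypes (no
core-allele partition), and the integration boundary is where the
*pooled* two-population EHH falls below the cutoff, so both populations
integrate over identical intervals and the ratio stays comparable.
Defaults: cutoff 0.05, maximum extension 1 Mb, maximum inter-SNP gap
200 kb (the conventional scan-tool defaults; all configurable). Raw
scores ln(iHH_A/iHH_B) are standardized genome-wide (not
frequency-binned — frequency binning is an iHS convention); cores with
zero iHH in either population are flagged and excluded from
standardization. Positive scores mean longer haplotypes — a recent-sweep
signal — in the first-named population.

**Tajima's D** is computed in sliding windows (default 100 kb advancing
by 10 kb) from S and π with the 1989 normalization constants; windows
with S < 2 or zero variance are skipped with a recorded reason, and any
window containing a missing genotype call is skipped outright (the
stricter reading of "windows containing missing variants were ignored";
a flag restores the untyped-region reading). π comes from haplotypes when
phased data are present, else from allele counts with the unbiased
n/(n−1) pairwise formula.

**Candidate regions.** Empirical p-values are rank/N with rank 1 the most
extreme in the stated direction and ties sharing the smallest rank; a
degenerate all-equal track yields p = 1 everywhere. The composite caller
takes the top 0.1% of the standardized XP-EHH distribution (the tail
indicating longer haplotypes in the population of interest), clusters
outliers per chromosome by single linkage with a 200 kb maximum gap (the
grouping rule is otherwise unspecified in the emulated procedure; the gap
is prominent and configurable), keeps clusters of ≥ 2 SNPs, and retains a
cluster span only if at least one SNP *anywhere in the span* — not only
outlier SNPs — has F_ST empirical p < 0.01. Tajima regions merge
overlapping or book-ended significant windows (empirical p < 0.01,
ascending D), so k consecutive windows give a region of
window + (k−1)·step bp. Overlap between labeled region lists merges
intersecting regions (≥ 1 bp, same chromosome) into connected components
and reports Venn-cell counts per label set.

## Synthetic cohorts

**Structured genotypes** follow the Balding–Nichols model: ancestral
frequencies uniform on (0.05, 0.95), population frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target F_ST (F = 0 uses p
directly), genotypes Binomial(2, p_pop). The closed-form expectation
makes F_ST recovery a sharp test: the ratio-of-sums estimator recovers
F = 0.2 within ±0.02 at 5,000 SNPs and 100 samples per population.

**Sweep cohorts** come from a discrete-generation Wright–Fisher forward
simulation with Poisson crossovers on the physical map (no gene
conversion), because hitchhiking must actually shape haplotypes. The
simulated population holds `pop_size` (default 500) diploids per
population — deliberately larger than the sampled cohort, since a sample
drawn from a population of its own size accumulates drift-driven
homozygosity tracts that mimic sweeps. The default recombination rate is
population-scaled: 2e-7 per bp per generation, chosen so that
ρ = 4Nr per bp at N = 500 matches a human-like population (N_e ≈ 10⁴ at
~1e-8), giving sweep footprints of realistic extent relative to the
5 Mb default chromosome. Founder haplotypes are in linkage equilibrium
with a neutral site-frequency spectrum (allele counts k drawn with
probability ∝ 1/k), and a mutation–drift renewal process re-seeds any
column that fixes or is lost as a fresh singleton at its (uniform-random)
coordinate — an infinite-sites process with recycled positions. Without
this renewal a 200-generation mutation-free forward phase purges rare
variants and pushes Tajima's D to ≈ +2 genome-wide; with it, neutral
windows average D ≈ 0.02.

The beneficial allele starts as ~2 copies (`start_freq` 0.002 at the
default population size): a single-origin hard sweep up to its immediate
duplication. Selection is multiplicative, (1+s) per copy, only in the
target population; the run is rejection-sampled (cap 100 attempts) until
the allele reaches `final_freq_min`, which conditions trajectories on
completion exactly as a completed-sweep test case requires — attempts in
which the allele is lost abort immediately, so the cap is cheap. The
neutral partner population evolves once under identical demography
without selection. The returned ground-truth `sweep_interval` is the
diversity trough: the contiguous run around the selected site where the
25-SNP moving average of carrier heterozygosity falls below half the
chromosome median, measured on the full pre-sampling population.

Detection tests use 10,000–20,000 SNPs over 5 Mb. Density matters
because the composite rule is quantile-based: with only a few thousand
SNPs the top-0.1% tail holds a handful of SNPs, cluster spans shrink to a
few kb, and the F_ST gate fails by discreteness rather than by signal.
The emulated study likewise ran its selection scans on a cohort merged
with a dense external reference panel rather than on the raw array.

**Pedigree cohorts** are gene-dropped at unlinked loci (kinship
estimators assume independent markers): founders draw alleles at supplied
or uniform(0.1, 0.9) frequencies; children inherit one randomly chosen
allele per parent per locus. Expected kinship and inbreeding come from
the standard tabular path-counting recursion, giving exact targets
(parent–offspring φ = 1/4, second-cousin-offspring F = 1/64 = 0.015625).
Inbreeding-recovery tests embed the inbred family among ~200 unrelated
founders: estimating allele frequencies from the cohort itself biases F
down by roughly 1/(2n), which would halve the second-cousin signal in a
few-dozen-sample cohort but is negligible at the few-hundred-sample
scale of the emulated study.

**Drift trees** evolve allele frequencies root-to-leaf with a
Balding–Nichols perturbation per branch (newick branch lengths are the
drift amounts; one designated outgroup leaf), then sample leaves
binomially as diploid counts. Shared branch length orders expected
outgroup f3, which the f3 tests assert across seeds.

### What the generators do not emulate

No realistic human demography (growth, bottlenecks, migration), no gene
conversion, no genotyping error, no ancient-DNA damage or pseudo-haploid
sampling, no ascertainment bias beyond the uniform ancestral-frequency
draw, and array-like marker spacing is uniform rather than
gene-centric. Passing tests therefore demonstrate that the estimators
and the calling procedure are implemented correctly and recover truth
under their own model assumptions — not that the procedure is powerful or
calibrated on real human data.

## Numerical and procedural details

- Coordinates are 1-based inclusive everywhere (VCF convention); BED
  output converts to 0-based half-open at the writer only.
- Every generator takes a mandatory integer seed; there is no hidden
  global random state, and identical spec + seed reproduces output
  byte-identically (the forward kernels use a private seeded generator).
- The EHH partition refinement and the Wright–Fisher generation step are
  compiled kernels (numba); the partition relabel is a counting pass in
  first-occurrence order, O(n) per SNP step.
- The HWE exact test sums probabilities ≤ the observed configuration's
  with a 1 + 1e-12 relative tolerance, the standard guard against
  floating-point ties.
- Jackknife SEs use the weighted (unequal block size) formulation, so the
  trailing short block is handled exactly.
- Degenerate inputs: monomorphic sites give HWE p = 1 and are skipped by
  the inbreeding estimator; SNPs monomorphic in both populations have
  undefined F_ST and are excluded from means; an all-equal statistic
  track gets empirical p = 1 everywhere; an empty outlier set yields an
  empty region list, not an error; QC that would remove every variant
  raises instead of returning an empty success.

## Problem sizes in the test suite

Unit and property tests run on cohorts of 40–200 samples and 300–20,000
variants; the end-to-end sweep-detection check uses 25 seeded replicates
of a 100 + 100-diploid cohort at 20,000 SNPs over 5 Mb with s = 0.05.
These sizes were chosen so the full suite exercises every stage at
meaningful scale while remaining a desk-scale run.
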