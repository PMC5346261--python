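# Methods

## Data model and conventions

All coordinates are 0-based half-open internally; VCF positions are
converted on read and BED output keeps the 0-based convention. A CpG is
identified as `chrom:pos` with `pos` the position of the C. Phased
counts are tabular: one row per CpG × sample × phasing SNP with
methylated/unmethylated read counts for haplotypes A and B (the
sample's first and second phased haplotype). Orientation with respect
to the phasing SNP's reference/alternative allele is recovered from the
haplotype matrix only where a test needs it (the allele-pooled ASM
test); the genotype-independent test never needs it. A CpG within
500 bp of several heterozygous SNPs yields one record per CpG–SNP pair;
per-CpG summaries take the minimum q over a CpG's pairs, and the raw
per-pair values are always retained so alternative roll-ups can be
recomputed. Samples with missing or unphased genotypes at a pair are
excluded from that pair rather than aborting the scan.

Filtering rules applied before testing:

* **Depth:** a phased record is used only when both alleles carry at
  least 5 reads. The filter is idempotent and monotone in the
  threshold.
* **Strand:** at a C/T SNP only reverse-strand reads are usable (the
  bisulfite conversion of unmethylated C to T collides with the SNP
  alleles on the forward strand); at a G/A SNP only forward-strand
  reads; all other allele pairs sum both strands.
* **CpH sites:** retained when interrogated in ≥ 50 individuals, with
  ≥ 25 individuals showing methylation > 0, and no SNP overlapping the
  dinucleotide (pos and pos+1 on +, pos and pos−1 on −).

## The allelic tests

**ASM.** Reads are pooled across samples by the phasing SNP's
reference/alternative allele and the pooled 2×2 table is tested with a
two-sided Fisher's exact test: the p-value sums hypergeometric point
probabilities at most (1 + 1e-7)× that of the observed table, margins
fixed. The test is implemented as a vectorised enumeration over the
whole support on a log-gamma hypergeometric kernel (exact to ~1e-14
relative); the unit tests cross-check it against both scipy's
implementation and an exact integer-arithmetic enumeration, exhaustively
for every table with total ≤ 40. Row order (ref, alt) does not affect
the two-sided p.

**GIT.** Per sample, the allele with the greater methylated fraction
is labelled *high* (fractions compared by cross-multiplication, so the
comparison is exact in integers); exact ties are broken by a seeded
fair coin and flagged. Reads are then pooled over high and low alleles
across samples. Because sorting selects each sample's maximum, the
pooled high row is biased upward under the null — the naive one-sided
Fisher tail on the sorted pooled table rejects essentially every CpG at
any realistic cohort size (measured: 100% of 2000 null CpGs at
α = 0.05, 50 samples, 30× per allele). The corrected test treats the
selection per sample, where it actually happens:

* For sample *i* with observed high/low depths (n_hi, n_lo) and total
  methylated count K_i, the null law of the high-allele methylated
  count X_i is hypergeometric with those margins, conditioned on the
  selection event that was actually observed — the strict-inequality
  set E_i = {X_i·n_lo > (K_i−X_i)·n_hi} when the sample had a strict
  winner, or the tie set when the two fractions were equal (a tie
  carries no selection bias; the assignment was a fair coin).
* Samples with a zero-depth allele, or an empty conditioning event,
  are uninformative and drop out of the statistic.
* The per-sample conditional distributions are convolved and the
  one-sided p-value is the tail probability of the observed pooled
  high-row methylated count under the convolution.

For a single contributing sample this reduces to the closed form
P(X ≥ x_obs and X ∈ E)/P(E) on the 2×2 table, which is also exposed
directly (`git_table_test`); the sorted table [[3,0],[0,3]] gives
exactly 0.1. Ties in E are excluded (the selection inequality is
strict), and the numerator is restricted to E so the quantity is a
proper conditional probability. The per-sample construction is what
makes the test calibrated for cohorts: the selection bias grows with
the number of sorted samples, and conditioning the pooled table as a
whole removes only one sample's worth of it. Measured on 2000 null
CpGs (binomial reads, μ = 0.5, 30× per allele, 50 samples) the
corrected test rejects 4.1% at α = 0.05.

**ASH.** Allelic ChIP reads at a heterozygous SNP are tested with a
two-sided exact binomial test against 0.5. The allelic ratio reported
alongside is 0.5 − (fraction of ChIP reads on the allele), so positive
values mean depletion. Histone counts map onto a CpG either through
all SNPs within 500 bp (phase-resolved, used with the GIT) or through
the CpG's own phasing SNP only (used with ASM).

**mQTL.** Per-sample total methylation fraction (both alleles, ≥ 5
reads total, mirroring the 5× site-coverage rule) regressed on additive
dose for all SNPs with MAF ≥ 0.05 within 250 kb; slope t-test with
n−2 df; no covariates (a covariate hook can be added at the interface;
the default model is the simple linear regression behind standard
matrix-QTL scans). Methylation is used untransformed. A constant
response is reported as slope 0, p 1; a constant dose or < 3 complete
samples yields no test.

**Multiple testing.** Step-up Benjamini–Hochberg with monotonisation,
computed within each test family per dataset (all ASM pairs together,
all mQTL pairs together, all GIT pairs together). Classification
precedence is AS-genetic (ASM q < 0.1) → NAS-genetic (mQTL q < 0.1) →
epigenetic (GIT q < 0.01) → none; missing tests count as
non-significant and are flagged. A CpG with ASM q ≥ 0.1, mQTL q < 0.1
and GIT q < 0.01 is NAS-genetic under this precedence; the raw
q-values are kept in the output so other roll-ups remain computable.

## Expression and histone linkage

Allelic methylation is methylated/(methylated+unmethylated) per allele.
Allelic expression is the allele-A fraction of haplotype-resolved RNA
reads. Non-allelic expression is asinh(quantile-normalised(gene
reads / library reads)) across samples; quantile normalisation replaces
each sample's values by the across-sample mean order statistics at the
same rank, ties receiving the mean of the reference values they span.
CpG–gene pairs are formed within 50 kb of the TSS; Pearson R with the
two-sided t-test (n−2 df) requires ≥ 3 complete pairs and skips
zero-variance series. In allelic mode each sample contributes up to
two (methylation, expression) points, one per haplotype, with the two
tables assumed phase-consistent (both resolved onto the same phased
haplotypes); samples where the phase cannot be joined are skipped.
Nominal significance (p < 0.05) is used for the correlation analyses;
no FDR is applied in this module by default. The mode comparison
reports median |R| per mode, the two-sample KS statistic on |R|, and
the Pearson concordance of R between modes over pairs significant in
both.

## Region procedures

* **Epigenetic clusters:** among CpGs with ASM and mQTL q ≥ 0.1, the
  k = 500 smallest GIT q (ties broken by position) are chained by
  single linkage with a 2 kb gap threshold; clusters need ≥ 3 members.
  Chaining was chosen over a fixed-anchor window because "within 2 kb"
  constrains gaps, not an absolute span anchor.
* **High-confidence non-genetic windows:** maximal runs of ≥ 15
  consecutive tested CpGs (only CpGs tested in all three analyses
  count toward consecutiveness) where every member has ASM and mQTL
  q ≥ 0.1 and GIT q < 1e-5, and the run's median ln(GIT q) < −10
  (natural log).
* **Positional analysis:** chromatin-state regions ≤ 10 kb whose
  histone signal tracks expression (|R| > 0.4, p < 0.05 across
  samples) are centered; member CpGs are phased onto the high- and
  low-expression allele of the linked gene (transcript chosen by
  exonic reads, ties by gene reads, then lexicographic id) and grouped
  by absolute distance from the center in 100 bp bins, pooling across
  regions; each bin reports log2(mean methylation on high-expression
  alleles / mean on low-expression alleles), flagged undefined when
  the low-allele mean is zero.

## LD and GWAS enrichment

r² is the squared haplotype correlation over the 2n phased haplotypes.
Pruning is greedy best-p-first clumping: accept SNPs in increasing p
order, reject a candidate with r² ≥ 0.1 to an accepted SNP within
±250 kb (deterministic; the standard clumping behaviour). The ASM SNP
set is all SNPs with ASM q < 0.1 plus any SNP with r² > 0.8 to one
within ±250 kb. Enrichment is a two-sided Fisher test on
{disease-associated (p ≤ 1e-5) vs background-only} × {in ASM set vs
not}, background being all pruned tested SNPs overlapping ASM-tested
SNPs; disease and background are pruned jointly, then split. The fold
is the rate ratio of the two rows; the odds ratio is reported as well.

## The synthetic cohort generator

The generator emulates the tables a phased bisulfite pipeline produces
downstream of alignment; it does not model reads, bisulfite conversion
error, or cell-type mixtures. Per CpG one of four architectures is
planted: `null` (both alleles at baseline μ), `genetic_cis` (the
haplotype carrying the alternative allele of the CpG's own phasing SNP
at μ+δ/2, the other at μ−δ/2), `genetic_distal` (same, but the causal
SNP is a different cis SNP, 50 kb away by default), and
`imprinted_like` (per sample a uniformly random haplotype — independent
of genotype — at μ+δ/2). Counts are beta-binomial with mean given by
the architecture and dispersion ρ; per-allele depths are Poisson.
Phased records are emitted only for samples heterozygous at the phasing
SNP, total counts for every sample; records failing the 5-read filter
are kept in the output so the filters are exercised. Haplotypes have
block-wise LD (copy-with-mutation within a block, independence across
blocks). Expression couples to methylation twice: the allelic read
fraction through a logit link with negative slope on the allele
methylation difference (the hypermethylated allele is expressed less),
and the total read count through a log-linear factor on the mean
methylation, so the non-allelic channel carries the same coupling sign —
without the latter, non-allelic correlations would be pure noise and
the mode comparison meaningless. Totals are negative-binomial with a
log-normal library-size factor. Allelic histone counts couple with
negative sign for activating marks and positive for repressive ones.
One RNG stream per table, all derived from the master seed; scenario
counts match the configuration exactly.

Default study conditions: 100 samples, 900 CpGs (500 null / 200 cis /
100 distal / 100 imprinted), δ = 0.4, μ = 0.5, 30× per allele,
MAF 0.3, CpGs 10 kb apart with the phasing SNP 100 bp away. The
default dispersion is ρ = 0, so the generator's read-sampling null
coincides with the binomial null the exact tests assume — calibration
measured under the default is then a property of the tests, not of a
noise choice. Real cohorts are overdispersed; setting ρ > 0 shows what
that does to read-pooling exact tests (at ρ = 0.05 the GIT flags ~94%
of null CpGs at q < 0.01 and the pooled ASM ~23% at q < 0.1). This
anti-conservativeness under biological replicate variance is a known
property of pooled exact tests and the main caveat when transferring
calibration statements from the generator to real data.

## What the simulations do and do not show

Passing the recovery checks shows the pipeline separates the planted
architectures when reads are binomial, phasing is error-free, and
effects are homogeneous across samples. They do not show robustness to
overdispersion (see above), phasing error, cell-type heterogeneity, or
covariate structure — none of which the generator emulates.

One structural effect deserves emphasis: at an imprinted-like CpG the
shifted allele aligns with the phasing genotype by chance, with
standard deviation δ/√n across n phased samples, while the pooled
Fisher read noise is √(2μ(1−μ)/(n·d)) at depth d per allele. The
allele-pooled ASM z-statistic is therefore inflated by
√(1 + δ²d/(2μ(1−μ))) — about 3.3 at δ = 0.4, d = 30 — *independent of
sample size*, so roughly half of imprinted-like CpGs genuinely reach
ASM q < 0.1 and take classification precedence over the epigenetic
label (measured 43–50% across seeds). Deeper coverage makes this
worse, not better. The genotype-independent test detects essentially
all of them (100% at GIT q < 0.01 in the default study); the shortfall
is purely in the four-way labelling of a genotype-random signal by a
genotype-aligned test, and is reported as-is rather than patched by
balancing the simulated allele choice, which would misrepresent how
parent-of-origin methylation relates to genotype.

## Numerical choices

Hypergeometric masses are computed in log space via gammaln (exact to
~1e-14 relative); Fisher's comparison uses the conventional 1 + 1e-7
relative slack. High/low assignment compares fractions by integer
cross-multiplication; ties are decided by a seeded RNG recorded via the
scan's seed argument, so reruns are deterministic. Degenerate margins
(empty rows/columns, all-methylated or all-unmethylated pools) return
p = 1 throughout. BH is computed with a stable sort so equal p-values
keep input order. Problem sizes used by the test-suite and the
acceptance script (2000 null CpGs for calibration, the 900-CpG mixed
cohort, 60–80 samples for the correlation and region studies) were
chosen to give Monte-Carlo error comfortably below the asserted
margins while keeping a full run in tens of seconds.
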