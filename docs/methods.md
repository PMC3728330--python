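# Methods

## The experimental design the pipeline assumes

Two DNA pools are formed from the opposite phenotypic tails of a large
segregating population derived from a biparental cross (the reference design
is an F3 of ~10,800 rice plants, with ~4% tails pooled as 430 extremely
sensitive and 385 extremely tolerant individuals) and sequenced deeply
(~70× and ~89×).  At every biallelic SNP the reads are classified by
parental origin, giving a 2×2 table of pool × parental allele depths
(n₁, n₂ in the low-trait ES pool; n₃, n₄ in the high-trait ET pool), with
parent 1 the reference parent.  Loci linked to the trait show an allele
frequency difference between the pools; unlinked loci differ only by
sampling.

## SNP screening

Three rules, applied in order with each rejection attributed to the first
failing rule: overall parent-1 frequency (n₁+n₃)/N in [0.20, 0.80]; total
depth N in [100, 400]; each pool's depth ≥ 40.  All bounds are closed
("neither < L nor > U").  A zero-depth record is rejected under the depth
rule since its frequency is undefined.  The screen removes loci with
distorted segregation and loci whose depth is too low for stable tests or
high enough to suggest repetitive sequence.

## The G′ scan

Per SNP, G = 2 Σ nᵢ ln(nᵢ/n̂ᵢ) (likelihood-ratio statistic of the 2×2
table, 0·ln 0 := 0, n̂ᵢ from the table margins), asymptotically χ²₁ under
the no-linkage null.  The scan statistic at a SNP is the weighted average of
G over all SNPs within ±500 kb on the same chromosome (1000-kb fixed window),
with tricube weights kⱼ ∝ (1 − Dⱼ³)³, Dⱼ = |posⱼ − centre|/500 kb,
renormalised to sum to one within each window.  Renormalisation makes G′ a
weighted average, so min ≤ G′ ≤ max over the window and a single-SNP window
returns its own G.  Windows are truncated at chromosome ends simply because
no SNPs exist beyond them; SNPs exactly at the window edge carry zero raw
weight.  Smoothing trades single-SNP noise for the linkage signal shared by
neighbouring SNPs.

## The empirical null and the FDR threshold

In non-QTL regions G′ is modelled as log-normal.  Writing x = ln G′:

1. values with x − Median(x) > 5.2 × Median(z), where z = Median(x) − x
   over the lower half (x ≤ Median(x)), are discarded — one-sided robust
   trimming of the contaminated upper tail;
2. μ = ln Median(G′) and σ² = μ − ln Mode(G′) on the trimmed set, using the
   median/mode identities of the log-normal;
3. upper-tail p-values of all G′ under lnN(μ, σ²) are ranked, and the
   largest k with p(k) ≤ q*·k/n (Benjamini–Hochberg step-up, q* = 0.05)
   fixes the p-value cut; the G′ threshold is the lnN(μ, σ²) quantile at
   that cut.

Because G′ values are dense, unevenly spaced, and strongly locally
correlated, estimation never uses all of them: one G′ value is drawn
uniformly per 200-kb bin (bins anchored at position 1 per chromosome, final
partial bin kept), restricted to putative non-QTL regions for the parameter
fit; the draw–trim–fit cycle is repeated 20 times and the parameter
estimates averaged.  The step-up cut is likewise computed on 20 genome-wide
one-per-bin subsamples; the p-cuts of the repetitions that reject anything
are averaged and the averaged cut converted to the G′ threshold, so the
reported (p, G′) pair satisfies the quantile identity exactly.  If no
repetition rejects, the threshold is +∞ (nothing significant) with a
warning.  The threshold is then applied to every SNP's G′.

**Excluded regions.**  The non-QTL restriction defaults to a data-driven
rule: the exclusion set is seeded by applying the trimming criterion of
step 1 along the genome (flagged SNPs merged across gaps ≤ 1 Mb) and then
grown iteratively — fit on the remainder, add SNPs with p < 0.001, merge,
repeat until the flagged set stops growing (growth is monotone, so the
iteration terminates).  The seeding step matters: when QTL peaks cover a
large genome fraction, a single unexcluded fit is inflated enough that no
SNP reaches p < 0.001 and a non-iterative rule excludes nothing.  An
explicit interval list can override the automatic rule.

**Mode estimation.**  The sample mode of a continuous positive sample is
estimated by default from a Gaussian KDE of x = ln G′: the density of G′
satisfies f(eˣ) ∝ f_x(x)e⁻ˣ, so the mode solves argmax[ln f̂_x(x) − x].
For near-normal x (which the trimmed log-data are), smoothing with
bandwidth h shifts that argmax down by exactly h², which is added back; a
deliberately wide bandwidth (2.5× Scott's rule) therefore suppresses
variance at no bias cost.  On 10⁵ clean log-normal draws this recovers σ²
to within ~0.03 across parameter settings, whereas the bandwidth-free
half-sample mode (kept as `mode_method="hsm"`) wanders by up to ~0.11 —
which is why the KDE form is the default.

## The Jensen–Shannon differential-SNP scan

With pool allele distributions P_ES = (n₁, n₂)/N_ES, P_ET = (n₃, n₄)/N_ET
and depth-proportional mixture weights, the weighted JSD (natural log)
satisfies the exact algebraic identity 2·N·JSD = G.  The scan therefore
refers 2·N·JSD to χ²₁ — making the divergence scan and the G′ scan provably
consistent — and flags SNPs with p ≤ 0.05/M (Bonferroni over the M tested
SNPs).  Depth weighting is what makes the identity exact; an equal-weight
JSD has no such calibration.

## NAFD

Per pool, the windowed parent-1 frequency is the depth-pooled estimate
f̂ = Σaᵢ/Σ(aᵢ+bᵢ) over the m SNPs in a 300-kb window stepped every 10 kb
(pooled counts, not the mean of per-SNP frequencies, so deep SNPs count for
more); NAFD = f̂(ET) − f̂(ES).  Windows tile from position 1 with closed-open
spans; empty windows are omitted rather than reported as zero.  NAFD > 0 at
a QTL means the parent-1 allele increases the trait.

## QTL calling

Full intervals are maximal runs of consecutive SNPs with G′ ≥ threshold,
merged across gaps < 500 kb; merged runs spanning < 500 kb or holding < 50
supra-threshold SNPs are reported as *minor peaks*, not QTLs.  The summit is
the (leftmost, on ties) maximal-G′ SNP of the interval.  The most-probable
("head") interval is the contiguous region around the summit with
G′ ≥ threshold + 0.75·(summit − threshold) — a parameterised surrogate for
the visual "shoulder" that divides a peak's head from its body; with
head-fraction 0 it reduces to the full interval.  The allele source is read
from the NAFD window whose centre is nearest the summit (parent 1 if
positive, parent 2 if negative, undetermined at exactly 0 or without
coverage).  Calls are named `<prefix>-<chrom>`, with a/b/... suffixes in
positional order when a chromosome yields several.  An optional
valley-splitting mode divides a twin peak at an interior minimum below the
head level when both flanks exceed the threshold (the centromere-straddling
case); it is off by default because such splits are speculative.

## Read quality control

Each base's error probability is p = 10^(−q/10) (Sanger/PHRED+33 only;
other encodings are rejected rather than guessed).  With limit 0.05 the
base scores are s = 0.05 − p, and the retained segment is the contiguous
run maximising Σs (modified Mott trimming as a maximum-scoring-segment
problem), empty when every score is negative.  Ties between equal-sum
segments resolve leftmost-first, then longest, which also makes trimming
idempotent.  Ambiguous bases are scored at p = 0.75 regardless of their
stated quality so they can never rescue a segment.  Trimmed reads shorter
than 25 bp or with more than 2 Ns are discarded; paired-end trimming can
drop the mate of a discarded read.

## The simulator

What it emulates: an F1 heterozygous everywhere; meiosis as a two-state
Markov chain along each chromosome with Haldane switch probabilities
r = (1 − e^(−2d))/2 at a constant 200 kb/cM and no interference; F3
individuals as selfed offspring of independent F2 plants (one per family by
default), reproducing the F3 genotype law (3/8, 1/4, 3/8); additive
phenotypes y = Σ a_q·s_q·(g_q − 1) + e with e normal, the residual sd either
given or derived from a target heritability against the realised genetic
variance; truncation selection of the lowest/highest tails (ties broken by
stable index order); and pooled sequencing with per-SNP negative-binomial
depth (gamma–Poisson, dispersion 5, truncated at 1; Poisson available)
around the pool mean, parent-1 reads Binomial(depth, f) at the true pooled
frequency f, and an optional symmetric sequencing-error flip (default 0,
matching the clean-biallelic assumption of the SNP filter).  SNP positions
are either supplied or drawn as a gamma-gap process (mean spacing 18.7 kb by
default, ~20,000 SNPs genome-wide on the 12 rice-sized chromosomes; the
coefficient of variation controls clustering).  Everything is deterministic
given the config seed.

What it does not model: read-level artefacts (FASTQ synthesis, mapping
bias, the reference-allele mapping bias that shifts real pooled frequencies
below 50%), indels or multiallelic sites, dominance and epistasis, crossover
interference, batch structure in phenotyping, or family sizes per F2 other
than a constant.  Passing tests therefore demonstrate the statistical
machinery under the design's sampling assumptions, not robustness to
alignment artefacts.

## Problem sizes used by the tests and the acceptance script

Simulation-backed checks run at reduced scale chosen once as a realistic
compromise: null-genome error-rate runs use the full 12-chromosome genome
with population 2,000 (with no selection, the null is driven by pool
composition and read sampling, not population size) and the study's pools
(430/385) and depths (70×/89×); planted-QTL recovery uses the first six
chromosomes (~212 Mb), population 2,000, 20% tails giving pools of 400/400
at 80×, and two QTLs of ~0.3 heritability each.  The acceptance script runs
10 null genomes and 30 recovery replicates; the acceptance tests run 20
and 100.

## Numerical choices

Zero cells in the G statistic use 0·ln 0 = 0; zero total depth is an error
for G and a depth-rule rejection in the filter.  Tricube weights are exact
zeros at the window edge; the degenerate all-edge window falls back to the
centre SNP's own G.  The log-normal fit refuses samples whose mode is not
below their median (no right skew) and trimming refuses degenerate samples
with Median(z) = 0.  BH on an empty p-vector is an error; a subsample
repetition with no rejection simply contributes nothing to the averaged
p-cut.  All intervals are 1-based inclusive internally; BED exports are
0-based half-open.

## Known limitations

* **Finite-pool overdispersion of the per-SNP test.**  Read counts are
  binomial *given* the pool's composition, but the pool of n individuals is
  itself a sample: Var(f_pool) = 0.75/(4n) for an F3.  At the reference
  design (pools 430/385, 70–89×) this inflates the null G by ~15% over
  χ²₁, so the Bonferroni differential-SNP scan is anticonservative — about
  one null genome in five shows a (spurious) Bonferroni hit where the
  nominal rate would be ~5%.  The inflation shrinks with depth (at 40× it
  is ~7–9%) and would vanish for infinite pools.  The G′ threshold is
  immune: its null is estimated empirically from the same data and absorbs
  the overdispersion.  A practical reading: trust the G′/FDR machinery for
  discovery, and treat isolated Bonferroni-significant SNPs with caution.
* **Marginal extra calls under FDR thresholding.**  With strong QTLs
  present, the step-up rule's threshold is liberal by design; weak linked
  satellites and drift bumps at 1–2× the threshold occasionally survive the
  span/SNP-count filters, so ~1 replicate in 10 yields a second extra call
  beyond the single false call the calling contract anticipates (the true
  QTLs are still recovered).  A summit-height criterion for the major/minor
  split would suppress these but is not part of the calling contract.
* G′ tends to be underestimated where SNP density is very low (few SNPs
  share a window); no density correction is applied.
* The most-probable-interval rule is a convention (head fraction 0.75);
  real shoulder shapes vary and the parameter is exposed for that reason.
* SNP calling and alignment are out of scope: the pipeline consumes allele
  depths produced by external callers.
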