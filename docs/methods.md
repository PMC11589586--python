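# Methods

`hbdkit` implements a model-based analysis of inbreeding and genetic load in
multi-population genotype panels: homozygosity-by-descent (HBD) segment
inference with a multi-class hidden Markov model, two complementary
inbreeding coefficients (F_HBD and F_AS) whose contrast diagnoses the origin
of inbreeding, nucleotide diversity and effective population size with block
bootstrap uncertainty, a genome-wide autozygosity landscape, and the R_XY
family of minor-allele load ratios. A synthetic-panel generator with planted
truth makes every stage testable by parameter recovery.

## The HBD model

An individual's genome is modelled as a mosaic of segments from K HBD age
classes plus one non-HBD background class. Class k has a per-Morgan exit
rate R_k; segment lengths are exponential with mean 1/R_k Morgans. Because
an IBD segment produced by a coalescence g generations ago has expected
genetic length 1/(2g) Morgans, R_k equals twice the age (in generations) of
the coalescence events the class represents. The default model has 13 HBD
classes with rates 2, 4, 8, …, 8192 and a non-HBD class with rate 8192.

Transitions over a genetic distance d: stay in the current state with
probability exp(−R_k·d); otherwise exit and re-enter state l (the same
state is allowed) with mixing probability M_l. The chain starts at the
mixing distribution, and each scaffold is decoded as an independent chain.

Emissions condition on the ALT-allele frequency f at each marker. In an HBD
state both allele copies descend from one founder haplotype, so
P(g) = (1−e)·[1−f, 0, f][g] + e·HWE(g) with genotyping-error rate e
(default 0.001); the non-HBD state emits Hardy–Weinberg probabilities.
Missing genotypes emit likelihood 1 in every state. Frequencies are
estimated from the panel, per population by default; a `global` scope is
available and is the right choice when populations should be measured
against the panel-wide gene pool (see the origin contrast below).

Inference is by scaled forward–backward (per-marker rescaling keeps the
recursion stable for millions of markers). Mixing coefficients are fitted
per individual by EM with the class rates fixed: the E-step accumulates the
expected first-marker occupancy plus the expected number of *jump* entries
into each state — an apparent stay may be an exit followed by re-entry into
the same class, so each transition is reweighted by its jump share
(1−p_k)·M_l — and the M-step renormalises. The log-likelihood is
non-decreasing; non-convergence within `max_iter` is flagged, not raised.
Initialisation is uniform over the K+1 states. Segment calls come from a
log-space Viterbi pass; consecutive markers in the same HBD class merge
into one segment spanning first to last marker (reported 0-based
half-open).

F_HBD is the mean over markers of the summed posterior of classes with rate
≤ T; the default T = 1024 counts coalescence events within the last 512
generations (rate = 2 × age). The threshold is implemented inclusively,
with a `strict_inequality` switch for the exclusive reading. N_HBD and
S_HBD (count and mean length of autozygous Viterbi segments) use the same
threshold; an empty segment set reports S_HBD = 0 so summaries stay total.

## Allele sharing, F_AS and the origin contrast

The allele-sharing matrix holds, for every pair, the mean per-locus
matching (x_i·x_j + (2−x_i)(2−x_j))/4 over loci non-missing in both — the
probability that one allele drawn from each individual matches. On the
diagonal this scores 1 at homozygous and 0.5 at heterozygous loci.
Standardising by the mean between-individual matching M̄_B gives coancestry
coefficients β = (M − M̄_B)/(1 − M̄_B). Off-diagonal β is the relatedness
used to build unrelated sets (all pairwise β < 0.05, greedy removal of the
individual with most violations, ties removing the lowest id; full sibs sit
near β ≈ 0.25). The diagonal matching samples an individual's two alleles
*with replacement*, so its standardised value estimates the self-coancestry
(1+F)/2; the inbreeding coefficient is therefore F_AS = 2β_ii − 1. This
convention makes F_AS average zero under random mating, reach 1 for a fully
homozygous individual when M̄_B = 0.5, and go negative for individuals that
match less than random pairs — the behaviours the statistic is used for.
F_AS is standardised within population, with the unrelated set as the
reference for M̄_B when related individuals are present.

The contrast labels each individual by F_HBD − F_AS (δ = 0.01 by default):
"ancient" when F_HBD exceeds F_AS (autozygosity from old coalescence —
small long-term effective size, the island signature), "recent/structured"
when F_AS exceeds F_HBD (consanguineous mating or unaccounted population
structure), otherwise "on-line". The labels are a reporting convenience;
the coefficients themselves are the quantitative output. Note that the
signature separating the two coefficients arises when F_HBD is measured
against a wider gene pool than the population's own (use
`freq_scope="global"` for the HBD decoding when diagnosing it): F_AS is
always relative to the current population, so drift-driven co-ancestry
raises F_HBD but not F_AS.

## Diversity and effective size

Per-site diversity is the unbiased pairwise heterozygosity
π_i = 2d(m−d)/(m(m−1)) with d ALT copies among m non-missing allele copies.
The population π averages over a denominator that is either the number of
analysed SNP sites (default; matches SNP-panel reporting and yields
inflated absolute values relative to per-bp diversity — the report states
which mode was used) or a supplied sequence length for per-bp values.
Ne = π/(4µ) with µ = 4.6e-9 per site per generation by default.
Uncertainty comes from a seeded bootstrap over contiguous physical 1 Mb
blocks, 1000 replicates by default, optionally restricted to unrelated
individuals; the replicate SD is reported as the SE.

## Autozygosity landscape

The per-SNP track is each individual's summed HBD-class posterior
(equivalently 1 − P(non-HBD)), averaged across individuals; an age-limited
variant (classes with rate ≤ T only) is available. Windows are physical,
100 kb wide with a 20 kb step, left-aligned at the scaffold start with the
last partial window kept; scaffolds with fewer than 10,000 SNPs are dropped
(configurable), and SNP-free windows are emitted with a missing value.
Islands and deserts are the top and bottom 2.5% tails of the non-missing
window values (k = ceil(tail·n) each); ties at a tail boundary that would
over-fill it are left unflagged so the calls are deterministic. Gene
density association counts genes overlapping each window (half-open
intervals, a gene counted in every window it touches) and reports the
Spearman correlation with the window HBD probability plus a two-sided
permutation p-value (10,000 seeded shuffles, computed as Pearson
correlation of precomputed ranks for speed).

## Minor-allele load

Minor alleles are called globally by a seeded bootstrap over unrelated
individuals: each of 1000 replicates draws, with replacement, an equal
number of individuals from every population's unrelated set (the smallest
set size by default, so a large population cannot dominate the call),
counts alleles panel-wide and votes for the rarer allele; exact 0.5
replicate frequencies and across-replicate ties vote for the ALT allele.
Sites monomorphic in every replicate are flagged non-informative and
excluded from the ratios.

Per-individual load counts report minor-allele copies (het = 1, hom = 2)
and homozygous-minor site counts per functional category
(intergenic/neutral/low/moderate/high, with "unclassified" for sites
missing from the category table), plus versions normalised by the
individual's polymorphic-site count (non-missing sites carrying at least
one minor allele).

For groups X and Y, L_XnotY = Σ_i (d_X/n_X)(1 − d_Y/n_Y) over a category's
sites and R_XY = L_XnotY/L_YnotX; R_XY(X,Y)·R_XY(Y,X) = 1 exactly. The
homozygosity form L² defaults to the literal weighting 2d(n−d)/(n(n−d))
(which reduces algebraically to 2d/n); `l2_form="dodds"` substitutes the
expected-homozygote form d(d−1)/(n(n−1)). R′ divides a category's ratio by
the intergenic ratio to control for demography; R′ < 1 means group Y is
enriched in that category's minor alleles beyond intergenic expectation.
SEs come from a delete-one weighted block jackknife over contiguous 5 Mb
physical blocks (block size and the minimum block count are configurable);
a ratio is flagged significant when |R′ − 1| > SE. Group comparisons use
the two-sided Wilcoxon rank-sum test (normal approximation with tie
correction; W reported as the rank-sum statistic of the first sample) with
effect size r = |Z|/√N labelled small/moderate/large at 0.1/0.3/0.5.

## The synthetic-data generator

The generator emulates the statistical structure the analyses consume, not
a full coalescent: per-site ancestral frequencies from a symmetric Beta
(shape 0.8 by default, clipped to (0.01, 0.99)); population frequencies by
the Balding–Nichols construction with a per-population F_ST-like divergence
knob; genotypes Hardy–Weinberg outside HBD tracts. HBD tracts alternate
with exponential non-HBD gaps: each tract's class is drawn with probability
∝ w_k·R_k and its length from Exponential(mean 1/R_k), and the gap mean is
set so the expected genome fraction covered by class k equals its
configured weight w_k — an alternating-renewal equivalent of a Poisson
tract process that guarantees non-overlap and exact asymptotic coverage.
Inside a tract both copies descend from one founder haplotype (homozygous
ALT with probability f), heterozygous only through the genotyping-error
channel. Full-sib pairs are generated by Mendelian transmission from two
simulated parents and appended after the unrelated individuals. Load
asymmetry multiplies a group's minor-allele frequencies in selected
categories by a positive factor (clamped to [0,1]; intergenic never
shifted) — it is imposed on frequencies, not evolved. Site positions are
evenly spaced; the genetic map is uniform at a configurable rate (2e-8
Morgans/bp by default, raised in tests so that desk-scale scaffolds span
whole Morgans). Depths are Poisson around a configurable mean (16×). One
integer seed determines everything.

What the generator does *not* emulate — linkage disequilibrium from shared
haplotypes, realistic site-frequency spectra, selection dynamics, variable
recombination, sequencing error beyond the single error knob — bounds what
passing tests show: parameter recovery demonstrates the estimators are
correct under the model's own assumptions, not that they are robust to
every property of real resequencing data.

## Problem sizes and numerical choices

The replicated acceptance-style checks run at reduced scale chosen so
sampling error stays well inside the asserted tolerances: F_HBD recovery
uses 30 individuals × 30-Morgan genomes (45,000 SNPs); the origin-contrast
and null-calibration checks use 100–200 replicates of panels with ~6,000
SNPs; load-shift detection uses 4-scaffold panels with 20 jackknife blocks.
Forward–backward uses per-marker rescaling; emission frequencies are
clipped away from 0/1 (default 1/(m+2) with m the allele-copy count) so
monomorphic-in-population sites stay finite; EM stops on |Δloglik| < tol or
an iteration cap. Degenerate inputs (empty observation sequences, zero
genetic length, monomorphic panels for F_AS, zero jackknife denominators,
all-missing window tracks) raise typed errors rather than returning NaN.

## Known limitations

* The HMM assumes conditionally independent markers given the hidden state;
  background LD is not modelled and can inflate F_HBD slightly at very high
  marker density, as seen in the small positive bias at low planted
  autozygosity.
* F_AS and the relatedness filter share one standardisation (M̄_B), so the
  unrelated-set choice feeds back into F_AS through the reference mean.
* The R′ normalisation assumes intergenic sites are neutral and share the
  groups' demography; jackknife SEs assume blocks are exchangeable.
* Ne = π/(4µ) inherits every bias of π's denominator and of µ; with the
  "sites" denominator the absolute values are intentionally on the SNP-panel
  scale and only relative comparisons are meaningful.
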