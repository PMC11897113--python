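# Methods

This note documents the statistical models, the generative assumptions of
the simulators, the defaults that matter, and the numerical choices made
where the design was genuinely open.

## Phenotype model and heritability

Plot-level trait values are modeled as genotype value + i.i.d. Gaussian
plot noise. Broad-sense heritability is estimated per experiment from a
one-way random-effects ANOVA on plot values:

    sigma2_G = (MS_genotype - MS_error) / r_bar,   H2 = sigma2_G / (sigma2_G + MS_error)

with `r_bar` the harmonic mean of per-genotype replicate counts, a standard
choice under unbalanced replication. A negative genetic variance component
is clamped to zero and flagged rather than propagated. The estimator
operates on plot values (not genotype means), so the reported H2 is
plot-level repeatability; with r replicates the corresponding
genotype-mean-level value would be H2m = r·H2 / (1 + (r−1)·H2). A table in
which all values are identical has zero phenotypic variance and raises an
error rather than reporting 0/0.

## Half-diallel mode of inheritance

For a hybrid group (F1 plus its two parents, all as trait means over
years/replicates): a = |P1 − P2|/2 is defined non-negative, so the degree
of dominance d/a is read as a magnitude-scaled deviation; d = F1 −
mid-parent is signed positive toward the high parent (on an increasing
trait scale this is simply F1 − mid). When the parents are equal (a = 0)
the degree is undefined and returned as NaN, not an error. The dominance
summary retains groups with a strictly above the threshold (default
2 °Brix) and tests mean d against zero with a two-sided one-sample t-test.
All correlations (mid-parent/F1, trait-trait) are computed on genotype
means, not plot values, so plot noise attenuates them only through the
variance of means.

The diallel matrix orders parents by GCA computed as the mean of each
parent's off-diagonal (cross) cells; ties preserve input order (stable
sort). Cells without observations stay NaN and are excluded from GCA.

## Single-seed-descent population simulator

Each line descends from an F1 carrying one chromosome from each parent.
Every meiosis places exactly one crossover uniformly along each chromosome
(a map-distance proxy of a ~50 cM chromosome; no genetic map input), and
each selfing draws two independent gametes. After g − 1 selfings the
per-locus residual heterozygosity is (1/2)^(g−1) (3.125% at F6) and the
parent-A allele frequency is 1/2, both checked by test. Planted QTLs are
inserted as extra marker loci, so QTL-marker linkage emerges from the
shared crossover process rather than being imposed.

Phenotypes are baseline + sum of signed QTL contributions (the two
homozygote classes of a QTL of effect e differ by exactly e) + Gaussian
noise. The noise variance is calibrated against the *realized* genetic
variance of the simulated lines, not the theoretical one, so the target
line-level heritability is met in each draw; with a single QTL the
heritability equals that QTL's PVE. With no segregating QTL the noise
standard deviation defaults to 1 °Brix.

The default genome is a melon-like karyotype of 12 chromosomes, 25-36 Mb
each and 355 Mb in total, chosen so a 5-Mb partition yields 75 bins (the
scale of the published melon assembly); sizes are realistic but not
assembly-exact.

## Tail selection and pooled sequencing

Tails are the top/bottom line means with ties broken lexically by line id;
using one total order for both ends guarantees disjoint bulks. Bulk DNA is
pooled equimolar per line (the field protocol does not state the pooling
model; equimolar is the natural default). The bulk reference-allele
frequency at a site is the mean parent-A dosage/2 over the bulk's lines
(heterozygote = 0.5; missing genotypes excluded from the denominator);
read depth is Poisson with the stated mean (default 30x) and
reference-read counts are Binomial(depth, frequency). Simulated sites take
the genotype of their nearest marker, a dense-SNP proxy that preserves the
local haplotype structure real pooled data would show.

## Delta-SNP-index scan

SNP-index = ref/total per bulk; delta = high − low. The depth filter
requires > `min_depth` (default 20) reads in *each* bulk — the source
protocol says "total depth" without specifying; the per-bulk rule is
stricter and avoids calling index values from a one-sided depth hole. The
sliding window (default 1 Mb, step 100 kb; the protocol states neither)
averages member sites arithmetically. Only full-width windows are emitted:
the trend line stops half a window short of each chromosome end, because a
truncated terminal window can hold a handful of sites whose binomial read
noise is then essentially unsmoothed. Region calling applies the |delta| >=
threshold rule (default 0.4) to the *windowed* trend line — the threshold
line is drawn against the trend in the source figures — with sign
tracking, because favorable alleles can come from the low-phenotype parent
and negative-delta regions are real. Same-sign qualifying runs separated by
at most `merge_gap` (default 2) windows merge; region bounds are the
outermost window bounds intersected with covered sites; the peak is the
max-|delta| window, leftmost on ties. Coordinates are 1-based inclusive in
all tables and half-open internally.

A caveat the simulator makes explicit: with bulks of ~30 lines the null
delta-SNP-index carries bulk-composition drift with a standard deviation of
about sqrt(2 · 0.25 · 0.85 / 30) ≈ 0.12 that window averaging cannot
reduce (it is shared by all sites of a haplotype block). Genome-wide, the
fixed 0.4 cutoff therefore admits occasional drift excursions (roughly one
spurious region every other genome scan at these bulk sizes); a fixed
threshold trades simplicity against bulk-size-aware confidence bands,
which are deliberately out of scope here.

## Marker-level QTL statistics

Scans and effect estimates operate on line means with heterozygous and
missing genotypes excluded (inbred-line analyses are homozygote
contrasts); the two-class one-way ANOVA F test is vectorized across
markers, and a marker whose classes separate the phenotype with zero
within-class variance reports p = 0, the smallest attainable value. The
genome-wide threshold is the alpha-quantile of the per-permutation minimum
p over markers (default 1,000 permutations; with n permutations the
attainable p floor is 1/(n+1)); q-values use Benjamini-Hochberg. PVE is
100·SS_between/SS_total of the marker ANOVA, exactly 100 when within-class
variance is zero.

Pair interactions use a two-way ANOVA with interaction on the four
double-homozygote classes (type-II sums of squares; identical to type-I on
balanced data) and an interaction estimate defined as the cell-mean
contrast m_AA − m_AB − m_BA + m_BB. The letter display uses Tukey's HSD at
alpha = 0.05 with the standard insert-and-absorb connected-letters
construction. An empty class yields a flagged missing-class result, not a
silent drop. Stacking groups lines by their favorable-homozygote haplotype;
the headline contrast is full-favorable minus full-unfavorable, absolute
and as percent of the unfavorable mean. Expected-vs-observed additivity
regresses observed pair effects (double-favorable minus double-unfavorable
class means, the scale on which expected = sum of singular effects lives)
on expected; the slope's deviation from 1 is tested with a t statistic on
the regression standard error.

## Pan-QTLome binning

Bins tile each chromosome at the configured width (default 5 Mb), terminal
bins truncated at the chromosome end, so bin widths sum exactly to the
chromosome length. Interval length uses end − start + 1 (1-based
inclusive) and intervals longer than `max_interval` (default 15 Mb) are
excluded. Because "falls within" a bin is ambiguous for intervals, overlap
assignment (every overlapped bin) is the default with midpoint assignment
(exactly one bin) available — hotspot counts differ between the rules, so
the choice is explicit and recorded on the result. Per-bin support counts
distinct studies, not records; per-study record counts are kept as an
auxiliary matrix. GWAS point associations are representable as 1-bp
intervals. Malformed rows are rejected with their row numbers logged;
out-of-bounds intervals are clipped with a warning; an unknown chromosome
is an error.

## What the simulators do and do not emulate

They reproduce the statistical structure the analyses rest on: additive +
dominance genetic values with plot noise in the diallel; SSD inbreeding,
linkage and heritability-calibrated noise in the biparental populations;
binomial read sampling over tail-bulk allele frequencies; and multi-study
QTL tables with shared hotspots and background intervals. They do not
emulate genotyping error, multi-allelic sites, segregation distortion,
selection during SSD, genotype-by-environment interaction, or
sequence-level artifacts (mapping bias, duplicated regions), so passing
tests demonstrate correctness of the statistical machinery under the
stated model, not robustness to those real-data pathologies.

## Problem sizes

The replicate counts and population sizes used in tests and in
`scripts/acceptance.py` (100 replicates; 200-line populations; 10,000
sites; 1,000-marker grids) match the scale of the study designs they
emulate while keeping the whole suite runnable on a laptop in well under a
minute per pipeline.
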