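# Methods

## Data model and units

Expression enters the pipeline as a dense tensor of non-negative values per
(gene, accession, organ, strand), organs fixed to root/seedling/flower and
strands to sense/antisense. Values are read-depth-normalized abundances
(reads per million, RPM). Because both index formulas divide by the sample
total, any per-sample proportional normalization (RPM or RPKM alike) yields
identical indices up to the per-gene length factor; the package treats the
values as opaque "normalized expression" and documents RPM as the intended
unit. A gene absent from one input table is an explicit zero in that slice:
unmeasured expression is treated as no expression, not missing data.

Phylostrata are integers 1–12 over the ladder Cellular organisms →
Eukaryota → Viridiplantae → Embryophyta → Tracheophyta → Magnoliophyta →
Eudicotyledons → core Eudicotyledons → Rosids → Brassicales → Arabidopsis →
A. thaliana (1 = oldest). dN/dS tables are filtered on ingestion to
dN < 0.5, dS < 5 and dN/dS < 2; rows with dS = 0 are dropped with a warning
rather than assigned an infinite ratio, since the retention rule presumes
finite ratios. The filter is idempotent.

## Expression calls and groups

A gene is called expressed in an organ (per strand) when its value is
≥ `rpm_threshold` (default 0.8) in at least `min_accessions` (default 5)
accessions; both comparisons are inclusive. Each expressed gene's
organ-presence profile places it in exactly one of R, S, F, RS, FR, FS,
RSF. The call is monotone in expression and the partition is independent of
gene order.

Sample similarity is Pearson correlation between full transcriptome columns
(zeros included — the profiles being compared are whole transcriptomes, not
expressed subsets; a config switch enables log1p transform first).
Clustering is agglomerative on Euclidean distances between the samples'
correlation profiles; only the distance metric is fixed by the analysis
design, so linkage is configurable with average linkage as default.
Zero-variance samples have undefined correlations and are excluded from
clustering with a warning.

## Indices and bootstrap

TAI and TDI are expression-weighted means (ratio-of-sums form); the
partial-concentration sum-of-products form is implemented separately and
the two agree to 1e-12, which the tests enforce. Genes lacking a stratum
(TAI) or a retained ratio (TDI) are excluded and counted. A sample with
zero total expression over the annotated genes raises an undefined-index
error.

Bootstrap: for each accession and strand, the eligible set is annotated
genes with nonzero expression in at least one organ of that accession. Each
replicate draws N genes with replacement from the N eligible genes and
applies the same resample to all organs, preserving cross-organ dependence
within replicates so the organ comparisons are paired. A gene drawn k times
contributes k-fold to numerator and denominator. Replicates in which some
organ's resampled total is zero are redrawn, capped at 100 attempts. The
standard error is the standard deviation (ddof = 1) of the replicate
values; with 1,000 replicates its own relative noise is about 2%.

Organ differences are two-sided Mann–Whitney tests between the two organs'
replicate vectors: exact enumeration for n ≤ 8 (the regime the test oracle
covers), tie-corrected normal approximation otherwise. Treating bootstrap
replicates as samples makes these tests extremely powerful — a small
p-value means the bootstrap distributions are separated, not that
biological variability was assessed (the emulated design has no biological
replicates).

## Relative expression and the old/young contrast

Partial concentrations are computed per sample over the genes with an
assigned stratum, making RE invariant to per-sample rescaling. For each
stratum, the mean partial concentration per organ is min–max scaled across
organs to [0, 1]; a stratum with identical means across organs is
degenerate and reported as 0.5 everywhere with a warning; an empty stratum
is reported missing. Classes split at `old_class_max_stratum` = 3 (PS1–3
pre-date land plants). The class contrast is Welch's t-test on
stratum-level RE values within an organ — the finest granularity consistent
with plotting class means — with gene-level concentrations available as an
alternative unit. When both classes have (machine-level) zero variance the
statistic is undefined; equal means report p = 1, separated means are
reported as a degenerate perfect separation with the effect direction.

## Enrichment

For groups R, S, F and RSF restricted to genes with assigned strata, the
expected count in a stratum is group size × stratum share of all assigned
genes (the genome-proportion background; a 4 × 12 contingency-table
expectation over grouped genes only is available behind
`expected_model="table"`). Enrichment is log(observed/expected), natural
log by default. A zero observed count has undefined log-odds; it is
conservatively replaced by 1 and flagged adjusted. Significance is the
two-tailed hypergeometric test, doubling the smaller tail with the observed
point included in each tail and capping at 1 (a minimum-likelihood-sum rule
is available via `two_tailed_rule="minlike"`); the doubled-tail rule is
slightly conservative on discrete supports. Bonferroni correction
multiplies by the number of tests actually performed per strand (strata
holding zero genes are excluded from testing, so at most 48).

## Synthetic-data generator

The generator draws, per gene: a stratum from an old-heavy spectrum
(64.87% total mass on PS1–3 split 0.30/0.23/0.1187, 10.43% Embryophyta,
6.22% Magnoliophyta, 6.94% A. thaliana, remainder uniform); a breadth group
(defaults RSF 0.40, R 0.06, F 0.06, S 0.02, pairs 0.14 total, unexpressed
0.32, giving roughly half of genes per organ above the call threshold and
~79% of expressed genes shared by more than one organ); and a base
abundance, log-normal with median 8 RPM, log-sd 0.35, floored at 2 RPM so
group membership survives the expression call essentially exactly.

Organ structure is a log-linear age tilt exp(slope × ps) with default
slopes −0.08 (seedling), 0 (root), +0.08 (flower), planting the
seedling < root < flower transcriptome-age ordering. Because per-sample
normalization cancels any constant per-organ factor, the stratum at which
an organ's relative expression flips from seedling-high to flower-high is
the expression-weighted mean stratum (≈ 3.7 under these defaults), which
places the old class PS1–3 on the seedling side and the young class on the
flower side, as the old/young contrast expects. The slope magnitude was
chosen so that for the large old strata the cross-organ tilt exceeds the
cross-organ accession noise (log-sd 0.2 per cell, i.e. relative noise of a
stratum's organ mean ≈ 0.2/√n_l), making the planted pattern detectable at
stratum granularity.

The dispersion parameters place the generator in the small-standard-error
regime the emulated study reports (bootstrap SEs well under 1% of the index
mean at 25,260 genes). Real RPM data are far more dispersed across genes;
their equally small SEs arise from how expression concentrates with
respect to gene age, which this stylized generator does not model. Passing
tests therefore demonstrate correctness of the estimators and the
recoverability of planted structure, not robustness to full RNA-seq
heavy-tailedness.

Antisense expression is age-independent and sparse: 3% of genes are
antisense-active, active cells fire with probability 0.5 with log-normal
values (median 1 RPM, log-sd 1), so just under 1% of all gene × accession
cells reach the 0.8 RPM threshold, matching the emulated study's
description of antisense abundance.

dN/dS ratios cover 85% of genes, Gamma(shape 2) with scale increasing in
stratum (0.10 + 0.02 ps) so younger transcriptomes are also more divergent;
the rare tail ≥ 2 is redrawn, and dS is drawn uniformly below
min(4.9, 0.499/ratio), so every generated row passes the retention filter.

Planted enrichment peaks default to seedling→Embryophyta (5×),
root→Tracheophyta (8×) and flower→Magnoliophyta (5×), realized by scaling
the group probabilities within the peak stratum and renormalizing. The
root fold is the strongest because Tracheophyta is the smallest default
stratum (~1.9% of genes) and root's peak there is the most prominent
adaptive signal being emulated; at 2,000 genes an 8× fold keeps the peak
the group's most significant cell in ≈97% of seeds. A scenario whose
planted mass would exceed the stratum is rejected as infeasible. An
optional accession-bias flag zeroes a quarter of PS12 genes outside the
first (reference-like) accession to mimic presence/absence polymorphism;
it is off by default.

Problem sizes: organ-level analyses default to 2,000 genes × 19 accessions
with 1,000 bootstrap replicates; the genome-scale scenario uses 25,260
genes. The null-calibration input for the enrichment test uses 50,000 genes
with uniform strata and four equal groups, large enough that the discrete
hypergeometric p-values behave nearly continuously.

## Numerical choices and limitations

- Weighted indices are computed in double precision as ratio of sums; the
  two algebraic forms agree to 1e-12 on random instances.
- Bootstrap resampling draws gene indices directly (uniform integers), so
  runs are bit-reproducible for a fixed seed; per-accession substreams come
  from spawned seed sequences.
- Ties in the enrichment ranking (`most_significant_stratum`) break toward
  the larger log-odds, then stable order.
- The doubled-tail two-sided p is conservative on discrete supports; its
  null rejection rate at the sizes used is ≈ 4.7–5% rather than exactly 5%.
- The pipeline assumes every accession has expression in each organ for
  the sense strand; extremely sparse antisense data can make an
  antisense index undefined for an accession, which aborts the run with a
  named stage error rather than silently skipping.
- Correlation heatmaps/dendrograms are descriptive; no uncertainty is
  attached to the clustering.
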