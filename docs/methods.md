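# Methods

This note documents the statistical models, parameter defaults and design
choices behind `cni`, and what the synthetic benchmark does and does not
establish about behaviour on real data.

## Coordinates and scales

All internal coordinates are 0-based half-open. SEG files are read and
written 1-based inclusive (the common dialect); BED and UCSC cytoBand files
are natively 0-based half-open. Copy number is handled on the absolute scale
throughout (diploid = 2): the state thresholds (gain > 2.5, loss < 1.5), the
gain-group cutoff (> 3) and the high-amplitude cutoff (≥ 5) are only
meaningful on that scale, so marker input is expected as absolute copy
estimates rather than log ratios.

## Circular binary segmentation

Each (sample, chromosome) marker series is segmented recursively. For a
current segment of n markers, every arc `x[i:j]` with at least `min_width`
markers on both sides is scored by the two-sample t statistic between arc
and complement with pooled variance. Internally the search runs on the
between-group sum of squares `B = D²·n/(m(n−m))`, where `D` is the
difference of mean-centred partial sums and `m` the arc length: `t² =
(n−2)·B/(SS_tot − B)` is strictly increasing in `B` and `SS_tot` is
invariant under permutation, so maximising and thresholding `B` is exactly
equivalent to maximising and thresholding `|t|`, at a fraction of the cost.
Ties break to the leftmost, then shortest, arc.

The best arc is kept iff its permutation p-value `(1 + #exceedances)/(1 +
n_perm)` is below `alpha`. Permutations are index shuffles of the segment's
markers, so p-values are exactly invariant to adding a constant to the
series. The permutation loop stops early as soon as the p-value can no
longer fall below `alpha`, and the effective permutation count is capped at
`ceil(perm_cap_factor/alpha)` (default 5/α = 500 at α = 0.01), which keeps
resolution a factor five below the decision threshold. A noiseless change
point gives zero pooled variance; its statistic is treated as +∞ and is in
practice never exceeded by permutations, so noiseless piecewise-constant
series are reproduced exactly.

Defaults: `alpha = 0.01`, `n_perm = 10 000` (capped as above), `min_width =
2`, no undo-splits step (`undo_sd = None`; setting it merges adjacent
segments whose means differ by fewer residual standard deviations than the
threshold). Breakpoints are converted to base pairs at inter-marker
midpoints, so the segments of one series tile the marker span exactly; any
segment boundary is therefore uncertain by up to half a marker spacing by
construction.

## Recurrence, cytoband collapsing, CNP subtraction

Gain frequency is computed by a breakpoint sweep (verified against per-base
counting in the tests); the cohort denominator is the number of profiled
samples unless overridden. The ≥ 40% threshold is inclusive. Qualifying
intervals wholly inside one cytoband are grouped per band and re-bounded by
their members' minimum start and maximum end; intervals spanning a band
boundary stay separate and carry a joined band tag. Region ids are
`<chrom>_<ordinal>` in genomic order.

Germline CNPs are intervals where **more than** 5% (strict: 3/57 qualifies,
2/57 does not) of segmented normal profiles show gain or loss; gain and loss
carriers are pooled by default because germline CNV loci commonly show both
states across individuals (a separate-counting mode exists). CNPs are
subtracted from candidate regions by interval difference: interior CNPs
split a region, edge CNPs trim it, covering CNPs delete it. There is no
minimum surviving-fragment length. Each surviving fragment's gain frequency
is re-measured and fragments that fall below the threshold are retained but
flagged `below_freq` (and excluded from the expression analysis) rather than
silently dropped, so the region accounting stays auditable.

## Differential expression and dosage correlation

Per candidate region, each sample's region copy number is the
length-weighted mean of its segment means over the region. Group G is
region CN **strictly above 3**, group N is 1.5–2.5 inclusive; losses,
intermediates (2.5–3] and samples without coverage are excluded with a
recorded reason. (The alternative "3 or more copies" reading is available
via `gain_group_cutoff`.) Regions with fewer than two samples in either
group are flagged untestable and skipped with a log record.

For every gene in the region a linear model `expr ~ intercept + group +
histotype` is fitted by least squares; histotype levels with fewer than two
samples among G∪N are collapsed into "other", and collinear dummies are
dropped. The group coefficient is the log2 fold change. Residual variances
are moderated by empirical Bayes: with `z_g = log s²_g`, the prior
(d₀, s₀²) solves the moment equations based on `E[z] = ψ(d/2) − log(d/2) +
log σ²` and `Var[z] = ψ′(d/2)` (trigamma inverse by Newton iteration);
`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` and the moderated t has `d₀ + d_g`
degrees of freedom. When the observed spread of `z_g` does not exceed the
chi-square component, d₀ = ∞ and all variances shrink to s₀². The
implementation is validated in the test suite against the reference
Bioconductor implementation (agreement to < 1e-8 on a shared fixture) and,
at d₀ forced to 0, against the plain covariate-adjusted OLS t (1e-10).

Hyperparameters are estimated per region when the region holds ≥ 10 genes;
smaller regions borrow a pooled estimate over all analysed regions, because
the moment matching is unstable on tiny gene sets. P-values are adjusted
within region by the Benjamini–Hochberg step-up rule (self-contained
implementation; NaN p-values propagate and do not count toward m).
Significance is p_adj < 0.05 strict.

Gene-level copy number adds a 10 kb flank on each side of the gene before
taking the length-weighted mean of overlapping segments — without the flank,
short genes can lack marker coverage entirely. Correlation with expression
is Pearson's r over samples with both values (r undefined below 3 pairs or
at zero variance). The Welch unequal-variance t-test is provided for
reference-tissue comparisons (e.g. amplified tumours vs normal epithelium);
degenerate zero-variance inputs with equal means return p = 1.

## High-amplitude amplicons and prioritisation

High-amplitude regions are maximal intervals where at least `amp_support`
(default 5) samples carry a covering segment of mean CN ≥ `amp_cn`
(default 5); genes within ± 10 kb of such a region form the high-amplitude
gene set. An optional rescue of near-threshold loci (4 supporting samples
within 10 kb of a breakpoint) is deliberately not implemented; it is a
manual-curation rule that resists principled automation and its absence only
makes the high-amplitude branch slightly conservative.

The candidate cascade has two branches. Branch A (high frequency): adjusted
p < 0.05 AND (logFC > 0.7 OR r > 0.7) AND gene-level gain frequency passing
the per-chromosome cut (defaults chr8 ≥ 60%, chr3 ≥ 50%, chr20 ≥ 42%;
chromosomes without a configured cut fall back to the global 40% floor with
a logged warning — the synthetic chromosomes always use the fallback).
Gene-level gain frequency is the fraction of the copy-number cohort whose
flanked gene CN exceeds the 2.5 gain cutoff; this is the most local reading
of "frequency of gain" for a gene and is computed independently of region
bounds. Branch B (high amplitude): membership in the high-amplitude gene
set AND (r > 0.6 OR logFC > 0.6). Strict/inclusive comparisons follow the
cutoffs' definitions exactly as written above. The final list is the union;
every candidate carries per-criterion boolean flags, and an audit function
replays the rules from the flags to guarantee the list is internally
consistent.

## Synthetic cohorts

The generator emulates the statistical shape of a SNP-array
ovarian-carcinoma cohort at desk scale. Marker copy number is `2 + event
effects + N(0, noise_sd)` with overlapping gains resolved to the maximum
event CN and losses to the minimum. Planted amplicons draw each carrier's
attained CN uniformly from a configured range (3–4 for low-gain drivers,
≥ 5 for high-amplitude ones). Passenger CNAs arrive per tumour at a Poisson
rate (default 6) with log-uniform lengths on [50 kb, 10 Mb] and ± 1 copy
offsets; per-histotype rate multipliers exist but default to 1 because no
reliable subtype-specific rates are established. Germline CNPs are carried
by both the tumour and its matched normal; the carrier's offset is ± 1
(randomised per carrier by default, matching loci that show gain in some
individuals and loss in others).

Expression is `μ_g + β_g·(CN_g,s − 2) + histotype offset + N(0, σ_e)` per
gene, where `CN_g,s` is the noiseless event copy number averaged over the
gene interval. By default 10% of genes receive random per-histotype offsets
(sd 0.5); these are drawn among genes *without* a planted dosage slope so
the two planted effect types remain separable in the truth object —
combining both on one gene is possible by passing offsets explicitly.

Carrier assignment is Bernoulli per tumour by default (empirical frequencies
are then binomial around the configured value). The
`exact_frequencies` switch assigns exactly `round(freq·n)` carriers chosen
uniformly; the validation cohort uses it because a 10%-frequency amplicon in
60 tumours would otherwise fail its own ≥ 5-sample support condition in
roughly a quarter of replicates, turning the benchmark into a test of the
binomial sampler rather than of the detectors.

The validation cohort (`cni.pipeline.validation_config`): 60 tumours, 20
matched normals, two 60 Mb chromosomes at 100 kb marker spacing (600 markers
per chromosome), 250 genes per chromosome, four histotypes (serous 0.55,
endometrioid 0.20, clear cell 0.15, mucinous 0.10), three low-gain driver
amplicons at 50–60% frequency with five β = 0.5 dosage genes each, one
high-amplitude amplicon (CN 5.5–6.5) at 10% frequency with three dosage
genes, two germline CNPs (population frequency 0.25 inside the first driver
amplicon and 0.15 outside any region), marker noise sd 0.25 and expression
noise σ_e = 0.3. These sizes keep an end-to-end run in the tens of seconds
on one CPU while leaving every stage non-trivial (hundreds of segments,
frequency fluctuations around the 40% threshold, a CNP that genuinely splits
a candidate region).

What the benchmark shows: the pipeline recovers ≥ 90% of planted dosage
genes, admits ≤ 5% (in practice ~0%) of dosage-neutral genes, removes
germline CNP loci from candidates up to segmentation resolution, and all
interval algebra matches brute-force per-base computation exactly. What it
does not show: robustness to tumour-purity dilution, allele-specific events,
GC waves or probe-level artefacts — none of which are modelled — nor
anything about the biological validity of specific cutoffs (0.7/0.6, 40%),
which are taken as given.

## Numerical and degenerate-input conventions

- Constant marker series: no admissible split (B ≤ 0), single segment.
- Genes constant across all used samples: logFC 0, t 0, p 1 by convention.
- Zero residual variance with non-zero logFC: handled by moderation (the
  prior keeps s̃² positive).
- Pearson r at zero variance or n < 3: reported missing, never ± 1.
- BH with NaN inputs: NaN propagates, m counts only valid p-values.
- Frequency-track counts are integers; frequencies are exact ratios of
  counts to the configured cohort denominator.
- All result tables are written with stable float formatting, so identical
  configs and seeds give byte-identical outputs.

## Known limitations

- The CBS permutation cap trades tail resolution for speed; p-values far
  below α/5 are not resolved (they do not need to be for the accept/reject
  decision).
- One probeset per gene is the default synthetic design; multi-probeset
  expression is supported by the statistics but not exercised by the
  generator.
- Loss-region analysis is summarised (per-sample loss fractions) but losses
  do not feed region discovery or prioritisation.
- The per-chromosome frequency cuts are cohort-specific constants from the
  analysis this package operationalises; on other data they should be
  re-derived or left at the global floor.
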