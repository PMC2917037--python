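# Methods

This note documents the statistical model behind each stage of cnakit, the
parameters that matter, the design of the synthetic-cohort generator, and the
numerical and design choices a user should know before trusting the output.

## Data model and coordinates

All analyses operate on a *probe map* (probe id, chromosome, start, end) and
a probes-by-samples matrix of log2 copy-number ratios. Coordinates are
1-based inclusive internally; BED input/output converts at the boundary.
Probes must be non-overlapping and are sorted by chromosome and position on
load (a notice is logged if sorting was needed). Missing values are allowed
and stay missing through segmentation.

## Segmentation (CBS)

Each sample's profile is segmented per chromosome with circular binary
segmentation: the candidate split maximizes the arc statistic
|mean(arc) − mean(complement)| normalized by sqrt(k(n−k)/n), and a split is
accepted when its permutation p-value is below `alpha` (default 0.01,
`n_perm` = 1000 Fisher–Yates permutations with early stopping once
non-significance is guaranteed). Segments shorter than 4 probes are not
split further. Recursion continues on accepted pieces; every segment's mean
is the plain average of its probes. The test is exact under exchangeability
within a segment; it assumes independent, homoscedastic noise around a
piecewise-constant mean.

Per-test permutation seeds are derived deterministically from the master
seed and a test counter, so results are reproducible and independent of
evaluation order.

**Calling.** Per-sample gain/loss thresholds come from the data: the profile
is smoothed with a positional window (default 250 kbp, never crossing
chromosome boundaries), and tau = k·MAD of the smoothed values (k = 2.5)
with a floor of 0.1 log2 units; segments with |mean| above tau (and at least
`min_probes` = 4 probes) are called gained or lost, and segment means ≥ 1.0
are additionally flagged as high-level amplifications (≈ 4 copies or more on
this scale). FGA (fraction of genome altered) is the fraction of valid
probes in a non-neutral state. The MAD floor makes very quiet genomes
conservative rather than hypersensitive.

## Recurrent regions (GISTIC-style)

Per probe and aberration kind (gain/loss separately), the G-score is the sum
over samples of |segment mean| for samples aberrant at that probe, with each
contribution capped at 2.0 so single extreme amplicons cannot dominate. The
null preserves each sample's aberration structure: every sample's per-probe
contribution vector is cyclically shifted by an independent random offset
(per-sample seeds derived from the master seed), which keeps the per-sample
aberration load exactly fixed while destroying cross-sample alignment.
Per-probe p-values are (1 + exceedances)/(n_perm + 1) against that probe's
null, adjusted by Benjamini–Hochberg; probes with q < 0.25 are significant.

**Peel-off.** Significance is assessed once, on the original scores. The
smallest G among significant probes becomes the retention threshold g*.
Iteratively, the maximal re-scored probe defines a peak (the contiguous run
within 95% of the peak score) and a wide region (the original contiguous
significant run); the driving samples' contiguous aberrant runs are removed
and scores recomputed, until no re-scored probe reaches g*. Same-kind peaks
on one chromosome closer than 5 probes are merged. Because retention is via
g* on re-scored values, a reported region's *marginal* q-value (the q of its
peak probe before any peel-off) can exceed 0.25; the q column is
diagnostic, not the retention rule.

## Amplicon catalog and coamplification

Recurrent high-level amplicons are contiguous probe runs flagged high-amp
(log2 ≥ 1), clustered across samples into loci by overlap; loci kept at
recurrence > 1% (strict inequality). The coamplification matrix is directed:
entry (A, B) is |carriers(A) ∩ carriers(B)| / |carriers(A)|, so
(A,B)·|A| = |A∩B| identically. Loci need ≥ 3 carriers to enter the matrix;
a display-masked copy hides entries below 0.2.

## Expression–dosage integration

Genes are mapped to significant regions by coordinate overlap with the
region's wide span expanded by one probe on each side. Per gene, Pearson r
between expression and the region's per-sample mean segmented log2 is
compared to a pooled permutation null: sample labels of the region values
are permuted (100 permutations per gene, pooled across genes) and the
cutoff r* is the (1 − alpha) quantile (alpha = 0.05, one-sided for
dosage-concordant correlation; a two-sided mode exists). Pooling stabilizes
the cutoff where per-gene nulls with 100 permutations would be coarse. At
n = 100 samples the null pass rate calibrates to 5% ± 1.5% and planted cis
genes (unit slope, expression noise sd 0.2) pass at ≥ 90%.

## Genomic subtyping

Each sample is summarized by the mean segmented log2 over every significant
region's peak probes; each region row is standardized (z-scores across
samples; constant rows become zeros with a notice). Samples are clustered
with correlation distance (1 − Pearson) and complete linkage, cut at k = 6.
Complete linkage on correlation distance is worst-pair driven: a class
survives the cut only if its least-similar member pair is closer than the
heights at which stray branches merge, which is why the default generator
plants near-deterministic defining events (below). Cluster names are
assigned post hoc by maximal-correlation matching of cluster mean profiles
to archetype template profiles (Hungarian assignment, logged). Supervised
characterization uses per-region Welch t-tests, Bonferroni-adjusted over the
tested regions, reported when adjusted P < 0.05 and the aberration frequency
is ≥ 20% in at least one group. Subtype expression centroids are per-gene
means over member samples; external samples classify to the
maximal-correlation centroid, with an optional minimum-r rule yielding
"unclassified" and ties broken by declared centroid order.

## Survival

Kaplan–Meier estimation and the k-group log-rank test are implemented
directly (hypergeometric variance, chi-square with k−1 degrees of freedom);
Cox proportional-hazards regression uses lifelines (Efron tie handling) with
Wald confidence intervals. Times must be positive; events are 0/1. Over 200
null replicates the Wald CI covers the true hazard ratio of 1 at ≈ 95%.

## Synthetic cohort generator

The generator tiles probes at 50-kb spacing across a scaled 22-autosome
genome (probe counts proportional to chromosome length, ≥ 20 per chromosome)
so that the 250-kbp smoothing window always covers several probes at any
`n_probes`. Six default archetypes plant segmental events in named
chromosome-arm regions; per-event amplitude is drawn
Normal(mean, 0.1) floored away from zero (gains ≥ 0.2, losses ≤ −0.2,
amplicons ≥ 1.0); probe noise is i.i.d. Gaussian (default sd 0.15).
Archetype highlights: 17q12 carries a high-level 17q12 amplicon with
probability 0.9; the amplifier archetype carries an 8p12 amplicon (0.95)
with conditional 11q13 coamplification at 0.7; FGA orders
basal-complex > luminal-complex > luminal-simple by construction.

Two calibration principles shape the default catalog, both driven by the
behavior of complete-linkage correlation clustering rather than by any
particular test: (1) *defining* events of a class are near-deterministic
(probability ≥ 0.85–0.95) so that class membership is essentially the event
pattern — probabilistic defining events create within-class outliers whose
worst-pair distances exceed cross-class merge heights and consume cluster
slots; (2) background events (rate per archetype, 0.01–0.10) are shorter
(15–50% of an arm) and lower-amplitude (0.2–0.35) than planted drivers, so
they perturb rather than mimic signatures. Rare very-high z-score spikes
(e.g. one-off amplicons shared by two samples) can otherwise bind unrelated
samples at correlation ≈ 0.9 and seed spurious clusters.

Expression: each planted region gets cis genes whose expression is
slope·(local log2) + Gaussian noise (slope 1, sd 0.2 by default), plus
unlinked noise genes. Survival: exponential OS times with per-subtype
hazards (0.03/yr luminal-simple … 0.16/yr 17q12), DMFS at 1.3× the hazard,
independent censoring by a 10-year horizon and exponential dropout
(scale 25 yr).

Scope: the generator is a test harness, not a biological simulator — no
intra-tumor heterogeneity, no probe-specific noise or GC waves, no
whole-genome doubling, independent noise across probes, and exponential
(non-proportional-hazards-violating) survival only.

## Determinism and problem sizes

Every stochastic step takes an explicit seed; sub-seeds are derived
arithmetically (never from global state), so pipeline runs reproduce
byte-identical outputs and manifests. The test suite and
`scripts/acceptance.py` use deliberately modest sizes chosen as the
package's own verification scale: 50 noise-free profiles for the
segmentation oracle; 50 samples × 2,000 probes of pure noise for calling
specificity; 20 samples × 250 probes × 20 replicates for GISTIC null/power;
1,000 null genes at n = 100 for correlation calibration; the default cohort
(200 samples × 5,000 probes) for end-to-end subtype recovery; 500
amplifier-archetype samples for coamplification convergence.

## Limitations

- CBS split search is exhaustive O(n²) per segment per permutation
  (numba-compiled); very long chromosomes (≫ 10⁴ probes) will be slow.
- The cyclic-shift null preserves within-sample autocorrelation but not
  inter-chromosomal structure; q-values are calibrated per probe, and the
  peel-off g* rule (not q) decides retention.
- The pooled permutation cutoff assumes genes are exchangeable under the
  null; strong gene-gene correlation inflates the effective pass rate.
- Subtype clustering is unsupervised; the post-hoc template naming assumes
  the archetype templates are meaningful for the cohort at hand. For
  external data, clusters keep neutral `cluster_k` labels.
- Cox regression inherits lifelines' assumptions (proportional hazards,
  non-informative censoring); no diagnostics are bundled.
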