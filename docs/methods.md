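# Methods

This note documents the statistical procedures implemented in `bbtraj`,
the defaults they ship with, and the design decisions taken where a
convention had to be pinned.

## Compositional analysis

Microbiome count tables are compositional: only relative information is
meaningful, and sequencing depth is arbitrary.  All clustering therefore
runs on centred log-ratio (CLR) coordinates,
`clr_i = ln x_i − mean_j ln x_j`, computed per sample after replacing
zeros with a pseudo-count of **1 on the count scale**.  One read is the
natural detection unit; at metagenomic depths (~5×10⁶ reads) the
replacement perturbs observed features negligibly while keeping the
transform defined.  The pseudo-count is configurable
(`zero_replacement`).  The Aitchison distance is the Euclidean distance
between CLR vectors; it is scale-invariant and permutation-invariant over
features.

Diversity conventions (the underlying literature rarely states them):
Shannon uses the natural log; Chao1 uses the bias-corrected form
`S_obs + f1(f1−1)/(2(f2+1))` and refuses non-integer input, since
singleton counts are undefined after normalization.  Rarefaction is
available (`composition.rarefy`) but not applied by default.  The
presence-absence Jaccard dissimilarity of two empty communities is
defined as 0 (no evidence of difference).  Longitudinal stability
(`successive_jaccard_stability`) thresholds **relative** abundance
(default: presence = any reads; 10⁻³ is a reasonable detection limit when
taxonomic noise should be suppressed) and compares each subject's
consecutive available timepoints, skipping subjects with fewer than two
samples.

## Feature filtering

`filter_features(table, detection, prevalence)` keeps a feature iff its
relative abundance reaches `detection` in at least a `prevalence`
fraction of samples.  Removal rules in the field are often stated as a
conjunction of "< detection" and "< prevalence" without saying whether
detection is per-sample or mean; this package pins the
prevalence-of-detection reading (the MaAsLin2 convention) and the tests
enforce it.  Removed mass is not redistributed.  Features lacking a
lineage at the aggregation rank are pooled into an `unclassified` bucket
(kept by default) so that column sums — compositional closure — are
preserved exactly.

## Community typing

Hierarchical clustering uses the **ward.D2** convention: the
Lance-Williams recurrence with Ward coefficients is applied to *squared*
dissimilarities and reported heights are square roots of the updated
values, so heights live on the input scale and, for Euclidean input,
reproduce `hclust(..., method = "ward.D2")` and scipy's Ward linkage.
Ties in the merge criterion are broken by the smallest cluster-index
pair, making the dendrogram deterministic for a given sample order.  The
`ward.D` variant (no squaring) is exposed behind a flag for sensitivity
checks.  A brute-force oracle (stepwise minimisation of the increase in
within-cluster sum of squares, computed from raw coordinates) pins the
merge sequence for n ≤ 7 in the test suite.

The number of clusters is chosen by cutting the tree at every
k ∈ [2, min(8, n−1)] and maximising the mean silhouette width
`(b−a)/max(a,b)`; ties go to the smallest k; singleton clusters and
coincident points get width 0.  The search range is pinned here because
silhouette is undefined at k = 1 and community-typing studies rarely
entertain more than a handful of types.

Cluster labels are arbitrary per timepoint, so they are aligned by an
anchor taxon: the cluster with the highest mean relative abundance of
*Bacteroidaceae* (configurable) becomes "A" at each timepoint, the next
"B", and so on.  Exact ties resolve to the lower original label with a
warning.  Principal components of the feature-centred CLR matrix (via
SVD) identify the families driving the separation; drivers are ranked by
absolute PC1 loading, which is sign-invariant.

## PERMANOVA

The one-way pseudo-F partitions squared pairwise distances:

    SS_total  = (1/n)  Σ_{i<j} d²_ij
    SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij
    F = ((SS_total − SS_within)/(k−1)) / (SS_within/(n−k))

The permutation p-value counts relabellings with `F_perm ≥ F_obs` and
uses the add-one convention `p = (1 + count)/(1 + B)`, which guarantees
validity; with 999 permutations the attainable floor is p = 0.001.
Degenerate designs with `SS_within = 0` report an infinite F with a
warning rather than an error, which also gives the exact-enumeration
variant sensible behaviour on all-singleton designs (p = 1).  The exact
variant enumerates every distinct assignment of the label multiset
(budget-capped) and is the oracle for the permutation test on small
fixtures.  Only one-way designs are supported; the analyses this package
targets never test more than a single grouping at a time.

## Trajectories and *Bacteroides* groups

A subject's trajectory is its sequence of aligned letters: all-A →
`stable_A`, all-B → `stable_B`, anything mixed → `intermediary`.  The
default policy requires the full sampling series (mirroring restricting
longitudinal claims to completely sampled subjects); an integer relaxes
the minimum.  The *Bacteroides* group uses a strict `< 1 %` relative
abundance cutoff for the genus at the subject's first sampled timepoint
("first available" by default; a concrete label can be enforced, with
missing subjects flagged rather than dropped).  Only the label-switching
definition of "intermediary" is implemented; graded notions of partial
depletion are out of scope.

## Differential abundance

`feature_lm` follows the MaAsLin2 default pipeline — prevalence filter,
total-sum scaling, log2 transform with a per-feature half-minimum
pseudo-count, per-feature OLS on the exposure plus declared covariates,
Wald p, BH q — and is documented as *MaAsLin2-like*, not a
reimplementation guarantee.  Negative coefficients mean association with
the reference (alphabetically first) exposure level.  Features with zero
residual variance report p = 1.

`feature_negbin` fits per-feature negative-binomial log-link GLMs with
`log(library size × TMM factor)` offsets.  The dispersion is estimated by
method of moments from Poisson residuals of the **null** model (exposure
excluded, floor 10⁻⁸) and held fixed for a Wald test referred to a
t(n − p) distribution.  Estimating dispersion under the full model lets
chance group separation shrink the dispersion and inflates small-sample
tail p-values roughly two-fold at p = 0.01; the null-model estimate
restores uniform null p-values (verified by KS tests in the suite) at a
negligible cost in power for the effect sizes of interest.  Iterative ML
dispersion estimation was deliberately avoided as fragile below ~50
samples.

TMM factors are computed as in edgeR: M-values (log2 ratios against a
reference sample, the one whose upper-quartile fraction is closest to the
mean) trimmed at 30 %, A-values at 5 %, inverse-delta-method-variance
weighted mean of the survivors, factors scaled to geometric mean 1.  Note
a known small-panel caveat, reproduced identically by edgeR: when ~10 %
of a few-hundred-feature panel changes in one direction, rank-based
trimming mis-centres the kept set and the factors absorb part of the
signal.  TMM's assumptions (mostly non-differential features, roughly
balanced directions) should be checked before trusting NB results on
small panels.

Confounder control is declarative: exposures marked as confounded by
birth mode are routed to stratified tests — Cochran–Mantel–Haenszel for
binary outcomes, van Elteren (stratum-weighted Wilcoxon with weights
1/(n_s + 1) and tie-corrected variance) for numeric ones.  Degenerate
strata are dropped with a notice.  All tests are two-sided.

## Power sensitivity

`mdes_wilcoxon(n1, n2, alpha, power, are)` computes the minimum
detectable Cohen's d for the Wilcoxon rank-sum test by the asymptotic
relative efficiency method: effective sample sizes `are·n_i`
(0.955 = 3/π is the Wilcoxon-vs-t A.R.E. for normal data, the G*Power
convention), two-sided noncentral-t power at
`df = n1′ + n2′ − 2`, `ncp = d·√(n1′n2′/(n1′+n2′))`, root-found to 1e-6.
With `are = 1` it reduces exactly to the two-sample t-test MDES.  A
Monte-Carlo Wilcoxon power simulation in the tests confirms the returned
d yields ~80 % power under a normal shift model.

## k-mer module

Reads (FASTA/FASTQ, optionally gzipped) are reduced to canonical k-mer
counts: the lexicographic minimum of each window and its reverse
complement, windows with non-ACGT symbols skipped, k-mers below
`min_abundance` (default 2, suppressing singleton sequencing errors)
dropped at finalization.  Default k = 21 — odd by convention and
comfortably inside 2-bit/64-bit encoding range — is pinned but
configurable, since published annotation-free pipelines rarely state
their k.  Samples are equalized to the smallest read count by seeded
reservoir subsampling before counting, and compared with
abundance-weighted Bray-Curtis over the union key set.  Counting is exact
hashing; the module targets desk-scale fixtures, not billion-read inputs.

## Synthetic cohort generator

The generator is the package's test bed: it draws cohorts with the
structure the analysis assumes and returns full ground truth.

Model: each sample's family composition is Dirichlet-distributed around
its community type's mean (total concentration mass 60, a moderate
overdispersion typical of family-level profiles), split into genera by
fixed within-family proportions, and converted to counts by a multinomial
draw at a log-normal depth (median 5×10⁶ reads, σ = 0.4) — so column sums
equal depths exactly and the Dirichlet-multinomial is the count model.
Type A carries ~32 % *Bacteroidaceae* plus *Tannerellaceae* and
*Rikenellaceae*; type B has 0.05 % *Bacteroidaceae* (matching the
reported near-absence in the low-*Bacteroidaceae* trajectory) and carries
*Clostridiaceae*.  An age drift raises *Lachnospiraceae* and
*Oscillospiraceae* concentrations toward 12 months; mothers draw from an
adult-like vector, optionally correlated with the infant's type via a
`transmission_bias` knob.

Trajectories: subjects draw birth mode (P(CS) = 0.30), then a trajectory
from P(trajectory | birth mode); the defaults put stable_A at 0 after
caesarean birth and reproduce roughly 40/13/46 % stable_A / stable_B /
intermediary overall.  Intermediary subjects flip community type between
consecutive timepoints with probability 0.5, conditioned on at least one
flip (a forced flip at a random interval when none occurred): the class
is defined by observable instability, so the planted label must be
visible in the realized sequence — otherwise no recovery method could
match the truth.  Caesarean-born subjects always start in type B, which
makes them *Bacteroides*-depleted at the first timepoint by construction.

Randomness is hierarchical: subject i consumes a stream seeded by
(global seed, i), so subject sets are reproducible under cohort growth or
subsetting, and identical configs give bit-identical output.

Pathway profiles are taxa-mixtures: pathway abundance = taxa relative
abundances × a non-negative loading matrix × log-normal noise.  The
default mixing ties degradation/fermentation pathways (β-mannan,
chondroitin sulfate, starch, sphingolipid, succinate) to the
*Bacteroides* clade, a few to *Clostridium*, and spreads housekeeping
pathways over all taxa — so *Bacteroidaceae*-linked pathways are higher
in type-A samples in expectation.

`simulate_differential_features` is a separate calibration fixture for
the per-feature models: independent NB counts (dispersion 0.5) around
lognormal baselines, a 400-feature panel (the scale of a prokaryotic
MetaCyc pathway table), with fold-change perturbations planted spike-in
style on features jointly carrying 0.2 % of library mass, half up and
half down.  Those choices keep the non-perturbed features genuinely null
under total-sum scaling and under TMM: one-directional perturbations, or
perturbations on a large mass fraction, shift every other feature's
relative abundance (closure) and mis-centre TMM trimming — real
compositional effects that would make "null" features differential in
truth.  Real cluster comparisons enrich pathways in both directions, so
the balanced design is also the realistic one.

What the generator does **not** emulate: taxonomic misassignment and
database artifacts, strain-level dynamics, read-level errors, zero
inflation beyond the Dirichlet-multinomial, covariance between exposures
and composition other than the planted birth-mode rule, and batch or
extraction effects.  Passing recovery tests therefore demonstrates the
statistical machinery is correct under its stated assumptions — not that
those assumptions hold in any particular real cohort.

## Problem sizes and determinism

Test and acceptance runs use 80-subject cohorts (~320 samples), 999
permutations, 10-seed replication for recovery claims and a few hundred
features for calibration panels — sizes chosen so the full suite runs in
well under a minute of compute per heavy check while keeping Monte-Carlo
error far from the asserted margins.  All randomness flows through
explicit integer seeds; identical inputs give identical outputs, and the
pipeline's JSON report is byte-stable under rerun.

## Known limitations

- One-way PERMANOVA only; no dispersion (PERMDISP) companion test, so a
  significant p can reflect dispersion as well as location differences.
- No mixed/random-effects models: repeated measures are handled by
  analysing timepoints separately, not jointly.
- The NB model's method-of-moments dispersion is a pragmatic small-sample
  choice; it is mildly conservative for strongly dispersed low-count
  features.
- The r×c Fisher enumeration is exponential in table size; the seeded
  Monte-Carlo fallback engages beyond the budget.
- Ward linkage is O(n³) in pure Python — ample for cohort-scale n (a few
  hundred samples), not for thousands.
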