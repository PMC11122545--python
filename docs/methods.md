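# Methods

`uskit` implements a biomarker-discovery pipeline for colonic mucosal qPCR
profiles of ulcerative-colitis patients starting ustekinumab: per-gene
differential expression by the comparative-Ct method, rank-correlation
co-expression networks with hub/bottleneck centrality ranking per response
group, supervised response classification, and univariate baseline
statistics. Because raw threshold-cycle data of this kind are rarely
deposited, the package ships a Ct-level cohort simulator whose defaults
encode the study conditions the pipeline targets (22 responders vs 14
non-responders on an 84-gene inflammation/autoimmunity array with five
housekeeping genes), so every stage can be validated end to end against
planted ground truth.

## Differential expression (ΔΔCt)

For sample *s* and target gene *g*, relative expression is
`2^-ΔCt(s,g)` with `ΔCt(s,g) = Ct(s,g) − mean_hk(s)`, where `mean_hk`
is the arithmetic mean of the sample's five housekeeping Ct values
(ACTB, B2M, GAPDH, HPRT1, RPLP0) — equivalently, the geometric mean of
their expression. Fold change is the ratio of group-mean relative
expression, non-responders over responders (responders act as the control
group); this "group means first, then ratio" order matches the array
vendor's analysis software rather than averaging per-sample ratios.
Fold regulation is the display transform `FR = FC` for `FC ≥ 1` and
`FR = −1/FC` otherwise, so |FR| ≥ 1 always and under-expression appears
as a negative reciprocal.

Per-gene inference uses a two-sided Student's t-test on the `2^-ΔCt`
values, pooled-variance by default (Welch available). No multiple-testing
correction is applied by default, mirroring how these 84-gene panels are
conventionally screened at nominal p < 0.05; a Benjamini–Hochberg option
exists. Candidate genes for the network stage pass |FR| ≥ 2, plus any
explicitly forced genes (the canonical example being TNFSF14, significant
at only +1.38-fold).

Degenerate inputs: zero pooled variance with equal means reports p = 1;
with unequal means the smallest positive float, with a warning. Wells
flagged `Undetermined` are masked and imputed at a configurable ceiling of
35 cycles — a detection-limit convention, recorded in the matrix's mask so
downstream users can see it. An undetermined housekeeping well is fatal.

The literal `log2(1/ΔCt)` display transform offered by some report
figures is provided for plotting parity only; it is dimensionally odd
(the natural log-scale quantity is −ΔCt) and is never used in computation.

## Co-expression networks and centrality

The correlation method is gated by per-gene, per-group Shapiro–Wilk tests
at α = 0.05: any rejection selects Spearman rank correlation (the expected
outcome for expression data; constant vectors count as non-normal),
otherwise Pearson. Candidates are correlated against the full panel within
each response group separately, average ranks resolving ties. Pairs with
|rho| strictly above 0.9 become edges (inclusive mode available); nodes
with no surviving edge are dropped. Because Spearman correlation is
invariant under strictly monotone per-gene transforms, the analysis is
identical on the ΔCt and expression scales — asserted by a test.

Centralities are computed on the unweighted thresholded graph, keeping the
signed rho only as an edge annotation: degree centrality is the integer
edge count (hubs) and betweenness centrality is exact Brandes betweenness
normalized by `(n−1)(n−2)/2` with *n* the number of connected nodes, so
values lie in [0, 1] (bottlenecks). Weighted variants are deliberately not
used: reported hub degrees in this setting are integers and the
|rho| > 0.9 filter already encodes edge strength. Ranks are dense and
tie-aware (tied genes share a rank and are all reported); the two groups'
top-k hub/bottleneck sets are compared by intersection and difference with
per-gene DC/BC deltas.

## Response classification

One stratified train/test split at a 60 % training fraction, rounding the
training share up *within each class*: for 22 + 14 samples this yields
exactly 23 training and 13 test samples while keeping both classes on
both sides (plain `ceil(0.6·36) = 22` would not reproduce the 23/13
protocol). Five-fold stratified cross-validation on the training set
drives a small hyperparameter grid per learner; the held-out test set is
scored exactly once. Non-response is the positive class.

Five learners cover the usual small-cohort tabular ensemble: gradient
boosting (scikit-learn), XGBoost, extremely-randomized trees, a random
forest, and an L2-penalized logistic model on standardized features. All
84 panel genes enter as features. AUC is computed rank-based in-package
(Mann–Whitney with half-weight ties) and cross-checked against both a
brute-force pair enumeration and scikit-learn in tests. Per-model feature
importances (tree impurity gains, |coefficients| for the linear model) are
normalized to sum to one; the consensus ranking is the mean normalized
importance across models.

A caveat the tests make explicit: when many genes separate the classes
perfectly, impurity-based importance concentrates on an arbitrary
tie-broken feature, so single-model top-feature lists on strongly
separable cohorts are not stable; the consensus ranking and deliberately
sparse planted designs (three informative genes) are used when feature
recovery itself is under test.

## Baseline clinical statistics

Categorical variables: Pearson chi-square without continuity correction on
the group-by-category contingency table, df = (r−1)(c−1). The
no-correction default is what reproduces the published baseline p-values
from their printed counts (sex 0.932, prior anti-TNF 0.755, Montreal
extent 0.721); Yates correction is a flag. Continuous variables: two-sided
pooled-variance t-tests reconstructed from n/mean/SD summaries
(`sp² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2)`), which reproduces the printed
CRP comparison (p ≈ 0.164 vs printed 0.166 from rounded inputs); Welch is
a flag. Ordinal severity scores are summarized by medians without a test,
with an optional rank-sum test labelled as an extension. Known
non-reproducible rows from printed summaries (smoking status; several
haematology rows) are documented test exclusions: the printed values
cannot be recovered from the printed inputs under either t-variant or
plain chi-square, indicating unprinted missing data or a different test.

## Synthetic cohort generator

The generator works on the raw Ct scale:

    Ct(s,g) = baseline(g)
              − 1[s non-responder]·log2(FC_g)
              + Σ_m λ_m(g)·L_m(s)·1[g ∈ m, s ∈ scope(m)] + shift_m(g)
              + ε(s,g)

with `FC_g` recovered from the signed planted fold regulation,
`L_m ~ N(0,1)` one shared factor per module per sample, and
`ε ~ N(0, noise_sd)` i.i.d. Gaussian well noise (multiplicative on the
expression scale, the standard qPCR error model). Housekeeping genes get
their own baseline plus noise only, so normalization is exercised
realistically. Defaults: target baseline 25 cycles, housekeeping 20
cycles, noise 0.5 cycles. Results are invariant to per-sample global Ct
shifts (they cancel in ΔCt), which makes the pipeline insensitive to the
arbitrary baselines.

Design choices that required a decision:

* **Planted effects.** The default spec plants the 30-gene
  ustekinumab-response signature (29 genes from +6.95 to −24.3 plus
  TNFSF14 at +1.38) with all other genes null, at group sizes 22/14.
* **Mean-faithfulness of modules.** A Gaussian Ct component of loading λ
  inflates mean expression by `exp((λ·ln2)²/2)` (log-normal mean), which
  would bias fold-change estimates of genes in group-scoped modules by up
  to ~70 %. The generator therefore shifts in-scope Ct by `+λ²·ln2/2`
  cycles per module gene, making module factors pure variance components:
  planted fold regulations remain the true group-mean ratios. In the
  noiseless limit (`spec.noiseless()`: no noise, no modules) the pipeline
  returns every planted fold regulation to machine precision.
* **Anchored modules.** At the default member loading/noise ratio of 3,
  the population correlation between two module genes is
  `λ²/(λ² + sd²) = 0.9` — exactly at the strict |rho| > 0.9 edge cutoff —
  so flat-loading modules produce edges only ~45 % of the time and have
  no identifiable hub. Each module therefore designates its first gene as
  an anchor with 4× the member loading, pushing anchor–member correlations
  near the cap `sqrt(λ²/(λ²+sd²)) ≈ 0.94` imposed by member-side noise.
  Simulated recovery of the anchor as a top-2-degree hub at the default
  conditions was 0.56 with no anchoring and ≥ 0.92 with the chosen design
  (200 cohorts). Module memberships default to the hub/bottleneck genes
  reported per response group (responder module anchored on BCL6,
  non-responder on CCL11), with deliberate overlap (CRP, CD40) emulating
  shared hubs.
* **Seeding.** One user-facing integer seed feeds `numpy.SeedSequence`
  substreams with fixed per-stage spawn keys (cohort generation, split,
  model fitting), so stages are independently reproducible.

What the generator does *not* emulate: PCR efficiency curves, primer and
plate/batch effects, count-like dispersion at high Ct, non-Gaussian
outliers, and correlated housekeeping drift. Passing tests therefore
demonstrate the pipeline's correctness and its behaviour under an
idealized error model, not robustness to instrument artefacts.

## Validation problem sizes

The test suite and acceptance script size their simulations as follows:
null calibration over 100 independent cohorts of 100 null genes each
(10,000 null tests; a single large cohort is avoided deliberately, since
the shared housekeeping normalizer correlates all genes within a cohort
and makes a one-cohort false-positive fraction extremely unstable — up to
0.23 in single draws); hub recovery over 200 cohorts at the default
conditions; betweenness against a path-enumeration oracle on hundreds of
random ≤ 7-node graphs; Spearman against rank-then-Pearson on ~1,000
random tied/untied vectors; classification on one separable cohort plus a
20-permutation label null (mean test AUC across the five learners and
permutations is expected near 0.5; observed ≈ 0.51–0.53).

## Known limitations

* Published centrality values and AUCs from the original cohort are not
  numeric targets here: the raw Ct data are not public, and with 13 test
  samples an AUC of 1 is fragile. The ML stage is validated on planted
  synthetic structure instead.
* The per-gene t-test on `2^-ΔCt` values is mildly conservative under the
  log-normal error model at these group sizes (empirical type-I error
  ≈ 0.045–0.05 at nominal 0.05).
* The equal-variance default for both the gene-level and the clinical
  t-tests follows the conventions the pipeline reproduces; Welch variants
  are available and preferable when variances differ strongly.
* Fold-change estimates for genes inside group-scoped co-expression
  modules carry extra sampling variance from the shared factor (the mean
  bias is compensated, the variance is real), so recovery is noticeably
  noisier for module genes than for independent genes.
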