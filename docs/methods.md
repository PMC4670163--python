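# Methods

## The problem

Many synaptic receptors are built from subunits that exist in several
variants coded by paralogous genes (NR2A/NR2B of the NMDA receptor, the
GABA-A alpha subunits, glycine receptor alphas, serotonin receptor
families). During brain development the variant in use can *switch*: one
gene's expression falls across life while its counterpart rises. devswitch
detects candidate switch pairs in population expression data — log2
expression of many genes measured in postmortem brain samples spanning ages
from 10 post-conception weeks to late adulthood — and separately asks
whether the two genes of a pair co-vary from subject to subject once the
population age trend is removed.

Two quantities are computed per gene pair and brain region:

1. **Trend (anti-)correlation.** The correlation (Pearson by default,
   Spearman available) between the two raw expression profiles across
   age-sorted samples. A strong negative value is the signature of a
   developmental switch.
2. **Age-corrected (residual) correlation.** Each gene's population age
   trend x̄(t) is estimated with a cubic regression spline; the correlation
   of the residuals x_t − x̄(t) and y_t − ȳ(t) measures subject-to-subject
   co-fluctuation beyond age. When trends are linear this is exactly the
   classical partial correlation of x and y given age; the spline makes it
   a nonlinear generalization.

These two measures are deliberately independent: mirrored trends need not
imply correlated residuals and vice versa, and both configurations are
exercised in the test suite.

## Candidate pair selection

Pairs are never formed genome-wide. Two genes are candidates only when

* they occur in the same *pathway element* — a pathway-diagram node that
  groups functionally interchangeable proteins (e.g. the NMDAR node of the
  glutamatergic-synapse pathway). The packaged default pathway list contains
  the seventeen brain-related KEGG accessions (nervous-system, substance
  dependence, neurodegenerative-disease pathways plus the neuroactive
  ligand-receptor interaction map); the membership table itself is user
  input.
* their protein sequences reach ≥ 30% similarity under Needleman–Wunsch
  global alignment with BLOSUM62 and affine gap costs of 11 for gap
  existence plus 1 per gap residue (a length-L gap costs 11 + L; end gaps
  are penalized). Similarity is the number of identically aligned residues
  divided by the length of the *longer raw sequence*, so it is insensitive
  to alignment length and bounded by 1. Pairs strictly below 0.30 are
  excluded; the boundary value is kept.

The alignment is delegated to Biopython's `PairwiseAligner`
(open = −12, extend = −1 reproduces the 11 + L convention); the test suite
verifies score optimality against an independently written Gotoh dynamic
program on hundreds of random peptides. Among co-optimal alignments the
score is unique but the identity count can differ; the reported similarity
is the one of the aligner's canonical (first) traceback.

## Differential-expression filter

Genes whose expression range (max − min, log2 units) in a region is below
1.5 are treated as not differentially expressed there: the pair is recorded
but no correlation is computed (a "gray" cell in heat-map reports). The
boundary 1.5 is kept. Multiple testing is corrected per region with
Benjamini–Hochberg over the family of pairs actually tested in that region
(via statsmodels); a pair is a significant switch when q < 0.01 **and**
ρ < 0.

## Trend model

For one gene in one region, with samples (t_i, y_i) sorted by age:

* **Age transform.** Splines are fitted on x = log2(age in post-conception
  days). Developmental change concentrates perinatally, and the log axis
  spreads the fetal and early-postnatal samples where the switches happen;
  a linear axis is available via `age_transform="linear"`.
* **Noise estimate σ̂².** The mean of sample variances (ddof = 1) over all
  overlapping windows of 10 age-consecutive raw values. No local
  detrending is applied inside windows, so a steep trend inflates σ̂²; that
  bias is part of the procedure's definition and makes the knot bound
  easier to satisfy exactly where trends are steep. Profiles shorter than
  the window fall back to a single window (logged); fewer than 3 points is
  an error.
* **Basis and knot search.** Least-squares cubic B-splines with k interior
  knots at the (i/(k+1)) quantiles of the distinct transformed ages
  (boundary knots at the data extremes, full multiplicity). k is searched
  upward from 0; the selected model is the smallest k with
  MSE = (1/n)Σ(y_i − f(x_i))² < σ̂². If no k up to `max_knots`
  (default ⌊n/4⌋) satisfies the bound, it is relaxed to 2σ̂² and the fit is
  flagged `relaxed`; if even that fails, the max-knot fit is returned,
  still flagged. An exactly interpolating fit (MSE numerically zero) is
  accepted even when σ̂² = 0, so constant or perfectly polynomial profiles
  select k = 0. Because quantile-knot bases are not nested, the in-sample
  MSE is only *approximately* non-increasing in k; small upticks (a few
  percent) occur and are tolerated by the search, which only ever asks
  whether a given k clears the bound.
* **Degenerate inputs.** All-equal ages is an error. Duplicate ages are
  handled naturally by least squares; knot quantiles use unique ages so
  knots cannot collide. Rank-deficient designs are resolved by the
  minimum-norm least-squares solution.
* **Goodness of fit.** Leave-one-sample-out R²: each point is predicted
  from a model refitted on the remaining n − 1 points with σ̂² recomputed
  and k re-selected per fold (a faster fixed-k mode exists but is not the
  default); R² = 1 − Σ(y_i − ŷ_i)²/Σ(y_i − ȳ)². It is bounded by 1, near 0
  for trendless data, and negative when the model overfits. Left-out
  extreme-age points are predicted by the spline's natural cubic
  extrapolation.

The residual correlation of a pair correlates the two genes' residual
vectors over the shared samples. Trend correlation between fitted curves is
evaluated at the shared sample ages. Age-windowed analyses (e.g. prenatal
[70, 280] PCD vs postnatal) refit trends inside the window rather than
reusing whole-life fits, avoiding boundary bias from the windowed-out data;
whole-life reuse is available by windowing profiles externally.

## Null models

* **Random pairing.** Trend-correlation p-values for pairs drawn uniformly
  (without self-pairs, duplicates across draws allowed) from the measured
  genes, binned on −log10(p) with integer edges and an open final bin
  (edges configurable; no canonical histogram exists for this analysis so
  unit-width bins are the package default).
* **Paralog overlap bins.** Pairs annotated with a sequence-overlap
  percentage are grouped in left-closed/right-open bins (default 0/30/60/100,
  last bin closed) and each group's p-value distribution is computed the
  same way.
* **Bin enrichment.** Observed bin counts are compared with counts from
  redrawn same-size random pair sets; per bin,
  perm_p = (1 + #{permutations ≥ observed})/(n_permutations + 1) — the
  add-one estimator, so p can never be zero and the smallest attainable
  value is 1/(n+1). Requesting a threshold below that value is an error.
* **Housekeeping baseline.** The fraction of housekeeping-gene pairs versus
  pathway pairs whose residual-correlation p falls below 10^−θ across a
  threshold grid, plus the ratio curve. Housekeeping lists are user input;
  tests use the synthetic flat-profile genes.
* **Subject subsampling.** Uniform draw of subjects without replacement
  (all of a kept subject's samples retained) to bring a large cohort to a
  common scale; the default target is 53 subjects, matching the size of the
  smaller multi-region cohort this analysis is designed around.

All stochastic operations require an explicit seed and are bit-reproducible.

## Synthetic cohorts

The generator produces the data-generating process the analysis assumes:

    y_g(s) = trend_g(age_s) + λ_g·u_s + ε_gs

with subject latent factor u_s ~ N(0, su²) shared by the two genes of a
pair and ε i.i.d. Gaussian. The implied residual correlation
λ_a λ_b su² / √((λ_a² su² + σ²)(λ_b² su² + σ²)) is recorded as ground
truth. Defaults: logistic ("switch") trends on the log2-age axis with
baseline 6 and amplitude ±4 log2 units — the scale of the strongest
subunit switches in postmortem microarray data — midpoint at birth
(280 PCD), slope τ = 0.5 log2-age units; noise and factor sd 0.5, giving a
planted residual correlation of 0.5. Ages are stratified so every one of
the 13 developmental age groups holds at least two subjects when n ≥ 26,
with the remainder log-uniform over [70, 30000] PCD. Housekeeping-like
genes are flat with sd 0.2 (below the 1.5 range filter); background genes
are i.i.d. noise with sd 1.

Gaussian noise and factors are the minimal assumptions matching the Pearson
machinery; the generator does not emulate microarray probe effects,
quantile-normalization artifacts, or RNA-seq count noise. Passing tests
therefore demonstrate correctness of the statistical procedure under its
own model, not robustness to platform-specific distortions of real data.

A note on steep switches: when the logistic transition is sharp relative to
the local sample density, the minimal-knot fit can slightly underfit the
transition, leaving mirrored trend remnants in both genes' residuals that
bias the residual correlation of an otherwise independent pair downward.
This is a property of the method itself (the knot bound stops at σ̂², which
is itself inflated near steep transitions), visible in the simulations and
documented rather than corrected; at n = 200 the planted 0.5 is recovered
to well within ±0.1.

## Age conventions

All ages are stored in post-conception days: 1 PCW = 7 days, birth fixed at
280 days, months = 30.44 days and years = 365.25 days after birth. The 13
developmental age-group labels (EF3 … LA15) form a contiguous
left-closed/right-open partition of [70, ∞); the late-fetal group runs to
birth so every age has a label. Labels are reporting sugar only — no
fitting or filtering uses them. Ages below 10 PCW are rejected, as such
subjects are outside the analysis' domain.

## Reported sizes and numerical tolerances

Simulation-based checks use n = 100–200 subjects and 20–100 replicates,
sizes at which every Monte-Carlo margin in the test suite is several
standard errors wide. Exact-arithmetic checks (alignment scores, BH
q-values, partial-correlation identity with a linear basis) are asserted to
1e-6 or tighter; basis-invariance properties to 1e-8. The end-to-end demo
cohort is one region × 100 subjects with one planted switch pair and two
co-directed decoy pairs; the pipeline must rank the planted pair first and
flag it on both measures.

## Known limitations

* The knot-placement scheme (quantiles of unique ages) and the reading of
  the relaxation bound as 2σ̂² (doubled variance, not a doubled standard
  deviation) are documented package choices; both are configurable.
* σ̂² from raw sliding windows is upward-biased under steep trends (see
  above).
* Residual correlations between genes fitted with relaxed bounds should be
  interpreted cautiously; the `relaxed` flag is propagated into reports.
* Reported similarity refers to the canonical optimal alignment; co-optimal
  alignments with different identity counts exist for some pairs.
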