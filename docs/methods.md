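# Methods

`bioturb` quantifies how inoculating exogenous *Bacillus* isolates
("bioturbation") restructures the indigenous microbiota of a
medium-temperature *Daqu* fermentation starter and how that restructuring
relates to the starter's enzymatic function. The package analyses
per-kingdom ASV count tables over a three-arm design — DD (a two-strain
*B. velezensis* + *B. subtilis* consortium), CD (a single
*B. licheniformis* strain) and PD (uninoculated control) — sampled on days
3, 4, 5, 6, 7, 10, 12, 15, 17 and 28 in biological triplicate, with
fermentation parameters (temperature, moisture, acidity) and four
enzymatic activities (liquefying LA, saccharifying SA, esterifying EA,
fermenting FA) recorded per sample. The fermentation has three
temperature phases: rising (RV, days 0–6), stable-high (RS, days 7–12,
peak 58–61 °C) and cooling (C, days 13–28); the phase is derived from the
day, never stored.

## The classification cascade

The core output is a per-ASV classification:

1. **pASV (parameter-driven).** A fermentation parameter first passes a
   community-level gate: a Mantel test (Spearman on distance upper
   triangles, 999 permutations) between the Bray–Curtis community
   distance and the parameter's Euclidean distance, at p < 0.05. An ASV
   is a pASV iff, for at least one gated parameter, |Spearman ρ| > 0.60
   with p < 0.05. The screen runs within each treatment arm (30 samples)
   and an ASV qualifying in any arm qualifies overall; an ASV driven by
   any gated parameter is excluded from the bioturbation candidates
   (the conservative reading of "primarily parameter-driven").
2. **iASV (indicator).** IndVal over group combinations: for combination
   c, specificity A = Σ_{g∈c} x̄_g / Σ_g x̄_g (group means, not sums, so
   unbalanced groups do not bias A), fidelity B = occurrence fraction in
   c, statistic √(A·B). Combinations up to size 2 of the 3 arms are
   scored (the full set is uninformative); significance of the best
   combination is by permuting arm labels (999 permutations, add-one
   estimator), retaining p < 0.05. Specificity uses TMM-scaled CPM,
   fidelity raw presence.
3. **brASV = iASV \ pASV** — responsive to inoculation rather than to
   the process trajectory.
4. **bsASV = brASV ∩ {NB-LRT differential at BH-FDR < 0.05}.** The
   differential test is a per-ASV negative-binomial GLM (log link,
   offset = log(library size × TMM factor), one mean per arm vs
   intercept-only) with a likelihood-ratio statistic against χ²(2).
5. **eASV (activity-linked).** Maximal information coefficient between
   each ASV's CPM profile and each activity; eASV at MIC ≥ 0.35, strong
   eASV at MIC ≥ 0.55.

Derived summaries: the **effect size** of bioturbation (percentage of all
raw sequence counts carried by bsASVs), **bsModules** (among the 10
largest co-occurrence modules, those holding ≥ 10% of the network's bsASV
nodes), per-activity **effect intensity** (percentage of an activity's
eASVs that are bsASVs) and **bsModule coverage** (percentage of an
activity's in-network eASVs that fall inside bsModules).

## Component models and numerical choices

**TMM/CPM.** Trimmed-mean-of-M normalization follows the canonical
algorithm: reference sample = the one whose 0.75-quantile of count
proportions is closest to the mean; per pair, the factor is
2^(weighted mean of log2 proportion ratios), weights = inverse asymptotic
binomial variances, after removing 30% of M-values and 5% of A-values
*from each tail* (rank windows ⌊n·trim⌋+1 … n+1−⌊n·trim⌋−… on average
ranks). Factors are rescaled to geometric mean 1. Zeros in either member
of a pair are excluded from that pair's M/A computation. CPM adds no
prior count by default; a log option applies log2(CPM + 0.5). A test
verifies equality with edgeR's `calcNormFactors` to 1e-6.

**NB dispersion.** A single common dispersion φ maximizes the Cox–Reid
adjusted profile likelihood (the adjustment is −½·Σ log of per-arm Fisher
information, exact for the group-means design), searched on log10 φ over
[−6, 1] by bounded scalar minimization (xatol 1e-4). Fitting is Fisher
scoring on the one-parameter-per-group problem, vectorized over ASVs
(max 50 iterations, step tolerance 1e-10, coefficients clipped to ±50).
ASVs with total count < 5 are excluded from testing and from the FDR
denominator; tagwise shrinkage is deliberately out of scope. The Poisson
limit (φ = 0) matches `statsmodels` GLM deviance differences exactly.

**Spearman / Mantel / PERMANOVA / PCoA.** Spearman ρ is the Pearson
correlation of average ranks; p is the two-sided t-approximation
t = ρ√((n−2)/(1−ρ²)) for n ≥ 10 and an exact enumeration of rank
permutations below that (ties fall back to the approximation). Screens
over many ASVs use a vectorized rank-correlation matrix with the same
t-approximation. Mantel correlates rank-transformed distance upper
triangles, permuting one matrix's rows/columns jointly; PERMANOVA
partitions squared Bray–Curtis distances (R² = SS_between/SS_total,
pseudo-F permuted); both use the add-one permutation estimator with an
explicit seed, so p ∈ [1/(B+1), 1] and reruns are identical. The Mantel
inner statistic is Spearman, consistent with the rank-based screens
elsewhere. PCoA is classical scaling of the double-centred −d²/2 matrix;
negative eigenvalues are reported, never dropped. Chao1 (bias-corrected)
and Shannon (natural log) come from scikit-bio.

**MIC.** The estimator is the MINE characteristic matrix with the
ApproxMaxMI dynamic program. For every grid (k, l) with
k·l ≤ B(n) = max(⌊n^0.6⌋, 4): one axis is equipartitioned into l bins by
rank quantiles (boundaries snap to the nearest cut that does not split
tied values), the other axis is partitioned into ≤ k columns by a DP over
clump boundaries — maximal runs of x-consecutive points sharing a row,
merged into at most c·k superclumps (defaults α = 0.6, c = 15). Both
orientations are computed; the matrix entry is the larger normalized
mutual information I*/log2 min(k, l) and MIC is the matrix maximum. The
DP is validated against exhaustive cut enumeration at n ≤ 12 to 1e-12.
Constant vectors score 0 by convention. Note the estimator's well-known
small-sample null bias: for independent inputs at n = 90 the null mean is
≈ 0.26 (95th percentile ≈ 0.33), which is why the eASV screen uses the
0.35 threshold rather than a nominal significance level. MIC is computed
on TMM-CPM profiles of the network-filtered ASV universe (total
count > 2, prevalence > 4 samples), pooled across all 90 samples.

**Networks.** Edges are positive Spearman correlations (ρ > 0.65,
p < 0.001, deliberately unadjusted raw gate) between network-filtered
ASVs' CPM profiles; isolated nodes are retained. Modules come from
greedy (CNM) modularity maximization on the ρ-weighted graph — chosen
over Louvain because it is deterministic under the stable node ordering
used here; module ids are assigned by descending size (ties broken by
smallest member id). The pooled all-sample network drives bsModule
logic; per-arm networks are also produced.

## The synthetic-data generator

The generator stands in for raw sequencing data from a real fortified
fermentation experiment and defines the conditions under which the
pipeline is validated.

*Design.* 3 arms × 10 days × 3 replicates. Temperature follows the
three-phase profile (rise to ~40 °C by day 3, peak ~59.5 °C, below 35 °C
in the cooling phase; fortified arms warm ~1.5 °C faster in RV), with
1 °C replicate noise; moisture falls from 0.40 to 0.15 and acidity from
1.2 to 0.5, both monotone in expectation.

*Communities.* Per-taxon log relative weights = a log-normal baseline
(SD 1.5 across taxa) + planted effects + per-sample noise (SD 0.5),
softmax-normalized and drawn multinomially (negative-binomial per taxon
available) at a negative-binomial depth around 80,000 reads — the
effective-sequence depth typical of such amplicon experiments (roughly
60k–100k after quality control); a scaled-down preset uses 5,000.
Default bacterial community: 500 ASVs = 273 guilded + 147 free
background, 30 parameter-driven, 30 type-responsive, 20 enzyme-linked.

* Parameter-driven taxa: slope 2/3 per SD of the (standardized) driving
  parameter, giving a realized |ρ| ≈ 0.8 against parameter trajectories
  at the chosen noise level.
* Type-responsive taxa: log2 fold change 2 in one enriched arm, a
  baseline shift of −2 log units (inoculation responders are typically
  rare rather than dominant taxa), and a within-group latent factor (loading 0.8) so
  co-responding taxa co-occur in the network without drowning the fold
  change (at loading 0.8 the within-group correlation ≈ 0.72, above the
  network edge gate, while the fold change remains ≈ 1.5 residual SD).
* Enzyme-linked taxa: five per activity share a per-activity latent
  factor (loading 1.5). Each activity is a deterministic function of the
  summed relative abundance of its linked taxa — linear (LA), quadratic
  (SA), sinusoidal (EA), step (FA) — plus Gaussian noise with SD = 10%
  of the signal SD. The nonlinear forms are nearly invisible to rank
  correlation but fully visible to MIC, which is the point of the MIC
  stage. A small number of type-responsive taxa (2/3/1/1 for
  LA/SA/EA/FA) are additionally coupled to the activity latents
  (loading 1.0): these "overlap" taxa are the planted mechanism by which
  responsive taxa carry function, and give SA the largest expected
  effect intensity, followed by LA, then EA and FA.
* Background guilds: 65% of background taxa belong to six successional
  guilds whose latent is 0.8·(a smooth Gaussian bloom in day, width 5
  days, centres spread over days 3–28) + 0.6·sample noise, with loading
  1.5. Guilds give the community realistic day-structured succession
  (so the parameter Mantel gate passes, as it does in real fermentations)
  and non-trivial network modules. Guild membership is restricted to
  sub-dominant taxa: if the heavy upper tail of the baseline were
  day-structured, the compositional denominator would impose a spurious
  common trend on every taxon and attenuate planted correlations
  asymmetrically.

*What the generator does not emulate.* Activity and response latents are
iid across samples rather than smooth functions of time: a day-structured
response latent would make planted responsive taxa parameter-correlated,
and the pipeline would (correctly) remove them as pASVs — the planted
truth would be self-contradictory. Consequently synthetic activities
lack the smooth temporal dynamics of real enzymatic assays, and the
bsModule coverage summary, while structurally exercised, comes out low
on the synthetic default because the dedicated enzyme-linked cliques
form their own small modules outside the responder modules — in real
communities, functional taxa are embedded in the same co-occurrence
neighbourhoods as responders and coverage can be far higher. Read-level
artifacts (chimeras, taxonomic misassignment) and replicate-level
spatial heterogeneity are out of scope. Passing recovery tests therefore
demonstrates that the statistical machinery identifies the planted
structure at realistic depth, sample size and noise — not that the
biological conclusions of any particular fermentation would be
reproduced.

## Problem sizes used in validation

Oracle checks run on instances small enough for exhaustive enumeration
(n ≤ 12 for MIC and Mantel, ≤ 12-node graphs for modularity). Null
calibration and recovery use the default scenario (500 ASVs × 90
samples, depth 80k) over 20 seeds in the test suite and 5 seeds in the
acceptance script; the dispersion-recovery check uses 500 ASVs × 30
samples at a known φ = 0.2. The scaled-down preset (110 ASVs, depth
5,000) backs the structural-invariant and interface tests.

## Known limitations

* Common dispersion only; strongly heterogeneous overdispersion across
  taxa makes the LRT conservative for quiet taxa and slightly liberal
  for noisy ones.
* IndVal's permutation test has limited power for rare, heavy-tailed
  taxa at n = 30 per arm; recovery of planted responsive taxa is
  ~0.85–0.95, not 1.
* MIC's null level at n = 90 (≈ 0.26 mean) sits close to the 0.35
  screen; eASV sets at this sample size include a visible false-positive
  fringe, which dilutes effect-intensity percentages.
* The pASV screen inherits the compositional coupling of relative
  abundances; strongly dominant, temporally structured taxa can induce
  spurious parameter correlations in other taxa.
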