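# Methods

`dietmr` implements a two-sample Mendelian randomization (MR) pipeline for
estimating causal effects of dietary traits on blood metabolites from GWAS
summary statistics, together with a synthetic-data generator that encodes the
structural assumptions the pipeline is built on. This note records the
statistical model of each stage, the tunable parameters and their defaults,
the numerical conventions, and what the validation studies do and do not
demonstrate.

## The two-sample MR model

For SNP *j*, let β̂_Xj (SE σ_Xj) be its estimated per-allele effect on the
exposure (a food trait) and β̂_Yj (SE σ_Yj) its effect on the outcome (a
metabolite), estimated in two non-overlapping studies so the sampling errors
are independent. Under the instrumental-variable assumptions (relevance,
no confounding of the SNP–outcome relation, and no effect on the outcome
except through the exposure), each valid instrument identifies the causal
effect β through β_Yj = β · β_Xj.

### Estimators

- **Wald ratio** (single instrument): β̂ = β̂_Y/β̂_X with first-order delta
  SE σ_Y/|β̂_X|. Used whenever exactly one instrument survives filtering.
- **IVW** (main analysis, ≥2 instruments): weighted regression of β̂_Yj on
  β̂_Xj through the origin with weights w_j = 1/σ_Yj². Cochran's
  Q = Σ w_j (β̂_Yj − β̂ β̂_Xj)² is referred to χ²(k−1); when its p-value
  falls below the heterogeneity threshold (default 0.05/123, a Bonferroni
  adjustment over the 123-outcome panel) the fixed-effect SE is multiplied
  by √max(1, Q/(k−1)) and the result is labelled a random-effects model.
  This is the multiplicative (residual-SE floored at one) convention of the
  standard MR software stack.
- **MR-Egger**: the same weighted regression with an intercept, after
  orienting every instrument so β̂_Xj > 0. The slope estimates β under the
  InSIDE assumption; the intercept estimates average directional
  pleiotropy. The same heterogeneity SE rule is applied with k−2 degrees
  of freedom. (The heterogeneity rule is stated for the main analysis;
  extending it to Egger is this package's choice, for internal consistency.)
- **Weighted median**: per-SNP ratios with normalized weights
  β̂_Xj²/σ_Yj²; the estimate interpolates the ratio at cumulative weight
  0.5, and is consistent while instruments carrying >50% of the weight are
  valid. Its SE is a parametric bootstrap (default 1000 resamples of both
  betas from their stated normal errors). Instruments are sorted by SNP id
  and the bootstrap seed is derived from the id set, so the result is
  invariant to input order.
- **MR-RAPS** (profile score): β̂ minimizes Σ t_j(β)² with
  t_j(β) = (β̂_Yj − β β̂_Xj)/√(σ_Yj² + β² σ_Xj²), which accounts for
  error in the SNP–exposure estimates. The optimum is bracketed on
  [−10, 10] (tolerance 1e-8); the SE is √(2/f″) from the numerical
  curvature at the optimum, which reduces exactly to the IVW fixed-effect
  SE as σ_X → 0. The simple (non-robust, no-overdispersion) profile score
  is implemented. A boundary optimum is reported as non-convergence and
  the method is omitted from the sensitivity table for that pair.

### Radial outlier filtering

Before estimation, instruments pass a radial heterogeneity filter: fit IVW,
compute each SNP's Q contribution Q_j = w_j (β̂_Yj − β̂ β̂_Xj)², and remove
the largest contribution whose χ²(1) tail probability is below
α/k (α default 0.05; the Bonferroni scaling by the current set size matches
radial-MR software convention and keeps the per-set false-removal rate near
α). The fit is repeated after each removal, up to `radial_max_iter` (10)
rounds. Two deliberate choices:

- *Worst-first removal.* Removing all flagged SNPs in one pass fails under
  outlier masking: a single dominant outlier drags the pooled slope far
  enough that every concordant instrument appears heterogeneous in the
  first fit, and the whole set is discarded. Removing one SNP per round and
  refitting removes exactly the planted outlier in simulation.
- *Bonferroni inside the filter.* At a raw per-SNP 0.05 level a homogeneous
  20-instrument set would lose at least one SNP in ~64% of replicates; with
  the α/k threshold homogeneous sets pass untouched ~95% of the time while
  a 10× outlier is still detected essentially always.

## Instrument selection and harmonization

Instruments are SNPs with exposure p < 5×10⁻⁸ (strict inequality), pruned
to an independent set by greedy clumping: visit candidates in ascending-p
order (ties broken by SNP id) and keep a SNP only if its r² with every kept
SNP is < 0.001. LD is a pairwise table input; absent pairs are treated as
independent.

Outcome effects are re-signed onto the exposure's effect allele. Swapped
orientations negate the outcome beta and complement its allele frequency;
non-palindromic strand flips are resolved through the complement;
palindromic SNPs (A/T, C/G) are kept only when both allele frequencies are
available and both lie outside 0.5 ± 0.08 on the same side, otherwise they
are dropped as unresolvable. All drops are counted per category. SNP
matching is by identifier only. Instrument strength is summarized by
F_j = (β̂_Xj/σ_Xj)² and its mean.

## PC-traits: dietary patterns with propagated errors

A PC-trait is a principal component of the *genetic* correlation matrix G of
a group of food items (both correlation matrices are configuration inputs;
estimating them is outside this package's scope). The rotation comes from
the eigendecomposition of G, eigenvalues in descending order, each
eigenvector oriented so its largest-magnitude entry is positive (PC signs
are otherwise arbitrary and every downstream causal estimate would flip with
them; ties in eigenvalues keep the decomposition's native order). Per-SNP
item effects b with SEs s project as

    β_PC = Lᵀ b,    se_PC² = Σ_i Σ_j L_i L_j s_i s_j P_ij,

with L the selected eigenvector and P the *phenotypic* correlation matrix —
the item estimates come from overlapping samples, so their sampling errors
are correlated phenotypically, not genetically.

Candidate instruments for a PC-trait are SNPs associated (p < 5×10⁻⁸) with
at least one member item; each then carries the p-value of its projected
effect in the rotated space (a Wald z-test of β_PC/se_PC), which may exceed
the selection threshold and is used only to order LD pruning. A config
switch (`pc_pvalue_rule: min_pc`) instead assigns the minimum Wald p across
all of the group's components; the Wald p of the target component is the
default as the only self-consistent reading given β_PC and se_PC.
Hierarchical patterns are expressed by letting a group's members be
previously computed PC-traits.

## CUR: corrected-to-uncorrected ratio filtering

Food-frequency GWAS signals are contaminated by heritable traits that change
reporting or behaviour (BMI, lipids, blood pressure, type-2 diabetes,
coronary artery disease, Crohn's disease, ulcerative colitis, educational
attainment). CUR keeps only SNPs whose food association is essentially
direct:

1. **Multivariable MR** with the food trait as outcome: no-intercept
   weighted regression (weights 1/σ_food²) of SNP→food betas on SNP→
   confounder beta columns, the confounders entering by forward stepwise
   selection (add the candidate with the smallest coefficient p while
   p < 0.05; an AIC criterion is available via config). Collinear
   candidates are dropped with a logged trace. This yields causal effects
   α_c of each selected confounder on the food trait.
2. **Expected effect** of SNP j: Σ_c α̂_c b̂_jc — the part of its food
   association mediated by the confounders.
3. **CUR** = (observed − expected)/observed. SNPs are kept iff CUR lies in
   1 ± 0.05 (boundary inclusive; a zero observed effect leaves the ratio
   undefined and the SNP excluded).

The window is treated as a fixed property of the method. Its operating
characteristics depend on scale: the sampling noise of the expected effect
(≈ √(Σ α̂_c² se_c²) per SNP, plus any spurious stepwise admission) must be
small relative to 5% of the observed effect. The validation scenario
(100 instruments, confounder effect α = 0.5, all SEs 0.01) draws direct
effects of magnitude 0.2–0.4 and mediated confounder effects 0.3–0.6 so
that this condition holds by design; at those settings the filter's
sensitivity and specificity both exceed 0.9.

## Grid-level inference and reporting

All main-analysis p-values (IVW or Wald ratio, one per analyzed
exposure–outcome pair) are pooled into a single Storey q-value computation.
π₀ is estimated on the grid λ = 0.05, 0.10, …, 0.95 as
π̂₀(λ) = #{p > λ}/(m(1−λ)), smoothed by a degree-3 polynomial least-squares
fit evaluated at λ = 0.95 and clipped to (0, 1]; with fewer than 100 tests
the estimator is too unstable and π₀ = 1 is used (the q-values then equal
Benjamini–Hochberg step-up values exactly). Sorted q-values are
q(i) = min_{j≥i} π̂₀ m p(j)/j, mapped back to input order. Significance is
declared at q < 0.05 (strict).

Sensitivity concordance is flagged per pair: *opposite direction* when any
sensitivity estimate's sign differs from the main estimate's, and
*attenuated* when any sensitivity |β| falls below half the main |β|. Flags
are reported, never used to drop results automatically.

For display, betas are shrunk by the normal–normal posterior mean under a
N(0, τ²) prior with τ = 0.1: shrunk = β τ²/(τ² + se²), pulling imprecise
estimates toward zero. The heatmap export pairs the shrunk-beta matrix with
a significance mask (q < 0.05).

## The synthetic-data generator

`simulate_grid` produces one complete study: per-trait summary-statistics
tables for 25 food items, 123 metabolites and 11 confounders over a shared
SNP panel, an LD table, PC-group definitions with consistent genetic and
phenotypic correlation matrices, and the full ground truth.

Model, on the standardized scale with SE = 1/√N per study:

- Items are partitioned into clusters (the disjoint cores of the PC groups
  plus singletons). Each *direct* or *pleiotropic* SNP instruments one
  cluster; within the cluster, a shared latent factor gives the declared
  within-group genetic correlation (default 0.6; phenotypic 0.4).
- *Confounder-mediated* SNPs act on one confounder (effect ~ N(0,
  effect_size_sd²)); every confounder affects every item's reporting with
  α = 0.5, and affects metabolites directly (N(0, 0.3²)) — the biasing
  path CUR exists to cut.
- *Pleiotropic* SNPs additionally hit each metabolite with probability 0.2
  with an extra effect N(pleiotropy_mean, 0.05²) (balanced by default;
  directional when the mean is nonzero).
- The true exposure→metabolite grid is sparse (10% nonzero, effects
  N(0, 0.4²)) or entirely null for FDR studies; PC-trait rows of the truth
  grid are the loadings-weighted item rows.
- Exposure, outcome and confounder noise are drawn independently — the
  two-sample property the estimators rely on.

Default sample sizes mirror the studies being emulated: 445,799 (food
GWAS), 24,925 (metabolite GWAS), 1,000,000 (confounder GWAS, modern
meta-analysis scale). `effect_size_sd = 0.1` places instruments in the
strong-lead-hit regime (per-SNP F ≫ 100); this is deliberate, because the
CUR window is only meaningful when instrument effects dominate the noise of
the expected-effect estimate (see above), and MR instrument sets are in
practice built from exactly such hits. The panel-wide share of mediated
SNPs is small (5%) because each one contaminates *every* item at once.

What the generator does **not** emulate: realistic LD (blocks are
constant-r² and block-diagonal), allele-frequency-dependent SEs, winner's
curse in instrument discovery, sample overlap between studies, non-normal
effect-size distributions, and metabolite–metabolite correlation. Passing
tests therefore demonstrate the pipeline's internal correctness and its
behaviour under the stated generative assumptions, not performance on any
real cohort.

## Validation studies (tests/test_acceptance.py, scripts/acceptance.py)

All studies are seeded and sized to run on one CPU in about a minute
total; the problem sizes are stated in `dietmr/studies.py` and reported in
the acceptance JSON (`n` per entry).

- IVW equals an independent brute-force weighted-SSE minimizer (coarse
  grid + interval refinement, no closed form) to 1e-6 on 100 random sets.
- 95% CI coverage on 1000 clean 30-instrument simulations lies in
  [0.93, 0.97]; type-I error on 2000 null simulations in [0.04, 0.06].
- With 40% directionally pleiotropic instruments the weighted median's
  bias stays below 0.02 while naive IVW's exceeds 0.05 (500 runs). This
  study draws all SNP–exposure effects positive — with signed effects,
  ratio-forming turns directional pleiotropy into balanced pleiotropy and
  the contamination washes out — and uses strong instruments so quantile
  noise does not mask the contamination effect.
- The Egger intercept recovers planted mean pleiotropy 0.05 within 3
  Monte-Carlo SEs (500 runs, all effects positive, InSIDE by construction).
- Radial filtering removes a planted 10×-ratio outlier in ≥95% of 500
  replicates and leaves homogeneous sets untouched in ≥95%.
- The CUR scenario above gives sensitivity and specificity ≥ 0.9.
- Propagated se_PC matches the Monte-Carlo SD of projected betas within 2%
  at 10⁶ draws; eigenvalue sums are conserved to 1e-10.
- Storey q-values reproduce the hand-computed 4-test example exactly and
  estimate π₀ ∈ [0.9, 1.1] on 5000 uniform p-values.
- Fifty fully-null 40 × 123 grids through the complete pipeline yield a
  mean false-positive proportion at q < 0.05 within Monte-Carlo noise of
  the nominal level. These grids use a 400-SNP panel (≈5 instruments per
  item), and the sensitivity estimators are disabled — the claim under
  test concerns the main analysis' error control.

## Known limitations

- Weighted-median SE is bootstrap-based and therefore the one
  stochastic component of a run; it is fully determined by the global seed
  and the instrument id set.
- The stepwise MVMR inherits forward selection's instability: with many
  null candidate confounders it occasionally admits one spuriously, and a
  noise column admitted into a no-intercept weighted regression can carry a
  large coefficient. The selection trace is retained for audit.
- CUR filtering is only as good as the scale regime allows (see above); on
  weak instruments it is aggressive by construction.
- At the item level, genetically correlated food items share instruments,
  so a causal effect of one item produces q-significant calls for its
  siblings. Against a strict per-pair truth grid these count as false
  positives; they are better read as the dietary-pattern entanglement that
  motivates analyzing PC-traits alongside single items (the demo driver
  `analysis/02_run_pipeline.py` reports this decomposition).
- π₀ smoothing uses a polynomial fit rather than the spline of the original
  q-value software; on realistic grids the difference is well inside the
  estimator's own sampling noise.
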