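# Methods

This note documents the statistical models implemented in `clonmeth`, the
assumptions of the synthetic-cohort generator, the default parameter
choices and why they were made, numerical details, and known limitations.

## The association model

Methylation beta values β ∈ (0, 1) are analyzed on the M scale,
M = log2(β / (1 − β)), after clipping to [ε, 1 − ε] with ε = 1e-6 (avoids
infinities at the array's dynamic-range limits; the induced bias is
negligible). M values have approximately constant variance across the
methylation range, which the linear models assume.

For twin cohorts, each CpG is fit with the linear mixed model

    M_ij = x_ij' b + u_j + e_ij,    u_j ~ N(0, s2_pair),  e_ij ~ N(0, s2_e),

where j indexes twin pairs (singletons form their own group, at most two
samples per group) and x contains the mutation indicator (or VAF), age,
sex, batch dummies, estimated cell-type fractions, and optionally leading
principal components. For a binary mutation exposure, the comparison group
excludes carriers of the other driver mutations, so a TET2 analysis
contrasts TET2-mutated against mutation-free samples.

**Fitting.** The model has a single variance ratio θ = s2_pair/s2_e.
Rotating each pair into sum and difference components diagonalizes the
marginal covariance (difference variance 1, sum variance 1 + 2θ, singleton
1 + θ on the s2_e scale), so the restricted likelihood at any θ reduces to
weighted combinations of three precomputed Gram blocks. The REML criterion
is minimized by golden-section search on log θ ∈ [−12, 12] (about 50
bracketing steps, vectorized across all probes at once), with an explicit
comparison against the θ = 0 boundary; boundary probes are flagged, not
dropped. This is numerically identical to `lmer`'s REML solution for this
model class (validated against lmerTest to 7 significant digits).

**Inference.** The Wald test on the exposure coefficient uses

- *Satterthwaite degrees of freedom*, obtained by the delta method from the
  REML information of (s2_e, θ) — numerically identical to lmerTest's df on
  validation fits (e.g. 33.76621 vs 33.76621); and
- the *Kenward–Roger (Kackar–Harville) variance inflation*, which accounts
  for the extra variability from plugging in the estimated θ. For the
  compound-symmetry structure V = s2(I + θZZ') the s2- and cross-derivative
  terms of the adjustment vanish identically, leaving the closed form
  2·Var(θ̂)·[G⁻¹(C − BG⁻¹B)G⁻¹] at the exposure coefficient, with G, B, C
  weighted Gram blocks of the rotated design.

Both refinements matter at cohort sizes of ~100–300: with a plain
t(n − rank X) reference the plugged-in θ̂ makes the test systematically
anticonservative (genomic inflation λ ≈ 1.02–1.05 in null simulations at
n = 120, 45 pairs), and even exact Satterthwaite df leaves that bias. With
the KR adjustment the null simulation is calibrated (mean λ = 1.002 over
20 replicate cohorts; Kolmogorov–Smirnov uniformity holds). Flags restore
the plain-df and unadjusted paths for comparison.

Unpaired cohorts (e.g. patient/control replication sets) use per-probe
ordinary least squares with classical t tests; limma-style empirical-Bayes
variance moderation (inverse-chi-square prior fit by moment matching on
log s²) is available but off by default — the cross-cohort logic downstream
depends only on signs and ranks.

**Genomic inflation** is λ = median(χ²_obs)/median(χ²_exp), with χ² the
1-df quantile transform of the two-sided P values.

## Covariate principal components

Adjusting for leading PCs of the M matrix (conventionally k = 4 in
cohort-scale EWAS) is implemented but **off by default**. At simulation scale (120
samples, 2k–20k probes, planted effects at ~1% of probes) a true mutation
signature is itself a leading principal component: plain PC adjustment
absorbs it (recovery drops from 100% to ~20%), while computing PCs on
exposure-residualized M (the surrogate-variable convention) instead
captures the within-carrier clone-size direction, collides with the
exposure after partialling the covariates, and inflates its standard error
several-fold. PC adjustment earns its keep on real arrays with hundreds of
thousands of probes, where technical variance dominates the top components;
with this package's simulated cohorts the fitted model already contains the
true confounders (batch, cell fractions), so the default is no PCs.

## Directional site selection

The significance threshold is chosen from the data: among sites with
P ≤ c, let q(c) be the fraction whose effect sign matches the direction of
interest; the cutoff is the **largest** observed P value with q(c) ≥ 0.95.
Ties in P are pooled inclusively (the proportion is evaluated on ≤-sets).
The selected set is then all directional sites with P ≤ cutoff. When no
cutoff reaches the required purity — typical for small or heterogeneous
cohorts — the K most significant directional sites are taken instead
(K = 2000 by default) and the rule is recorded as `top_k`. Raising the
purity requirement never enlarges the selected set (verified by property
test against an exhaustive cutoff scan).

## Replication and 2×2 testing

Dichotomous associations use Pearson's χ² without continuity correction
unless any expected cell count is below five, in which case the two-sided
Fisher exact test (point-probability method — the sum of hypergeometric
tables no more probable than the observed) is used; the dispatch boundary
sits exactly at expected count 5. The ranked motif enrichment (below) uses
the one-sided enrichment tail instead, as its question is directional.
P values that underflow are reported as the bound 1e-300, never zero.
Cross-cohort concordance drops probes absent from the target cohort from
both numerator and denominator.

## Enrichment

Chromatin-state and CpG-island composition enrichment forms, per category,
the 2×2 of (selected vs background) × (in category vs not), dispatched as
above, and reports within-set and background proportions. Ontology
enrichment follows the regulatory-domain approach: each gene owns a
strand-aware basal window (5 kb upstream, 1 kb downstream of the TSS)
extended in both directions up to 1 Mb but stopping at the nearest
neighboring basal domain — published defaults, since no alternative is
specified. Each selected CpG is a 1-bp region; term significance requires
Bonferroni-corrected P < 0.05 in **both** the region-level binomial test
(against the term's genome-coverage fraction) and the gene-level
hypergeometric test (on genes hit by ≥1 selected site). Domain unions and
coverage fractions are verified against brute-force base-pair counting.

Cell-type-specific enhancer comparisons z-scale the effect estimates over
all probes and contrast A-specific (enhancer in A's segmentation, not in
B's) against B-specific probes with Welch's t test (classical Student's
available by flag; group variances are not guaranteed equal).

## Motif enrichment

Motifs are position probability matrices (MEME-minimal I/O; a missing
background line defaults to uniform). A region's score is the maximum
log-odds, score(l, b) = log2((p_lb + pseudocount)/bg_b) with pseudocount
1e-3, over all windows on both strands; N bases contribute zero. A region
is a *hit* when its score is ≥ 0 bits — the motif model is at least as
likely as the background — a deliberate simplification of AME's internal
thresholding options. For each motif, every partition of the descending
hypermethylation ranking into top-i vs rest (every rank for n ≤ 1000, else
1000 evenly spaced) is tested with the one-sided Fisher/hypergeometric
tail; the minimum P over partitions, multiplied by the number of motifs
*and* partitions tested (the conservative choice; motif-count-only
correction available by flag), is the E value, and E < 0.05 calls
enrichment. Under random ranks the per-motif enrichment rate is far below
5% (the correction is conservative by construction); planted motifs in the
top 20% of 500 regions are detected with the optimal partition within a few
ranks of the planted boundary. When two effect rankings are available
(mutation status and clone size), the composite ranking score is the mean
of the two z-normalized effect vectors.

## Prediction

Mutation status is predicted from methylation with elastic-net logistic
regression minimizing −loglik/n + λ[(1−α)‖β‖²/2 + α‖β‖₁], α = 0.5 by
default ("elastic net" without qualification suggests a genuine mix;
α is exposed and reported in all outputs). The solver is IRLS with cyclic
coordinate descent on the penalized weighted quadratic approximation,
warm-started along a descending 30-point log-spaced λ path
(λ_max·1e-3 floor), with a step-halving safeguard that makes the penalized
objective monotone. KKT conditions are property-tested at convergence, and
the λ → 0 limit matches unpenalized Newton–Raphson MLE to 1e-4.
Out-of-sample performance uses leave-one-out cross-validation: per held-out
sample, inner 10-fold stratified CV on the remaining samples picks λ by
minimum mean binomial deviance (λ-min rule), the model is refit and the
held-out probability recorded. Features are standardized inside each
training set only. Labels use cutoff 0.5 with ties classified positive.
Among carriers, predicted probability is regressed on VAF to report the
clone-size association.

## The synthetic-data generator

A simulated cohort is built as follows. A genome (default 20 Mb for 20k
probes, single chromosome) is tiled into ~1 kb segments labelled with the
15 ChromHMM-style states per cell type, using a monocyte-like composition
(6% EnhA, 48% quiescent, …). Probes fall at random positions; their
CpG-island relation is drawn conditionally on chromatin class (promoters
mostly islands, enhancers mostly open sea, matching array-wide
composition). Reference beta profiles per cell type follow the island
relation (islands low, open sea high) with cell-type deviations of SD 0.2
M-units, plus 25 marker probes per cell type (0.9 in that type, 0.1
elsewhere) so deconvolution is identifiable.

Each sample's baseline beta vector is its Dirichlet-drawn cell-fraction
mixture of the reference profiles (granulocyte-dominant whole-blood
composition, concentration 150). On the M scale the simulator then adds:
a per-(pair, probe) Gaussian twin intercept (SD = 0.5 × noise_sd) shared by
co-twins — probe-specific, matching the per-CpG random-intercept analysis
model; per-(batch, probe) shifts (SD 0.1); planted mutation effects; and
iid noise (SD 0.25). The result maps back to (0, 1).

Planted effects are linear in clone size: an affected probe shifts by
(effect size) × VAF in carriers, motivated by the observed correlation of
methylation with VAF at associated sites and recorded as a simulator
assumption. Defaults: TET2 effect +5/3 M-units per VAF unit with
VAF ~ U(0.1, 0.5), so the mean carrier shift is 0.5 M-units; DNMT3A −5/3 at
~10× fewer probes. Affected probes are drawn per state: probability 0.06 in
EnhA/EnhG and 0.006 elsewhere, giving ~1% affected overall at 10:1 enhancer
odds and ~35% of affected probes in EnhA — so a successful analysis
reproduces an enhancer fraction of the selected set near 30%, with
background near 5–7%. Cohort structure defaults to 45 twin pairs plus 30
singletons (120 samples), TET2 carrier rate 1/3 and DNMT3A 0.15 — sized for
the power analyses the package is validated on rather than to any
particular registry cohort, whose carrier rates are much lower. TET2
carriers also receive a +3-percentage-point monocyte-fraction bump
(direction reported for real carriers; magnitude unpublished, chosen
small). Twin pairs share age and sex.

A *zero-effect* (null-calibration) configuration sets the effect sizes
**and** the monocyte bump to zero: the composition shift is itself part of
the mutation phenotype, and leaving it active injects genuine
composition-mediated signal that a calibration experiment must not contain.

Companion generators produce: variant-call tables with artifact rows
exercising each filter rule; detection-P/bead-count channels for QC;
MEME-format PWM sets; and ranked 200 bp region sets with a motif consensus
(optionally mutated per base) embedded in the top fraction of the ranking,
with truth labels.

**What the simulator does not emulate.** Probe-type chemistry differences
(Infinium I/II) and functional/SWAN normalization; spatially correlated
probes (each probe is independent given the sample state); realistic
linkage between chromatin states across cell types (segmentations are
independent per cell type, which makes cell-type-specific enhancer sets
larger than in reality); registry-scale carrier rates; measurement-error
structure of IDAT intensities. Passing the recovery experiments therefore
demonstrates correctness of the statistical machinery under the stated
generative model, not performance on any particular array product.

## Numerical details and conventions

- BED intervals are 0-based half-open; manifest and TSS positions 1-based.
  A 1-based position p lies in [start, end) iff start ≤ p−1 < end.
- Regions around CpGs are [pos − flank, pos + flank) with flank 100
  (200 bp), clipped at contig bounds with a warning.
- Deconvolution solves nonnegative least squares with Σf ≤ 1 by an
  active-set method (exact for the small cell-type counts used); residual
  mass is implicit.
- Overlapping segmentation intervals resolve first-wins after sorting, with
  a warning; ties in P-value selection include all tied sites.
- The PCA outlier screen uses robust z-scores (median/1.4826·MAD) with
  z_max = 6 by default; flagging is reported, removal is caller-controlled.
- All generators take explicit integer seeds and are byte-reproducible;
  pipeline artifacts carry JSON sidecars with parameters, seed, package
  version and input checksums.

## Problem sizes used in the validation experiments

Null calibration runs five independent 120-sample cohorts at 20k probes;
planted recovery one such cohort; motif null calibration 200 replicates of
60 regions with 2 motifs and detection 500 regions with 5 motifs; predictor
recovery n = 150 with 50 features (10 causal, +2 SD shift). These sizes
give stable Monte-Carlo behavior while keeping the full validation suite
and the reproduction script in the minutes range on one CPU.

## Known limitations

- The KR-adjusted Wald t is still an approximation; at very small pair
  counts (<15 pairs) a parametric bootstrap would be preferable.
- The directionality threshold is a data-dependent selection rule; the
  package reports it with provenance but does not correct downstream
  enrichment P values for the selection event (matching field practice).
- AME's hit-threshold optimization and background models are not
  reproduced; the fixed 0-bit hit rule is documented above.
- GREAT's curated ontology and regulatory-domain database are not bundled;
  ontology tests run on user-supplied term→gene and TSS tables.
- The elastic-net path uses a fixed λ grid per training set; glmnet's exact
  grid endpoints can differ slightly.
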