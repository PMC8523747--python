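# clonmeth

Analysis of DNA-methylation changes driven by clonal-hematopoiesis mutations
(TET2, DNMT3A) in CHIP, CCUS and AML cohorts — and a synthetic-cohort
generator for validating every step of that analysis.

Somatic loss-of-function mutations in *TET2* (a 5mC dioxygenase) cause CpG
hypermethylation concentrated at active enhancers, while *DNMT3A* mutations
cause hypomethylation. `clonmeth` implements the statistical pipeline used
to establish and characterize these associations from Illumina-style
methylation arrays:

- **Preprocessing** — probe-level QC (zero signal, bead counts, detection-P
  call rates, sex chromosomes, exclusion lists), beta ↔ M transforms,
  reference-based (Houseman-style) cell-type deconvolution by constrained
  projection, robust PCA outlier screening, per-batch mean centering, and
  CHIP variant-call filtering (VAF ≥ 2%, population MAF ≤ 1%, exclusion of
  twin-concordant near-heterozygous variants).
- **Twin-aware EWAS** — per-CpG linear mixed model
  `M ~ mutation + age + sex + batch + cell fractions (+ PCs)` with a twin-pair
  random intercept, fit by profile REML over the variance ratio
  θ = σ²_pair/σ²_ε, with Satterthwaite degrees of freedom and the
  Kenward–Roger small-sample variance adjustment; ordinary least squares for
  unpaired cohorts (optional empirical-Bayes variance moderation); genomic
  inflation factor λ = median(χ²_obs)/median(χ²_exp); per-site VAF
  (clone-size) directionality checks.
- **Directional site selection** — the significance threshold is the largest
  P-value cutoff below which ≥95% of sites share the direction of interest
  (hyper for TET2, hypo for DNMT3A); a top-K fallback (K = 2000) when no
  cutoff reaches that purity.
- **Replication** — cross-cohort direction concordance of selected site
  sets, and 2×2 association tests with the classical dispatch rule
  (Pearson χ² unless an expected cell < 5, then two-sided Fisher exact).
- **Enrichment** — ChromHMM chromatin-state and CpG-island composition
  (2×2 per category), GREAT-style ontology enrichment treating each CpG as a
  1-bp region (basal-plus-extension regulatory domains, region-level
  binomial + gene-level hypergeometric, Bonferroni), and comparisons of
  scaled effect sizes at cell-type-specific enhancers (HSC vs monocyte).
- **Motif enrichment** — PWM scanning of 200 bp regions centered on CpG
  sites (max log-odds over both strands), ranked-sequence enrichment by
  partition-maximized one-sided Fisher tests with multiplicity-corrected
  E-values (E < 0.05), composite hypermethylation ranking scores, and
  motif-family (ETS, C/EBP) summaries.
- **Prediction** — elastic-net logistic regression (IRLS + cyclic coordinate
  descent, glmnet objective) with leave-one-out cross-validation, inner
  k-fold λ selection by binomial deviance, confusion metrics, and the
  association of predicted probability with clone size.
- **Simulation** (`clonmeth.synthdata`) — twin/unpaired cohorts as
  cell-fraction-weighted mixtures of reference profiles with planted
  VAF-proportional M-scale shifts at enhancer-biased probes, chromatin
  segmentations, TSS tables, variant calls, and ranked region sets with
  planted transcription-factor motifs — all seeded and recorded in truth
  tables so recovery can be scored exactly.

## Worked example

```python
from clonmeth import synthdata as sd, ewas, siteselect as ss, enrichment as en

ann, beds, tss = sd.make_annotation(20_000, seed=1)
refs, markers = sd.make_reference_profiles(ann, seed=2)
cohort, truth = sd.simulate_cohort(sd.SimDesign(seed=3), ann, refs)

spec = ewas.DesignSpec(exposure="mut_TET2", exclude_other_chip=("mut_DNMT3A",))
table = ewas.run_ewas(cohort, spec)
hyper = ss.select_hyper_set(table, direction=+1)

print(f"cohort: {cohort.n_samples} samples x {len(cohort.probes)} probes, "
      f"{int(cohort.samples['mut_TET2'].sum())} TET2 carriers")
print(f"genomic inflation lambda = {ewas.genomic_inflation(table['p']):.2f}")
print(f"selection rule: {hyper.rule}, cutoff P = {hyper.cutoff:.2e}, "
      f"{len(hyper)} hypermethylated sites")
planted = truth.index[truth["affected_TET2"]]
print(f"recovered {planted.isin(hyper.probes).sum()} of {len(planted)} planted sites")

sites = ann.rename(columns={"state_monocyte": "state"})
comp = en.composition_enrichment(hyper.probes, sites, "state").set_index("category")
row = comp.loc["EnhA"]
print(f"active-enhancer (EnhA) fraction: {100*row['prop_set']:.0f}% of selected "
      f"vs {100*row['prop_background']:.0f}% of background (P = {row['p']:.1e})")
```

Output:

```
cohort: 120 samples x 20000 probes, 32 TET2 carriers
genomic inflation lambda = 1.00
selection rule: proportion_threshold, cutoff P = 5.95e-04, 221 hypermethylated sites
recovered 215 of 216 planted sites
active-enhancer (EnhA) fraction: 30% of selected vs 5% of background (P = 5.7e-58)
```

The cohort carries a planted hypermethylation signature at ~1% of probes
(10:1 enhancer-biased, M-shift proportional to clone size). The
directionality rule fires at P ≈ 6e-4, the selected set recovers 215/216
planted sites, and — as in real TET2-mutated blood — the selected sites
concentrate in active-enhancer chromatin.

The same analyses are scriptable from the shell:

```bash
clonmeth run --seed 7 --out results/demo          # simulate → … → predict
clonmeth ewas --config config.yaml --seed 7 --out results/demo
```

Each stage writes TSV tables with JSON provenance sidecars (parameters,
seed, version, input checksums) plus QQ/volcano/directionality plots, and
`clonmeth run` checkpoints completed stages so interrupted pipelines resume.

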