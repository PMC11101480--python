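# Methods

## Overview

`emtridge` implements a phenotype-anchored signature-transfer procedure:
six in-vitro plasticity phenotypes measured on a small panel of cell lines
are each regressed on baseline gene expression with an L2 penalty, the
penalty is tuned by leave-one-out cross-validation, concordant models are
consolidated, and the resulting coefficient vectors are projected onto
patient biopsies to produce per-patient mesenchymal-plasticity scores.
This note records the modelling assumptions, the numerical choices, what
the synthetic cohorts do and do not emulate, and the design decisions made
where the procedure was genuinely open.

## Phenotype quantification

- **Marker induction.** Flow-cytometry geometric mean fluorescence is
  background-corrected by *subtracting* the isotype control
  (ΔgMFI = gMFI − isotype), floored at 1e-6 of the isotype value so the
  log stays defined when signal is indistinguishable from background. The
  phenotype entered into the model is log2(ΔgMFI_CRT / ΔgMFI_untreated) —
  the fold induction of the marker under chemoradiation. Subtraction (not
  a ratio) was chosen for the isotype correction because the control
  measures additive background fluorescence.
- **Morphology.** The onset of mesenchymal morphology is encoded as a rank
  per observer (lower = faster transition; midranks for ties), averaged
  over ≥ 2 blinded observers. Ranks rather than day counts keep the score
  scale-free, matching the scaled-and-centered regression input.
- **Observer agreement.** Cohen's kappa with chance agreement from marginal
  products; for ≥ 3 observers the package reports all pairwise kappas and
  their mean (Cohen's statistic is inherently pairwise; Fleiss' kappa is a
  different estimand and is not used). Kappa is undefined when both raters
  are constant with identical marginals, and that case raises explicitly.

## Gene filtering

Two deterministic stages, computed on the shared gene universe:

1. **Expression filter** — intersection of each cohort's top
   `expressed_fraction` (default 0.33) of genes by mean expression; the
   per-cohort cutoff is `floor(fraction × n_shared)`; boundary ties break
   lexicographically by gene id. "Expressed in both cohorts" is
   operationalised as membership in both top-tertile sets.
2. **Variance filter** — top `n_variable` (default 5000) of the surviving
   candidates by variance on the *cell-line* matrix (the training cohort
   defines informativeness; the tumor cohort's variance mixes in stromal
   and cellularity variation).

The normalisation entry point (`normalize_log2`: equal-column-sum scaling
followed by log2(x+1)) is a deliberately simple library-size stand-in for a
variance-stabilising transform and is bypassed for data that is already on
a log scale, as the synthetic cohorts are.

## Ridge model and penalty selection

With X the training matrix (lines × genes, each gene standardized to mean
0 / sd 1 with denominator n−1) and y the scaled-and-centered phenotype:

- β̂(λ) solves (Xcᵀ Xc + λI) β = Xcᵀ yc on centered data; the intercept is
  the response mean. For p > n the dual form
  β = Xcᵀ (Xc Xcᵀ + λI)⁻¹ yc is used — algebraically identical for λ > 0
  and O(n²p) instead of O(p³). λ = 0 with p ≥ n is rejected as
  rank-deficient.
- Replicate expression columns are averaged per cell line before training,
  so the number of LOOCV folds equals the number of lines (8 by default).
- The LOOCV error curve over a 50-point log grid on [1e-3, 1e5] is
  computed from a single SVD of Xc via the exact leverage identity
  e₍ᵢ₎ = eᵢ/(1 − hᵢᵢ), hᵢᵢ = 1/n + Σₖ u²ᵢₖ s²ₖ/(s²ₖ + λ) — the hat
  diagonal of the ridge smoother with an unpenalised intercept. The test
  suite holds this identity to 1e-8 against n explicit refits; ties in the
  minimal error resolve toward the larger λ (more regularisation).
- **Transfer standardization.** How cell-line-scale coefficients meet
  biopsy-scale data is the largest open design point. The default
  re-standardizes each model gene *within the target cohort* (per-gene
  mean/sd of the biopsies), which removes cohort-level location/scale
  differences; training-scale standardization is available behind a flag.
  Model genes missing from the target (or constant in it) contribute 0 —
  mean imputation under standardization. Prediction requires ≥ 50% of the
  model's genes to be present.

## Model consolidation

Each model's leave-one-out predicted training scores are Spearman-
correlated with every measured phenotype and with every other model's
predictions; z-scores use the Fisher transform z = atanh(r)·√(n−3)
(|r| capped at 1−1e-12 and flagged — exact rank agreement is routine at
n = 8). A model is selected when its LOOCV self-correlation is ≥ 0.5 and,
under iterative pruning of the weakest candidate, its median correlation
with the other candidates' predictions is ≥ 0.5. Both thresholds are
configuration, not constants of nature; Spearman is used throughout for
robustness at n = 8.

## Enrichment

The top 25 positive-coefficient genes of each selected model are pooled
(deduplicated union) and tested per TF-target set with the one-sided
hypergeometric tail, conditioning on the post-filter 5,000-gene universe
as background — the statistically defensible background, since only those
genes could have entered a model. Odds ratios use a Haldane 0.5 correction
when a 2×2 cell is zero; q-values are Benjamini–Hochberg across all tested
sets; sets without background overlap are skipped and logged. Negative
coefficients are not pooled: the volcano-style consolidation asks which
regulators drive the *induced* program.

## Outcome statistics

Implemented in-package (scipy/lifelines act only as cross-check oracles in
the tests), with explicit exact/approximate crossovers:

- Mann–Whitney U: exact enumeration of the U null for pooled n ≤ 12
  without ties; otherwise normal approximation with tie correction and
  0.5 continuity correction.
- Welch t with Welch–Satterthwaite degrees of freedom (the recurrence
  comparison is one-sided: higher plasticity score in recurrent patients).
- Spearman: Pearson of midranks; p by full permutation enumeration for
  n ≤ 8, else the t approximation with n − 2 df.
- Median dichotomization sends ties to the "low" group (deterministic and
  conservative); a degenerate all-equal split warns.
- Kaplan–Meier product-limit estimator and the two-group log-rank test
  with hypergeometric variance at each event time.
- Mandard association: pairwise Mann–Whitney across populated regression
  grades, uncorrected by default (per-pair reporting), BH behind a flag.
- Missing clinical fields propagate as missing and are excluded pairwise
  per association.

## Synthetic cohorts

The generator emulates the study design: a latent plasticity factor
s ~ N(0,1) per sample; expression b_g + w_g·s + ε with gene baselines
b ~ N(8, 2) on a log2-like scale (program genes N(10, 1), placing them in
the expressed tail, as EMT genes are in this tissue), ε ~ N(0, noise_sd);
8 lines × 2 replicates and 100 patients. Loadings w are zero outside the
informative block; inside it, signs split half positive / half negative
and magnitudes are log-normal around `effect_size` (σ_log = 0.8) — a core
of strongly driven genes with a long weak tail. Three phenotypes
(morphology, CDH2, ZEB1) equal s plus N(0, 0.3) measurement noise; three
(CD24, CXCR4, VIM) are pure N(0,1) noise. The causal TF's regulon is 200
genes drawn from the positively loaded program genes (consensus TF-target
sets are typically hundreds of genes), hidden among 25 same-sized random
decoy sets. Outcomes couple to s: Mandard grade by quartile thresholds on
s + N(0, 0.5); recurrence ~ Bernoulli(logistic(s)); survival exponential
with hazard (1/40 month⁻¹)·exp(s), censored with probability
`censor_rate` (default 0.3) uniformly before the event time. Ground-truth
files are written to a separate `ground_truth/` directory the pipeline
never reads.

Default `n_informative` is 2000 of 20,000 genes. This is a deliberate
design condition, not a neutral number: with 8 training samples and 5,000
standardized genes, leave-one-out prediction can only see the latent
factor if the program carries a dominant share of the variable-gene
covariance — which is also the situation in real panels where EMT is the
main axis of variation. With a much smaller program the generated cohorts
contain no LOO-recoverable signal at n = 8 and the selection stage
(correctly) returns nothing.

**What the generator does not emulate:** read counts and their
mean-variance relation, batch effects, correlated co-expression outside
the single program, tumor cellularity/stromal admixture, histological
subtype structure, and competing risks. Consequently, passing recovery
tests show that the pipeline's machinery is correct and statistically
calibrated under its own assumptions — not that real biopsies carry this
much recoverable signal.

**A property worth knowing:** models anchored to pure-noise phenotypes
still transfer with *large-magnitude* rank correlation to the latent
factor, but with a chance-determined sign — at n = 8, any response has a
non-trivial chance correlation with the factor, and the dominant program
direction amplifies whatever component the fit picks up. Across seeds the
sign flips, so the signed median across runs is near zero while the median
magnitude is high. This is the in-silico image of phenotype models that
"fail to be consistently predictive", and it is why model selection gates
on LOOCV self-concordance rather than on transfer performance.

## Numerical conventions

- Data files are written at full float precision (%.17g): write/read
  round-trips are exact to 1e-12. Report tables use 6 significant digits.
- All orderings (filters, top-gene lists, set enumerations) break ties by
  identifier, so every stage is deterministic given its inputs; the run
  manifest records SHA-256 hashes of all inputs and outputs.
- Duplicate gene rows at read time keep the row with the highest mean
  expression and log the event.
- p-values are floored at the smallest positive float, never reported as 0.

## Known limitations

- The concordance thresholds (0.5/0.5) and the iterative-pruning rule are
  one reasonable operationalisation of "mutually concordant"; at n = 8 a
  noise model occasionally slips past the self-correlation gate.
- Target-cohort standardization assumes the target cohort is large enough
  for stable per-gene moments; it is not meaningful for single-sample
  prediction.
- The LOOCV error curve at n = 8 is nearly flat over weak penalties for
  strongly factor-coupled phenotypes, so the selected λ is not itself
  interpretable; only the induced score ordering is.
- The enrichment background is the filtered gene universe; results are
  conditional on the filter chain.
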