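# Methods

This note documents the statistical model behind each stage of `microrem`,
the defaults and why they were chosen, and what the synthetic-data
generator does and does not emulate.

## Synthetic cohorts

The generator (`microrem.simulate`) emulates a 5-year dietary-intervention
cohort of newly diagnosed type 2 diabetes patients with coronary heart
disease: by default 110 subjects, 44 responders (remission within
follow-up) and 66 nonresponders, 60 genera.

**Composition.** Genus abundances follow a logistic-normal model: a
per-genus baseline log-intensity is drawn once per cohort from N(0, 2²)
(heavy-tailed genus frequency spectrum), per-sample log-normal noise with
SD `overdispersion` (default 1.0, a typical within-genus log-abundance SD
in 16S genus tables) is added, and the intensities are closed to sum to 1.
A logistic-normal was preferred over a plain Dirichlet because genus
tables are heavy-tailed and correlated; closure induces the usual negative
compositional correlation. Planted effects act multiplicatively on the
log-scale intensity *before* closure, so `effect_fold` is a
pre-compositional fold change: beneficial genera get × `effect_fold` in
responders, detrimental genera in nonresponders. With the defaults
(fold 2, n = 110), a per-genus two-sample z-approximation
(log 2 / (1.0·√(1/44 + 1/66)) ≈ 3.6) puts Kruskal–Wallis power well above
0.8, which the test suite confirms empirically. No multinomial count layer
is added on top of the closed composition: the emitted table is the
relative-abundance matrix the downstream analysis consumes.

**Clinical covariates.** Continuous covariates are drawn per group from
normal distributions whose means, SDs and responder−nonresponder shifts
are calibrated to the magnitudes of such cohorts (e.g. BMI 31.7 vs
29.2 kg/m², SD 4; disposition index 0.46 vs 0.65, SD 0.28; SDs on the
SEM·√n scale). A single shared latent factor induces an equicorrelation of
~0.2 among the metabolic covariates; non-negative quantities are floored.
Binary covariates (gender, medication, histories) are Bernoulli with
per-group rates; statin-treatment intensity is a 3-level ordinal
(15/55/30%). `covariate_shift` overrides any continuous shift. This is
plumbing for adjustment variables, not a physiological model: covariates
are conditionally independent of the microbiome given group.

**Outcomes.** Responders get a remission time uniform on
(0, `followup_years`] — the hazard shape over follow-up is unknown, so the
uniform is a deliberate stand-in — and nonresponders are censored at the
horizon. For proportional-hazards parameter recovery there is a separate
exponential-hazard generator (`simulate_tertile_survival`) with hazard
λ·r^(tertile−1), i.e. a known per-step rate ratio r.

**LPS.** Fasting LPS is log-normal; the postprandial fold change is
coupled to the per-sample beneficial-minus-detrimental abundance contrast
through a Gaussian copula on ranks. The latent Pearson correlation is set
to 2·sin(π·`lps_coupling`/6) so that the implied Spearman correlation
equals `lps_coupling` (default −0.5, an ordinal inverse relation).

**What passing tests show.** Recovery, AUC and monotonicity results on
these cohorts demonstrate that the pipeline's inference chain is correct
and well calibrated under its own assumptions. Real 16S data add
phylogenetic covariance structure, zero inflation, sequencing-depth
variation and microbiome–covariate dependence that the generator does not
emulate, so the synthetic pass rates are not estimates of performance on
real cohorts.

## α-diversity

"Main α-diversity indexes" are taken as the canonical 16S set: observed
richness, Chao1, Shannon (natural log by default; the base is a flag) and
Simpson (1 − Σp²). Chao1 is S_obs + F₁²/(2F₂), with the bias-corrected
F₁(F₁−1)/(2(F₂+1)) term when no doubletons exist; it is reported as
missing on relative data, where singleton counts are undefined. Group
comparison uses two-sided Mann–Whitney U rather than a t-test because
diversity indexes are non-normal at n ≈ 50.

## Differential abundance

The two-stage procedure mirrors the published LDA-effect-size (LEfSe)
method in its two-class form (there is no subclass factor here, so the
subclass Wilcoxon stage is omitted):

1. **Screen.** Per-taxon two-class Kruskal–Wallis with midrank tie
   correction; χ² approximation for combined n > 20, exact enumeration of
   all C(n, n₁) rank splits for n ≤ 20. Constant taxa get p = 1 and are
   flagged degenerate. Default α = 0.05.
2. **Effect size.** On the per-million scale, 30 bootstrap rounds
   subsample each class without replacement at 2/3 (minimum 3 per class)
   and fit a two-class LDA with analytic shrinkage regularization (genus
   count ≫ sample count makes the raw within-class covariance singular).
   Per feature f, the effect combines the unit-normalized discriminant
   coefficient w_f with the raw class-mean difference:
   e_f = |w_f·(m̄₁−m̄₂)_proj + Δmean_f| / 2, averaged over bootstraps.
   The reported score is sign(enrichment)·log₁₀(max(ē_f, 1)) — the floor
   at 1 keeps sub-unit effects at score 0 instead of −∞. Taxa pass at
   p < α and |score| > 2.

Per-bootstrap subsample streams are keyed by class membership, not by
label value, so relabeling the two classes flips every score's sign while
leaving magnitudes unchanged. This is a faithful re-implementation of the
procedure, not a bit-exact clone of the original tool; scores agree with
closed-form expectations in the single-feature case and recover planted
effects with correct directionality.

## Random-forest classification

Feature variants: classic risk variables (gender, age, BMI, HDL,
triglycerides, HbA1c, physical activity, fruit/vegetable consumption,
antihypertensive medication, family history of diabetes), OGTT-derived
indexes (HOMA-IR, disposition, hepatic insulin resistance, insulin
sensitivity, muscle insulin sensitivity, insulinogenic), the genus-level
microbiome, and combinations; the diet arm and statin intensity enter
every design matrix. Missing clinical values are median-imputed and
logged.

Evaluation is stratified 10-fold cross-validation. Forest defaults
(n_trees = 1000, √p features per split, unlimited depth, class-balanced
bootstrap) are standard choices exposed in the config. Per-fold ROC curves
are vertically averaged on a 101-point specificity grid (mean ± SD), AUC
is mean ± SD across folds, and the sensitivity/specificity operating point
is Youden's J on the pooled out-of-fold probabilities — a reproducible,
threshold-free rule. MDA importance permutes each held-out feature column
(5 repeats per fold by default, batched into one forest prediction per
fold for speed) and averages the accuracy drop over repeats and folds;
held-out permutation was chosen over out-of-bag importance to stay inside
the same 10-fold evaluation framework. All randomness derives from one
seed via independent substreams; fold assignments are exposed for audit.

## Response prediction score

Direction per taxon: beneficial if the responder mean baseline relative
abundance exceeds the nonresponder mean, detrimental if the reverse; an
exact tie excludes the taxon (contributes 0) rather than forcing an
arbitrary direction. Tertiles use empirical 1/3 and 2/3 quantiles with
linear interpolation, boundary values assigned downward (≤), computed on
the full cohort; taxa with fewer than 3 distinct abundances are dropped
with a log entry. The patient score is the exact signed sum Σ sᵢ·MDAᵢ with
the +1/0/−1 tertile coding (protective tertile +1), using MDA weights as
emitted by the classifier without re-normalization. Score tertiles use the
same quantile rule; with fewer than 3 distinct scores the assignment falls
back to ranks with ties sharing a tertile.

By default the MDA weights come from the microbiome-only model
(configurable via `mda_variant`), since the score is defined over the
microbiome feature space.

## Outcome models

Cox proportional hazards (lifelines, Efron ties) with T1 as reference and
two adjustment sets: primary (age, BMI, gender, diet, HDL, triglycerides,
statin intensity) and extended (plus smoking and histories of myocardial
infarction, stroke/TIA, peripheral vascular disease, hypertension, CABG,
PCI). Constant covariates are dropped with a warning. When strongly
predictive tertiles completely separate the events the unpenalized MLE
diverges; the fit then retries with a small ridge penalty (0.1, then 1.0)
and logs it. Adjusted cumulative remission-probability curves are
model-based: the fitted survival function evaluated at each tertile's
covariate means.

Contingency tests are Pearson χ² without continuity correction — the
convention that reproduces standard clinical baseline-table p-values
exactly — with Yates correction behind a flag. The score–LPS association
reports the 3×3 cross-tabulation, the χ² test (statistic *and* p-value,
to avoid the common ambiguity of reporting a bare "χ² =" number) and a
Spearman rank correlation of the tertile indices as the directionality
summary. Baseline tables use two-group one-way ANOVA (identical to the
pooled-variance t-test, F = t²) for continuous variables and χ² for
categorical ones, reporting mean ± SEM per group.

## Numerical and design choices

- Seeds: every stochastic component accepts one integer seed and derives
  substreams with `numpy.random.SeedSequence`; identical configs are
  bit-reproducible, including pipeline manifests (SHA-256 per output).
- Tolerances: compositional closure to 1e-9 (relative) / 1e-3
  (per-million); score recomputation from emitted signs and weights is
  exact, not approximate.
- Tie-breaks: top-taxa and cladogram orderings break MDA/|LDA| ties
  lexicographically by lineage for stable output.
- Degenerate inputs fail loudly and specifically: zero-sum samples,
  constant taxa, empty classes, zero contingency margins, all-censored
  survival data.
- BIOM input is optional; the TSV dialect (lineage-string columns,
  `sample_id` first) is the primary interchange format.

## Problem sizes

Replicated experiments (recovery rates, AUC distributions, coverage,
oracle comparisons) use 10–50 cohort replicates, forests of 300 trees and
n = 110–1000 subjects as noted per check; single-run analyses default to
1000 trees. These sizes give stable estimates of the checked proportions
(Monte-Carlo SE of a 90% rate over 500 planted genera is ~1.3%) while
keeping the full suite fast.

## Known limitations

- The generator's covariates are independent of the microbiome given the
  outcome; real cohorts have diet–microbiome–covariate dependence.
- Uniform remission times encode no hazard shape; Cox curves on default
  synthetic cohorts are therefore illustrative, and parameter-recovery
  claims rest on the exponential-hazard generator.
- The LEfSe stage is two-class only and does not reproduce the original
  tool bit-for-bit.
- Single-cohort scope: tertile cutpoints and score weights are estimated
  and applied on the same cohort, as in the underlying design; no
  external-validation machinery is provided.
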