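# microrem

Baseline gut-microbiota profiling for predicting dietary-intervention-induced
**type 2 diabetes remission**.

Newly diagnosed type 2 diabetes can remit under sustained dietary
intervention (low-fat or Mediterranean diet), and the baseline gut
microbiota carries signal about who will remit. `microrem` implements the
complete analysis chain for a genus-level 16S cohort of responders
(patients whose diabetes remitted within 5-year follow-up) and
nonresponders:

1. **Abundance tables & α-diversity** — validated sample-by-genus
   compositional tables with taxonomy lineages; observed richness, Chao1,
   Shannon, Simpson; Mann–Whitney group comparison.
2. **Differential abundance (LEfSe-style)** — Kruskal–Wallis screen
   (p < 0.05) followed by bootstrapped regularized LDA effect sizes,
   reported as signed log₁₀ scores with a |LDA| > 2 cutoff and a
   cladogram-ready table.
3. **Random-forest classifiers** — stratified 10-fold CV over feature sets
   (classic clinical risk variables, OGTT-derived insulin indexes, the
   genus-level microbiome, combined), always adjusted for diet arm and
   statin-treatment intensity; vertically averaged ROC (mean ± SD),
   Youden operating point, and **mean decrease accuracy** (MDA) permutation
   importance.
4. **Microbiome-based response prediction score** — for each of the top-10
   MDA genera, a direction (beneficial = higher mean baseline abundance in
   responders; detrimental = the reverse) and cohort tertile coding:

   score(patient) = Σᵢ sᵢ · MDAᵢ, with sᵢ ∈ {−1, 0, +1}

   where for a detrimental genus T1/T2/T3 → +1/0/−1 and for a beneficial
   genus T1/T2/T3 → −1/0/+1, so |score| ≤ Σ MDAᵢ.
5. **Outcome models** — Cox proportional hazards of remission by ascending
   score tertile (T1 reference, Efron ties, primary and extended adjustment
   sets), χ² association of score tertiles with postprandial LPS
   fold-change tertiles (metabolic endotoxemia), and mean ± SEM baseline
   tables (one-way ANOVA / χ²).
6. **Synthetic cohorts** — a logistic-normal compositional generator that
   plants responder/nonresponder-enriched genera, draws correlated clinical
   covariates, remission event times and LPS fold changes inversely coupled
   to the beneficial-taxon burden, so the whole pipeline is testable
   without patient data.

## Worked example

```python
from microrem import (FeatureSpec, SimulationConfig, build_features,
                      build_score_rules, cv_random_forest, generate_cohort,
                      mda_importance, patient_score, top_taxa)

cohort = generate_cohort(SimulationConfig(seed=1, effect_fold=4.0))
X, y = build_features(cohort.abundance, cohort.cohort, FeatureSpec("microbiome"))
cv = cv_random_forest(X, y, k=10, n_trees=300, seed=5)
print(f"AUC {cv.auc_mean:.3f} +/- {cv.auc_sd:.3f}, "
      f"sens {cv.sensitivity:.2f}, spec {cv.specificity:.2f}")

imp = mda_importance(X, y, k=10, n_trees=300, seed=5)
top = top_taxa(imp, m=10)
rules = build_score_rules(cohort.abundance, cohort.cohort.responder, top)
result = patient_score(cohort.abundance, rules)
print(result.tertiles.value_counts().sort_index().to_string())
```

prints (strong-signal synthetic cohort, n = 110 with 44 responders):

```
AUC 0.997 +/- 0.011, sens 0.98, spec 0.98
T1    37
T2    36
T3    37
```

i.e. near-perfect out-of-fold discrimination when ten genera carry a
four-fold planted effect, and the 110 patients split into balanced
ascending score tertiles. Cross-tabulating `result.tertiles` against
`cohort.cohort.responder` shows all 37 T3 patients are responders and all
37 T1 patients are nonresponders.

The same analysis runs from the shell:

```bash
microrem simulate --out cohort/ --seed 1
microrem run --config examples/run.yaml --seed 1
```

(see `microrem --help` for the per-stage subcommands `diversity`, `lefse`,
`rf`, `score`, `outcomes`).

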