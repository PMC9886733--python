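# frailkit

Data-driven construction and evaluation of deficit-accumulation frailty
indices (FIs) for cohorts with mixed binary/ordinal/continuous health
variables.

The workflow supplements the standard FI procedure with a data-driven
refinement loop:

1. **Screening** — admit candidate deficits by prevalence (1–80%) and
   missingness (≤ 5%) criteria; drop diagnosis-related exclusions
   (`frailkit.deficits`).
2. **Coding** — binarise deficits, recode activities-of-daily-living items on
   an ordinal 0 / 0.25 / 0.5 / 1 scale, and dichotomise continuous variables
   against (optionally age/sex-stratified) reference ranges declared in a
   YAML codebook.
3. **Factor analysis of mixed data** — kNN imputation, joint PCA/MCA
   decomposition, components retained at 80% cumulative variance
   (`frailkit.famd`).
4. **Subject clustering** — Ward agglomeration on the retained component
   scores, cluster count by highest relative within-inertia loss, k-means
   consolidation (`frailkit.hcpc`).
5. **Deficit ranking** — per-variable logistic / ordinal-logistic / linear
   regressions of each deficit on cluster membership, likelihood-ratio
   p-values, Benjamini–Hochberg FDR control at q < 0.05, refined item list
   (`frailkit.ranking`).
6. **FI scoring** — FI = observed deficit sum / observed item count, defined
   only below 20% item missingness; variants: standard full list, refined
   data-driven list, and a published 40-item comparison list shipped as a
   packaged fixture codebook (`frailkit.deficits`).
7. **Evaluation** — single-feature LDA with repeated stratified 10-fold CV
   (plus undersampling and external pseudo-fold validation)
   (`frailkit.classify`); Kaplan–Meier quartile curves with log-rank, Cox PH
   (Efron/Breslow ties, robust SEs, Grambsch–Therneau proportionality tests),
   IPCW cumulative/dynamic AUC(t), and Prentice-weighted average hazard
   ratios (`frailkit.survival`).

A synthetic-cohort generator (`frailkit.synthetic`) produces mixed-type
cohorts with a known latent fit/frail structure, three-level diagnosis labels,
and right-censored conversion times whose log-hazard is linear in FI × 100, so
the whole pipeline is testable without restricted clinical data.

## CLI

```sh
frailkit simulate --out-dir sim --n-subjects 600 --seed 7
frailkit run-all sim/cohort.csv --codebook sim/codebook.yaml --out-dir run --seed 7
frailkit classify run/fi_table.csv sim/cohort.csv --codebook sim/codebook.yaml --pair HC:AD
frailkit survive run/fi_table.csv sim/cohort.csv --codebook sim/codebook.yaml --fi-variant fi_r
```

Individual stages are also exposed (`screen`, `famd`, `cluster`, `rank`,
`build-fi`). `run-all` writes every stage artifact plus a `manifest.json`
recording parameters and the master seed; a rerun with the same configuration
is bit-identical.

Cohorts are plain CSV (one subject per row, empty cell = missing). The
codebook YAML declares each deficit's type, coding map or reference ranges,
exclusion flags, and FI-variant membership; `frailkit.deficits.load_table1_codebook()`
returns the packaged 93-item fixture (93 standard / 26 refined / 40 published
items — reference ranges in the fixture are illustrative defaults).

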