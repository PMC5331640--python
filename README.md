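# microvar

Longitudinal microbiome temporal-variability analysis.

`microvar` quantifies how much a patient's oral and gut microbial
communities fluctuate over a course of dense longitudinal sampling, and
links that variability to taxa and clinical covariates:

* **Diversity** — Shannon / Gini–Simpson / bias-corrected Chao1
  α-diversity and unweighted / weighted (normalized) UniFrac
  β-diversity distances over a rooted Newick tree.
* **Variability** — per patient and body site (oral / stool), the
  coefficient of variation (sample sd over mean) of the longitudinal
  α-diversity values and of the within-patient UniFrac distance set
  (all unordered pairs by default, consecutive pairs optional).
* **Stability categories** — per-site cohort quartiles of a CV measure:
  first quartile *stable*, middle two *average*, fourth *variable*
  (linear-interpolation quantiles, boundary ties to the extreme
  category).
* **Association screens** — genus↔CV Pearson correlations (heatmap
  ordering by r), Kruskal–Wallis genus tests across stability
  categories, Welch-t / Mann–Whitney outcome comparisons, and
  multivariable OLS of each CV measure on clinical covariates; all
  genus families Benjamini–Hochberg corrected, genera filtered at ≥1%
  cohort-wide mean relative abundance.
* **Synthetic cohorts** — a seeded generator of two-site longitudinal
  cohorts with planted per-patient volatility, pathogen blooms,
  antibiotic-driven oral instability, and outcome couplings, so every
  pipeline stage is testable offline with known ground truth.

## CLI

```bash
# simulate a cohort
microvar simulate --out cohort/ --seed 17 --n-patients 30 --depth 2000

# diversity artifacts
microvar diversity --table cohort/table.tsv --tree cohort/tree.nwk --out div/

# per-patient CV profiles + stability categories
microvar variability --alpha div/alpha.tsv --beta-uu div/beta_uu.tsv \
    --beta-wu div/beta_wu.tsv --samples cohort/samples.tsv \
    --patients cohort/patients.tsv --out profiles.tsv

# one association screen
microvar associate --profiles profiles.tsv --table cohort/table.tsv \
    --samples cohort/samples.tsv --patients cohort/patients.tsv \
    --screen genus_cv --site stool --measure cv_wu --out assoc/

# or everything at once from a YAML config
microvar run --config run.yaml
```

A `run.yaml` holds either `inputs:` (paths to `table`, `tree`,
`samples`, `patients`) or a `simulate:` block, plus `out_dir`, `seed`,
`pair_mode`, `min_samples`, `genus_threshold`. A run writes nine TSV
artifacts plus `summary.json`, stamped with a config hash; identical
configs reproduce byte-identical outputs.

## File formats

All text. Feature table: QIIME-classic TSV (`#TaxonID` header cell,
taxa × samples, optional trailing `taxonomy` column; genus = 6th
semicolon rank or the bare label). Tree: Newick. Metadata: two TSVs
with fixed columns (`sample_id, patient_id, site, day, order` and
`patient_id, age, days_all_abx, days_treatment_abx, n_antibiotics,
pip_tazo_gt72h, cefepime_gt72h, carbapenem_gt72h, chemo_category,
infection_during_ic, infection_90d_post, remission`). Distance
matrices: labeled square TSV.

## Conventions worth knowing

The upstream analysis tools this package mirrors disagree on several
definitions, so the choices here are explicit: natural-log Shannon,
Gini–Simpson (1 − Σp²), bias-corrected Chao1, weighted UniFrac
normalized to [0, 1] by default, no rarefaction by default (seeded
`rarefy()` available), trees used as rooted-as-written, sample sd
(n−1) in every CV, and β-CV over all within-patient unordered pairs
unless `--pair-mode consecutive` is given.

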