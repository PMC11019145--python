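# metabaxes

Metabolome–phenome integration pipeline: derive composite "aging axis"
metabolic scores from paired metabolite/phenotype cohort tables and
carry them through outcome association and pathway enrichment.

The pipeline implements, as reusable tested components:

1. **Synthetic cohorts** (`metabaxes.synthetic`) — paired older/younger
   cohorts with planted latent axes driving log metabolite intensities,
   a 20-phenotype / 7-domain panel, LOD-type missingness, pooled-QC
   replicate rows, and exponential proportional-hazards outcomes, so
   every downstream stage can be validated against ground truth.
2. **Preprocessing** (`metabaxes.preprocess`) — presence (≥90%) and CV
   (≤10%) QC filtering, half-minimum imputation (per cohort), log /
   center / standardize, and phenotype harmonization (optional log,
   height^1.7 indexing, healthier-is-higher sign orientation).
3. **MWAS** (`metabaxes.mwas`) — covariate-adjusted linear scan of every
   phenotype against every metabolite (Frisch–Waugh–Lovell fast path,
   exactly equal to per-pair OLS), Benjamini–Hochberg control, and
   UpSet-style domain overlap counts.
4. **Integration** (`metabaxes.integrate`) — iterative correlation
   pruning at |r| > 0.8, 10-fold cross-validated LASSO per phenotype
   (one-standard-error penalty rule by default; minimum-CV-error via
   `cv_rule="min"`), PCA of the metabolites × phenotypes coefficient
   matrix, component selection by the ≥10%-variance rule,
   per-participant standardized metabolic scores, and sign/label
   orientation.
5. **Outcomes & transfer** (`metabaxes.outcomes`) — weight transfer to a
   second cohort, composite time-to-first-event endpoint with a
   healthy-ager flag, per-SD Cox hazard ratios with serial adjustment
   tiers (Efron ties), Kaplan–Meier curves by score tertile, and the
   score × phenotype association grid.
6. **Pathway enrichment** (`metabaxes.enrichment`) — metabolite→gene
   expansion (top-50 genes by mapping score, boundary ties kept),
   measured-panel background, one-sided hypergeometric
   over-representation, and top-3 pathway reporting per phenotype.
7. **Pipeline & CLI** (`metabaxes.pipeline`, `metabaxes.cli`) — TSV I/O,
   a digest-bearing run manifest, stage caching, and a `metabaxes`
   command-line entry point.

## Quick start

Run the whole pipeline on a synthetic cohort pair:

```sh
metabaxes run --out out/ --seed 1
```

or stage by stage:

```sh
metabaxes simulate --out sim/ --seed 1 --pair
metabaxes preprocess --metabolites sim/train_metabolites.tsv \
    --qc sim/train_qc.tsv --phenotypes sim/train_phenotypes.tsv \
    --pheno-config pheno.yaml --covariates sim/train_covariates.tsv \
    --out pre/
metabaxes mwas --in pre/ --covariates sim/train_covariates.tsv --out mwas/
metabaxes integrate --in pre/ --out axes/
metabaxes transfer --weights axes/metabolite_weights.tsv \
    --metabolites pre_young/metabolites_standardized.tsv --out young_scores.tsv
metabaxes cox --scores axes/train_scores.tsv --outcomes sim/train_outcomes.tsv \
    --covariates sim/train_covariates.tsv --tier full --out cox.tsv
metabaxes km --scores axes/train_scores.tsv --outcomes sim/train_outcomes.tsv \
    --out km.tsv
```

From Python:

```python
from metabaxes import GeneratorConfig, generate_cohort_pair, truth_alignment
from metabaxes.integrate import integrate
from metabaxes.outcomes import transfer_scores
from metabaxes.preprocess import (
    PhenotypeTable, harmonize_phenotypes, impute_half_min,
    log_standardize, qc_filter,
)

older, younger = generate_cohort_pair(GeneratorConfig(seed=1))
filtered, report = qc_filter(older.metabolites)
Z, _ = log_standardize(impute_half_min(filtered))
harm, _ = harmonize_phenotypes(
    PhenotypeTable(older.phenotypes, older.phenotype_meta),
    heights=older.covariates["height_m"],
)
axes, scores, coeffs, prune_log = integrate(
    harm, Z, domain_map=older.phenotype_meta["domain"].to_dict(), cv_seed=1
)
print(axes.variance_proportion)          # scree values
print(truth_alignment(older.truth.axes, scores.scores).correlations)
```

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(axis recovery over 20 seeds, oracle equivalences, estimator
calibration, exactness rules, transfer specificity, end-to-end
stability); the rest are per-module unit and property tests.

## Data formats

All tables are plain TSV. Participant-keyed tables carry
`participant_id` as the first column; metabolite matrices use one
column per metabolite with empty fields/`NA` for missing; outcomes are
long format (`participant_id`, `endpoint`, `time_years`, `event`,
`prevalent`); phenotype metadata (domain, adverse orientation,
log-transform, height indexing) comes from a YAML config or the
generated `*_phenotype_meta.tsv`. Mapping tables for enrichment are
(`metabolite_id`, `gene_id`, `mapping_score`) and
(`pathway_id`, `gene_id`[, `pathway_name`]).
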