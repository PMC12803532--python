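# File formats

All tables are plain text with a header row. Missing values are empty cells
(read as NaN); a missed visit is an absent row, not a NaN row.

## visits.csv (long format, one row per attended echo)

| column         | type  | meaning                                  |
|----------------|-------|------------------------------------------|
| participant_id | str   | stable participant identifier            |
| visit          | int   | 1-based visit number                     |
| age_years      | float | age at the echo                          |
| lvef_pct       | float | LV ejection fraction, percent (NaN ok)   |
| ea_ratio       | float | mitral E/A ratio, natural scale (NaN ok) |

## covariates.csv (one row per participant)

participant_id, age_years (baseline), male, obesity, hypertension, diabetes,
ckd, chd, af - binary covariates coded 0/1.

## survival.csv (one row per participant)

| column     | type  | meaning                                           |
|------------|-------|---------------------------------------------------|
| participant_id | str | identifier                                       |
| time_years | float | follow-up to first event or censoring (> 0)       |
| event      | str   | one of none, hf_pef, hf_ref, hf_unknown, death    |

## proteins.tsv

Participants x aptamers matrix, tab separated; first column participant_id,
remaining columns aptamer ids, raw (unstandardized) relative concentrations.

## annotation.tsv

aptamer_id, gene, chrom, tss_bp - one row per aptamer, used for cis/trans
labelling of pQTL instruments.

## GWAS summary tables (gwas_*.tsv)

variant_id, chrom, pos_bp, effect_allele, other_allele, beta, se, pval, eaf.
Alleles are single bases (A/C/G/T); beta is per copy of effect_allele.

## model.json

Versioned trajectory-model document: schema_version, k_max, concentration,
basis {reference_age, scale, degree}, weights, per-group coefficients and
residual SDs per target, priors and fit metadata (seed, restarts, ELBO
trace). Round-trips losslessly.

## Run configuration (YAML or JSON)

Keys per stage: `visits`, `covariates`, `survival`, `proteins`, `model`
(file paths), `seed` (int, required for stochastic stages), and a `fit`
block (k_max, restarts, concentration, min_weight, basis
{reference_age, scale, degree}, max_iter). The simulate stage takes
`style` (derivation | testing), `n_participants`, and optional `proteome`
/ `gwas` blocks mirroring ProteomeConfig / GwasSimConfig fields.
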