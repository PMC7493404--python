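# File formats

All tabular files are UTF-8, tab-separated, LF line endings, one header row.
Genomic coordinates are 1-based fully closed everywhere except BED input
(standard 0-based half-open, converted on read). Allele pairs are normalized
to minimal left-aligned representation, so keys from different callers match.

## Variant table (`variants_*.tsv`; also readable as VCF v4.2)

| column | type | notes |
|---|---|---|
| subject_id | text | |
| sample_id | text | unique per sample |
| sample_type | `tissue` \| `plasma` | |
| chrom | text | e.g. `chr17` |
| pos | int >= 1 | 1-based |
| ref | A/C/G/T string | never equal to alt |
| alt | A/C/G/T string | |
| depth | int >= 0 | de-duplicated read depth |
| alt_count | int, <= depth | |
| af | fraction in [0,1] | must equal alt_count/depth within display rounding; written to 6 decimals |
| gene | text, may be empty | pass-through annotation |
| cds_change | text, may be empty | e.g. `c.712T>G` |
| is_hotspot | `true`/`false` | whitelist flag |
| is_synonymous | `true`/`false` | |

For VCF input, depth/alt counts come from `DP`/`AD` (FORMAT preferred, INFO
fallback), allele frequency from a configurable key (default `AF`), and
gene/CDS annotations from configurable INFO keys (`GENE`, `CDS`).

## Sample manifest (`manifest.tsv`)

`subject_id`, `sample_id` (unique), `sample_type`, `collection_day`
(integer days from histological diagnosis, >= 0), `input_mass_ng`
(positive), `plasma_volume_ml` (optional, empty for tissue).

## Clinical anchors (`clinical.tsv`)

One row per subject: `subject_id`, `treatment_start_day`,
`last_imaging_day` (empty if none), `death_day` (empty if alive).
Diagnosis is day 0 by convention.

## RECIST assessments (`recist.tsv`)

`subject_id`, `day`, `response` in {CR, PR, SD, PD}. Only the first PD per
subject is used downstream.

## Annotation tables

- Population AF tables (`pop_<db>.tsv`, db in exac/dbsnp/g1000):
  `chrom`, `pos`, `ref`, `alt`, `af` (population allele frequency in [0,1]).
- Somatic evidence tables (`somatic_<db>.tsv`, db in cosmic/tcga):
  `chrom`, `pos`, `ref`, `alt`, `count` (non-negative evidence count).
- Repetitive-region mask (`mask.bed`): standard BED, first three columns
  used; overlapping intervals are merged.
- Hotspot whitelist (`hotspots.tsv`): `chrom`, `pos`, `ref`, `alt`.

## Ground truth (synthetic cohorts only)

- `ground_truth_variants.tsv`: `subject_id`, key columns, `label` in
  {somatic, germline, background}.
- `ground_truth_samples.tsv`: `subject_id`, `sample_id`,
  `true_tumor_fraction`.
- `ground_truth_subjects.tsv`: `subject_id`, `arm`, `ctdna_bearing`,
  `molecular_progression_day` (empty for responders), `pfs_time_days`,
  `pfs_event`, `hazard_ratio_true`.

## Germline model file (`germline_model.txt`)

Flat text: one `feature<TAB>weight` line per feature, then `intercept`,
`threshold`, `seed`, `n_train`. Floats are written with full `repr`
precision and reload bit-equal.
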