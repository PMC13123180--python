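# Column mapping for biosample-level encoding of GDC-style biospecimen
# exports (one row per sample; several rows may share a case UUID).
entity: biosample

id_policy:
  mode: sequential
  column: cases.case_id

# Single-species cohort: species is fixed rather than read from a column.
constants:
  species: HomSap

columns:
  project: project.project_id
  tissue: tissue_type
  sample_type: sample_type
  assay: experimental_strategy
  condition: diagnoses.icd_10_code
  timepoint: timepoint
  duration: duration
  batch: batch
  replicate: replicate

# Missing mandatory values are standardized to the vocabulary's
# not-available sentinels before validation.
na_policy:
  assay: NAV
  duration: P0N

na_token: "NA"
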