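# Column mapping for subject-level encoding of GDC-style clinical exports.
# Binds input table columns to identifier components; the same conversion
# adapts to other datasets by editing this file, not the code.
entity: subject

# UUIDs stay the persistent key; identifiers get a numeric subject_id
# assigned 1, 2, 3... in first-appearance order of the UUID column.
id_policy:
  mode: sequential
  column: unique_id

columns:
  study: project.project_id
  type: type
  condition: diagnoses.icd_10_code
  sex: demographics.gender

# Integer ages are binned into decades: age 43 -> A40_49.
age_binning:
  column: demographics.age_at_index
  width: 10

na_token: "NA"
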