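# Reference codebook: controlled vocabularies and pattern-defined fields
# for both identifier entities. Vocabulary entries map a long-form `code`
# (human format) to a compact `stub_code` (stub format); `id`/`label` are
# ontologyClass reference annotations (CURIE + class name) and are never
# emitted into identifiers. `tax_code` (species) is likewise retained for
# reference only. Fields with unenumerable values carry an anchored
# `pattern` instead of entries.
version: "1.0"

biosample:
  project:
    CNAG_Test:
      code: CNAG_Test
      stub_code: CT
      label: CNAG test project
    TARGET_AML:
      code: TARGET_AML
      stub_code: TAML
      label: TARGET acute myeloid leukemia project
  species:
    HomSap:
      code: HomSap
      stub_code: "01"
      id: NCBITaxon:9606
      label: Homo sapiens
      tax_code: PRI
    MusMus:
      code: MusMus
      stub_code: "02"
      id: NCBITaxon:10090
      label: Mus musculus
      tax_code: ROD
  subject_id:
    pattern: '^\d{1,5}$'
    human_width: 5
    stub_width: 3
  tissue:
    LIV:
      code: LIV
      stub_code: L
      id: UBERON:0002107
      label: liver
    BMR:
      code: BMR
      stub_code: R
      id: UBERON:0002371
      label: bone marrow
    LNG:
      code: LNG
      stub_code: G
      id: UBERON:0002048
      label: lung
    BLD:
      code: BLD
      stub_code: B
      id: UBERON:0000178
      label: blood
  sample_type:
    TUM:
      code: TUM
      stub_code: T
      id: NCIT:C18009
      label: tumor tissue
    PRI:
      code: PRI
      stub_code: P
      id: NCIT:C8509
      label: primary neoplasm
    NOR:
      code: NOR
      stub_code: N
      id: NCIT:C14165
      label: normal tissue
  assay:
    RNA:
      code: RNA
      stub_code: R
      id: OBI:0001271
      label: RNA-seq assay
    DNA:
      code: DNA
      stub_code: D
      id: OBI:0002117
      label: whole genome sequencing assay
    NAV:
      code: NAV
      stub_code: n
      label: assay not available
  condition:
    pattern: '^[A-Z]\d{2}(\.\d{1,2})?$'
  timepoint:
    TRT:
      code: TRT
      stub_code: T
      label: treatment event
    COL:
      code: COL
      stub_code: CT
      label: collection time
    BSL:
      code: BSL
      stub_code: B
      label: baseline
  duration:
    pattern: '^P\d{1,2}[A-Z]$'
  batch:
    pattern: '^B\d{2}$'
  replicate:
    pattern: '^R\d{2}$'

subject:
  study:
    # free-form by default (pattern below); entries register stub aliases
    pattern: '^[A-Za-z][A-Za-z0-9_]*$'
    TCGA_LIHC:
      code: TCGA_LIHC
      stub_code: TCGA-LIHC
      label: TCGA liver hepatocellular carcinoma study
  subject_id:
    pattern: '^\d{1,5}$'
    human_width: 5
    stub_width: 3
  type:
    Case:
      code: Case
      stub_code: C
    Control:
      code: Control
      stub_code: N
  condition:
    pattern: '^[A-Z]\d{2}(\.\d{1,2})?$'
  sex:
    Male:
      code: Male
      stub_code: M
      id: PATO:0000384
      label: male
    Female:
      code: Female
      stub_code: F
      id: PATO:0000383
      label: female
  age_group:
    A0_9:    {code: A0_9,    stub_code: A0}
    A10_19:  {code: A10_19,  stub_code: A1}
    A20_29:  {code: A20_29,  stub_code: A2}
    A30_39:  {code: A30_39,  stub_code: A3}
    A40_49:  {code: A40_49,  stub_code: A4}
    A50_59:  {code: A50_59,  stub_code: A5}
    A60_69:  {code: A60_69,  stub_code: A6}
    A70_79:  {code: A70_79,  stub_code: A7}
    A80_89:  {code: A80_89,  stub_code: A8}
    A90_99:  {code: A90_99,  stub_code: A9}

# Byte-exact compatibility stubs for specific ICD-10 codes; any code not
# listed here falls back to the algorithmic base-36 -> Base62 encoding.
condition_stub_overrides:
  C22.0: "0N401"
  J44.9: "3Of01"
  C92.0: "0iC01"
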