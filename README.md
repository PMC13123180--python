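# clarid

Structured, decodable identifiers for research subjects and biosamples.

## The problem

Biomedical studies track subjects and biospecimens with UUIDs or accession
numbers. These guarantee uniqueness but carry no meaning: to learn that
`550e8400-e29b-41d4-a716-446655440000` is a liver tumor RNA-seq sample from
a male case in his forties, you must join against external metadata tables.
Structured barcodes (TCGA, GTEx, SPREC) embed that context directly in the
identifier, but each is welded to its consortium's fields.

`clarid` implements a configurable identifier scheme with **two renderings
of the same record**, driven by a YAML **codebook** of controlled
vocabularies:

* **human** — verbose, hyphen-delimited, self-explanatory:

  * biosample (9 mandatory + 2 optional components):
    `<project>-<species>-<subject_id>-<tissue>-<sample_type>-<assay>-<condition>-<timepoint>-<duration>[-<batch>][-<replicate>]`
  * subject (6 components):
    `<study>-<subject_id>-<type>-<condition>-<sex>-<age_group>`

* **stub** — compact, delimiter-free, for filenames, labels and databases.
  Each component is replaced by a short codebook stub; the subject id is
  rendered in fixed-width Base62 (`0-9A-Za-z`, width 3 → 238 327 ids) and
  the ICD-10 condition becomes a 5-character Base62 stub (override table
  first for byte-exact compatibility, otherwise the dotless code read as a
  base-36 integer).

Both directions are total on valid identifiers: `decode(encode(r)) = r`
in either format. Conditions use ICD-10 codes, resolved to names through a
bundled JSON table at decode time (`--with-condition-name`). Vocabulary
entries carry optional CURIE/label ontology annotations (UBERON tissues,
NCBITaxon species, PATO sexes) for reference.

The package also ships batch CSV/TSV processing with a YAML column-mapping
layer (NA standardization, decade age binning, UUID → sequential numeric
ids), codebook validation against a JSON Schema plus semantic rules, QR
label generation/read-back, and a seeded synthetic-cohort generator that
emulates repository-style clinical/biospecimen exports for testing.

## Worked example

```sh
$ clarid code --entity biosample --action encode --format stub \
    --set project=CNAG_Test --set species=HomSap --set subject_id=1 \
    --set tissue=LIV --set sample_type=TUM --set assay=RNA \
    --set condition=C22.0 --set timepoint=TRT --set duration=P1W \
    --set batch=B01 --set replicate=R05
CT01001LTR0N401T1WB01R05
```

Reading it back: `CT` is the CNAG_Test project, `01` the species stub for
HomSap, `001` the Base62 subject id 1, `L`/`T`/`R` liver/tumor/RNA-seq,
`0N401` the condition stub for C22.0, `T` the treatment timepoint, `1W` a
one-week duration, then batch 01 and replicate 05. The same record in human
format is `CNAG_Test-HomSap-00001-LIV-TUM-RNA-C22.0-TRT-P1W-B01-R05`.

Decoding a compact subject identifier, with condition annotation:

```sh
$ clarid code --entity subject --action decode --format stub \
    --text "TCGA-LIHC003C0N401MA4" --with-condition-name
study	TCGA_LIHC
subject_id	3
type	Case
condition	C22.0
sex	Male
age_group	A40_49
condition_name	Liver cell carcinoma
```

Bulk mode reads a CSV/TSV, applies a mapping file
(`src/clarid/data/mapping_*.yaml` show the repository-export layout) and
appends a `clarid` column; decode emits one column per component. Failed
rows are marked `!ERROR` and the exit status is nonzero, but the rest of
the table is still written.

```python
from clarid import reference_codebook, decode_stub, encode_human

cb = reference_codebook()
rec = decode_stub("TAML01002RPn0iC01CT0N", "biosample", cb)
print(encode_human(rec, cb))
# TARGET_AML-HomSap-00002-BMR-PRI-NAV-C92.0-COL-P0N
```

QR labels:

```sh
clarid qrcode --action generate --text "CT01001LTR0N401T1W" --output label.png
clarid qrcode --action read --input label.png
```

## Layout

| module | role |
| --- | --- |
| `clarid.codebook` | load/validate/query the YAML codebook |
| `clarid.records` | `BiosampleRecord` / `SubjectRecord` + field validation |
| `clarid.human`, `clarid.stub` | the two codecs |
| `clarid.conditions` | ICD-10 code → name table and annotation |
| `clarid.tables`, `clarid.mapping`, `clarid.batch` | CSV/TSV I/O, column mapping, bulk runs |
| `clarid.qr` | QR label generation and read-back |
| `clarid.fixtures` | reference codebook, worked examples, synthetic cohorts |
| `clarid.cli` | the `clarid` command (`code`, `validate`, `qrcode`) |

See `docs/methods.md` for design notes (stub layout and its parsing rules,
the condition stub scheme, what the synthetic cohorts do and do not
emulate, numerical choices and limitations).
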