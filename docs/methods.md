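# Methods and design notes

## The identifier model

A record is the single source of truth; the two textual formats are
renderings of it. `subject_id` is stored as a plain integer and rendered
twice: zero-padded decimal in human format (default width 5) and
fixed-width Base62 in stub format (default width 3). The binding cap on a
subject id is the smaller of the two renderings' ranges — with the default
widths, 99 999. Both widths are per-codebook settings (`human_width`,
`stub_width` on the `subject_id` pattern field), so a project expecting
more subjects can widen them without touching code.

The hyphen is reserved as the human-format delimiter, so no component may
contain one; multi-word names use underscores (`CNAG_Test`, `TARGET_AML`).
Decoding splits on hyphens and demands exactly 6 parts (subject) or 9–11
parts (biosample). A 10-part biosample identifier is disambiguated by
shape: a part matching `B\d{2}` is a batch, `R\d{2}` a replicate, anything
else an error — the two optional components are independently optional but
always ordered batch before replicate.

## Stub layout

```
biosample: projectStub · species(2) · id62(3) · tissue(1) · sample_type(1) ·
           assay(1) · condition(5) · timepoint(1–2) · durationPayload(2–3) ·
           [B##] · [R##]
subject:   studyStub · id62(3) · type(1) · condition(5) · sex(1) · age_group(2)
```

Subject stubs have a fixed 12-character tail, so the study stub is simply
everything before it; registered study aliases (e.g. `TCGA_LIHC` ↔
`TCGA-LIHC`) are reverse-mapped, unknown prefixes pass through verbatim
(free-form studies are their own stubs). Study stubs are the one place a
hyphen may appear in stub format.

Biosample stubs have two variable-width regions, resolved as follows:

* the **project stub** is matched as the longest registered prefix —
  projects must be registered in the codebook to be stub-encodable at all
  (free-text projects have no defined compact form);
* the trailing `timepoint · duration` region is parsed **from the end**:
  strip an optional `R\d{2}`, then an optional `B\d{2}`, then match the
  duration payload `\d{1,2}[A-Z]`, and the residue must resolve as a
  timepoint stub. Timepoint stubs are deliberately variable width (1–2
  characters); when both a 3- and a 2-character duration split are
  syntactically possible, the longer payload is tried first and the parse
  backtracks if the residue does not resolve in the timepoint vocabulary.
  A tail such as `CT0N` therefore parses as timepoint `CT` + duration
  `0N`, because `C` alone is not a registered timepoint stub. Projects
  that register both one- and two-character timepoint stubs should avoid
  two-character stubs ending in a digit, which could make both splits
  resolvable; the parser then prefers the longer duration.

Durations are ISO-8601-style period tokens `P<1-2 digits><unit letter>`
(`P1W` = one week), capped at a 3-character payload; `P0N` is the sentinel
for "duration not available" and round-trips like any other value. Unit
letters are not enumerated — any single uppercase letter is accepted,
since only the length and shape are structural.

## Base62 and the condition stub

The Base62 alphabet is `0-9A-Za-z` in that order (so `0G9` = 16·62 + 9 =
1001). Encoding is fixed-width with left zero-padding; overflow is an
error, never truncation. Case is meaningful everywhere — the assay stub
`n` (assay not available) is distinct from `N`.

Condition stubs are always 5 Base62 characters, produced in two layers:

1. an **override table** in the codebook (`condition_stub_overrides`)
   is consulted first, pinning specific codes to specific stubs —
   the shipped overrides (`C22.0→0N401`, `J44.9→3Of01`, `C92.0→0iC01`)
   keep the reference identifiers byte-exact;
2. otherwise the **algorithmic fallback**: strip the dot, read the
   remaining 3–5 characters as a base-36 integer (`0-9A-Z`), render at
   Base62 width 5. Decoding inverts (override reverse-map first), and the
   dot is reinserted after the third character when more than three
   remain. Because every ICD-10 code starts with a letter (base-36 value
   ≥ 10), the natural base-36 rendering of the integer has no leading
   zero, which makes the fallback a bijection on syntactically valid
   codes; the largest code (`Z99.99`) is ≈ 5.9 × 10⁷, well inside the
   9.2 × 10⁸ capacity of five Base62 digits.

Codebook validation rejects an override whose stub coincides with the
fallback image of a *different* valid code, so the two layers can never
make a stub ambiguous. The accepted condition syntax is
`^[A-Z]\d{2}(\.\d{1,2})?$` — WHO-style codes plus one extra decimal digit;
longer clinical-modification codes are rejected. Records carry a single
condition; multi-diagnosis subjects should be modelled with the primary
diagnosis (the fixed-width stub slot admits exactly one code).

## Codebook and validation

Vocabulary entries map a `code` (human token) to a `stub_code` (stub
token), optionally annotated with a CURIE `id` and `label` following the
ontologyClass convention; annotations are reference-only and never
rendered. Species entries may carry a 3-letter `tax_code`, likewise
retained for disambiguation only. Fields with unenumerable values
(`subject_id`, `condition`, `duration`, `batch`, `replicate`, `study`) are
defined by anchored regular expressions; `study` may carry both a pattern
(free-form default) and entries (stub aliases).

`validate_codebook` layers three checks: a JSON-Schema pass over the raw
document (structure, entry shape, override syntax), semantic rules the
schema cannot express (cross-entry code/stub uniqueness, per-field stub
widths — species 2, tissue/sample_type/assay/type/sex 1, age_group 2,
timepoint 1–2, uniform length elsewhere except the free-form
project/study stubs — hyphen-free codes, CURIE shape, pattern anchoring,
override/fallback collisions), and, in debug mode, a self-validation of
the schema document. The schema validator is a small in-package
implementation of the draft-2020-12 keyword subset the bundled schema
uses (`type`, `properties`, `required`, `additionalProperties`,
`patternProperties`, `pattern`, `enum`, `minLength`/`maxLength`,
`minimum`/`maximum`, `items`, `anyOf`); unsupported applicators such as
`$ref` are rejected at schema self-validation rather than silently
ignored, so a schema the validator cannot honor fails loudly.

Violations are data, not exceptions: validation returns a report listing
every finding with a path into the document, serializable to JSON lines.
Exceptions are reserved for malformed inputs (unparseable YAML, unknown
tokens at decode time, structurally wrong identifiers).

## Batch processing and the mapping layer

A mapping file binds input columns to components (`columns`), fixes
table-wide values (`constants`, e.g. the species of a single-species
cohort), standardizes missing values (`na_token`, default `NA`, plus
`na_policy` substitutes — assay→`NAV`, duration→`P0N`; an NA in the
optional batch/replicate columns means the component is absent), bins
integer ages into groups (`age_binning`, default decade width, so
43 → `A40_49`) and derives numeric ids (`id_policy`: pass a numeric column
through, or assign 1, 2, 3… in first-appearance order of a unique-id
column, letting UUID-keyed exports keep their persistent key while gaining
compact ids). All failures during bulk runs are row-scoped: the run
continues, failed rows are marked `!ERROR` in the output, and the exit
status is nonzero iff any row failed. Outputs contain no timestamps, so
identical inputs give byte-identical outputs; diagnostics go to stderr.

CSV/TSV handling uses the stdlib `csv` machinery (RFC-4180 quoting for
CSV; TSV is quote-free with tabs forbidden in cells) rather than a
dataframe library, because cells must survive verbatim — in particular the
literal `NA` token, which general-purpose readers eagerly coerce to
missing values.

## QR labels

Labels are generated as byte-mode QR symbols, versions 1–10 (213-byte
payload capacity at the default error-correction level M — both renderings
fit with a wide margin), with standard Reed–Solomon parity over GF(256),
mask selection by the four-rule penalty score, and a 4-module quiet zone;
default scale is 8 px/module. The QR machinery is implemented in-package
(tables for versions 1–10 at all four EC levels) and rendered via Pillow.

The reader targets clean, upright label images: finder patterns are
located by their 1:1:3:1:1 run signature in both axes, the unique
geometrically consistent triple (equal module size, right-angle corner,
equal spans) selects the symbol, the module grid is sampled from the
finder centres, format information is matched against the 32 legal
codewords (tolerating ≤ 3 bit errors), and each block is Reed–Solomon
corrected. Zero consistent triples is a detection error; two disjoint
ones (several symbols in one image) an ambiguity error. Rotated or
perspective-distorted photographs are out of scope; reads are reliable
down to ~2 px/module and through moderate speckle noise (the RS decoder
corrects up to ⌊parity/2⌋ byte errors per block, verified by randomized
corruption tests).

## Synthetic cohorts

`synth_cohort` emulates repository-style exports at toy scale so every
layer is testable offline: a UUID key column (version-4, drawn from the
seeded generator), integer ages uniform over 0–99, vocabulary codes drawn
uniformly from the reference codebook, ICD-10 codes from the bundled
condition table, durations `P<1-12><D|W|M|Y>`, batch/replicate each
present in half the rows, and `NA` injected at the requested rate into
the columns that have standardized substitutes (assay, duration) and the
optional columns. Biosample rows share case UUIDs (pool of ~n/2 cases) so
the sequential-id policy is actually exercised. Column names mirror
repository export conventions (`demographics.age_at_index`,
`cases.case_id`, `experimental_strategy`), which lets the shipped mapping
files double as documentation of the conversion setup.

The generator returns the ground-truth records alongside the raw table,
so mapper and generator check each other. What it does **not** emulate:
free-text vocabulary noise ("Primary Tumor" vs `PRI` — real exports need
a value-normalization pass before mapping), missing values in columns
without NA substitutes, multi-diagnosis subjects, and real repositories'
scale and column count. Passing tests therefore demonstrate the codec and
mapping contracts, not robustness to arbitrary dirty metadata.

Subject cohorts are generated complete regardless of the NA rate: the
subject grammar has no not-available sentinels in its vocabulary, so an
NA in a mandatory subject column is a per-row mapping issue by design
rather than a substitutable value.

## Problem sizes and other fixed choices

The test suite and the acceptance script run the property suites at
10 000 round-trip records, 5 000 Base62 oracle samples over [0, 10⁶),
the full 2 600-code condition bijection plus 1 000 sampled decimal codes,
100 QR round-trips and a 1 000-row bulk table pass — sizes chosen to
exercise every variable-width path (all vocabulary combinations, 1- and
2-digit durations, both optional components, override and fallback
condition stubs) many times over while keeping a full run in seconds.
Determinism: every randomized suite is seeded; two runs on the same seed
and inputs are byte-identical.

Known limitations, beyond those noted above: the codebook is a reference
fixture, not a comprehensive vocabulary — projects are expected to extend
it (validation keeps extensions honest); identifiers are contextual
companions to persistent keys, not replacements — if metadata changes,
the identifier changes with it, while the UUID link persists; and two
biosamples from the same subject under identical conditions share an
identifier unless batch/replicate distinguish them, so uniqueness is a
property of the metadata, not a guarantee of the scheme.
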