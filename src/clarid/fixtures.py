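"""Reference fixtures and a seeded synthetic-cohort generator.

``worked_examples`` carries the canonical human↔stub identifier pairs that
pin down both grammars (including the Base62 subject-id rendering, the
condition stub overrides and the variable-width timepoint parse).

``synth_cohort`` emulates a repository-style clinical/biospecimen export at
toy scale: a UUID key column, integer age-at-index values, vocabulary codes
drawn from the reference codebook and ``NA`` for missing values — shaped so
the bundled mapping files apply to it unchanged. It returns the raw table
together with the ground-truth records the mapping layer must recover, so
generator and mapper can be tested against each other.
"""

from __future__ import annotations

import random
import uuid
from dataclasses import dataclass
from typing import Optional

from .codebook import Codebook, bundled_codebook_path, load_codebook
from .conditions import load_conditions
from .mapping import bin_age
from .records import BiosampleRecord, Record, SubjectRecord


def reference_codebook() -> Codebook:
    """Load the bundled reference codebook (validates cleanly by contract)."""
    return load_codebook(bundled_codebook_path())


@dataclass(frozen=True)
class WorkedExample:
    entity: str
    human: str
    stub: str
    record: Record


def worked_examples() -> list[WorkedExample]:
    """The four canonical identifier pairs, byte-exact in both renderings."""
    return [
        WorkedExample(
            entity="biosample",
            human="CNAG_Test-HomSap-00001-LIV-TUM-RNA-C22.0-TRT-P1W-B01-R05",
            stub="CT01001LTR0N401T1WB01R05",
            record=BiosampleRecord(
                project="CNAG_Test", species="HomSap", subject_id=1,
                tissue="LIV", sample_type="TUM", assay="RNA",
                condition="C22.0", timepoint="TRT", duration="P1W",
                batch="B01", replicate="R05",
            ),
        ),
        WorkedExample(
            entity="subject",
            human="COPDStudy-01001-Case-J44.9-Male-A40_49",
            stub="COPDStudy0G9C3Of01MA4",
            record=SubjectRecord(
                study="COPDStudy", subject_id=1001, type="Case",
                condition="J44.9", sex="Male", age_group="A40_49",
            ),
        ),
        WorkedExample(
            entity="subject",
            human="TCGA_LIHC-00003-Case-C22.0-Male-A40_49",
            stub="TCGA-LIHC003C0N401MA4",
            record=SubjectRecord(
                study="TCGA_LIHC", subject_id=3, type="Case",
                condition="C22.0", sex="Male", age_group="A40_49",
            ),
        ),
        WorkedExample(
            entity="biosample",
            human="TARGET_AML-HomSap-00002-BMR-PRI-NAV-C92.0-COL-P0N",
            stub="TAML01002RPn0iC01CT0N",
            record=BiosampleRecord(
                project="TARGET_AML", species="HomSap", subject_id=2,
                tissue="BMR", sample_type="PRI", assay="NAV",
                condition="C92.0", timepoint="COL", duration="P0N",
            ),
        ),
    ]


#: column order of the generated tables; matches the bundled mapping files
SUBJECT_COLUMNS = (
    "unique_id", "project.project_id", "type",
    "diagnoses.icd_10_code", "demographics.gender", "demographics.age_at_index",
)
BIOSAMPLE_COLUMNS = (
    "cases.case_id", "project.project_id", "tissue_type", "sample_type",
    "experimental_strategy", "diagnoses.icd_10_code", "timepoint",
    "duration", "batch", "replicate",
)

_STUDIES = ("COPDStudy", "TCGA_LIHC", "GDC_Cohort")
_DURATION_UNITS = "DWMY"


def synth_cohort(
    n: int,
    entity: str,
    seed: int = 0,
    na_rate: float = 0.0,
    codebook: Optional[Codebook] = None,
) -> tuple[list[dict[str, str]], list[Record]]:
    """Generate a toy cohort table plus its ground-truth records.

    Deterministic under ``seed``. ``na_rate`` is the per-cell probability of
    an ``NA`` token in the columns that have a standardized substitute
    (biosample assay → NAV, duration → P0N) and in the optional
    batch/replicate columns (where NA means the component is absent); the
    expected records already carry the substituted values. The subject
    grammar has no NA sentinels in its vocabulary, so subject tables are
    generated complete regardless of ``na_rate``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= na_rate < 1.0):
        raise ValueError("na_rate must be in [0, 1)")
    cb = codebook if codebook is not None else reference_codebook()
    rng = random.Random(seed)
    conditions = sorted(load_conditions().entries)

    def vocab_codes(ent: str, field: str) -> list[str]:
        return sorted(cb.vocab(ent, field).by_code)

    if entity == "subject":
        return _subject_cohort(n, rng, conditions, vocab_codes)
    if entity == "biosample":
        return _biosample_cohort(n, rng, na_rate, conditions, vocab_codes)
    raise ValueError(f"unknown entity {entity!r}")


def _uuid4(rng: random.Random) -> str:
    return str(uuid.UUID(int=rng.getrandbits(128), version=4))


def _subject_cohort(n, rng, conditions, vocab_codes):
    types = vocab_codes("subject", "type")
    sexes = vocab_codes("subject", "sex")
    rows, records = [], []
    for i in range(1, n + 1):
        age = rng.randint(0, 99)
        rec = SubjectRecord(
            study=rng.choice(_STUDIES),
            subject_id=i,
            type=rng.choice(types),
            condition=rng.choice(conditions),
            sex=rng.choice(sexes),
            age_group=bin_age(age),
        )
        rows.append({
            "unique_id": _uuid4(rng),
            "project.project_id": rec.study,
            "type": rec.type,
            "diagnoses.icd_10_code": rec.condition,
            "demographics.gender": rec.sex,
            "demographics.age_at_index": str(age),
        })
        records.append(rec)
    return rows, records


def _biosample_cohort(n, rng, na_rate, conditions, vocab_codes):
    projects = vocab_codes("biosample", "project")
    tissues = vocab_codes("biosample", "tissue")
    sample_types = vocab_codes("biosample", "sample_type")
    assays = [a for a in vocab_codes("biosample", "assay") if a != "NAV"]
    timepoints = vocab_codes("biosample", "timepoint")

    # several samples may share a case: draw from a smaller UUID pool
    pool = [_uuid4(rng) for _ in range(max(1, (n + 1) // 2))]
    case_ids: dict[str, int] = {}
    rows, records = [], []
    for _ in range(n):
        case = rng.choice(pool)
        sid = case_ids.setdefault(case, len(case_ids) + 1)
        assay = rng.choice(assays)
        duration = f"P{rng.randint(1, 12)}{rng.choice(_DURATION_UNITS)}"
        batch = f"B{rng.randint(1, 99):02d}" if rng.random() < 0.5 else None
        replicate = f"R{rng.randint(1, 99):02d}" if rng.random() < 0.5 else None

        assay_cell, assay_val = assay, assay
        if rng.random() < na_rate:
            assay_cell, assay_val = "NA", "NAV"
        dur_cell, dur_val = duration, duration
        if rng.random() < na_rate:
            dur_cell, dur_val = "NA", "P0N"
        if batch is not None and rng.random() < na_rate:
            batch = None
        if replicate is not None and rng.random() < na_rate:
            replicate = None

        rec = BiosampleRecord(
            project=rng.choice(projects),
            species="HomSap",
            subject_id=sid,
            tissue=rng.choice(tissues),
            sample_type=rng.choice(sample_types),
            assay=assay_val,
            condition=rng.choice(conditions),
            timepoint=rng.choice(timepoints),
            duration=dur_val,
            batch=batch,
            replicate=replicate,
        )
        rows.append({
            "cases.case_id": case,
            "project.project_id": rec.project,
            "tissue_type": rec.tissue,
            "sample_type": rec.sample_type,
            "experimental_strategy": assay_cell,
            "diagnoses.icd_10_code": rec.condition,
            "timepoint": rec.timepoint,
            "duration": dur_cell,
            "batch": batch if batch is not None else "NA",
            "replicate": replicate if replicate is not None else "NA",
        })
        records.append(rec)
    return rows, records
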