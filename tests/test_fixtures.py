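"""Fixture vectors and the synthetic cohort generator contract."""

import pytest

from clarid import synth_cohort, worked_examples
from clarid.fixtures import BIOSAMPLE_COLUMNS, SUBJECT_COLUMNS


def test_reference_codebook_carries_vector_entries(cb):
    assert cb.lookup("biosample", "species", "HomSap").stub_code == "01"
    assert cb.lookup("biosample", "timepoint", "COL").stub_code == "CT"
    assert cb.lookup("subject", "study", "TCGA_LIHC").stub_code == "TCGA-LIHC"


def test_worked_examples_shape(examples):
    assert len(examples) == 4
    assert {e.entity for e in examples} == {"biosample", "subject"}
    subject = [e for e in examples if e.entity == "subject"]
    assert any(e.stub == "COPDStudy0G9C3Of01MA4" for e in subject)


@pytest.mark.parametrize("entity,cols", [
    ("biosample", BIOSAMPLE_COLUMNS), ("subject", SUBJECT_COLUMNS),
])
def test_generator_deterministic_under_seed(entity, cols):
    a = synth_cohort(100, entity, seed=7)
    b = synth_cohort(100, entity, seed=7)
    assert a == b
    c = synth_cohort(100, entity, seed=8)
    assert a != c
    assert all(set(row) == set(cols) for row in a[0])


def test_na_rate_zero_table_is_complete():
    rows, _ = synth_cohort(100, "biosample", seed=7, na_rate=0.0)
    for row in rows:
        for col in ("experimental_strategy", "duration"):
            assert row[col] != "NA"


def test_na_cells_map_to_sentinels_in_ground_truth():
    rows, records = synth_cohort(300, "biosample", seed=7, na_rate=0.3)
    saw_na = 0
    for row, rec in zip(rows, records):
        if row["experimental_strategy"] == "NA":
            saw_na += 1
            assert rec.assay == "NAV"
        if row["duration"] == "NA":
            assert rec.duration == "P0N"
        if row["batch"] == "NA":
            assert rec.batch is None
    assert saw_na > 0


def test_uuid_sharing_matches_sequential_ids():
    rows, records = synth_cohort(50, "biosample", seed=4)
    seen: dict[str, int] = {}
    for row, rec in zip(rows, records):
        expected = seen.setdefault(row["cases.case_id"], len(seen) + 1)
        assert rec.subject_id == expected


def test_generator_input_validation():
    with pytest.raises(ValueError):
        synth_cohort(0, "subject")
    with pytest.raises(ValueError):
        synth_cohort(5, "subject", na_rate=1.0)
    with pytest.raises(ValueError):
        synth_cohort(5, "sample")
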