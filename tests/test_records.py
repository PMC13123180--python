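"""Field-level record validation shared by both codecs."""

import dataclasses

import pytest

from clarid import BiosampleRecord, SubjectRecord, synth_cohort, validate_record


@pytest.fixture(scope="module")
def cnag_record(request):
    return BiosampleRecord(
        project="CNAG_Test", species="HomSap", subject_id=1, tissue="LIV",
        sample_type="TUM", assay="RNA", condition="C22.0", timepoint="TRT",
        duration="P1W", batch="B01", replicate="R05",
    )


class TestBiosampleValidation:
    def test_worked_example_record_is_clean(self, cnag_record, cb):
        assert validate_record(cnag_record, cb).ok

    def test_malformed_icd10_is_one_pattern_violation(self, cnag_record, cb):
        bad = dataclasses.replace(cnag_record, condition="22C.0")
        report = validate_record(bad, cb)
        assert len(report) == 1
        assert report.violations[0].path == "biosample.condition"
        assert report.violations[0].kind == "pattern"

    @pytest.mark.parametrize("field,value,kind", [
        ("duration", "P123W", "pattern"),   # payload > 3 chars
        ("duration", "1W", "pattern"),      # missing ISO 'P'
        ("tissue", "EAR", "vocabulary"),
        ("batch", "B1", "pattern"),
        ("project", "CNAG-Test", "hyphen"),
        ("assay", "", "empty"),
    ])
    def test_single_field_violations(self, cnag_record, cb, field, value, kind):
        bad = dataclasses.replace(cnag_record, **{field: value})
        report = validate_record(bad, cb)
        assert [v.kind for v in report] == [kind]

    def test_duration_na_sentinel_is_valid(self, cnag_record, cb):
        rec = dataclasses.replace(cnag_record, duration="P0N", batch=None,
                                  replicate=None)
        assert validate_record(rec, cb).ok

    def test_optional_fields_independently_optional(self, cnag_record, cb):
        for kw in ({"batch": None}, {"replicate": None},
                   {"batch": None, "replicate": None}):
            assert validate_record(dataclasses.replace(cnag_record, **kw), cb).ok


class TestSubjectValidation:
    def test_subject_id_overflow_at_human_width(self, cb):
        rec = SubjectRecord(study="COPDStudy", subject_id=10**5, type="Case",
                            condition="J44.9", sex="Male", age_group="A40_49")
        report = validate_record(rec, cb)
        assert len(report) == 1
        assert report.violations[0].kind == "range"

    def test_free_form_study_accepted_hyphen_rejected(self, cb):
        ok = SubjectRecord(study="MyNewStudy42", subject_id=1, type="Control",
                           condition="I10", sex="Female", age_group="A60_69")
        assert validate_record(ok, cb).ok
        bad = dataclasses.replace(ok, study="My-Study")
        assert [v.kind for v in validate_record(bad, cb)] == ["hyphen"]


@pytest.mark.parametrize("entity", ["biosample", "subject"])
def test_all_generated_records_validate_cleanly(entity, cb):
    """Generator/validator consistency across >=1000 seeded records."""
    _, records = synth_cohort(1000, entity, seed=42, na_rate=0.15)
    for rec in records:
        report = validate_record(rec, cb)
        assert report.ok, f"{rec} -> {report.to_json_lines()}"


def test_record_dict_round_trip(cnag_record):
    assert BiosampleRecord.from_dict(cnag_record.to_dict()) == cnag_record
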