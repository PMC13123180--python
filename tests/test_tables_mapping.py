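"""Table I/O and the column-mapping layer (NA policy, binning, id assignment)."""

import pytest

from clarid import apply_mapping, bin_age, load_mapping, read_table, write_table
from clarid.errors import MappingError, TableFormatError
from clarid.mapping import bundled_mapping_path, mapping_from_dict


class TestTables:
    def test_tsv_smoke(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("a\tb\n1\tx\n2\ty\n")
        header, rows = read_table(p)
        assert header == ["a", "b"]
        assert rows == [{"a": "1", "b": "x"}, {"a": "2", "b": "y"}]

    def test_ragged_row_is_format_error_with_line(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("a\tb\n1\tx\n2\n")
        with pytest.raises(TableFormatError, match="line 3"):
            read_table(p)

    def test_quoted_comma_preserved(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text('a,b\n"hello, world",NA\n')
        _, rows = read_table(p)
        assert rows[0] == {"a": "hello, world", "b": "NA"}

    def test_round_trip_write_read(self, tmp_path):
        p = tmp_path / "t.csv"
        rows = [{"a": "x,y", "b": "NA"}, {"a": "", "b": "2"}]
        write_table(p, ["a", "b"], rows)
        assert read_table(p)[1] == rows


class TestAgeBinning:
    @pytest.mark.parametrize("age,expected", [
        (43, "A40_49"), (0, "A0_9"), (9, "A0_9"), (10, "A10_19"), (99, "A90_99"),
    ])
    def test_decade_bins(self, age, expected):
        assert bin_age(age) == expected

    def test_custom_width(self):
        assert bin_age(43, width=5) == "A40_44"


@pytest.fixture()
def subject_rows():
    base = {"project.project_id": "COPDStudy", "type": "Case",
            "diagnoses.icd_10_code": "J44.9", "demographics.gender": "Male",
            "demographics.age_at_index": "43"}
    return [dict(base, **{"unique_id": u}) for u in ("uuid-a", "uuid-b", "uuid-a")]


class TestApplyMapping:
    def test_sequential_ids_follow_first_appearance(self, cb, subject_rows):
        m = load_mapping(bundled_mapping_path("subject"))
        records, issues = apply_mapping(subject_rows, m, cb)
        assert not issues
        assert [r.subject_id for r in records] == [1, 2, 1]
        assert all(r.age_group == "A40_49" for r in records)

    def test_na_policy_substitutes_before_validation(self, cb):
        m = load_mapping(bundled_mapping_path("biosample"))
        row = {"cases.case_id": "u1", "project.project_id": "TARGET_AML",
               "tissue_type": "BMR", "sample_type": "PRI",
               "experimental_strategy": "NA", "diagnoses.icd_10_code": "C92.0",
               "timepoint": "COL", "duration": "NA", "batch": "NA",
               "replicate": "NA"}
        records, issues = apply_mapping([row], m, cb)
        assert not issues
        rec = records[0]
        assert rec.assay == "NAV" and rec.duration == "P0N"
        assert rec.batch is None and rec.replicate is None

    def test_na_without_policy_is_row_issue_not_crash(self, cb, subject_rows):
        m = load_mapping(bundled_mapping_path("subject"))
        subject_rows[1]["demographics.gender"] = "NA"
        records, issues = apply_mapping(subject_rows, m, cb)
        assert records[1] is None and records[0] is not None
        assert len(issues) == 1 and issues[0].row == 2

    def test_mapping_must_cover_header(self, cb, subject_rows):
        m = load_mapping(bundled_mapping_path("subject"))
        for r in subject_rows:
            del r["demographics.gender"]
        with pytest.raises(MappingError, match="demographics.gender"):
            apply_mapping(subject_rows, m, cb)

    def test_mapping_must_cover_mandatory_components(self):
        with pytest.raises(MappingError, match="sex"):
            mapping_from_dict({
                "entity": "subject",
                "columns": {"study": "s", "type": "t", "condition": "c"},
                "id_policy": {"mode": "passthrough", "column": "sid"},
                "age_binning": {"column": "age"},
            }).check(["s", "t", "c", "sid", "age"])

    def test_passthrough_id_policy(self, cb, subject_rows):
        doc = {
            "entity": "subject",
            "columns": {"study": "project.project_id", "type": "type",
                        "condition": "diagnoses.icd_10_code",
                        "sex": "demographics.gender"},
            "age_binning": {"column": "demographics.age_at_index"},
            "id_policy": {"mode": "passthrough", "column": "unique_id"},
        }
        for i, r in enumerate(subject_rows):
            r["unique_id"] = str(100 + i)
        records, issues = apply_mapping(subject_rows, mapping_from_dict(doc), cb)
        assert not issues
        assert [r.subject_id for r in records] == [100, 101, 102]
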