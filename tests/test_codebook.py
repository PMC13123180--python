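"""Codebook loading, queries, JSON-Schema + semantic validation."""

import pytest

from clarid import load_codebook, validate_codebook
from clarid.codebook import (
    BIOSAMPLE_FIELDS,
    BIOSAMPLE_OPTIONAL,
    SUBJECT_FIELDS,
    VocabField,
    bundled_schema_path,
)
from clarid.errors import CodebookError, VocabularyError

from conftest import rebuild


class TestLoading:
    def test_reference_codebook_tissue_entry(self, cb):
        entry = cb.lookup("biosample", "tissue", "LIV")
        assert entry.stub_code == "L"
        assert entry.id == "UBERON:0002107"
        assert entry.label == "liver"

    def test_defines_all_grammar_fields(self, cb):
        assert set(BIOSAMPLE_FIELDS + BIOSAMPLE_OPTIONAL) <= set(cb.entities["biosample"])
        assert set(SUBJECT_FIELDS) <= set(cb.entities["subject"])

    def test_missing_entity_section_is_structural_error(self, tmp_path):
        p = tmp_path / "cb.yaml"
        p.write_text("subject:\n  sex:\n    Male: {code: Male, stub_code: M}\n")
        with pytest.raises(CodebookError, match="biosample"):
            load_codebook(p)

    def test_empty_file_never_yields_a_codebook(self, tmp_path):
        p = tmp_path / "empty.yaml"
        p.write_text("")
        with pytest.raises(CodebookError):
            load_codebook(p)

    def test_yaml_syntax_error_names_line(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("biosample:\n  tissue: [unclosed\n")
        with pytest.raises(CodebookError, match=r"line \d+"):
            load_codebook(p)


class TestLookup:
    def test_assay_code_to_stub(self, cb):
        assert cb.lookup("biosample", "assay", "RNA").stub_code == "R"

    def test_assay_stub_to_code_lowercase_meaningful(self, cb):
        assert cb.reverse_lookup("biosample", "assay", "n").code == "NAV"

    def test_unknown_token_raises_vocabulary_error(self, cb):
        with pytest.raises(VocabularyError) as exc:
            cb.lookup("subject", "sex", "Unknownsex")
        assert exc.value.entity == "subject"
        assert exc.value.field == "sex"
        assert exc.value.token == "Unknownsex"

    def test_lookups_are_total_inverses_over_whole_codebook(self, cb):
        for entity, fields in cb.entities.items():
            for fname, fdef in fields.items():
                if not isinstance(fdef, VocabField):
                    continue
                for entry in fdef.entries.values():
                    assert cb.reverse_lookup(entity, fname, entry.stub_code) is entry
                    assert cb.lookup(entity, fname, entry.code) is entry


class TestValidation:
    def test_reference_codebook_is_valid(self, cb):
        report = validate_codebook(cb)
        assert report.ok, report.to_json_lines()

    def test_debug_mode_self_validates_bundled_schema(self, cb):
        assert validate_codebook(cb, schema=bundled_schema_path(), debug=True).ok

    def test_duplicate_tissue_stub_reported_at_field(self, raw_codebook):
        raw_codebook["biosample"]["tissue"]["BMR"]["stub_code"] = "L"
        report = validate_codebook(rebuild(raw_codebook))
        dup = [v for v in report if v.kind == "duplicate_stub"]
        assert len(dup) == 1
        assert dup[0].path.startswith("biosample.tissue")

    def test_three_character_species_stub_is_width_violation(self, raw_codebook):
        raw_codebook["biosample"]["species"]["HomSap"]["stub_code"] = "001"
        report = validate_codebook(rebuild(raw_codebook))
        assert any(v.kind == "width" and "species" in v.path for v in report)

    @pytest.mark.parametrize(
        "mutate",
        [
            lambda d: d["biosample"]["tissue"]["BMR"].__setitem__("code", "LIV"),
            lambda d: d["biosample"]["tissue"]["BMR"].__setitem__("stub_code", "L"),
            lambda d: d["biosample"]["species"]["HomSap"].__setitem__("stub_code", "X"),
            lambda d: d["biosample"]["tissue"]["LIV"].__setitem__("code", "LI-V"),
            lambda d: d["biosample"]["tissue"]["LIV"].__setitem__("id", "no curie here"),
        ],
        ids=["duplicate_code", "duplicate_stub", "stub_width", "hyphen_in_code",
             "malformed_curie"],
    )
    def test_mutation_classes_all_detected(self, raw_codebook, mutate):
        mutate(raw_codebook)
        assert not validate_codebook(rebuild(raw_codebook)).ok

    def test_override_colliding_with_fallback_image_detected(self, raw_codebook):
        # "02MLA" is the algorithmic image of C22.0; claiming it for X80.1 is ambiguous
        raw_codebook["condition_stub_overrides"]["X80.1"] = "02MLA"
        report = validate_codebook(rebuild(raw_codebook))
        assert any(v.kind == "override_collision" for v in report)

    def test_broken_schema_reported_in_debug_mode(self, cb, tmp_path):
        bad = tmp_path / "schema.json"
        bad.write_text('{"type": "object", "allOf": [{"type": "object"}]}')
        report = validate_codebook(cb, schema=bad, debug=True)
        assert any(v.kind == "meta" for v in report)

    def test_report_serializes_to_json_lines(self, raw_codebook):
        raw_codebook["biosample"]["tissue"]["BMR"]["stub_code"] = "L"
        report = validate_codebook(rebuild(raw_codebook))
        import json

        lines = report.to_json_lines().splitlines()
        assert lines and all(set(json.loads(l)) == {"path", "kind", "message"}
                             for l in lines)
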