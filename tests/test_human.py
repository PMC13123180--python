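"""Hyphen-delimited human format: grammar, worked examples, round-trips."""

import pytest

from clarid import decode_human, encode_human, synth_cohort
from clarid.errors import EncodeError, StructuralError, VocabularyError


class TestWorkedExamples:
    def test_encode_matches_printed_identifiers(self, cb, examples):
        for ex in examples:
            assert encode_human(ex.record, cb) == ex.human

    def test_decode_recovers_records(self, cb, examples):
        for ex in examples:
            assert decode_human(ex.human, ex.entity, cb) == ex.record

    def test_round_trip_is_identity_on_strings(self, cb, examples):
        for ex in examples:
            assert encode_human(decode_human(ex.human, ex.entity, cb), cb) == ex.human


class TestGrammar:
    def test_subject_has_six_parts(self, cb, examples):
        subject = next(e for e in examples if e.entity == "subject")
        assert subject.human.count("-") == 5

    def test_truncated_subject_is_structural_error(self, cb):
        with pytest.raises(StructuralError, match="6"):
            decode_human("COPDStudy-01001-Case-J44.9", "subject", cb)

    @pytest.mark.parametrize("n_extra,opt", [(0, ""), (1, "-B01"), (1, "-R05"),
                                             (2, "-B01-R05")])
    def test_biosample_part_counts(self, cb, n_extra, opt):
        s = "CNAG_Test-HomSap-00001-LIV-TUM-RNA-C22.0-TRT-P1W" + opt
        rec = decode_human(s, "biosample", cb)
        assert (rec.batch is not None) == ("B01" in opt)
        assert (rec.replicate is not None) == ("R05" in opt)

    def test_tenth_part_must_be_batch_or_replicate(self, cb):
        with pytest.raises(StructuralError):
            decode_human(
                "CNAG_Test-HomSap-00001-LIV-TUM-RNA-C22.0-TRT-P1W-X01",
                "biosample", cb)

    def test_unknown_vocabulary_token_signalled(self, cb):
        with pytest.raises(VocabularyError):
            decode_human("CNAG_Test-HomSap-00001-EAR-TUM-RNA-C22.0-TRT-P1W",
                         "biosample", cb)

    def test_whitespace_strict_but_lenient_flag_trims(self, cb, examples):
        ex = examples[1]
        with pytest.raises(StructuralError):
            decode_human(" " + ex.human, ex.entity, cb)
        assert decode_human(f"  {ex.human}\n", ex.entity, cb,
                            lenient=True) == ex.record

    def test_invalid_record_fails_encoding_with_aggregate(self, cb, examples):
        import dataclasses

        bad = dataclasses.replace(examples[0].record, condition="nope",
                                  tissue="EAR")
        with pytest.raises(EncodeError) as exc:
            encode_human(bad, cb)
        assert len(exc.value.violations) == 2


@pytest.mark.parametrize("entity", ["biosample", "subject"])
def test_round_trip_identity_on_generated_records(cb, entity):
    _, records = synth_cohort(400, entity, seed=11, na_rate=0.1)
    for rec in records:
        s = encode_human(rec, cb)
        parts = s.split("-")
        assert all(parts), "no empty parts"
        assert decode_human(s, entity, cb) == rec
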