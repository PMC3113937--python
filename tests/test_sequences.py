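"""Sequence import, MM generation, attachment and export."""

import io
import random

import pytest

from cdfkit.model import model_equal, model_key
from cdfkit.sequences import (
    AttachReport,
    SequenceFileError,
    attach_sequences,
    export_sequences,
    mm_from_pm,
    read_probe_sequences,
)
from conftest import build_spec

TAB = (
    "Probe Set Name\tProbe X\tProbe Y\tProbe Interrogation Position\t"
    "Probe Sequence\tTarget Strandedness\n"
    "alpha_at\t0\t0\t101\tACGTACGTACGTACGTACGTACGTA\tAntisense\n"
    "alpha_at\t1\t0\t108\tTTTTTTTTTTTTTTTTTTTTTTTTT\tAntisense\n"
    "beta_at\t3\t0\t205\tCCCCCCCCCCCCCCCCCCCCCCCCC\tAntisense\n"
)

FASTA = (
    ">probe:handchip:alpha_at:0:0; Interrogation_Position=101; Antisense;\n"
    "ACGTACGTACGTACGTACGTACGTA\n"
    ">probe:handchip:alpha_at:1:0; Interrogation_Position=108; Antisense;\n"
    "TTTTTTTTTTTTTTTTTTTTTTTTT\n"
    ">probe:handchip:beta_at:3:0; Interrogation_Position=205; Antisense;\n"
    "CCCCCCCCCCCCCCCCCCCCCCCCC\n"
)


class TestRead:
    def test_tab_fixture_hand_checked(self):
        recs = read_probe_sequences(io.StringIO(TAB), "tab")
        assert len(recs) == 3
        assert recs[0].probe_set_name == "alpha_at"
        assert (recs[0].x, recs[0].y) == (0, 0)
        assert recs[0].interrogation_position == 101
        assert recs[2].sequence == "C" * 25

    def test_fasta_and_tab_agree(self):
        assert (read_probe_sequences(io.StringIO(FASTA), "fasta")
                == read_probe_sequences(io.StringIO(TAB), "tab"))

    def test_empty_file_is_empty_collection(self):
        assert read_probe_sequences(io.StringIO(""), "tab") == []
        assert read_probe_sequences(io.StringIO(""), "fasta") == []

    def test_u_mapped_to_t_and_case_folded(self):
        recs = read_probe_sequences(io.StringIO(
            TAB.replace("ACGTACGTACGTACGTACGTACGTA",
                        "acguacguacguacguacguacgua")), "tab")
        assert recs[0].sequence == "ACGTACGTACGTACGTACGTACGTA"

    def test_non_acgt_reported_with_line(self):
        with pytest.raises(SequenceFileError, match="line 2"):
            read_probe_sequences(io.StringIO(
                TAB.replace("ACGTA\t", "ACGTN\t")), "tab")

    def test_bad_fasta_header_reported(self):
        with pytest.raises(SequenceFileError, match="header"):
            read_probe_sequences(io.StringIO(">oops\nACGT\n"), "fasta")

    def test_missing_tab_column_reported(self):
        bad = TAB.replace("Probe Sequence", "Mystery")
        with pytest.raises(SequenceFileError, match="seq"):
            read_probe_sequences(io.StringIO(bad), "tab")


class TestMmFromPm:
    def test_central_base_complemented(self):
        assert mm_from_pm("A" * 25) == "A" * 12 + "T" + "A" * 12
        # manually complemented at 1-based position 13
        assert mm_from_pm("ACGTACGTACGTACGTACGTACGTA") == \
            "ACGTACGTACGTTCGTACGTACGTA"

    def test_involution_on_random_25mers(self):
        rng = random.Random(42)
        for _ in range(200):
            seq = "".join(rng.choice("ACGT") for _ in range(25))
            mm = mm_from_pm(seq)
            assert mm_from_pm(mm) == seq
            assert len(mm) == 25
            assert sum(a != b for a, b in zip(seq, mm)) == 1

    @pytest.mark.parametrize("bad", ["ACGT", "A" * 24, "AXGTA"])
    def test_rejects_even_length_and_bad_alphabet(self, bad):
        with pytest.raises(ValueError):
            mm_from_pm(bad)


class TestAttach:
    def _records(self):
        return read_probe_sequences(io.StringIO(TAB), "tab")

    def test_generate_mm_annotates_both_partners(self, two_set_spec):
        report = attach_sequences(two_set_spec, self._records(),
                                  generate_mm=True)
        assert report.annotated == 6
        assert report.mm_generated == 3
        for ps in two_set_spec.probe_sets:
            for pair in ps.pairs:
                if pair.pm.sequence is not None:
                    assert pair.mm.sequence == mm_from_pm(pair.pm.sequence)

    def test_no_generate_mm_leaves_mm_bare(self, two_set_spec):
        report = attach_sequences(two_set_spec, self._records(),
                                  generate_mm=False)
        assert report.annotated == 3
        assert all(pair.mm.sequence is None
                   for ps in two_set_spec.probe_sets for pair in ps.pairs)

    def test_unmatched_record_strict_names_coordinate(self, two_set_spec):
        recs = self._records() + [type(self._records()[0])(
            probe_set_name="ghost", x=7, y=7, interrogation_position=1,
            sequence="A" * 25)]
        with pytest.raises(ValueError, match=r"\(7, 7\)"):
            attach_sequences(two_set_spec, recs, strict=True)

    def test_unmatched_record_lenient_reported(self, two_set_spec):
        recs = self._records()
        bad = type(recs[0])(probe_set_name="ghost", x=7, y=7,
                            interrogation_position=1, sequence="A" * 25)
        report = attach_sequences(two_set_spec, recs + [bad], strict=False)
        assert report.unmatched == [(7, 7)]
        assert report.annotated == 6

    def test_topology_untouched_by_annotation(self, two_set_spec):
        before = model_key(two_set_spec)  # sequence-blind key
        attach_sequences(two_set_spec, self._records())
        assert model_key(two_set_spec) == before


class TestExport:
    def _annotated(self):
        spec = build_spec([("alpha_at", 2)], rows=4, cols=4)
        recs = read_probe_sequences(io.StringIO(TAB), "tab")[:2]
        attach_sequences(spec, recs, generate_mm=True)
        return spec

    @pytest.mark.parametrize("fmt", ["fasta", "delimited", "xml"])
    def test_one_record_per_annotated_probe(self, fmt):
        buf = io.StringIO()
        assert export_sequences(self._annotated(), fmt, buf) == 4

    def test_fasta_reimport_reproduces_annotations(self):
        spec = self._annotated()
        buf = io.StringIO()
        export_sequences(spec, "fasta", buf)
        buf.seek(0)
        fresh = build_spec([("alpha_at", 2)], rows=4, cols=4)
        recs = read_probe_sequences(buf, "fasta")
        attach_sequences(fresh, recs, generate_mm=False, strict=False)
        assert model_equal(fresh, spec, include_sequences=True)

    def test_delimited_export_has_constant_column_count(self):
        buf = io.StringIO()
        export_sequences(self._annotated(), "delimited", buf)
        rows = [line.split("\t") for line in
                buf.getvalue().rstrip("\n").split("\n")]
        assert len({len(r) for r in rows}) == 1

    def test_no_sequences_is_an_error(self, two_set_spec):
        with pytest.raises(ValueError, match="no probe sequences"):
            export_sequences(two_set_spec, "fasta", io.StringIO())
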