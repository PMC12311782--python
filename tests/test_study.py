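"""Study model: fractions, JSON round-trips, sections table, invariants."""

import numpy as np
import pytest

import dmsprof as dp
from dmsprof.errors import FormatError, ValidationError


class TestMutationFraction:
    def test_direct_ratio(self):
        frac = dp.mutation_fraction([5], [200])
        assert frac[0] == pytest.approx(0.025)

    def test_zero_coverage_masked(self):
        frac = dp.mutation_fraction([0, 3], [0, 100])
        assert np.isnan(frac[0]) and frac[1] == pytest.approx(0.03)

    def test_mutated_exceeding_coverage_rejected(self):
        with pytest.raises(ValidationError, match="mutated > coverage"):
            dp.mutation_fraction([7], [0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            dp.mutation_fraction([-1], [10])

    def test_recompute_idempotent(self, golden_study):
        prof = golden_study.get_profile("s0", "ref1", "roi")
        again = prof.compute_fraction()
        assert np.array_equal(prof.fraction, again, equal_nan=True)
        expected = prof.mutated / prof.coverage
        assert np.allclose(prof.fraction, expected)


class TestJsonRoundTrip:
    def test_minimal_fixture_fraction(self, tmp_path):
        sec = dp.SectionAnnotation("full", "full", 1, 1)
        study = dp.Study(references={"r": "A"}, sections={"r": [sec]})
        rec = dp.SampleRecord(sample="s")
        rec.profiles[("r", "full")] = dp.PositionProfile(
            "r", sec, [1], ["A"], [200], [5]
        )
        study.samples["s"] = rec
        path = dp.write_study(study, tmp_path / "s.json")
        loaded = dp.load_study(path)
        assert loaded.get_profile("s", "r", "full").fraction[0] == pytest.approx(0.025)

    def test_masked_encoded_as_null_and_preserved(self, tmp_path):
        sec = dp.SectionAnnotation("full", "full", 1, 2)
        study = dp.Study(references={"r": "AC"}, sections={"r": [sec]})
        rec = dp.SampleRecord(sample="s")
        rec.profiles[("r", "full")] = dp.PositionProfile(
            "r", sec, [1, 2], ["A", "C"], [0, 100], [0, 4]
        )
        study.samples["s"] = rec
        path = dp.write_study(study, tmp_path / "s.json")
        assert '"fraction": [\n' in path.read_text() or "null" in path.read_text()
        loaded = dp.load_study(path)
        frac = loaded.get_profile("s", "r", "full").fraction
        assert np.isnan(frac[0]) and frac[1] == pytest.approx(0.04)

    def test_empty_study_round_trips(self, tmp_path):
        study = dp.Study()
        loaded = dp.load_study(dp.write_study(study, tmp_path / "e.json"))
        assert loaded.equals(study)

    def test_golden_study_round_trips_exactly(self, golden_study, tmp_path):
        path = dp.write_study(golden_study, tmp_path / "g.json")
        assert dp.load_study(path).equals(golden_study)

    def test_simulated_study_round_trips_exactly(self, sim_study, tmp_path):
        path = dp.write_study(sim_study, tmp_path / "sim.json")
        assert dp.load_study(path).equals(sim_study)

    def test_write_is_byte_stable(self, golden_study, tmp_path):
        a = dp.write_study(golden_study, tmp_path / "a.json").read_text()
        b = dp.write_study(golden_study, tmp_path / "b.json").read_text()
        assert a == b

    def test_parse_failure_names_offender(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text('{"schema_version": "1", "sections": {}, "samples": {}}')
        with pytest.raises(FormatError, match="references"):
            dp.load_study(bad)

    def test_extra_top_level_keys_preserved_in_provenance(self, tmp_path):
        doc = tmp_path / "x.json"
        doc.write_text(
            '{"schema_version": "1", "references": {}, "sections": {}, '
            '"samples": {}, "exporter_build": 42}'
        )
        loaded = dp.load_study(doc)
        assert loaded.provenance["extra_keys"]["exporter_build"] == 42


class TestInvariants:
    def test_profile_base_matches_reference_subsequence(self, golden_study):
        for sname, rec in golden_study.samples.items():
            for (ref, _), prof in rec.profiles.items():
                seq = golden_study.references[ref]
                sub = seq[prof.section.start - 1 : prof.section.end]
                assert "".join(prof.base) == sub
                assert len(prof.positions) == prof.section.length

    def test_mutated_above_coverage_fails_validation(self):
        sec = dp.SectionAnnotation("full", "full", 1, 1)
        with pytest.raises(ValidationError):
            dp.PositionProfile("r", sec, [1], ["A"], [10], [11]).validate()

    def test_sub_counts_above_mutated_fails_validation(self):
        sec = dp.SectionAnnotation("full", "full", 1, 1)
        prof = dp.PositionProfile(
            "r", sec, [1], ["A"], [100], [5],
            sub_counts={"C": [4], "G": [4], "T": [0], "A": [0]},
        )
        with pytest.raises(ValidationError, match="sub_counts"):
            prof.validate()

    def test_n_reference_base_always_masked(self):
        sec = dp.SectionAnnotation("full", "full", 1, 2)
        prof = dp.PositionProfile("r", sec, [1, 2], ["N", "A"], [100, 100], [5, 5])
        assert np.isnan(prof.fraction[0]) and np.isfinite(prof.fraction[1])

    def test_full_section_must_span_reference(self):
        study = dp.Study(
            references={"r": "ACGT"},
            sections={"r": [dp.SectionAnnotation("full", "full", 1, 3)]},
        )
        with pytest.raises(ValidationError, match="entire reference"):
            study.validate()


class TestSectionsTable:
    def _write(self, tmp_path, text):
        path = tmp_path / "sections.csv"
        path.write_text(text)
        return path

    def test_roi_row_length_73(self, tmp_path):
        refs = {"ref1": "A" * 170}
        path = self._write(
            tmp_path, "reference,section,start,end,role\nref1,var,40,112,roi\n"
        )
        sections = dp.read_sections_table(path, refs)
        roi = [s for s in sections["ref1"] if s.role == "roi"][0]
        assert roi.length == 73 and (roi.start, roi.end) == (40, 112)

    def test_implicit_full_section_added(self, tmp_path):
        refs = {"ref1": "A" * 170}
        path = self._write(
            tmp_path, "reference,section,start,end,role\nref1,var,40,112,roi\n"
        )
        sections = dp.read_sections_table(path, refs)
        full = [s for s in sections["ref1"] if s.role == "full"][0]
        assert (full.start, full.end) == (1, 170)

    def test_explicit_full_row_accepted(self, tmp_path):
        refs = {"r": "ACGTACGT"}
        path = self._write(
            tmp_path, "reference,section,start,end,role\nr,whole,1,8,full\n"
        )
        sections = dp.read_sections_table(path, refs)
        assert [s.name for s in sections["r"]] == ["whole"]

    def test_start_after_end_rejected(self, tmp_path):
        refs = {"r": "ACGT"}
        path = self._write(
            tmp_path, "reference,section,start,end,role\nr,x,3,2,roi\n"
        )
        with pytest.raises(ValidationError):
            dp.read_sections_table(path, refs)

    def test_out_of_bounds_rejected(self, tmp_path):
        refs = {"r": "ACGT"}
        path = self._write(
            tmp_path, "reference,section,start,end,role\nr,x,1,9,roi\n"
        )
        with pytest.raises(ValidationError, match="exceeds"):
            dp.read_sections_table(path, refs)

    def test_duplicate_section_names_rejected(self, tmp_path):
        refs = {"r": "ACGTACGT"}
        path = self._write(
            tmp_path,
            "reference,section,start,end,role\nr,x,1,4,roi\nr,x,5,8,flank3\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            dp.read_sections_table(path, refs)

    def test_missing_column_is_format_error(self, tmp_path):
        refs = {"r": "ACGT"}
        path = self._write(tmp_path, "reference,start,end\nr,1,4\n")
        with pytest.raises(FormatError, match="missing columns"):
            dp.read_sections_table(path, refs)


class TestFasta:
    def test_round_trip_and_u_normalization(self, tmp_path):
        path = tmp_path / "refs.fasta"
        path.write_text(">a\nACGU\nacg\n>b\nTTTT\n")
        refs = dp.read_fasta(path)
        assert refs == {"a": "ACGTACG", "b": "TTTT"}
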