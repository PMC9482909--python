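"""I/O round trips and validation for MSP, feature tables and suspect lists."""

import textwrap

import pytest

from exposcreen.msdata import (
    CohortDesign,
    Feature,
    MSPFormatError,
    Spectrum,
    SuspectEntry,
    read_feature_table,
    read_msp,
    read_suspect_list,
    write_feature_table,
    write_msp,
)

DESIGN = CohortDesign({"PD1": "PD", "PD2": "PD", "C1": "Ctrl", "C2": "Ctrl"})


@pytest.fixture
def msp_file(tmp_path):
    p = tmp_path / "lib.msp"
    p.write_text(
        textwrap.dedent(
            """\
            NAME: compound one
            PRECURSORMZ: 118.0863
            PRECURSORTYPE: [M+H]+
            FORMULA: C5H11NO2
            INCHIKEY: ABCDEFGHIJKLMN-OPQRSTUVWX-N
            Num Peaks: 3
            55.0 100
            72.1 50.5
            90.2 10

            NAME: structure unknown
            PRECURSORMZ: 200.1
            NumPeaks: 2
            90.0\t40
            100.0\t60
            """
        )
    )
    return p


class TestMsp:
    def test_peak_counts_and_metadata(self, msp_file):
        spectra = read_msp(msp_file)
        assert len(spectra) == 2
        assert len(spectra[0].peaks) == 3
        assert spectra[0].formula.hill() == "C5H11NO2"
        assert spectra[0].structure_known

    def test_record_without_inchikey_is_structure_unknown(self, msp_file):
        spectra = read_msp(msp_file)
        assert not spectra[1].structure_known

    def test_round_trip_preserves_peaks(self, msp_file, tmp_path):
        spectra = read_msp(msp_file)
        out = tmp_path / "out.msp"
        write_msp(spectra, out)
        again = read_msp(out)
        for a, b in zip(spectra, again):
            assert a.name == b.name
            for (m1, i1), (m2, i2) in zip(a.peaks, b.peaks):
                assert m1 == pytest.approx(m2, abs=1e-4)
                assert i1 == pytest.approx(i2, abs=1e-4)
        # second round trip is byte-stable
        out2 = tmp_path / "out2.msp"
        write_msp(again, out2)
        assert out.read_text() == out2.read_text()

    def test_peak_count_mismatch_reports_line(self, tmp_path):
        p = tmp_path / "bad.msp"
        p.write_text("NAME: x\nNum Peaks: 3\n55.0 1\n56.0 1\n")
        with pytest.raises(MSPFormatError, match="line 1"):
            read_msp(p)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "empty.msp"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert read_msp(p) == []

    def test_matchms_reads_our_output(self, msp_file, tmp_path):
        """Independent cross-check: the field-standard MSP reader agrees on
        peak content."""
        matchms_io = pytest.importorskip("matchms.importing")
        ours = read_msp(msp_file)
        out = tmp_path / "x.msp"
        write_msp(ours, out)
        theirs = list(matchms_io.load_from_msp(str(out)))
        assert len(theirs) == len(ours)
        for a, b in zip(ours, theirs):
            assert len(a.peaks) == len(b.peaks.mz)
            assert a.mz == pytest.approx(b.peaks.mz, abs=1e-4)


class TestFeatureTable:
    def _write(self, tmp_path, body):
        p = tmp_path / "ft.csv"
        p.write_text(body)
        return p

    def test_toy_table(self, tmp_path):
        p = self._write(
            tmp_path,
            "feature_id,mz,rt,esi_mode,lc_mode,fraction,PD1,PD2,C1,C2\n"
            + "\n".join(f"F{i},11{i}.05,2.5,+,RP,polar,1,2,3,4" for i in range(5)),
        )
        feats = read_feature_table(p, DESIGN)
        assert len(feats) == 5
        assert all(len(f.intensities) == 4 for f in feats)

    def test_orphan_sample_column(self, tmp_path):
        p = self._write(
            tmp_path,
            "feature_id,mz,rt,esi_mode,lc_mode,fraction,PD1,STRANGER\nF1,100.0,1.0,+,RP,polar,1,2\n",
        )
        with pytest.raises(ValueError, match="STRANGER"):
            read_feature_table(p, DESIGN)

    def test_duplicate_feature_id(self, tmp_path):
        p = self._write(
            tmp_path,
            "feature_id,mz,rt,esi_mode,lc_mode,fraction,PD1,PD2,C1,C2\n"
            "F1,100.0,1.0,+,RP,polar,1,2,3,4\nF1,101.0,1.0,+,RP,polar,1,2,3,4\n",
        )
        with pytest.raises(ValueError, match="duplicated"):
            read_feature_table(p, DESIGN)

    def test_non_numeric_intensity_reports_cell(self, tmp_path):
        p = self._write(
            tmp_path,
            "feature_id,mz,rt,esi_mode,lc_mode,fraction,PD1,PD2,C1,C2\n"
            "F1,100.0,1.0,+,RP,polar,1,oops,3,4\n",
        )
        with pytest.raises(ValueError, match="PD2"):
            read_feature_table(p, DESIGN)

    def test_round_trip(self, tmp_path):
        feats = [
            Feature(f"F{i}", 100.0 + i, 1.5, "+", "RP", "polar", {"PD1": 1.0, "PD2": 2.0, "C1": 0.0, "C2": 4.0})
            for i in range(3)
        ]
        p = tmp_path / "rt.csv"
        write_feature_table(feats, p)
        again = read_feature_table(p, DESIGN)
        assert [f.feature_id for f in again] == [f.feature_id for f in feats]
        assert again[0].intensities == feats[0].intensities


class TestSuspectList:
    def test_mass_backfilled_from_formula(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("name,formula\nL-Valine,C5H11NO2\n")
        entries = read_suspect_list(p, "PD-CTD")
        assert entries[0].neutral_mass == pytest.approx(117.078979, abs=1e-5)
        assert entries[0].list_code == "PD-CTD"

    def test_fifty_nine_row_file(self, tmp_path):
        p = tmp_path / "s.csv"
        rows = "\n".join(f"cmpd{i},,{100.0 + i}" for i in range(59))
        p.write_text("name,formula,monoisotopic_mass\n" + rows + "\n")
        assert len(read_suspect_list(p, "D020920")) == 59

    def test_row_without_formula_or_mass_skipped_with_warning(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("name,formula,monoisotopic_mass\ngood,C2H6O,\nbad,,\n")
        with pytest.warns(UserWarning, match="skipped 1"):
            entries = read_suspect_list(p, "X")
        assert len(entries) == 1

    def test_inconsistent_mass_and_formula_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            SuspectEntry("x", __import__("exposcreen.chem", fromlist=["parse_formula"]).parse_formula("C2H6O"), 99.0)


class TestCohortDesign:
    def test_groups_and_validation(self):
        d = CohortDesign({"a": "PD", "b": "PD", "c": "PD", "d": "Ctrl", "e": "Ctrl", "f": "Ctrl", "q": "QC"})
        assert d.qc_samples == ["q"]
        d.validate_for_stats()
        with pytest.raises(ValueError, match="< 3 samples"):
            CohortDesign({"a": "PD", "b": "Ctrl"}).validate_for_stats()
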