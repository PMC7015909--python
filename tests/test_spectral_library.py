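"""Mass arithmetic and library I/O checks against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import silacprm as sp
from silacprm.spectral_library import (
    HEAVY_K_SHIFT,
    HEAVY_R_SHIFT,
    LibraryValidationError,
    library_to_frame,
)

from conftest import oracle_peptide_mass, oracle_y_mz

peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25)
tryptic = peptides.map(lambda s: s + "K")


class TestPeptideMass:
    @pytest.mark.parametrize(
        "seq,channel,expected",
        [
            ("GK", sp.LIGHT, 203.12699),
            ("GK", sp.HEAVY, 211.14119),  # light + K shift 8.014199
            ("GR", sp.HEAVY, 203.12699 - 128.09496 + 156.10111 + 6.020129),
        ],
    )
    def test_reference_values(self, seq, channel, expected):
        assert sp.peptide_monoisotopic_mass(seq, channel) == pytest.approx(expected, abs=1e-5)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sp.peptide_monoisotopic_mass("")

    def test_unknown_residue_named(self):
        with pytest.raises(ValueError, match="'B'"):
            sp.peptide_monoisotopic_mass("ABK")

    @given(tryptic)
    def test_matches_brute_force_oracle(self, seq):
        for channel, heavy in ((sp.LIGHT, False), (sp.HEAVY, True)):
            assert sp.peptide_monoisotopic_mass(seq, channel) == pytest.approx(
                oracle_peptide_mass(seq, heavy), abs=1e-4
            )

    @given(peptides, peptides)
    def test_mass_additivity(self, a, b):
        """mass(A+B) = mass(A) + mass(B) - water, to 1e-6 Da."""
        lhs = sp.peptide_monoisotopic_mass(a + b)
        rhs = (
            sp.peptide_monoisotopic_mass(a)
            + sp.peptide_monoisotopic_mass(b)
            - sp.spectral_library.WATER
        )
        assert lhs == pytest.approx(rhs, abs=1e-6)

    @given(peptides)
    def test_heavy_light_difference_exact(self, seq):
        diff = sp.peptide_monoisotopic_mass(seq, sp.HEAVY) - sp.peptide_monoisotopic_mass(seq)
        expected = HEAVY_K_SHIFT * seq.count("K") + HEAVY_R_SHIFT * seq.count("R")
        assert diff == pytest.approx(expected, abs=1e-9)


class TestFragmentMz:
    @pytest.mark.parametrize(
        "seq,ordinal,charge,channel,expected",
        [
            ("GK", 1, 1, sp.LIGHT, 147.11280),
            ("GK", 1, 1, sp.HEAVY, 155.12700),
        ],
    )
    def test_reference_values(self, seq, ordinal, charge, channel, expected):
        assert sp.fragment_mz(seq, "y", ordinal, charge, channel) == pytest.approx(expected, abs=1e-5)

    def test_ordinal_must_be_less_than_length(self):
        with pytest.raises(ValueError):
            sp.fragment_mz("GK", "y", 2, 1)

    @given(tryptic, st.integers(1, 3))
    def test_matches_oracle(self, seq, charge):
        ordinal = max(1, len(seq) - 2)
        got = sp.fragment_mz(seq, "y", ordinal, charge, sp.HEAVY)
        assert got == pytest.approx(oracle_y_mz(seq, ordinal, charge, heavy=True), abs=1e-4)

    @given(peptides.filter(lambda s: len(s) >= 3))
    def test_y_ladder_telescoping(self, seq):
        """mz(y_n) - mz(y_{n-1}) at z=1 equals the n-th residue mass from the C terminus."""
        mods = {}
        for n in range(2, len(seq)):
            step = sp.fragment_mz(seq, "y", n, 1, sp.LIGHT, mods) - sp.fragment_mz(
                seq, "y", n - 1, 1, sp.LIGHT, mods
            )
            residue = seq[-n]
            assert step == pytest.approx(sp.spectral_library.RESIDUE_MASS[residue], abs=1e-9)


class TestPpmWindow:
    @pytest.mark.parametrize(
        "center,ppm,expected",
        [
            (500.0, 20.0, (499.99, 500.01)),
            (500.0, 0.0, (500.0, 500.0)),
        ],
    )
    def test_reference_values(self, center, ppm, expected):
        lo, hi = sp.ppm_window(center, ppm)
        assert (lo, hi) == pytest.approx(expected, abs=1e-9)

    def test_width_scales_with_center(self):
        lo, hi = sp.ppm_window(1000.0, 20.0)
        assert hi - lo == pytest.approx(0.04, abs=1e-9)

    def test_nonpositive_center_rejected(self):
        with pytest.raises(ValueError):
            sp.ppm_window(0.0, 20.0)

    @given(
        st.floats(1.0, 5000.0, allow_nan=False),
        st.floats(0.0, 100.0),
        st.floats(0.0, 100.0),
    )
    def test_symmetric_and_monotone(self, center, ppm1, ppm2):
        lo, hi = sp.ppm_window(center, ppm1)
        assert hi - center == pytest.approx(center - lo, rel=1e-12)
        lo2, hi2 = sp.ppm_window(center, ppm2)
        if ppm2 >= ppm1:
            assert hi2 - lo2 >= hi - lo


class TestLibraryModel:
    def _entry(self, n_transitions=4, **kw):
        defaults = dict(
            peptide_sequence="ELVISLIVESK",
            protein_id="KIN1",
            kinase_class="protein",
            precursor_charge=2,
            missed_cleavages=0,
            transitions=[sp.Transition("y", i + 3, 1, 0.25) for i in range(n_transitions)],
        )
        defaults.update(kw)
        return sp.LibraryEntry(**defaults)

    def test_transition_count_bounds(self):
        self._entry(4)
        self._entry(6)
        for bad in (3, 7):
            with pytest.raises(LibraryValidationError):
                self._entry(bad)

    def test_missed_cleavage_limit(self):
        with pytest.raises(LibraryValidationError):
            self._entry(missed_cleavages=2)

    def test_non_tryptic_rejected_unless_cterminal(self):
        with pytest.raises(LibraryValidationError):
            self._entry(peptide_sequence="ELVISLIVESA")
        self._entry(peptide_sequence="ELVISLIVESA", c_terminal=True)

    def test_ordinal_must_fit_sequence(self):
        with pytest.raises(LibraryValidationError):
            self._entry(
                peptide_sequence="SHORTK",
                transitions=[sp.Transition("y", o, 1, 0.25) for o in (2, 3, 4, 6)],
            )

    def test_duplicate_entries_rejected(self):
        e = self._entry()
        with pytest.raises(LibraryValidationError):
            sp.SpectralLibrary(entries=[e, self._entry()])

    def test_max_four_peptides_per_protein(self):
        entries = [
            self._entry(peptide_sequence="ELVISLIVES" + tail)
            for tail in ("K", "R", "AK", "AR", "GK")
        ]
        with pytest.raises(LibraryValidationError, match="exceeds"):
            sp.SpectralLibrary(entries=entries)


class TestLibraryIO:
    def test_round_trip_identity(self, tmp_path):
        cfg = sp.SimulationConfig(n_proteins=50, seed=4)
        lib = sp.generate_library(cfg)
        path = tmp_path / "library.tsv"
        sp.write_library(lib, path)
        back = sp.read_library(path)
        a, b = library_to_frame(lib), library_to_frame(back)
        intensity = "library_relative_intensity"
        np.testing.assert_allclose(a[intensity], b[intensity], rtol=1e-5)
        assert a.drop(columns=intensity).equals(b.drop(columns=intensity))

    def test_validation_error_reports_lines(self, tmp_path, small_library):
        df = library_to_frame(small_library)
        # duplicate one transition row of the first peptide -> 7 transitions or dup key
        df = __import__("pandas").concat([df.iloc[[0]], df], ignore_index=True)
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(LibraryValidationError, match="lines"):
            sp.read_library(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("protein_id\tpeptide_sequence\nA\tPEPK\n")
        with pytest.raises(LibraryValidationError, match="missing columns"):
            sp.read_library(path)
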