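"""Skyline-style PRM spectral library: data model, SILAC mass arithmetic, TSV I/O.

The library holds targeted tryptic peptides for kinases, each with 4-6 y-ion
transitions and their reference (library) relative intensities.  SILAC channels
are realized as fixed monoisotopic mass shifts on lysine and arginine:
[13C6,15N2]-Lys (+8.014199 Da) and [13C6]-Arg (+6.020129 Da).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from pyteomics import mass as _ptmass

__all__ = [
    "Transition",
    "LibraryEntry",
    "SpectralLibrary",
    "SilacChannel",
    "LIGHT",
    "HEAVY",
    "KINASE_CLASSES",
    "LibraryValidationError",
    "peptide_monoisotopic_mass",
    "fragment_mz",
    "precursor_mz",
    "ppm_window",
    "read_library",
    "write_library",
]

# Monoisotopic residue masses (pyteomics reference table, CODATA-consistent).
RESIDUE_MASS: Mapping[str, float] = dict(_ptmass.std_aa_mass)
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

WATER = 18.0105646863
PROTON = 1.007276

# Heavy isotopologue shifts: 6x(13C-12C) + 2x(15N-14N) on K, 6x(13C-12C) on R.
HEAVY_K_SHIFT = 8.014199
HEAVY_R_SHIFT = 6.020129

# Carbamidomethylation of cysteine, the usual fixed modification after
# iodoacetamide alkylation.  Overridable per call; keyed by residue letter.
DEFAULT_FIXED_MODIFICATIONS: Mapping[str, float] = {"C": 57.0214637}

KINASE_CLASSES = ("protein", "lipid", "nucleotide", "carbohydrate", "other")

LIBRARY_COLUMNS = [
    "protein_id",
    "kinase_class",
    "peptide_sequence",
    "precursor_charge",
    "missed_cleavages",
    "fragment",
    "fragment_charge",
    "library_relative_intensity",
]


class LibraryValidationError(ValueError):
    """Raised when a library entry or file violates a structural invariant."""


@dataclass(frozen=True)
class SilacChannel:
    """A SILAC channel as per-residue mass shifts on K and R."""

    label: str
    lysine_shift: float
    arginine_shift: float

    def residue_shift(self, residue: str) -> float:
        if residue == "K":
            return self.lysine_shift
        if residue == "R":
            return self.arginine_shift
        return 0.0


LIGHT = SilacChannel("light", 0.0, 0.0)
HEAVY = SilacChannel("heavy", HEAVY_K_SHIFT, HEAVY_R_SHIFT)

CHANNELS: Mapping[str, SilacChannel] = {"light": LIGHT, "heavy": HEAVY}


@dataclass(frozen=True, order=True)
class Transition:
    """One y-ion transition with its library reference intensity."""

    fragment_series: str
    ordinal: int
    fragment_charge: int
    library_relative_intensity: float

    def __post_init__(self) -> None:
        if self.fragment_series != "y":
            raise LibraryValidationError(
                f"only y-series fragments are supported, got {self.fragment_series!r}"
            )
        if self.ordinal < 1:
            raise LibraryValidationError(f"fragment ordinal must be >=1, got {self.ordinal}")
        if self.fragment_charge < 1:
            raise LibraryValidationError(f"fragment charge must be >=1, got {self.fragment_charge}")
        if not (math.isfinite(self.library_relative_intensity) and self.library_relative_intensity >= 0):
            raise LibraryValidationError(
                f"library relative intensity must be finite and >=0, "
                f"got {self.library_relative_intensity}"
            )

    @property
    def label(self) -> str:
        """Fragment label as written in transition lists, e.g. ``y7``."""
        return f"{self.fragment_series}{self.ordinal}"


@dataclass
class LibraryEntry:
    """One targeted peptide with its transitions."""

    peptide_sequence: str
    protein_id: str
    kinase_class: str
    precursor_charge: int
    missed_cleavages: int
    transitions: list[Transition] = field(default_factory=list)
    c_terminal: bool = False  # a protein C-terminal peptide need not end in K/R

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seq = self.peptide_sequence
        if not seq or not set(seq) <= CANONICAL_RESIDUES:
            bad = sorted(set(seq) - CANONICAL_RESIDUES)
            raise LibraryValidationError(
                f"peptide {seq!r}: non-canonical residues {bad}" if seq else "empty peptide sequence"
            )
        if not self.c_terminal and seq[-1] not in "KR":
            raise LibraryValidationError(f"peptide {seq!r} is not tryptic (must end in K or R)")
        if self.kinase_class not in KINASE_CLASSES:
            raise LibraryValidationError(
                f"unknown kinase class {self.kinase_class!r}; expected one of {KINASE_CLASSES}"
            )
        if self.precursor_charge < 1:
            raise LibraryValidationError(f"precursor charge must be >=1, got {self.precursor_charge}")
        if self.missed_cleavages not in (0, 1):
            raise LibraryValidationError(
                f"at most one missed cleavage allowed, got {self.missed_cleavages}"
            )
        if not 4 <= len(self.transitions) <= 6:
            raise LibraryValidationError(
                f"peptide {seq!r}: expected 4-6 transitions, got {len(self.transitions)}"
            )
        keys = [(t.fragment_series, t.ordinal, t.fragment_charge) for t in self.transitions]
        if len(set(keys)) != len(keys):
            raise LibraryValidationError(f"peptide {seq!r}: duplicate transitions")
        for t in self.transitions:
            if t.ordinal >= len(seq):
                raise LibraryValidationError(
                    f"peptide {seq!r}: y{t.ordinal} ordinal must be < peptide length {len(seq)}"
                )

    @property
    def key(self) -> tuple[str, int]:
        return (self.peptide_sequence, self.precursor_charge)

    def transition_labels(self) -> list[str]:
        return [t.label for t in self.transitions]


@dataclass
class SpectralLibrary:
    """A collection of :class:`LibraryEntry` with a per-protein index."""

    entries: list[LibraryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[str, int]] = set()
        per_protein: dict[str, int] = {}
        for e in self.entries:
            if e.key in seen:
                raise LibraryValidationError(
                    f"duplicate library entry {e.peptide_sequence}/{e.precursor_charge}+"
                )
            seen.add(e.key)
            per_protein[e.protein_id] = per_protein.get(e.protein_id, 0) + 1
        for pid, n in per_protein.items():
            if n > 4:
                raise LibraryValidationError(f"protein {pid}: {n} peptides exceeds the limit of 4")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.protein_id, None)
        return list(seen)

    def by_protein(self, protein_id: str) -> list[LibraryEntry]:
        return [e for e in self.entries if e.protein_id == protein_id]

    def get(self, peptide_sequence: str, precursor_charge: int | None = None) -> LibraryEntry:
        for e in self.entries:
            if e.peptide_sequence == peptide_sequence and (
                precursor_charge is None or e.precursor_charge == precursor_charge
            ):
                return e
        raise KeyError(peptide_sequence)


# ---------------------------------------------------------------------------
# Mass arithmetic
# ---------------------------------------------------------------------------

def _residue_masses(
    sequence: str,
    channel: SilacChannel,
    fixed_modifications: Mapping[str, float] | None,
) -> list[float]:
    mods = DEFAULT_FIXED_MODIFICATIONS if fixed_modifications is None else fixed_modifications
    out = []
    for aa in sequence:
        if aa not in CANONICAL_RESIDUES:
            raise ValueError(f"unknown residue {aa!r} in sequence {sequence!r}")
        out.append(RESIDUE_MASS[aa] + mods.get(aa, 0.0) + channel.residue_shift(aa))
    return out


def peptide_monoisotopic_mass(
    sequence: str,
    channel: SilacChannel = LIGHT,
    fixed_modifications: Mapping[str, float] | None = None,
) -> float:
    """Monoisotopic neutral mass of a peptide in the given SILAC channel (Da).

    Sum of residue monoisotopic masses plus water, plus the heavy K/R shifts
    when ``channel`` is heavy, plus any fixed modifications (by default
    carbamidomethyl on C, +57.02146 Da).
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    return sum(_residue_masses(sequence, channel, fixed_modifications)) + WATER


def fragment_mz(
    sequence: str,
    series: str,
    ordinal: int,
    fragment_charge: int,
    channel: SilacChannel = LIGHT,
    fixed_modifications: Mapping[str, float] | None = None,
) -> float:
    """m/z of a y-series fragment of a peptide.

    The y_n fragment is the C-terminal n residues with water; heavy shifts are
    included for every labeled K/R the fragment contains.
    """
    if series != "y":
        raise ValueError(f"only y-series fragments supported, got {series!r}")
    if not 1 <= ordinal < len(sequence):
        raise ValueError(
            f"fragment ordinal {ordinal} out of range for peptide of length {len(sequence)}"
        )
    if fragment_charge < 1:
        raise ValueError(f"fragment charge must be >=1, got {fragment_charge}")
    frag = sequence[-ordinal:]
    neutral = sum(_residue_masses(frag, channel, fixed_modifications)) + WATER
    return (neutral + fragment_charge * PROTON) / fragment_charge


def precursor_mz(
    sequence: str,
    charge: int,
    channel: SilacChannel = LIGHT,
    fixed_modifications: Mapping[str, float] | None = None,
) -> float:
    """Precursor m/z of the intact peptide at the given charge."""
    if charge < 1:
        raise ValueError(f"precursor charge must be >=1, got {charge}")
    neutral = peptide_monoisotopic_mass(sequence, channel, fixed_modifications)
    return (neutral + charge * PROTON) / charge


def ppm_window(mz_center: float, tolerance_ppm: float) -> tuple[float, float]:
    """Symmetric extraction window ``mz_center * (1 +/- tolerance_ppm * 1e-6)``.

    This realizes the fragment-ion mass gate (20 ppm by default elsewhere in
    the pipeline) used when extracting transition chromatograms.
    """
    if mz_center <= 0:
        raise ValueError(f"m/z center must be positive, got {mz_center}")
    if tolerance_ppm < 0:
        raise ValueError(f"ppm tolerance must be >=0, got {tolerance_ppm}")
    half = mz_center * tolerance_ppm * 1e-6
    return (mz_center - half, mz_center + half)


# ---------------------------------------------------------------------------
# TSV I/O — one row per transition, entry-level fields repeated
# ---------------------------------------------------------------------------

def library_to_frame(library: SpectralLibrary) -> pd.DataFrame:
    rows = []
    for e in library.entries:
        for t in e.transitions:
            rows.append(
                (
                    e.protein_id,
                    e.kinase_class,
                    e.peptide_sequence,
                    e.precursor_charge,
                    e.missed_cleavages,
                    t.label,
                    t.fragment_charge,
                    t.library_relative_intensity,
                )
            )
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def write_library(library: SpectralLibrary, path) -> None:
    library_to_frame(library).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _parse_fragment(label: str) -> tuple[str, int]:
    series, num = label[0], label[1:]
    if series != "y" or not num.isdigit():
        raise LibraryValidationError(f"unsupported fragment label {label!r} (expected e.g. 'y7')")
    return series, int(num)


def read_library(path) -> SpectralLibrary:
    """Read a transition-list TSV, enforcing all invariants.

    Validation failures report the offending peptide and the file line numbers
    of its rows (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide_sequence": str, "protein_id": str})
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryValidationError(f"{path}: missing columns {missing}")
    entries: list[LibraryEntry] = []
    errors: list[str] = []
    for (seq, charge), grp in df.groupby(["peptide_sequence", "precursor_charge"], sort=False):
        lines = [i + 2 for i in grp.index]  # header is line 1
        head = grp.iloc[0]
        try:
            transitions = []
            for _, row in grp.iterrows():
                series, ordinal = _parse_fragment(str(row["fragment"]))
                transitions.append(
                    Transition(
                        fragment_series=series,
                        ordinal=ordinal,
                        fragment_charge=int(row["fragment_charge"]),
                        library_relative_intensity=float(row["library_relative_intensity"]),
                    )
                )
            entries.append(
                LibraryEntry(
                    peptide_sequence=str(seq),
                    protein_id=str(head["protein_id"]),
                    kinase_class=str(head["kinase_class"]),
                    precursor_charge=int(charge),
                    missed_cleavages=int(head["missed_cleavages"]),
                    transitions=transitions,
                )
            )
        except (LibraryValidationError, ValueError) as exc:
            errors.append(f"lines {lines[0]}-{lines[-1]} ({seq}/{charge}+): {exc}")
    if errors:
        raise LibraryValidationError(f"{path}: " + "; ".join(errors))
    return SpectralLibrary(entries=entries)
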