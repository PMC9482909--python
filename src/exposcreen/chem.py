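"""Molecular formula arithmetic for small-molecule HRMS screening.

Monoisotopic masses, electrospray adduct m/z, ppm errors and theoretical
isotope envelopes are the mass backbone of suspect screening and molecular
formula annotation.  Atomic masses are IUPAC monoisotopic values hard-coded
to >= 6 decimals; isotope envelopes are aggregated on the unit-mass grid
(A, A+1, A+2, ...) as resolved by an Orbitrap-class instrument, not as fine
isotopologue structure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MolecularFormula",
    "Adduct",
    "IsotopePattern",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "isotope_pattern",
    "ADDUCTS",
    "PROTON_MASS",
    "ELECTRON_MASS",
]

PROTON_MASS = 1.00727646
ELECTRON_MASS = 0.00054858

#: monoisotopic (most abundant isotope) atomic masses, Da
MONOISOTOPIC_MASS = {
    "C": 12.000000,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "F": 18.99840320,
    "Cl": 34.96885271,
    "Br": 78.9183376,
    "Na": 22.98976928,
    "K": 38.96370649,
    "I": 126.9044719,
}

#: per-element isotope tables: (nominal mass offset from A, exact mass, abundance)
ISOTOPES = {
    "C": [(0, 12.000000, 0.9893), (1, 13.0033548378, 0.0107)],
    "H": [(0, 1.0078250319, 0.999885), (1, 2.0141017781, 0.000115)],
    "N": [(0, 14.0030740052, 0.99636), (1, 15.0001088984, 0.00364)],
    "O": [(0, 15.9949146221, 0.99757), (1, 16.9991315, 0.00038), (2, 17.9991604, 0.00205)],
    "P": [(0, 30.97376151, 1.0)],
    "S": [(0, 31.97207069, 0.9499), (1, 32.9714585, 0.0075), (2, 33.96786683, 0.0425), (4, 35.96708088, 0.0001)],
    "F": [(0, 18.99840320, 1.0)],
    "Cl": [(0, 34.96885271, 0.7576), (2, 36.9659026, 0.2424)],
    "Br": [(0, 78.9183376, 0.5069), (2, 80.9162906, 0.4931)],
    "Na": [(0, 22.98976928, 1.0)],
    "K": [(0, 38.96370649, 0.932581), (1, 39.96399817, 0.000117), (2, 40.96182526, 0.067302)],
    "I": [(0, 126.9044719, 1.0)],
}

SUPPORTED_ELEMENTS = frozenset(MONOISOTOPIC_MASS)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported formula strings."""


@dataclass(frozen=True)
class MolecularFormula:
    """An elemental composition, e.g. C5H11NO2.

    ``element_counts`` maps element symbols to strictly positive counts;
    zero-count elements are never stored.
    """

    element_counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        for el, n in counts.items():
            if el not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element symbol: {el!r}")
            if n <= 0:
                raise FormulaError(f"non-positive count for element {el!r}")
        if not counts:
            raise FormulaError("empty formula")
        object.__setattr__(self, "element_counts", tuple(sorted(counts.items())))

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "MolecularFormula":
        return cls(tuple((el, n) for el, n in counts.items() if n))

    def counts(self) -> dict[str, int]:
        return dict(self.element_counts)

    def __getitem__(self, element: str) -> int:
        return dict(self.element_counts).get(element, 0)

    def hill(self) -> str:
        """Canonical Hill-notation string (C first, H second, rest alphabetic)."""
        counts = self.counts()
        parts: list[str] = []
        order: list[str] = []
        if "C" in counts:
            order = ["C"] + (["H"] if "H" in counts else [])
            order += sorted(el for el in counts if el not in ("C", "H"))
        else:
            order = sorted(counts)
        for el in order:
            n = counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``"C5H11NO2"``.

    Underscores (as appear in some table typography, ``C_5_H_11_NO_2_``) and
    whitespace are stripped.  Unknown element symbols and explicit zero
    counts are rejected.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    cleaned = text.replace("_", "").replace(" ", "")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _FORMULA_TOKEN.match(cleaned, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unknown element symbol: {el!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return MolecularFormula.from_counts(counts)


def monoisotopic_mass(f: MolecularFormula | str) -> float:
    """Monoisotopic (most-abundant-isotope) mass in Da."""
    if isinstance(f, str):
        f = parse_formula(f)
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in f.element_counts)


@dataclass(frozen=True)
class Adduct:
    """An electrospray adduct: neutral molecule -> observed ion.

    ``mass_shift`` is the full ionic mass delta in Da relative to the
    neutral molecule, electron mass included.  ``intrinsic`` marks species
    such as ``[M]+`` where the formula already describes the ion's atoms
    (quaternary ammonium cations like choline) and only the electron is
    removed.
    """

    name: str
    mass_shift: float
    charge: int
    intrinsic: bool = False

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")

    @property
    def polarity(self) -> str:
        return "+" if self.charge > 0 else "-"


def _canonical_adduct_name(name: str) -> str:
    return name.replace(" ", "")


ADDUCTS: dict[str, Adduct] = {
    a.name: a
    for a in [
        Adduct("[M+H]+", PROTON_MASS, +1),
        Adduct("[M+Na]+", MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS, +1),
        Adduct("[M+NH4]+", MONOISOTOPIC_MASS["N"] + 4 * MONOISOTOPIC_MASS["H"] - ELECTRON_MASS, +1),
        Adduct("[M]+", -ELECTRON_MASS, +1, intrinsic=True),
        Adduct("[M-H]-", -PROTON_MASS, -1),
        Adduct(
            "[M+HCOO]-",
            MONOISOTOPIC_MASS["C"] + MONOISOTOPIC_MASS["H"] + 2 * MONOISOTOPIC_MASS["O"] + ELECTRON_MASS,
            -1,
        ),
    ]
}


def get_adduct(name: str) -> Adduct:
    """Resolve an adduct label, tolerating internal whitespace ("[M + H] +")."""
    key = _canonical_adduct_name(name)
    if key not in ADDUCTS:
        raise KeyError(f"unknown adduct: {name!r} (supported: {sorted(ADDUCTS)})")
    return ADDUCTS[key]


def adduct_mz(f: MolecularFormula | str, adduct: Adduct | str) -> float:
    """Theoretical m/z of a formula observed as the given adduct.

    For intrinsically charged species ("[M]+") the formula is taken as the
    ion's atom inventory and only the electron mass is corrected.
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    m = monoisotopic_mass(f)
    return (m + adduct.mass_shift) / abs(adduct.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class IsotopePattern:
    """Isotope envelope on the unit-mass grid, base peak normalized to 1."""

    peaks: tuple[tuple[float, float], ...]  # (mass Da, relative abundance)

    def __post_init__(self) -> None:
        masses = [m for m, _ in self.peaks]
        if masses != sorted(masses) or len(set(masses)) != len(masses):
            raise ValueError("isotope pattern masses must be strictly increasing")

    @property
    def abundances(self) -> np.ndarray:
        return np.array([a for _, a in self.peaks])

    @property
    def masses(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])


def _element_distribution(element: str, count: int, max_offset: int) -> np.ndarray:
    """Abundance over nominal-mass offsets for ``count`` atoms of ``element``."""
    base = np.zeros(max_offset + 1)
    for offset, _mass, ab in ISOTOPES[element]:
        if offset <= max_offset:
            base[offset] += ab
    base /= base.sum() + sum(ab for o, _m, ab in ISOTOPES[element] if o > max_offset)
    dist = np.zeros(max_offset + 1)
    dist[0] = 1.0
    # repeated squaring is unnecessary at metabolite atom counts
    for _ in range(count):
        dist = np.convolve(dist, base)[: max_offset + 1]
    return dist


def isotope_pattern(f: MolecularFormula | str, max_peaks: int = 4) -> IsotopePattern:
    """Theoretical isotope envelope, unit-mass aggregated.

    Per-element nominal-offset distributions are convolved and truncated to
    ``max_peaks`` peaks (A ... A+max_peaks-1); abundances are normalized so
    the base peak is 1.  Truncation drops only trailing mass peaks.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if max_peaks < 2:
        raise ValueError("max_peaks must be >= 2")
    max_offset = max_peaks - 1
    dist = np.zeros(max_offset + 1)
    dist[0] = 1.0
    for el, n in f.element_counts:
        dist = np.convolve(dist, _element_distribution(el, n, max_offset))[: max_offset + 1]
    mono = monoisotopic_mass(f)
    dist = dist / dist.max()
    # offsets separated by the C13-C12 mass difference approximate the grid
    neutron = 1.0033548378
    peaks = tuple((mono + k * neutron, float(dist[k])) for k in range(max_offset + 1))
    return IsotopePattern(peaks)
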