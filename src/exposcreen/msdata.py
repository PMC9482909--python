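"""Readers and writers for the tabular/text formats the pipeline touches.

Three formats: NIST-dialect MSP spectral libraries, aligned feature/intensity
CSV tables, and suspect-list CSVs; plus the cohort design (sample -> group).
All CSVs are RFC 4180 UTF-8 with "." decimal point; retention times are in
minutes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import MolecularFormula, monoisotopic_mass, parse_formula

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "Feature",
    "CohortDesign",
    "SuspectEntry",
    "read_msp",
    "write_msp",
    "read_feature_table",
    "write_feature_table",
    "read_suspect_list",
    "MSPFormatError",
]


class MSPFormatError(ValueError):
    """Malformed MSP record (carries the offending line number)."""


@dataclass
class Spectrum:
    """A centroided MS/MS peak list with precursor metadata.

    ``structure_known`` is False iff no structure identifier (InChIKey) is
    attached — the "structure unknown in library" condition of the
    confidence rules.
    """

    peaks: list[tuple[float, float]]
    precursor_mz: float | None = None
    precursor_type: str | None = None
    name: str = ""
    formula: MolecularFormula | None = None
    inchikey: str | None = None
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"spectrum {self.name!r} has no peaks")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError(f"spectrum {self.name!r} has negative intensity")
        self.peaks = sorted(self.peaks, key=lambda p: p[0])

    @property
    def structure_known(self) -> bool:
        return bool(self.inchikey)

    @property
    def mz(self) -> np.ndarray:
        return np.array([m for m, _ in self.peaks])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([i for _, i in self.peaks])


@dataclass
class Feature:
    """An aligned LC-HRMS feature with per-sample intensities."""

    feature_id: str
    mz: float
    rt: float  # minutes
    esi_mode: str  # "+" or "-"
    lc_mode: str  # "RP" or "HILIC"
    fraction: str  # "polar", "non-polar", "plasma"
    intensities: dict[str, float]
    ms2: Spectrum | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"feature {self.feature_id}: m/z must be positive")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id}: negative RT")
        if self.esi_mode not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: esi_mode must be '+' or '-'")


@dataclass
class CohortDesign:
    """Sample -> group assignment; groups include PD, Ctrl, QC, Blank."""

    groups: dict[str, str]

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @property
    def qc_samples(self) -> list[str]:
        return self.samples("QC")

    def validate_for_stats(self, group_a: str = "PD", group_b: str = "Ctrl") -> None:
        for g in (group_a, group_b):
            if len(self.samples(g)) < 3:
                raise ValueError(f"group {g!r} has < 3 samples; statistics not evaluable")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortDesign":
        df = pd.read_csv(path)
        return cls(dict(zip(df["sample_id"].astype(str), df["group"].astype(str))))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample_id": list(self.groups), "group": list(self.groups.values())}
        ).to_csv(path, index=False)


@dataclass
class SuspectEntry:
    """A candidate chemical from a screening list."""

    name: str
    formula: MolecularFormula | None
    neutral_mass: float
    inchikey: str | None = None
    list_code: str = ""

    def __post_init__(self) -> None:
        if self.formula is not None:
            calc = monoisotopic_mass(self.formula)
            if abs(self.neutral_mass - calc) > 0.001:
                raise ValueError(
                    f"suspect {self.name!r}: neutral_mass {self.neutral_mass} "
                    f"inconsistent with formula ({calc:.6f})"
                )


# ---------------------------------------------------------------------------
# MSP


_MSP_KNOWN_KEYS = {
    "name": "name",
    "precursormz": "precursor_mz",
    "precursortype": "precursor_type",
    "formula": "formula",
    "inchikey": "inchikey",
}


def read_msp(path: str | Path) -> list[Spectrum]:
    """Read a NIST-dialect MSP spectral library.

    Accepts both ``Num Peaks`` and ``NumPeaks``; peak lines split on any
    whitespace.  Unknown header keys are preserved in ``metadata``.  A
    record whose peak count disagrees with its ``Num Peaks`` header raises
    with the line number; an empty file returns an empty list with a
    warning.
    """
    lines = Path(path).read_text().splitlines()
    spectra: list[Spectrum] = []
    i = 0
    n = len(lines)
    while i < n:
        if not lines[i].strip():
            i += 1
            continue
        header: dict[str, str] = {}
        meta: dict[str, str] = {}
        num_peaks = None
        record_start = i + 1  # 1-based
        while i < n and lines[i].strip():
            line = lines[i]
            if ":" not in line:
                raise MSPFormatError(f"{path}: line {i + 1}: expected 'Key: value'")
            key, _, value = line.partition(":")
            key_norm = key.strip().lower().replace(" ", "")
            value = value.strip()
            if key_norm == "numpeaks":
                num_peaks = int(value)
                i += 1
                break
            if key_norm in _MSP_KNOWN_KEYS:
                header[_MSP_KNOWN_KEYS[key_norm]] = value
            else:
                meta[key.strip()] = value
            i += 1
        if num_peaks is None:
            raise MSPFormatError(f"{path}: record starting line {record_start} lacks Num Peaks")
        peaks: list[tuple[float, float]] = []
        while i < n and lines[i].strip():
            fields = lines[i].split()
            if len(fields) < 2:
                raise MSPFormatError(f"{path}: line {i + 1}: malformed peak line")
            peaks.append((float(fields[0]), float(fields[1])))
            i += 1
        if len(peaks) != num_peaks:
            raise MSPFormatError(
                f"{path}: record starting line {record_start}: "
                f"Num Peaks {num_peaks} but {len(peaks)} peak lines"
            )
        spectra.append(
            Spectrum(
                peaks=peaks,
                precursor_mz=float(header["precursor_mz"]) if "precursor_mz" in header else None,
                precursor_type=header.get("precursor_type"),
                name=header.get("name", ""),
                formula=parse_formula(header["formula"]) if header.get("formula") else None,
                inchikey=header.get("inchikey") or None,
                metadata=meta,
            )
        )
    if not spectra:
        warnings.warn(f"{path}: empty MSP file", stacklevel=2)
    return spectra


def write_msp(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra as NIST-dialect MSP (m/z to 4 decimals, byte-stable)."""
    out: list[str] = []
    for s in spectra:
        out.append(f"NAME: {s.name}")
        if s.precursor_mz is not None:
            out.append(f"PRECURSORMZ: {s.precursor_mz:.4f}")
        if s.precursor_type:
            out.append(f"PRECURSORTYPE: {s.precursor_type}")
        if s.formula is not None:
            out.append(f"FORMULA: {s.formula.hill()}")
        if s.inchikey:
            out.append(f"INCHIKEY: {s.inchikey}")
        for key in sorted(s.metadata):
            out.append(f"{key}: {s.metadata[key]}")
        out.append(f"Num Peaks: {len(s.peaks)}")
        for mz, inten in s.peaks:
            out.append(f"{mz:.4f} {inten:.4f}")
        out.append("")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# feature tables


FEATURE_FIXED_COLUMNS = ["feature_id", "mz", "rt", "esi_mode", "lc_mode", "fraction"]


def read_feature_table(path: str | Path, design: CohortDesign) -> list[Feature]:
    """Read an aligned feature/intensity CSV.

    Columns: the six fixed feature columns then one column per sample.
    Sample columns must all be present in the cohort design; samples in the
    design but absent from the table are filled with 0 and logged.
    """
    df = pd.read_csv(path, dtype={"feature_id": str})
    missing = [c for c in FEATURE_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    sample_cols = [c for c in df.columns if c not in FEATURE_FIXED_COLUMNS]
    orphans = [c for c in sample_cols if c not in design.groups]
    if orphans:
        raise ValueError(f"{path}: sample columns not in cohort design: {orphans}")
    if df["feature_id"].duplicated().any():
        dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
        raise ValueError(f"{path}: duplicated feature_id(s): {dups}")
    absent = [s for s in design.groups if s not in sample_cols]
    if absent:
        logger.warning("%s: samples missing from table, filled with 0: %s", path, absent)
    for col in sample_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"{path}: non-numeric intensity at row {row + 2}, column {col!r}")
        df[col] = vals
    features = []
    for _, row in df.iterrows():
        intens = {s: float(row[s]) for s in sample_cols}
        for s in absent:
            intens[s] = 0.0
        features.append(
            Feature(
                feature_id=str(row["feature_id"]),
                mz=float(row["mz"]),
                rt=float(row["rt"]),
                esi_mode=str(row["esi_mode"]),
                lc_mode=str(row["lc_mode"]),
                fraction=str(row["fraction"]),
                intensities=intens,
            )
        )
    return features


def write_feature_table(features: list[Feature], path: str | Path) -> None:
    sample_ids = sorted({s for f in features for s in f.intensities})
    rows = []
    for f in features:
        row = {
            "feature_id": f.feature_id,
            "mz": f.mz,
            "rt": f.rt,
            "esi_mode": f.esi_mode,
            "lc_mode": f.lc_mode,
            "fraction": f.fraction,
        }
        row.update({s: f.intensities.get(s, 0.0) for s in sample_ids})
        rows.append(row)
    pd.DataFrame(rows, columns=FEATURE_FIXED_COLUMNS + sample_ids).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# suspect lists


def read_suspect_list(path: str | Path, list_code: str) -> list[SuspectEntry]:
    """Read a suspect-list CSV (columns: name, formula, monoisotopic_mass,
    inchikey — at least name plus formula or mass required).

    Missing neutral mass is backfilled from the formula; rows lacking both
    are skipped with a counted warning.
    """
    df = pd.read_csv(path)
    if "name" not in df.columns:
        raise ValueError(f"{path}: suspect list needs a 'name' column")
    entries: list[SuspectEntry] = []
    skipped = 0
    for _, row in df.iterrows():
        formula_str = row.get("formula")
        mass = row.get("monoisotopic_mass")
        has_formula = isinstance(formula_str, str) and formula_str.strip()
        has_mass = pd.notna(mass)
        if not has_formula and not has_mass:
            skipped += 1
            continue
        formula = parse_formula(formula_str) if has_formula else None
        neutral_mass = float(mass) if has_mass else monoisotopic_mass(formula)
        inchikey = row.get("inchikey")
        entries.append(
            SuspectEntry(
                name=str(row["name"]),
                formula=formula,
                neutral_mass=neutral_mass,
                inchikey=str(inchikey) if isinstance(inchikey, str) and inchikey else None,
                list_code=list_code,
            )
        )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} row(s) lacking both formula and mass", stacklevel=2)
    return entries
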