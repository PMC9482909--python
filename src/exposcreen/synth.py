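"""Ground-truth synthetic cohort generator.

Stands in for an unreleased two-group LC-HRMS study: a PD-vs-control
cohort (default 10 vs 10) with pooled-QC replicates, log-normal feature
intensities with multiplicative group effects, mass errors of a few ppm,
designed MS/MS spectra, spectral libraries, suspect lists and pathway
definitions.  Every identification-confidence level of every rule scheme
is realized by at least three designed compounds, so the full pipeline can
be exercised end to end against known truth.

Design notes
------------
* MS/MS peak intensities are deterministic (equal-intensity peak sets), so
  library match scores land exactly in the score band each compound is
  designed for; "noise" peaks are placed on half-integer m/z values, which
  no small CHNO sub-formula can explain.
* QC intensities are affinely rescaled to hit each feature's target RSD
  exactly, so the QC filter outcome is part of the ground truth.
* InChIKeys are synthetic placeholders derived from the compound name —
  structurally valid in format, deliberately not registry keys.
* A handful of compounds carry the names, formulas, adducts and group
  effects of well-known PD-associated metabolites (valine, nicotinamide,
  choline, levodopa, cholic and glycocholic acid, ...), so end-to-end runs
  exercise realistic masses.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import ADDUCTS, ELECTRON_MASS, MONOISOTOPIC_MASS, adduct_mz, get_adduct, isotope_pattern, monoisotopic_mass, parse_formula
from .msdata import CohortDesign, Feature, Spectrum, write_feature_table, write_msp

__all__ = ["SynthConfig", "GroundTruthCompound", "generate_cohort", "ARCHETYPE_LEVELS"]


@dataclass
class SynthConfig:
    """Study conditions of the default synthetic cohort."""

    n_pd: int = 10
    n_ctrl: int = 10
    n_qc: int = 6
    n_features: int = 500
    n_spiked: int = 20
    spike_fc: float = 4.0
    noise_cv: float = 0.20  # log-normal coefficient of variation
    mass_ppm_sd: float = 1.0  # clipped at +-3 ppm
    qc_rsd: float = 0.10  # target QC RSD of well-behaved features
    n_bad_qc: int = 25
    bad_qc_rsd: float = 0.80  # deliberately fails the 50% filter
    tol_ppm: float = 5.0


#: expected confidence level per archetype and scheme — part of the ground truth
ARCHETYPE_LEVELS = {
    "lib_perfect": {"suspect_patroon": "2a", "nt_patroon": "2a", "nt_msdial": "2a"},
    "lib_perfect_nostruct": {"suspect_patroon": "2a", "nt_patroon": "2a", "nt_msdial": "2b"},
    "lib_good": {"suspect_patroon": "3a", "nt_patroon": "3a", "nt_msdial": "2a"},
    "lib_med": {"suspect_patroon": "3a", "nt_patroon": "3b", "nt_msdial": "3a"},
    "lib_few": {"suspect_patroon": "3a", "nt_patroon": "3a", "nt_msdial": "3b"},
    "lib_few_nostruct": {"suspect_patroon": "3a", "nt_patroon": "3a", "nt_msdial": "3c"},
    "lib_weak_many": {"suspect_patroon": "3b", "nt_patroon": "5", "nt_msdial": "4a"},
    "formula_ms2": {"suspect_patroon": "3c", "nt_patroon": "4a", "nt_msdial": "5"},
    "weak_lib_formula": {"suspect_patroon": "4a", "nt_patroon": "4a", "nt_msdial": "4a"},
    "iso_only": {"suspect_patroon": "4b", "nt_patroon": "5", "nt_msdial": "5"},
    "unknown": {"suspect_patroon": "5", "nt_patroon": "5", "nt_msdial": "5"},
}

# spectral design per archetype:
# (total query peaks, reference peaks shared with query, extra reference-only
#  peaks, in library?, structure known?, explainable query peaks?, isotope
#  sidecar?, has MS2?)
_ARCHETYPE_SPEC = {
    "lib_perfect": (6, 6, 0, True, True, False, False, True),
    "lib_perfect_nostruct": (6, 6, 0, True, False, False, False, True),
    "lib_good": (25, 16, 0, True, True, False, False, True),
    "lib_med": (25, 9, 0, True, True, False, False, True),
    "lib_few": (4, 2, 0, True, True, False, False, True),
    "lib_few_nostruct": (4, 2, 0, True, False, False, False, True),
    "lib_weak_many": (26, 4, 0, True, True, False, False, True),
    "formula_ms2": (6, 0, 0, False, False, True, True, True),
    "weak_lib_formula": (16, 3, 1, True, True, True, True, True),
    "iso_only": (0, 0, 0, False, False, False, True, False),
    "unknown": (0, 0, 0, False, False, False, False, False),
}


@dataclass
class GroundTruthCompound:
    name: str
    formula: str
    adduct: str
    esi_mode: str
    lc_mode: str
    fraction: str
    true_fc: float
    archetype: str
    suspect_lists: list[str]
    feature_id: str = ""
    theoretical_mz: float = 0.0
    measured_mz: float = 0.0
    inchikey: str | None = None
    expected_levels: dict[str, str] = field(default_factory=dict)

    @property
    def in_library(self) -> bool:
        return _ARCHETYPE_SPEC[self.archetype][3]

    @property
    def structure_known(self) -> bool:
        return _ARCHETYPE_SPEC[self.archetype][4]


def _compound_designs() -> list[GroundTruthCompound]:
    """The designed compound panel: real PD-associated metabolites plus
    synthetic compounds filling every archetype to >= 3 members."""

    def c(name, formula, adduct, esi, lc, frac, fc, arch, lists):
        return GroundTruthCompound(name, formula, adduct, esi, lc, frac, fc, arch, lists)

    return [
        # named metabolites with literature-scale group effects
        c("L-Valine", "C5H11NO2", "[M+H]+", "+", "RP", "polar", 2.2627, "lib_perfect", ["PD-CTD", "LITMIN"]),
        c("Nicotinamide", "C6H6N2O", "[M+H]+", "+", "HILIC", "polar", 0.2333, "lib_perfect", ["LITMIN", "PD-CTD", "D003863"]),
        c("Choline", "C5H14NO", "[M]+", "+", "RP", "polar", 2.0994, "lib_perfect", ["LITMIN"]),
        c("Alanine betaine", "C6H13NO2", "[M+H]+", "+", "HILIC", "polar", 0.2875, "lib_perfect", ["LITMIN"]),
        c("Isonicotinic acid", "C6H5NO2", "[M+H]+", "+", "RP", "non-polar", 2.8013, "lib_perfect", ["PD-CTD"]),
        c("Levodopa", "C9H11NO4", "[M+H]+", "+", "RP", "plasma", 9.8904, "lib_perfect", ["PD-CTD"]),
        c("Glycocholic acid", "C26H43NO6", "[M-H]-", "-", "RP", "plasma", 1.0, "lib_perfect", ["LITMIN"]),
        c("Cholic acid", "C24H40O5", "[M-H]-", "-", "RP", "plasma", 1.0, "lib_few", ["LITMIN"]),
        c("3-HPPA", "C9H10O3", "[M-H]-", "-", "RP", "non-polar", 0.1459, "lib_good", ["LITMIN", "D003863"]),
        # synthetic archetype fillers
        c("Syntholide A", "C7H13NO2", "[M+H]+", "+", "RP", "polar", 1.0, "lib_perfect_nostruct", ["LITMIN"]),
        c("Syntholide B", "C5H9NO4", "[M+H]+", "+", "HILIC", "polar", 1.0, "lib_perfect_nostruct", ["PD-CTD"]),
        c("Syntholide C", "C8H9NO2", "[M+H]+", "+", "RP", "polar", 1.0, "lib_perfect_nostruct", ["LITMIN"]),
        c("Goodamine A", "C8H11NO2", "[M+H]+", "+", "RP", "polar", 1.0, "lib_good", ["LITMIN"]),
        c("Goodamine B", "C10H13NO3", "[M+H]+", "+", "HILIC", "polar", 1.0, "lib_good", ["LITMIN"]),
        c("Medanol A", "C7H7NO2", "[M+H]+", "+", "RP", "polar", 1.0, "lib_med", ["LITMIN", "D003863"]),
        c("Medanol B", "C9H13NO2", "[M+H]+", "+", "RP", "non-polar", 1.0, "lib_med", ["LITMIN"]),
        c("Medanol C", "C11H12N2O2", "[M+H]+", "+", "HILIC", "polar", 1.0, "lib_med", ["LITMIN"]),
        c("Fewanone A", "C10H12N2O", "[M+H]+", "+", "RP", "polar", 1.0, "lib_few", ["LITMIN", "D020920"]),
        c("Fewanone B", "C12H16N2O2", "[M+H]+", "+", "RP", "polar", 1.0, "lib_few", ["LITMIN"]),
        c("Fewanox A", "C9H9NO3", "[M+H]+", "+", "RP", "polar", 1.0, "lib_few_nostruct", ["LITMIN"]),
        c("Fewanox B", "C10H11NO4", "[M+H]+", "+", "HILIC", "polar", 1.0, "lib_few_nostruct", ["LITMIN"]),
        c("Fewanox C", "C7H9N3O", "[M+H]+", "+", "RP", "polar", 1.0, "lib_few_nostruct", ["LITMIN"]),
        c("Weakanol A", "C15H21NO4", "[M+H]+", "+", "RP", "non-polar", 1.0, "lib_weak_many", ["LITMIN"]),
        c("Weakanol B", "C14H22N2O3", "[M+H]+", "+", "RP", "polar", 1.0, "lib_weak_many", ["LITMIN"]),
        c("Weakanol C", "C16H22O4", "[M+H]+", "+", "HILIC", "polar", 1.0, "lib_weak_many", ["LITMIN"]),
        c("Formulin A", "C8H15N3O2", "[M+H]+", "+", "RP", "polar", 1.0, "formula_ms2", ["PD-CTD"]),
        c("Formulin B", "C10H14N2O2", "[M+H]+", "+", "RP", "polar", 1.0, "formula_ms2", ["PD-CTD"]),
        c("Formulin C", "C7H8N4O2", "[M+H]+", "+", "HILIC", "polar", 1.0, "formula_ms2", ["PD-CTD"]),
        c("Weakform A", "C9H13N3O", "[M+H]+", "+", "RP", "polar", 1.0, "weak_lib_formula", ["LITMIN"]),
        c("Weakform B", "C11H16N2O3", "[M+H]+", "+", "RP", "polar", 1.0, "weak_lib_formula", ["LITMIN"]),
        c("Weakform C", "C8H10N2O3", "[M+H]+", "+", "HILIC", "polar", 1.0, "weak_lib_formula", ["LITMIN"]),
        c("Isotopin A", "C9H14N4O", "[M+H]+", "+", "RP", "polar", 1.0, "iso_only", ["LITMIN"]),
        c("Isotopin B", "C12H20N2O3", "[M+H]+", "+", "RP", "polar", 1.0, "iso_only", ["LITMIN", "D020920"]),
        c("Isotopin C", "C8H12N2O4", "[M+H]+", "+", "HILIC", "polar", 1.0, "iso_only", ["LITMIN"]),
        c("Umbrin A", "C13H22O3", "[M+H]+", "+", "RP", "polar", 1.0, "unknown", ["PD-CTD", "D003863"]),
        c("Umbrin B", "C11H18O5", "[M+H]+", "+", "RP", "non-polar", 1.0, "unknown", ["LITMIN"]),
        c("Umbrin C", "C10H17NO5", "[M+H]+", "+", "HILIC", "polar", 1.0, "unknown", ["LITMIN"]),
    ]


def _synthetic_inchikey(name: str) -> str:
    """Deterministic placeholder InChIKey (valid format, not a registry key)."""
    digest = hashlib.sha256(name.encode()).hexdigest().upper()
    letters = "".join(chr(ord("A") + int(ch, 16) % 26) for ch in digest)
    return f"{letters[:14]}-{letters[14:24]}-N"


# neutral losses used to build sub-formula-explainable fragment peaks
_LOSSES = ["H2O", "NH3", "CO", "CH2O", "CO2", "C2H4", "CH4", "H2", "C2H2", "CH2O2", "C2H4O", "C3H6"]


def _explainable_fragment_mzs(formula_str: str, k: int, polarity: str) -> list[float]:
    """m/z of k distinct sub-formula fragment ions (single and paired
    neutral losses from the precursor formula)."""
    counts = parse_formula(formula_str).counts()
    e_corr = -ELECTRON_MASS if polarity == "+" else ELECTRON_MASS
    losses = [parse_formula(s).counts() for s in _LOSSES]
    combos = [l for l in losses]
    for i in range(len(losses)):
        for j in range(i, len(losses)):
            combos.append({el: losses[i].get(el, 0) + losses[j].get(el, 0) for el in set(losses[i]) | set(losses[j])})
    mzs: list[float] = []
    for loss in combos:
        frag = {el: counts.get(el, 0) - loss.get(el, 0) for el in counts}
        if any(v < 0 for v in frag.values()) or frag.get("C", 0) < 1:
            continue
        mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in frag.items() if n > 0)
        if mass < 45:
            continue
        mz = mass + e_corr
        if all(abs(mz - m) > 0.05 for m in mzs):
            mzs.append(mz)
        if len(mzs) == k:
            break
    if len(mzs) < k:
        raise ValueError(f"cannot design {k} explainable fragments for {formula_str}")
    return sorted(mzs)


def _noise_mzs(precursor: float, k: int) -> list[float]:
    """Half-integer m/z values no small CHNO sub-formula can explain."""
    out = []
    m = math.floor(precursor) - 10.5
    while len(out) < k:
        if m < 45:
            raise ValueError("precursor too small for requested noise peaks")
        out.append(float(m))
        m -= 1.0
    return sorted(out)


def _design_spectra(comp: GroundTruthCompound, theo_mz: float) -> tuple[Spectrum | None, Spectrum | None]:
    """(query MS/MS attached to the feature, reference library spectrum)."""
    n_q, n_shared, n_ref_extra, in_lib, struct, explain, _iso, has_ms2 = _ARCHETYPE_SPEC[comp.archetype]
    if not has_ms2:
        return None, None
    if explain:
        signal = _explainable_fragment_mzs(comp.formula, n_q, comp.esi_mode)
        query_mzs = signal
        shared = signal[:n_shared]
    else:
        grid = _noise_mzs(theo_mz, n_q)
        query_mzs = grid
        shared = grid[:n_shared]
    query = Spectrum(
        peaks=[(m, 100.0) for m in query_mzs],
        precursor_mz=theo_mz,
        precursor_type=comp.adduct,
        name=comp.name,
    )
    reference = None
    if in_lib:
        ref_mzs = list(shared)
        for j in range(n_ref_extra):
            ref_mzs.append(math.floor(theo_mz) - 3.5 - 7.0 * j)
        reference = Spectrum(
            peaks=[(m, 100.0) for m in sorted(ref_mzs)],
            precursor_mz=theo_mz,
            precursor_type=comp.adduct,
            name=comp.name,
            formula=parse_formula(comp.formula),
            inchikey=_synthetic_inchikey(comp.name) if struct else None,
        )
    return query, reference


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def _rescale_to_rsd(values: np.ndarray, target_rsd: float) -> np.ndarray:
    """Affine rescale so the sample RSD equals the target exactly (clipped
    at a small positive floor, which can only lower the realized RSD)."""
    m = values.mean()
    s = values.std(ddof=1)
    if s == 0:
        return values
    out = m + (values - m) * (target_rsd * m / s)
    return np.clip(out, 1.0, None)


def _decoy_suspects(rng: np.random.Generator, n: int, feature_mzs: list[float], tol_ppm: float) -> list[dict]:
    """Plausible CHNO suspect entries whose adduct m/z hit no feature."""
    out = []
    adducts = list(ADDUCTS.values())
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n:
            raise ValueError("cannot place decoy suspects away from features")
        cc = int(rng.integers(4, 25))
        hh = int(rng.integers(max(4, cc // 2), min(2 * cc + 2, 50)))
        nn = int(rng.integers(0, 4))
        oo = int(rng.integers(0, 8))
        if (2 + 2 * cc - hh + nn) % 2 != 0 or (2 + 2 * cc - hh + nn) < 0:
            continue
        formula = f"C{cc}H{hh}" + (f"N{nn}" if nn else "") + (f"O{oo}" if oo else "")
        mass = monoisotopic_mass(formula)
        if not 80 < mass < 880:
            continue
        clash = any(
            abs(1e6 * (fmz - adduct_mz(parse_formula(formula), ad)) / fmz) < 4 * tol_ppm
            for ad in adducts
            for fmz in feature_mzs
        )
        if clash:
            continue
        name = f"Decoy {len(out) + 1:03d}"
        out.append({"name": name, "formula": formula, "monoisotopic_mass": round(mass, 6), "inchikey": _synthetic_inchikey(name)})
    return out


_PATHWAYS = {
    "PW_amino_acids": ["L-Valine", "Levodopa", "Alanine betaine", "Medanol A", "Goodamine A"],
    "PW_nicotinate": ["Nicotinamide", "Isonicotinic acid", "Fewanone A"],
    "PW_bile_acids": ["Cholic acid", "Glycocholic acid", "Umbrin B"],
    "PW_choline": ["Choline", "Syntholide A", "Weakanol A"],
    "PW_background_1": ["Goodamine B", "Medanol B", "Fewanox A", "Isotopin C"],
    "PW_background_2": ["Formulin A", "Formulin B", "Weakform B", "Umbrin C"],
}


def generate_cohort(config: SynthConfig, seed: int, outdir: str | Path) -> dict:
    """Generate the full synthetic study under ``outdir``.

    Writes: design.csv, feature_table.csv, ms2.msp (feature spectra, keyed
    by feature id), library_pos.msp / library_neg.msp, suspect_<CODE>.csv,
    pathways.csv, isotopes.csv (observed envelope sidecar),
    ground_truth.json and MANIFEST.json.  Deterministic given (config,
    seed).  Returns the ground-truth dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    compounds = _compound_designs()
    n_named = len(compounds)
    if config.n_spiked + n_named + config.n_bad_qc > config.n_features:
        raise ValueError(
            f"infeasible config: {config.n_spiked} spiked + {n_named} designed "
            f"+ {config.n_bad_qc} bad-QC features exceed n_features={config.n_features}"
        )

    samples = (
        [f"PD{i + 1:02d}" for i in range(config.n_pd)]
        + [f"C{i + 1:02d}" for i in range(config.n_ctrl)]
        + [f"QC{i + 1:02d}" for i in range(config.n_qc)]
    )
    design = CohortDesign(
        {s: ("PD" if s.startswith("PD") else "QC" if s.startswith("QC") else "Ctrl") for s in samples}
    )

    # --- assemble the feature panel ---------------------------------------
    # named compounds first, then spiked, then filler (bad-QC flagged last)
    rows: list[dict] = []  # per-feature truth
    for comp in compounds:
        comp.theoretical_mz = adduct_mz(parse_formula(comp.formula), comp.adduct)
        comp.inchikey = _synthetic_inchikey(comp.name) if comp.structure_known else None
        comp.expected_levels = dict(ARCHETYPE_LEVELS[comp.archetype])

    named_mzs = [c.theoretical_mz for c in compounds]
    for i, c1 in enumerate(named_mzs):
        for c2 in named_mzs[i + 1 :]:
            if abs(1e6 * (c1 - c2) / c1) < 3 * config.tol_ppm:
                raise ValueError("designed compound m/z too close; panel invalid")

    n_filler = config.n_features - n_named - config.n_spiked
    filler_mzs: list[float] = []
    while len(filler_mzs) < n_filler + config.n_spiked:
        m = float(rng.uniform(60.0, 900.0))
        if all(abs(1e6 * (m - t) / t) > 4 * config.tol_ppm for t in named_mzs):
            filler_mzs.append(m)
    spiked_mzs = filler_mzs[:config.n_spiked]
    filler_mzs = filler_mzs[config.n_spiked:]

    sigma = _lognormal_sigma(config.noise_cv)
    feat_idx = 0
    features: list[Feature] = []
    ms2_records: list[Spectrum] = []
    lib_pos: list[Spectrum] = []
    lib_neg: list[Spectrum] = []
    iso_rows: list[dict] = []
    truth_features: list[dict] = []

    def next_id() -> str:
        nonlocal feat_idx
        feat_idx += 1
        return f"F{feat_idx:04d}"

    def intensities(baseline: float, fc: float, qc_rsd: float) -> dict[str, float]:
        pd_vals = baseline * fc * np.exp(sigma * rng.standard_normal(config.n_pd))
        ctrl_vals = baseline * np.exp(sigma * rng.standard_normal(config.n_ctrl))
        pooled = float(np.concatenate([pd_vals, ctrl_vals]).mean())
        qc_vals = pooled * np.exp(_lognormal_sigma(qc_rsd) * rng.standard_normal(config.n_qc))
        qc_vals = _rescale_to_rsd(qc_vals, qc_rsd)
        vals = np.concatenate([pd_vals, ctrl_vals, qc_vals])
        return {s: float(v) for s, v in zip(samples, vals)}

    for comp in compounds:
        fid = next_id()
        comp.feature_id = fid
        ppm_err = float(np.clip(rng.normal(0.0, config.mass_ppm_sd), -3.0, 3.0))
        mz = comp.theoretical_mz * (1 + ppm_err * 1e-6)
        comp.measured_mz = mz
        baseline = 10 ** rng.uniform(5.5, 6.5)
        feat = Feature(
            feature_id=fid,
            mz=mz,
            rt=round(float(rng.uniform(1.0, 20.0)), 2),
            esi_mode=comp.esi_mode,
            lc_mode=comp.lc_mode,
            fraction=comp.fraction,
            intensities=intensities(baseline, comp.true_fc, config.qc_rsd),
        )
        features.append(feat)
        query, reference = _design_spectra(comp, comp.theoretical_mz)
        if query is not None:
            q = Spectrum(
                peaks=query.peaks,
                precursor_mz=mz,
                precursor_type=comp.adduct,
                name=fid,  # keyed by feature id for re-attachment
                metadata={"COMPOUND": comp.name},
            )
            ms2_records.append(q)
        if reference is not None:
            (lib_pos if comp.esi_mode == "+" else lib_neg).append(reference)
        if _ARCHETYPE_SPEC[comp.archetype][6]:  # isotope sidecar
            pat = isotope_pattern(parse_formula(comp.formula), max_peaks=3)
            obs = pat.abundances.copy()
            if len(obs) > 1:
                obs[1] = min(1.0, obs[1] + 0.002)  # small instrumental bias
            iso_rows.append({"feature_id": fid, "abundances": ";".join(f"{a:.5f}" for a in obs)})
        truth_features.append({"feature_id": fid, "kind": "compound", "name": comp.name, "true_fc": comp.true_fc})

    for m in spiked_mzs:
        fid = next_id()
        baseline = 10 ** rng.uniform(5.5, 6.5)
        features.append(
            Feature(fid, m, round(float(rng.uniform(1.0, 20.0)), 2), "+", "RP", "polar",
                    intensities(baseline, config.spike_fc, config.qc_rsd))
        )
        truth_features.append({"feature_id": fid, "kind": "spiked", "name": None, "true_fc": config.spike_fc})

    for j, m in enumerate(filler_mzs):
        fid = next_id()
        bad = j < config.n_bad_qc
        baseline = 10 ** rng.uniform(5.5, 6.5)
        features.append(
            Feature(fid, m, round(float(rng.uniform(1.0, 20.0)), 2), "+", "RP", "polar",
                    intensities(baseline, 1.0, config.bad_qc_rsd if bad else config.qc_rsd))
        )
        truth_features.append(
            {"feature_id": fid, "kind": "bad_qc" if bad else "null", "name": None, "true_fc": 1.0}
        )

    # --- suspect lists -----------------------------------------------------
    feature_mzs = [f.mz for f in features]
    list_rows: dict[str, list[dict]] = {"PD-CTD": [], "LITMIN": [], "D003863": [], "D020920": []}
    for comp in compounds:
        for code in comp.suspect_lists:
            list_rows[code].append(
                {
                    "name": comp.name,
                    "formula": comp.formula,
                    "monoisotopic_mass": round(monoisotopic_mass(parse_formula(comp.formula)), 6),
                    "inchikey": _synthetic_inchikey(comp.name),
                }
            )
    decoys = _decoy_suspects(rng, 120, feature_mzs, config.tol_ppm)
    list_rows["LITMIN"].extend(decoys[:30])
    list_rows["PD-CTD"].extend(decoys[30:45])
    list_rows["D003863"].extend(decoys[45:53])
    list_rows["D020920"].extend(decoys[53:53 + (59 - len(list_rows["D020920"]))])

    # --- decoy library entries (precursors away from every feature) --------
    for d in decoys[:5]:
        f = parse_formula(d["formula"])
        mz = adduct_mz(f, "[M+H]+")
        lib_pos.append(
            Spectrum(
                peaks=[(m, 100.0) for m in _noise_mzs(mz, 5)],
                precursor_mz=mz,
                precursor_type="[M+H]+",
                name=d["name"],
                formula=f,
                inchikey=d["inchikey"],
            )
        )

    # --- write everything --------------------------------------------------
    design.to_csv(outdir / "design.csv")
    write_feature_table(features, outdir / "feature_table.csv")
    write_msp(ms2_records, outdir / "ms2.msp")
    write_msp(lib_pos, outdir / "library_pos.msp")
    write_msp(lib_neg, outdir / "library_neg.msp")
    for code, entries in list_rows.items():
        pd.DataFrame(entries).to_csv(outdir / f"suspects_{code}.csv", index=False)
    pd.DataFrame(
        [(pid, m) for pid, members in _PATHWAYS.items() for m in members],
        columns=["pathway_id", "member"],
    ).to_csv(outdir / "pathways.csv", index=False)
    pd.DataFrame(iso_rows, columns=["feature_id", "abundances"]).to_csv(
        outdir / "isotopes.csv", index=False
    )

    truth = {
        "seed": seed,
        "config": asdict(config),
        "compounds": [asdict(c) for c in compounds],
        "features": truth_features,
        "archetype_levels": ARCHETYPE_LEVELS,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))

    manifest = {}
    for p in sorted(outdir.iterdir()):
        if p.name == "MANIFEST.json":
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return truth
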