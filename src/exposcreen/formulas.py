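"""Molecular formula annotation for feature masses.

Candidate formulas are enumerated within element bounds and a ppm window
(depth-first with mass pruning), filtered by chemical plausibility rules
(integer ring-double-bond equivalents >= 0, H/C ratio bounds), then scored:

* ``iso_score`` — agreement between an observed isotope envelope and the
  candidate's theoretical one, 1 minus the mean absolute abundance
  deviation over the aligned A..A+k peaks;
* ``ann_sim_form`` / ``ann_sim_comp`` — how much of the feature's MS/MS is
  explainable as sub-formula fragments of the candidate (with +-1 H
  latitude), expressed as the cosine between the spectrum and its
  explainable sub-spectrum.

Candidates are ranked by iso score, then |ppm error|, then MS/MS
consistency, with gap-to-next-candidate values exposed for the confidence
rules that test "0.2 higher than the next candidate".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .chem import (
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    IsotopePattern,
    MolecularFormula,
    monoisotopic_mass,
)
from .msdata import Spectrum
from .spectral import dot_product_score

__all__ = [
    "FormulaCandidate",
    "DEFAULT_ELEMENT_BOUNDS",
    "enumerate_formulas",
    "iso_score",
    "ann_sim",
    "rank_candidates",
]

#: defaults sized for a small-molecule scan range of m/z 60-900
DEFAULT_ELEMENT_BOUNDS = {"C": 40, "H": 80, "N": 6, "O": 12, "S": 3, "P": 2, "Cl": 3, "F": 6}

#: valence bookkeeping for ring-double-bond equivalents
_MONOVALENT = ("H", "F", "Cl", "Br", "I", "Na", "K")
_TRIVALENT = ("N", "P")

_MAX_EXPLORED = 1_000_000


@dataclass(frozen=True)
class FormulaCandidate:
    formula: MolecularFormula
    ppm_error: float
    iso_score: float | None = None
    ann_sim_form: float | None = None
    ann_sim_comp: float | None = None
    rank: int = 0
    gap_iso: float = math.inf
    gap_ann: float = math.inf


def rdbe_twice(counts: dict[str, int]) -> int:
    """2x ring-double-bond equivalents (integer arithmetic)."""
    c = counts.get("C", 0)
    mono = sum(counts.get(el, 0) for el in _MONOVALENT)
    tri = sum(counts.get(el, 0) for el in _TRIVALENT)
    return 2 + 2 * c - mono + tri


def passes_rules(counts: dict[str, int], hc_min: float = 0.1, hc_max: float = 3.5) -> bool:
    """Chemical plausibility: integer RDBE >= 0; H/C within bounds when both
    carbon and hydrogen are present (a bare carbon cluster is admitted)."""
    r2 = rdbe_twice(counts)
    if r2 < 0 or r2 % 2 != 0:
        return False
    c, h = counts.get("C", 0), counts.get("H", 0)
    if c > 0 and h > 0:
        ratio = h / c
        if ratio < hc_min or ratio > hc_max:
            return False
    return True


def enumerate_formulas(
    neutral_mass: float,
    tol_ppm: float = 5.0,
    element_bounds: dict[str, int] | None = None,
    hc_min: float = 0.1,
    hc_max: float = 3.5,
) -> list[MolecularFormula]:
    """All plausible formulas whose monoisotopic mass falls within
    ``tol_ppm`` of ``neutral_mass``.

    Depth-first search over element counts (heaviest elements first) with
    mass-window pruning; aborts if more than 10^6 combinations would be
    explored, instructing tighter bounds.  Results are sorted by |ppm
    error| then Hill string.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    bounds = dict(element_bounds or DEFAULT_ELEMENT_BOUNDS)
    lo = neutral_mass * (1 - tol_ppm * 1e-6)
    hi = neutral_mass * (1 + tol_ppm * 1e-6)
    elements = sorted(bounds, key=lambda el: -MONOISOTOPIC_MASS[el])
    caps = [min(bounds[el], int(hi / MONOISOTOPIC_MASS[el])) for el in elements]
    # max mass attainable from elements[i:]
    tail_max = [0.0] * (len(elements) + 1)
    for i in range(len(elements) - 1, -1, -1):
        tail_max[i] = tail_max[i + 1] + caps[i] * MONOISOTOPIC_MASS[elements[i]]

    out: list[MolecularFormula] = []
    explored = 0

    def recurse(i: int, mass: float, counts: dict[str, int]) -> None:
        nonlocal explored
        explored += 1
        if explored > _MAX_EXPLORED:
            raise ValueError(
                "formula enumeration exceeded 10^6 combinations; tighten element bounds"
            )
        if i == len(elements):
            if lo <= mass <= hi and any(counts.values()) and passes_rules(counts, hc_min, hc_max):
                out.append(MolecularFormula.from_counts(dict(counts)))
            return
        el = elements[i]
        el_mass = MONOISOTOPIC_MASS[el]
        for n in range(caps[i] + 1):
            m = mass + n * el_mass
            if m > hi:
                break
            if m + tail_max[i + 1] < lo:
                continue
            counts[el] = n
            recurse(i + 1, m, counts)
        counts[el] = 0

    recurse(0, 0.0, {el: 0 for el in elements})
    out.sort(key=lambda f: (abs(monoisotopic_mass(f) - neutral_mass), f.hill()))
    return out


def iso_score(observed: IsotopePattern, theoretical: IsotopePattern) -> float:
    """1 minus the mean absolute abundance deviation over the aligned
    A..A+k peaks (k = shorter pattern length), clipped to [0, 1]."""
    a = observed.abundances
    b = theoretical.abundances
    k = min(len(a), len(b))
    if k == 0:
        raise ValueError("empty isotope pattern")
    score = 1.0 - float(np.mean(np.abs(a[:k] - b[:k])))
    return min(1.0, max(0.0, score))


def _subformula_masses(candidate: MolecularFormula, max_mass: float) -> np.ndarray:
    """Sorted monoisotopic masses of every elementwise sub-formula of the
    candidate, pruned above ``max_mass``."""
    arr = np.array([0.0])
    for el, n in candidate.element_counts:
        steps = MONOISOTOPIC_MASS[el] * np.arange(n + 1)
        arr = (arr[:, None] + steps[None, :]).ravel()
        arr = np.unique(np.round(arr, 7))
        arr = arr[arr <= max_mass]
    return arr


def ann_sim(
    query_ms2: Spectrum,
    candidate: MolecularFormula,
    tol_mz: float = 0.01,
    library_dot: float | None = None,
    polarity: str = "+",
) -> tuple[float, float]:
    """MS/MS consistency of a spectrum with a candidate formula.

    A peak is explainable if some sub-formula of the candidate (elementwise
    <= the candidate counts, +-1 H latitude — covering both even-electron
    fragment ions and candidate-minus-neutral-loss readings) matches its
    m/z within ``tol_mz`` after electron-mass correction.  ``ann_sim_form``
    is the cosine between the spectrum and its explainable sub-spectrum;
    ``ann_sim_comp`` additionally caps it by structure-level library
    evidence (normalized dot product) when available.
    """
    if not query_ms2.peaks:
        raise ValueError("query spectrum has no peaks")
    e_corr = -ELECTRON_MASS if polarity == "+" else ELECTRON_MASS
    h = MONOISOTOPIC_MASS["H"]
    max_mass = float(query_ms2.mz.max()) + h + tol_mz + 1.0
    masses = _subformula_masses(candidate, max_mass)
    explained: list[tuple[float, float]] = []
    for mz, inten in query_ms2.peaks:
        ok = False
        for dh in (-1, 0, 1):
            target = mz - dh * h - e_corr
            idx = np.searchsorted(masses, target)
            for j in (idx - 1, idx):
                if 0 <= j < len(masses) and abs(masses[j] - target) <= tol_mz:
                    ok = True
                    break
            if ok:
                break
        if ok:
            explained.append((mz, inten))
    if not explained:
        return 0.0, 0.0
    sub = Spectrum(peaks=explained, name="annotated")
    form = dot_product_score(query_ms2, sub, tol_mz) / 100.0
    comp = form if library_dot is None else min(form, library_dot)
    return form, comp


def rank_candidates(candidates: list[FormulaCandidate]) -> list[FormulaCandidate]:
    """Total-order ranking of formula candidates with gap-to-next values.

    Sort: iso score descending (absent treated as 0), |ppm| ascending,
    ann_sim_form descending; ties broken by Hill string.  ``gap_iso`` /
    ``gap_ann`` on each candidate measure its lead over the next-ranked
    one (+inf past the end).
    """
    if not candidates:
        raise ValueError("no candidates to rank")

    def key(c: FormulaCandidate):
        return (
            -(c.iso_score if c.iso_score is not None else 0.0),
            abs(c.ppm_error),
            -(c.ann_sim_form if c.ann_sim_form is not None else 0.0),
            c.formula.hill(),
        )

    ordered = sorted(candidates, key=key)
    ranked: list[FormulaCandidate] = []
    for i, c in enumerate(ordered):
        if i + 1 < len(ordered):
            nxt = ordered[i + 1]
            gap_iso = (c.iso_score or 0.0) - (nxt.iso_score or 0.0)
            gap_ann = (c.ann_sim_form or 0.0) - (nxt.ann_sim_form or 0.0)
        else:
            gap_iso = math.inf
            gap_ann = math.inf
        ranked.append(replace(c, rank=i + 1, gap_iso=gap_iso, gap_ann=gap_ann))
    return ranked
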