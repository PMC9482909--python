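"""MS/MS spectral library search.

Produces the spectral evidence consumed by the confidence rules: a
square-root-weighted cosine ("dot product", 0-100), fragment presence
(fraction of reference fragments recovered, 0-100), the matched-fragment
count, and a normalized library score in [0, 1] standing in for
MassBank-of-North-America match scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .chem import ppm_error
from .msdata import Feature, Spectrum

__all__ = [
    "SpectralMatch",
    "match_peaks",
    "dot_product_score",
    "fragment_presence",
    "library_search",
]



@dataclass(frozen=True)
class SpectralMatch:
    query_feature_id: str
    library_name: str
    dot_product: float  # 0-100
    fragment_presence: float  # percent 0-100
    n_matched_fragments: int
    library_score: float  # 0-1
    candidate_rank: int  # 1-based
    structure_known: bool
    precursor_ppm: float
    library_index: int
    inchikey: str | None = None


def match_peaks(
    query: Spectrum,
    reference: Spectrum,
    tol_mz: float = 0.01,
) -> list[tuple[int, int]]:
    """Optimal one-to-one peak pairing within an absolute m/z tolerance.

    Returns (query index, reference index) pairs maximizing the number of
    matches and, among maximal pairings, minimizing the total |dmz|.  Each
    peak is used at most once.
    """
    if tol_mz <= 0:
        raise ValueError("tol_mz must be positive")
    qmz, rmz = query.mz, reference.mz
    d = np.abs(qmz[:, None] - rmz[None, :])
    # Costs are kept near unit magnitude so the tie-break term survives
    # floating-point summation: allowed pairs cost d/tol in [0, 1], minus an
    # epsilon intensity-product term (symmetric under operand swap) that
    # resolves equal-|dmz| ties; disallowed pairs cost more than any full
    # assignment of allowed ones, so cardinality is maximized first.
    wq = np.sqrt(query.intensities)
    wr = np.sqrt(reference.intensities)
    prod = np.outer(wq, wr)
    tie = prod / prod.max() if prod.max() > 0 else prod
    forbidden = d.shape[0] + d.shape[1] + 1.0
    cost = np.where(d <= tol_mz, d / tol_mz - 1e-9 * tie, forbidden)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if d[i, j] <= tol_mz]
    pairs.sort()
    return pairs


def _weighted(intensities: np.ndarray) -> np.ndarray:
    # sqrt weighting tempers dominant base peaks (common metabolomics choice)
    return np.sqrt(np.asarray(intensities, dtype=float))


def dot_product_score(query: Spectrum, reference: Spectrum, tol_mz: float = 0.01) -> float:
    """Cosine similarity of sqrt-scaled intensity vectors, scaled to 0-100.

    Vectors live on the union of matched and unmatched peak slots, so
    unshared peaks in either spectrum dilute the score.  Scale-invariant
    and symmetric.
    """
    pairs = match_peaks(query, reference, tol_mz)
    q = _weighted(query.intensities)
    r = _weighted(reference.intensities)
    num = sum(q[i] * r[j] for i, j in pairs)
    denom = np.linalg.norm(q) * np.linalg.norm(r)
    if denom == 0:
        return 0.0
    return float(100.0 * num / denom)


def fragment_presence(
    query: Spectrum,
    reference: Spectrum,
    tol_mz: float = 0.01,
    rel_int_floor: float = 0.01,
) -> float:
    """Percent of reference fragments (above a relative-intensity floor)
    recovered in the query."""
    r = reference.intensities
    floor = rel_int_floor * r.max()
    considered = {j for j in range(len(r)) if r[j] >= floor}
    if not considered:
        raise ValueError("reference has no peaks above the intensity floor")
    pairs = match_peaks(query, reference, tol_mz)
    matched = {j for _, j in pairs if j in considered}
    return 100.0 * len(matched) / len(considered)


def n_matched_fragments(
    query: Spectrum,
    reference: Spectrum,
    tol_mz: float = 0.01,
    rel_int_floor: float = 0.01,
) -> int:
    """Matched reference fragments with relative intensity >= the floor.

    The floor keeps the ">= 3 ion fragments matching" rule from being
    satisfiable by noise peaks.
    """
    r = reference.intensities
    floor = rel_int_floor * r.max()
    pairs = match_peaks(query, reference, tol_mz)
    return sum(1 for _, j in pairs if r[j] >= floor)


def library_search(
    feature: Feature,
    library: list[Spectrum],
    ms1_tol_ppm: float = 5.0,
    ms2_tol_mz: float = 0.01,
    rel_int_floor: float = 0.01,
) -> list[SpectralMatch]:
    """Score a feature's MS/MS against library spectra with matching precursor.

    Candidates are library entries whose precursor m/z lies within
    ``ms1_tol_ppm`` of the feature m/z; results are ranked by library score
    descending, ties by |precursor dppm| ascending then record index.  A
    feature without MS/MS yields an empty result (it proceeds mass-only).
    """
    if feature.ms2 is None:
        return []
    scored: list[SpectralMatch] = []
    for idx, ref in enumerate(library):
        if ref.precursor_mz is None:
            continue
        dppm = ppm_error(feature.mz, ref.precursor_mz)
        if abs(dppm) > ms1_tol_ppm:
            continue
        dot = dot_product_score(feature.ms2, ref, ms2_tol_mz)
        scored.append(
            SpectralMatch(
                query_feature_id=feature.feature_id,
                library_name=ref.name,
                dot_product=dot,
                fragment_presence=fragment_presence(feature.ms2, ref, ms2_tol_mz, rel_int_floor),
                n_matched_fragments=n_matched_fragments(feature.ms2, ref, ms2_tol_mz, rel_int_floor),
                library_score=dot / 100.0,
                candidate_rank=0,  # assigned after sorting
                structure_known=ref.structure_known,
                precursor_ppm=dppm,
                library_index=idx,
                inchikey=ref.inchikey,
            )
        )
    scored.sort(key=lambda m: (-m.library_score, abs(m.precursor_ppm), m.library_index))
    return [
        SpectralMatch(**{**m.__dict__, "candidate_rank": rank})
        for rank, m in enumerate(scored, start=1)
    ]
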