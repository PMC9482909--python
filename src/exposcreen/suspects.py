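"""Suspect screening and annotation-evidence assembly.

Features are matched against suspect lists by neutral mass + adduct within
a ppm tolerance; each hit (and, for non-target annotation, each feature)
gets an :class:`AnnotationEvidence` bundling every score the confidence
rules consume: library match scores, matched-fragment counts, formula
candidates with isotope and MS/MS-consistency evidence, and candidate
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chem import Adduct, ADDUCTS, IsotopePattern, adduct_mz, get_adduct, isotope_pattern, ppm_error
from .formulas import FormulaCandidate, ann_sim, enumerate_formulas, iso_score, monoisotopic_mass, rank_candidates
from .msdata import Feature, Spectrum, SuspectEntry
from .spectral import SpectralMatch, library_search

__all__ = [
    "AnnotationEvidence",
    "SuspectHit",
    "build_evidence",
    "screen_suspects",
    "merge_hits_across_lists",
]


@dataclass
class AnnotationEvidence:
    """All scores consumed by the confidence engine (absent = None)."""

    library_score: float | None = None  # 0-1
    dot_product: float | None = None  # 0-100
    fragment_presence: float | None = None  # 0-100
    n_matched_fragments: int | None = None
    candidate_count: int = 0
    top_formula: FormulaCandidate | None = None
    structure_known: bool = False
    library_match_name: str | None = None
    library_match_inchikey: str | None = None

    @property
    def is_single_candidate(self) -> bool:
        return self.candidate_count == 1


@dataclass
class SuspectHit:
    feature_id: str
    suspect: SuspectEntry
    adduct: Adduct
    ppm_error: float
    evidence: AnnotationEvidence
    feature: Feature | None = None


def build_evidence(
    feature: Feature,
    library: list[Spectrum],
    observed_iso: IsotopePattern | None = None,
    tol_ppm: float = 5.0,
    ms2_tol_mz: float = 0.01,
    rel_int_floor: float = 0.01,
    element_bounds: dict[str, int] | None = None,
) -> AnnotationEvidence:
    """Assemble annotation evidence for one feature.

    Spectral evidence comes from the best library match (when the feature
    carries MS/MS); formula evidence from candidate enumeration at the
    neutral mass implied by the mode's primary adduct ([M+H]+ / [M-H]-),
    scored against the observed isotope envelope (when supplied) and the
    MS/MS.  ``candidate_count`` is the number of library candidates when
    spectral evidence exists, else the number of formula candidates.
    """
    ev = AnnotationEvidence()
    matches: list[SpectralMatch] = library_search(
        feature, library, ms1_tol_ppm=tol_ppm, ms2_tol_mz=ms2_tol_mz, rel_int_floor=rel_int_floor
    )
    if matches:
        best = matches[0]
        ev.library_score = best.library_score
        ev.dot_product = best.dot_product
        ev.fragment_presence = best.fragment_presence
        ev.n_matched_fragments = best.n_matched_fragments
        ev.structure_known = best.structure_known
        ev.candidate_count = len(matches)
        ev.library_match_name = best.library_name
        ev.library_match_inchikey = best.inchikey

    primary = get_adduct("[M+H]+") if feature.esi_mode == "+" else get_adduct("[M-H]-")
    neutral = feature.mz * abs(primary.charge) - primary.mass_shift
    candidates = enumerate_formulas(neutral, tol_ppm, element_bounds)
    scored: list[FormulaCandidate] = []
    for f in candidates:
        theo_mz = adduct_mz(f, primary)
        cand = FormulaCandidate(formula=f, ppm_error=ppm_error(feature.mz, theo_mz))
        if observed_iso is not None:
            cand = _with(cand, iso_score=iso_score(observed_iso, isotope_pattern(f)))
        if feature.ms2 is not None:
            form, comp = ann_sim(
                feature.ms2, f, ms2_tol_mz,
                library_dot=ev.library_score if ev.structure_known else None,
                polarity=feature.esi_mode,
            )
            cand = _with(cand, ann_sim_form=form, ann_sim_comp=comp)
        scored.append(cand)
    if scored:
        ranked = rank_candidates(scored)
        ev.top_formula = ranked[0]
        if not matches:
            ev.candidate_count = len(ranked)
    return ev


def _with(c: FormulaCandidate, **kw) -> FormulaCandidate:
    from dataclasses import replace

    return replace(c, **kw)


def adducts_for_mode(esi_mode: str, adduct_set: list[str] | None = None) -> list[Adduct]:
    names = adduct_set if adduct_set is not None else list(ADDUCTS)
    return [get_adduct(n) for n in names if get_adduct(n).polarity == esi_mode]


def screen_suspects(
    features: list[Feature],
    suspect_lists: list[list[SuspectEntry]],
    adduct_set: list[str] | None = None,
    tol_ppm: float = 5.0,
    library: list[Spectrum] | None = None,
    observed_iso: dict[str, IsotopePattern] | None = None,
    ms2_tol_mz: float = 0.01,
    element_bounds: dict[str, int] | None = None,
) -> list[SuspectHit]:
    """Match features against suspect lists by neutral mass + adduct.

    Every adduct consistent with the feature's ESI mode is tested; a hit
    fires when |ppm| <= ``tol_ppm``.  All hits are retained — a feature may
    hit several suspects and several lists.  Evidence is attached from the
    spectral library and formula annotation when available.  Retention time
    plays no role in matching (suspect lists carry none).
    """
    if not suspect_lists or all(not lst for lst in suspect_lists):
        raise ValueError("no suspect entries supplied")
    hits: list[SuspectHit] = []
    ev_cache: dict[str, AnnotationEvidence] = {}
    lib = library or []
    iso_map = observed_iso or {}
    for f in features:
        mode_adducts = adducts_for_mode(f.esi_mode, adduct_set)
        for lst in suspect_lists:
            for suspect in lst:
                for ad in mode_adducts:
                    if suspect.formula is not None:
                        theo = adduct_mz(suspect.formula, ad)
                    else:
                        theo = (suspect.neutral_mass + ad.mass_shift) / abs(ad.charge)
                    dppm = ppm_error(f.mz, theo)
                    if abs(dppm) <= tol_ppm:
                        if f.feature_id not in ev_cache:
                            ev_cache[f.feature_id] = build_evidence(
                                f, lib, iso_map.get(f.feature_id),
                                tol_ppm=tol_ppm, ms2_tol_mz=ms2_tol_mz,
                                element_bounds=element_bounds,
                            )
                        hits.append(
                            SuspectHit(f.feature_id, suspect, ad, dppm, ev_cache[f.feature_id], f)
                        )
    return hits


def merge_hits_across_lists(hits: list[SuspectHit]) -> pd.DataFrame:
    """One row per (feature, InChIKey first block) with the union of list
    codes and the best evidence (highest library score, then most formula
    evidence); duplicate hit counts are reported.

    Suspects without an InChIKey are keyed by normalized name instead, so
    nothing is silently dropped.
    """
    groups: dict[tuple[str, str], list[SuspectHit]] = {}
    for h in hits:
        key_block = h.suspect.inchikey[:14] if h.suspect.inchikey else f"name:{h.suspect.name.lower()}"
        groups.setdefault((h.feature_id, key_block), []).append(h)
    rows = []
    for (fid, block), hs in sorted(groups.items()):
        best = max(
            hs,
            key=lambda h: (
                h.evidence.library_score or 0.0,
                (h.evidence.top_formula.iso_score or 0.0) if h.evidence.top_formula else 0.0,
                -abs(h.ppm_error),
            ),
        )
        rows.append(
            {
                "feature_id": fid,
                "inchikey_block": block,
                "name": best.suspect.name,
                "list_codes": ";".join(sorted({h.suspect.list_code for h in hs})),
                "adduct": best.adduct.name,
                "ppm_error": best.ppm_error,
                "library_score": best.evidence.library_score,
                "n_duplicates": len(hs) - 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "inchikey_block", "name", "list_codes",
            "adduct", "ppm_error", "library_score", "n_duplicates",
        ],
    )
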