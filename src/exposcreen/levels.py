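"""Identification-confidence level assignment.

Three rule cascades map annotation evidence to the communication levels of
the Schymanski identification-confidence scheme as specialized for the
three screening approaches: suspect screening (library score, fragment
counts, formula evidence), non-target screening with library scoring, and
non-target screening with dot-product/fragment-presence scoring.

Each cascade is evaluated best-level-first (2a -> ... -> 5), so a feature
receives the best level it qualifies for; level 5 ("unknown mass of
interest") is the total fallback.  Range conventions: a range written
"0.7-0.9" is the half-open interval (0.7, 0.9]; "70-100" is the closed
interval [70, 100]; explicit > / >= thresholds are literal.  Level 1
(reference-standard confirmation) has no computational analogue and is not
assigned.
"""

from __future__ import annotations

from dataclasses import dataclass

from .suspects import AnnotationEvidence

__all__ = ["ConfidenceLevel", "assign_level_suspect", "assign_level_nt_patroon", "assign_level_nt_msdial", "SCHEMES"]

LEVEL_ORDER = ["2a", "2b", "3a", "3b", "3c", "4a", "4b", "5"]


@dataclass(frozen=True)
class ConfidenceLevel:
    value: str  # one of LEVEL_ORDER
    scheme: str  # suspect_patroon | nt_patroon | nt_msdial
    fired_rule: str

    def __post_init__(self) -> None:
        if self.value not in LEVEL_ORDER:
            raise ValueError(f"unknown level {self.value!r}")


def _top(e: AnnotationEvidence):
    return e.top_formula if (e.top_formula is not None and e.top_formula.rank == 1) else None


def assign_level_suspect(e: AnnotationEvidence) -> ConfidenceLevel:
    """Suspect-screening cascade (library score, fragments, formula)."""
    scheme = "suspect_patroon"
    lib = e.library_score
    if lib is not None and lib > 0.9 and e.is_single_candidate:
        return ConfidenceLevel("2a", scheme, "library score > 0.9, one candidate only")
    if lib is not None and lib > 0.4:
        return ConfidenceLevel("3a", scheme, "library score > 0.4")
    nm = e.n_matched_fragments
    if nm is not None:
        if nm > 3:
            return ConfidenceLevel("3b", scheme, "> 3 fragments match")
        if nm < 3 and e.fragment_presence == 100.0:
            return ConfidenceLevel("3b", scheme, "< 3 fragments, all match")
    top = _top(e)
    if top is not None and top.ann_sim_comp is not None and top.ann_sim_comp > 0.7:
        return ConfidenceLevel("3c", scheme, "annotation similarity (compound) > 0.7")
    if (
        top is not None
        and top.ann_sim_form is not None
        and top.ann_sim_form >= 0.7
        and top.iso_score is not None
        and top.iso_score >= 0.5
        and top.gap_iso >= 0.2
        and top.gap_ann >= 0.2
    ):
        return ConfidenceLevel(
            "4a", scheme, "top formula: annSim >= 0.7, isoScore >= 0.5, gaps >= 0.2"
        )
    if top is not None and top.iso_score is not None and top.iso_score > 0.9 and top.gap_iso > 0.2:
        return ConfidenceLevel("4b", scheme, "top formula: isoScore > 0.9, gap > 0.2")
    return ConfidenceLevel("5", scheme, "unknown mass of interest")


def assign_level_nt_patroon(e: AnnotationEvidence) -> ConfidenceLevel:
    """Non-target cascade keyed on the library score bands."""
    scheme = "nt_patroon"
    lib = e.library_score
    if lib is not None:
        if lib > 0.9:
            return ConfidenceLevel("2a", scheme, "library score > 0.9")
        if 0.7 < lib <= 0.9:
            return ConfidenceLevel("3a", scheme, "library score 0.7-0.9")
        if 0.4 < lib <= 0.7:
            return ConfidenceLevel("3b", scheme, "library score 0.4-0.7")
    top = _top(e)
    if (
        top is not None
        and top.ann_sim_form is not None
        and top.ann_sim_form >= 0.7
        and top.iso_score is not None
        and top.iso_score >= 0.5
        and top.gap_iso >= 0.2
        and top.gap_ann >= 0.2
    ):
        return ConfidenceLevel(
            "4a", scheme, "top formula: annSim >= 0.7, isoScore >= 0.5, gaps >= 0.2"
        )
    return ConfidenceLevel("5", scheme, "unknown mass of interest")


def assign_level_nt_msdial(e: AnnotationEvidence) -> ConfidenceLevel:
    """Non-target cascade keyed on dot product / fragment presence."""
    scheme = "nt_msdial"
    dot, pres, nm = e.dot_product, e.fragment_presence, e.n_matched_fragments
    if dot is None or pres is None or nm is None:
        return ConfidenceLevel("5", scheme, "no spectral match")
    if e.is_single_candidate and nm >= 3 and 70 <= dot <= 100 and 50 <= pres <= 100:
        if e.structure_known:
            return ConfidenceLevel(
                "2a", scheme, ">= 3 fragments, dot 70-100, presence 50-100, one candidate"
            )
        return ConfidenceLevel(
            "2b", scheme, ">= 3 fragments, dot 70-100, presence 50-100, structure unknown"
        )
    if nm >= 3 and 50 <= dot < 70 and pres >= 50:
        return ConfidenceLevel("3a", scheme, ">= 3 fragments, dot 50-70, presence 50-100")
    if nm < 3 and 50 <= dot <= 100 and pres >= 50:
        if e.structure_known:
            return ConfidenceLevel("3b", scheme, "< 3 fragments, dot 50-100, presence 50-100")
        return ConfidenceLevel(
            "3c", scheme, "< 3 fragments, dot 50-100, presence 50-100, structure unknown"
        )
    if dot < 50 or pres < 50:
        return ConfidenceLevel("4a", scheme, "dot < 50 and/or presence < 50")
    return ConfidenceLevel("5", scheme, "unknown mass of interest")


SCHEMES = {
    "suspect_patroon": assign_level_suspect,
    "nt_patroon": assign_level_nt_patroon,
    "nt_msdial": assign_level_nt_msdial,
}
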