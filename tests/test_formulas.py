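"""Formula enumeration vs brute-force oracle, isotope scoring, MS/MS
consistency scores, candidate ranking."""

import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from exposcreen.chem import IsotopePattern, MONOISOTOPIC_MASS, isotope_pattern, monoisotopic_mass, parse_formula
from exposcreen.formulas import (
    FormulaCandidate,
    ann_sim,
    enumerate_formulas,
    iso_score,
    passes_rules,
    rank_candidates,
)
from exposcreen.msdata import Spectrum

CHNO_BOUNDS = {"C": 15, "H": 30, "N": 3, "O": 5}


def oracle_enumerate_simple(mass, tol_ppm, bounds):
    """Nested-loop brute force over the full CHNO bound box."""
    lo, hi = mass * (1 - tol_ppm * 1e-6), mass * (1 + tol_ppm * 1e-6)
    hits = set()
    for c in range(bounds.get("C", 0) + 1):
        for h in range(bounds.get("H", 0) + 1):
            for n in range(bounds.get("N", 0) + 1):
                for o in range(bounds.get("O", 0) + 1):
                    counts = {"C": c, "H": h, "N": n, "O": o}
                    if sum(counts.values()) == 0:
                        continue
                    m = sum(MONOISOTOPIC_MASS[el] * k for el, k in counts.items())
                    if lo <= m <= hi and passes_rules(counts):
                        hits.add(tuple(sorted((el, k) for el, k in counts.items() if k)))
    return hits


# masses of published reference compounds (worked m/z tables)
TABLE_MASSES = [117.078979, 122.048013, 131.094629, 123.032028, 197.068808, 166.062994]


class TestEnumerateFormulas:
    @pytest.mark.parametrize("mass", TABLE_MASSES)
    def test_matches_nested_loop_oracle(self, mass):
        got = {f.element_counts for f in enumerate_formulas(mass, 5.0, CHNO_BOUNDS)}
        assert got == oracle_enumerate_simple(mass, 5.0, CHNO_BOUNDS)

    def test_valine_mass_contains_truth(self):
        hits = enumerate_formulas(117.078979, 5.0, CHNO_BOUNDS)
        assert "C5H11NO2" in {f.hill() for f in hits}

    def test_bare_carbon(self):
        assert [f.hill() for f in enumerate_formulas(12.0, 5.0, CHNO_BOUNDS)] == ["C"]

    def test_monotone_in_tolerance(self):
        tight = {f.hill() for f in enumerate_formulas(117.078979, 0.1, CHNO_BOUNDS)}
        loose = {f.hill() for f in enumerate_formulas(117.078979, 5.0, CHNO_BOUNDS)}
        assert tight <= loose

    def test_combination_guard(self):
        with pytest.raises(ValueError, match="tighten"):
            enumerate_formulas(880.0, 2e5, {"C": 70, "H": 120, "N": 20, "O": 30})

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            enumerate_formulas(-5.0)


class TestIsoScore:
    def pattern(self, abundances):
        return IsotopePattern(tuple((float(i), a) for i, a in enumerate(abundances)))

    def test_identity_is_one(self):
        p = self.pattern([1.0, 0.3, 0.05])
        assert iso_score(p, p) == 1.0

    def test_worked_mean_deviation(self):
        obs = self.pattern([1.0, 0.0])
        theo = self.pattern([1.0, 0.30])
        assert iso_score(obs, theo) == pytest.approx(0.85)

    def test_clipped_at_zero(self):
        obs = self.pattern([1.0, 1.0, 1.0])
        # extreme synthetic mismatch cannot go below 0
        theo = IsotopePattern(((0.0, -5.0), (1.0, 5.0), (2.0, -5.0)))
        assert iso_score(obs, theo) >= 0.0

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=5))
    def test_self_similarity_property(self, abundances):
        abundances = [1.0] + abundances  # base peak
        p = self.pattern(abundances)
        assert iso_score(p, p) == 1.0


class TestAnnSim:
    CAND = parse_formula("C8H15N3O2")

    def frag_mz(self, formula):
        from exposcreen.chem import ELECTRON_MASS

        return monoisotopic_mass(formula) - ELECTRON_MASS

    def test_fully_explainable_is_one(self):
        peaks = [(self.frag_mz("C8H13N3O"), 100.0), (self.frag_mz("C7H15N3O"), 50.0)]
        form, comp = ann_sim(Spectrum(peaks=peaks), self.CAND)
        assert form == pytest.approx(1.0)
        assert comp == pytest.approx(1.0)

    def test_nothing_explainable_is_zero(self):
        form, comp = ann_sim(Spectrum(peaks=[(77.5, 100.0), (91.5, 50.0)]), self.CAND)
        assert form == 0.0 and comp == 0.0

    def test_two_of_three_equal_peaks(self):
        peaks = [
            (self.frag_mz("C8H13N3O"), 100.0),
            (self.frag_mz("C7H15N3O"), 100.0),
            (77.5, 100.0),
        ]
        form, _ = ann_sim(Spectrum(peaks=peaks), self.CAND)
        assert form == pytest.approx(2 / math.sqrt(6), abs=1e-6)  # cosine (1,1,1)x(1,1,0)

    def test_library_dot_caps_compound_similarity(self):
        peaks = [(self.frag_mz("C8H13N3O"), 100.0)]
        form, comp = ann_sim(Spectrum(peaks=peaks), self.CAND, library_dot=0.3)
        assert form == pytest.approx(1.0)
        assert comp == pytest.approx(0.3)

    def test_hydrogen_latitude(self):
        # fragment at sub-formula mass +1 H is still explainable
        mz = monoisotopic_mass("C8H13N3O") + MONOISOTOPIC_MASS["H"]
        form, _ = ann_sim(Spectrum(peaks=[(mz, 100.0)]), self.CAND)
        assert form == pytest.approx(1.0)


class TestRankCandidates:
    def cand(self, hill, ppm=0.0, iso=None, ann=None):
        return FormulaCandidate(parse_formula(hill), ppm, iso_score=iso, ann_sim_form=ann)

    def test_single_candidate_infinite_gaps(self):
        ranked = rank_candidates([self.cand("C5H11NO2")])
        assert ranked[0].rank == 1
        assert math.isinf(ranked[0].gap_iso) and math.isinf(ranked[0].gap_ann)

    def test_iso_gap_between_first_and_next(self):
        ranked = rank_candidates(
            [self.cand("C5H11NO2", iso=0.60), self.cand("C6H13O2", iso=0.95)]
        )
        assert ranked[0].formula.hill() == "C6H13O2"
        assert ranked[0].gap_iso == pytest.approx(0.35)

    def test_equal_scores_tie_break_by_hill_string(self):
        a, b = self.cand("C6H12O6", iso=0.5), self.cand("C3H6O3", iso=0.5)
        ranked = rank_candidates([a, b])
        assert [c.formula.hill() for c in ranked] == ["C3H6O3", "C6H12O6"]
        assert ranked[0].gap_iso == 0.0

    def test_permutation_invariance(self):
        cands = [
            self.cand("C5H11NO2", ppm=1.0, iso=0.9),
            self.cand("C6H13O2", ppm=0.5, iso=0.9),
            self.cand("C4H9N3O", ppm=2.0, iso=0.3),
        ]
        reference = [(c.formula.hill(), c.rank) for c in rank_candidates(cands)]
        rnd = random.Random(0)
        for _ in range(5):
            shuffled = cands[:]
            rnd.shuffle(shuffled)
            assert [(c.formula.hill(), c.rank) for c in rank_candidates(shuffled)] == reference

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_candidates([])
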