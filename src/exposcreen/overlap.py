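"""Set overlap across screening approaches and pathway over-representation.

Annotated features are compared across ESI modes, LC modes, libraries and
suspect lists as sets of InChIKeys (features lacking a structure key —
levels 2b/3c/5 — cannot enter the comparison and are reported, never
silently dropped).  Pathway over-representation on selected compounds uses
the hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy.stats import hypergeom

__all__ = ["OverlapReport", "PathwayResult", "overlap", "pathway_ora"]


@dataclass(frozen=True)
class OverlapReport:
    """Exact Venn partition of up to four named InChIKey sets."""

    set_names: tuple[str, ...]
    cells: dict[frozenset, int]  # membership combination -> count
    excluded_count: int

    def cell(self, *names: str) -> int:
        """Count of keys in exactly the named sets (and no others)."""
        return self.cells.get(frozenset(names), 0)

    @property
    def union_size(self) -> int:
        return sum(self.cells.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(1, len(self.set_names) + 1):
            for combo in combinations(self.set_names, r):
                rows.append(
                    {"sets": "&".join(combo), "count": self.cells.get(frozenset(combo), 0)}
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PathwayResult:
    pathway_id: str
    hits: int
    pathway_size: int
    universe_size: int
    selected_size: int
    p_value: float


def overlap(
    sets: dict[str, set[str]],
    excluded: set[str] | None = None,
    first_block: bool = False,
) -> OverlapReport:
    """Exact Venn partition of 2-4 named InChIKey sets.

    ``excluded`` carries identifiers of features that could not enter the
    comparison (no InChIKey available); their count is reported.  With
    ``first_block`` keys are collapsed to the 14-character connectivity
    block before comparison.
    """
    if not 2 <= len(sets) <= 4:
        raise ValueError("overlap supports 2-4 sets; report pairwise beyond that")
    if first_block:
        sets = {name: {k[:14] for k in s} for name, s in sets.items()}
    names = tuple(sorted(sets))
    universe = set().union(*sets.values())
    cells: dict[frozenset, int] = {}
    for key in universe:
        members = frozenset(n for n in names if key in sets[n])
        cells[members] = cells.get(members, 0) + 1
    return OverlapReport(names, cells, len(excluded) if excluded else 0)


def _normalize_name(name: str) -> str:
    return " ".join(name.lower().split())


def pathway_ora(
    selected: list[str],
    universe: list[str],
    pathways: dict[str, list[str]],
) -> list[PathwayResult]:
    """Hypergeometric over-representation of selected compounds per pathway.

    Compound names are matched exactly after case-folding and whitespace
    normalization; duplicates are removed before testing.  For each pathway
    with members in the universe, p = P(X >= hits) drawing
    ``len(selected)`` compounds from the universe with the pathway members
    as successes.  Pathways disjoint from the universe are excluded with a
    warning.  Results sorted by p then pathway id.
    """
    uni = {_normalize_name(n) for n in universe}
    if not uni:
        raise ValueError("empty universe")
    sel = {_normalize_name(n) for n in selected}
    stray = sel - uni
    if stray:
        raise ValueError(f"selected compounds missing from universe: {sorted(stray)}")
    results = []
    for pid, members in pathways.items():
        mem = {_normalize_name(n) for n in members} & uni
        if not mem:
            import warnings

            warnings.warn(f"pathway {pid!r} disjoint from universe; excluded", stacklevel=2)
            continue
        hits = len(mem & sel)
        # P(X >= hits); hits = 0 gives p = 1
        p = float(hypergeom.sf(hits - 1, len(uni), len(mem), len(sel)))
        results.append(PathwayResult(pid, hits, len(mem), len(uni), len(sel), min(p, 1.0)))
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results
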