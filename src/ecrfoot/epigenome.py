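"""Enhancer-state classification from histone marks and methylation.

Each candidate element is intersected, per tissue, with H3K4me1 and
H3K27ac peak sets and with hypomethylated regions.  The combination of
marks gives the chromatin state of an enhancer: H3K4me1 plus H3K27ac is
an active enhancer, H3K4me1 alone a poised one, H3K27ac alone is
flagged separately, neither is inactive.  Across tissues, an element is
called ubiquitous when it is active/poised (or hypomethylated,
depending on the configured criterion) in a strict majority of tissues,
tissue-specific when in at least one but not a majority, else inactive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval


class EnhancerState(str, Enum):
    ACTIVE = "active"            # H3K4me1 + H3K27ac
    POISED = "poised"            # H3K4me1 only
    ACETYL_ONLY = "acetyl_only"  # H3K27ac only
    NONE = "none"


class BreadthCriterion(str, Enum):
    MARKS = "marks"                      # active-or-poised tissues
    HYPOMETHYLATION = "hypomethylation"  # hypomethylated tissues
    EITHER = "either"                    # either line of evidence


@dataclass(frozen=True)
class BreadthCall:
    element: str
    n_tissues_supporting: int
    n_tissues_hypomethylated: int
    n_tissues_total: int
    call: str  # ubiquitous | tissue_specific | inactive


def intersect(query: list[GenomicInterval], subject: list[GenomicInterval],
              min_overlap: int = 1) -> list[tuple[bool, int]]:
    """Per query interval: (overlaps any subject?, total overlapped bp).

    Half-open semantics throughout: [0,10) and [10,20) do not overlap.
    The overlap length is the size of the union of subject coverage
    within the query.  ``min_overlap`` (default 1 bp) is the minimum
    overlap that counts as a flag.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for iv in subject:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    results = []
    for q in query:
        tree = trees.get(q.chrom)
        if tree is None:
            results.append((False, 0))
            continue
        pieces = sorted((max(q.start, h.begin), min(q.end, h.end))
                        for h in tree.overlap(q.start, q.end))
        covered = 0
        cur_s = cur_e = None
        for s, e in pieces:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            covered += cur_e - cur_s
        results.append((covered >= min_overlap, covered))
    return results


def classify_state(k4me1_overlap: bool, k27ac_overlap: bool,
                   hypometh_overlap: bool) -> tuple[EnhancerState, bool]:
    """Map mark-overlap flags to a chromatin state (plus hypomethylated
    flag carried alongside)."""
    if k4me1_overlap and k27ac_overlap:
        state = EnhancerState.ACTIVE
    elif k4me1_overlap:
        state = EnhancerState.POISED
    elif k27ac_overlap:
        state = EnhancerState.ACETYL_ONLY
    else:
        state = EnhancerState.NONE
    return state, bool(hypometh_overlap)


def profile_elements(elements: list[GenomicInterval],
                     tracks: dict[str, dict[str, list[GenomicInterval]]],
                     min_overlap: int = 1) -> pd.DataFrame:
    """State matrix over (tissue, element).

    ``tracks`` maps tissue -> {'H3K4me1': [...], 'H3K27ac': [...],
    'hypomethylation': [...]} interval lists (missing mark = no peaks).
    Returns a long-form frame with columns tissue, element, state,
    hypomethylated.
    """
    if not tracks:
        raise ValueError("tissue track set is empty")
    records = []
    for tissue, marks in tracks.items():
        flags = {}
        for mark in ("H3K4me1", "H3K27ac", "hypomethylation"):
            res = intersect(elements, marks.get(mark, []), min_overlap=min_overlap)
            flags[mark] = [r[0] for r in res]
        for i, elem in enumerate(elements):
            state, hypo = classify_state(flags["H3K4me1"][i], flags["H3K27ac"][i],
                                         flags["hypomethylation"][i])
            records.append({"tissue": tissue, "element": elem.name or f"{elem.chrom}:{elem.start}-{elem.end}",
                            "state": state.value, "hypomethylated": hypo})
    return pd.DataFrame.from_records(records)


def call_breadth(states: dict[str, EnhancerState], hypometh: dict[str, bool],
                 element: str = "",
                 criterion: BreadthCriterion = BreadthCriterion.EITHER) -> BreadthCall:
    """Ubiquitous / tissue-specific / inactive call across tissues.

    A tissue supports the element when it is ACTIVE or POISED there
    (criterion ``marks``), hypomethylated there (``hypomethylation``),
    or either (default).  Ubiquitous requires support in a *strict*
    majority of tissues; support in at least one but not a majority is
    tissue-specific.
    """
    if not states:
        raise ValueError("empty tissue set")
    if set(states) != set(hypometh):
        raise ValueError("state and hypomethylation tissue sets differ")
    criterion = BreadthCriterion(criterion)
    n = len(states)
    supporting = 0
    for tissue, state in states.items():
        by_marks = state in (EnhancerState.ACTIVE, EnhancerState.POISED)
        by_hypo = hypometh[tissue]
        ok = {BreadthCriterion.MARKS: by_marks,
              BreadthCriterion.HYPOMETHYLATION: by_hypo,
              BreadthCriterion.EITHER: by_marks or by_hypo}[criterion]
        supporting += int(ok)
    n_hypo = sum(map(bool, hypometh.values()))
    if supporting * 2 > n:
        call = "ubiquitous"
    elif supporting >= 1:
        call = "tissue_specific"
    else:
        call = "inactive"
    return BreadthCall(element=element, n_tissues_supporting=supporting,
                       n_tissues_hypomethylated=n_hypo, n_tissues_total=n, call=call)
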