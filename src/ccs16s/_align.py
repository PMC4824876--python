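"""Thin wrappers around edlib shared by error profiling, denoising and clustering.

Alignments are unit-cost (Levenshtein): every substitution, inserted base and
deleted base counts one.  This makes the alignment optimum coincide with the
difference count n_sub + n_ins + n_del that drives best-reference selection,
chimera distances, pre-clustering and OTU distances.  Two modes are used:

``NW``  global on both sequences (pairwise distances, chimera parents);
``HW``  global on the query with free terminal gaps on the reference
        (a read aligned within a longer reference; reference overhang is
        neither penalized nor counted).
"""

from __future__ import annotations

import edlib
from Bio import Align


def edit_distance(query: str, target: str, mode: str = "NW", k: int = -1) -> int:
    """Minimal difference count; -1 if ``k`` >= 0 and the distance exceeds it."""
    if not query or not target:
        if mode == "HW":
            d = len(query)  # empty reference forces all-insertion; empty read aligns free
        else:
            d = max(len(query), len(target))
        return -1 if 0 <= k < d else d
    return edlib.align(query, target, mode=mode, task="distance", k=k)["editDistance"]


def align_pair(query: str, target: str, mode: str = "NW") -> tuple[str, str]:
    """Aligned (query, target) strings with ``-`` for gaps.

    In HW mode the returned target slice covers only the aligned span, so
    free terminal reference columns never appear.
    """
    if not query:
        if mode == "HW":
            return "", ""
        return "-" * len(target), target
    if not target:
        return query, "-" * len(query)
    result = edlib.align(query, target, mode=mode, task="path")
    nice = edlib.getNiceAlignment(result, query, target)
    return nice["query_aligned"], nice["target_aligned"]


def _make_aligner(free_end_gaps: bool) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    if free_end_gaps:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older PairwiseAligner attribute names
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


_SCORED = _make_aligner(free_end_gaps=False)
_SCORED_FREE_ENDS = _make_aligner(free_end_gaps=True)


def align_pair_scored(a: str, b: str, free_end_gaps: bool = False) -> tuple[str, str]:
    """Affine-scored global alignment (match +1, mismatch -1, gap open -2,
    extend -1), used where gap *placement* matters: substitutions are
    preferred over indel pairs and gap runs stay contiguous.  With
    ``free_end_gaps`` terminal overhang on either sequence is unpenalized.
    """
    if not a or not b:
        return a + "-" * len(b), "-" * len(a) + b
    aligner = _SCORED_FREE_ENDS if free_end_gaps else _SCORED
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def count_events(aligned_query: str, aligned_target: str) -> tuple[int, int, int, int]:
    """(n_match, n_sub, n_ins, n_del) read-relative: an insertion is a base
    present in the query but absent from the target."""
    n_match = n_sub = n_ins = n_del = 0
    for q, t in zip(aligned_query, aligned_target):
        if q == "-":
            n_del += 1
        elif t == "-":
            n_ins += 1
        elif q == t:
            n_match += 1
        else:
            n_sub += 1
    return n_match, n_sub, n_ins, n_del
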