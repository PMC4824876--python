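"""Pairwise distances, average-neighbor OTU clustering and rarefaction.

OTUs are formed by agglomerative average-linkage ("average neighbor")
clustering of pairwise sequence distances, cut at 3% by default.  The
distance between two sequences is computed from a global alignment with
terminal gaps excluded; a contiguous run of gap columns counts as a single
difference event, so a 3-nt indel over 100 aligned columns gives
1 event / 98 compared positions.

Rarefied richness uses the closed-form expectation of the number of OTUs
observed in a random subsample of fixed depth (hypergeometric form):

    E[S_depth] = sum_i [ 1 - C(N - n_i, depth) / C(N, depth) ]
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln

from ccs16s._align import align_pair_scored
from ccs16s.seqio import SequenceRecord


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sequence ids."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("distances must lie in [0, 1]")
        self.matrix = m


def _strip_terminal_gaps(aq: str, at: str) -> tuple[str, str]:
    start, end = 0, len(aq)
    while start < end and (aq[start] == "-" or at[start] == "-"):
        start += 1
    while end > start and (aq[end - 1] == "-" or at[end - 1] == "-"):
        end -= 1
    return aq[start:end], at[start:end]


def pairwise_distance(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    gap_run_as_one: bool = True,
    ignore_terminal_gaps: bool = True,
) -> float:
    """Alignment distance between two sequences, in [0, 1].

    With the defaults, substitutions count one each, every contiguous
    internal gap run counts one, terminal gap runs are dropped, and the
    denominator is matches + substitutions + gap-run events.  Setting
    ``gap_run_as_one=False`` counts every gap column individually.
    """
    seq_a, seq_b = (x.bases if isinstance(x, SequenceRecord) else x for x in (a, b))
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if seq_b < seq_a:  # canonical order makes the measure exactly symmetric
        seq_a, seq_b = seq_b, seq_a
    aq, at = align_pair_scored(seq_a, seq_b, free_end_gaps=True)
    if ignore_terminal_gaps:
        aq, at = _strip_terminal_gaps(aq, at)
    n_match = n_sub = n_gap_events = 0
    in_gap = False
    for x, y in zip(aq, at):
        if x == "-" or y == "-":
            if gap_run_as_one:
                if not in_gap:
                    n_gap_events += 1
                in_gap = True
            else:
                n_gap_events += 1
        else:
            in_gap = False
            if x == y:
                n_match += 1
            else:
                n_sub += 1
    compared = n_match + n_sub + n_gap_events
    if compared == 0:
        return 0.0
    return (n_sub + n_gap_events) / compared


def distance_matrix(seqs: Sequence[SequenceRecord | str], **kwargs) -> DistanceMatrix:
    """All pairwise distances among a set of sequences."""
    ids = [s.id if isinstance(s, SequenceRecord) else f"seq_{i}" for i, s in enumerate(seqs)]
    n = len(seqs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_distance(seqs[i], seqs[j], **kwargs)
    return DistanceMatrix(ids=ids, matrix=m)


@dataclass
class OtuClustering:
    """A partition of sequences into OTUs at a distance cutoff."""

    cutoff: float
    assignment: dict[str, int]  # id -> OTU label
    otu_abundances: dict[int, int]

    @property
    def n_otus(self) -> int:
        return len(self.otu_abundances)


def average_neighbor(
    dm: DistanceMatrix,
    cutoff: float = 0.03,
    abundances: Mapping[str, int] | None = None,
) -> OtuClustering:
    """Average-linkage agglomerative clustering cut at ``cutoff``.

    Cluster-to-cluster distance is the unweighted mean over all cross pairs;
    merging proceeds while the minimum inter-cluster distance is <= cutoff.
    """
    n = len(dm.ids)
    if n == 0:
        return OtuClustering(cutoff=cutoff, assignment={}, otu_abundances={})
    if n == 1:
        labels = np.array([1])
    else:
        z = linkage(squareform(dm.matrix, checks=False), method="average")
        labels = fcluster(z, t=cutoff, criterion="distance")
    assignment = {seq_id: int(label) for seq_id, label in zip(dm.ids, labels)}
    otu_abundances: dict[int, int] = {}
    for seq_id, label in assignment.items():
        weight = abundances.get(seq_id, 0) if abundances is not None else 1
        otu_abundances[label] = otu_abundances.get(label, 0) + weight
    return OtuClustering(cutoff=cutoff, assignment=assignment, otu_abundances=otu_abundances)


def rarefied_otu_count(
    otu_abundances: Mapping[int, int] | Sequence[int],
    depth: int = 1000,
    method: str = "exact",
    n_iter: int = 1000,
    seed: int | None = None,
) -> float:
    """Expected number of OTUs observed in a random subsample of ``depth``.

    ``method="exact"`` evaluates the closed form with log-gamma arithmetic;
    ``method="montecarlo"`` subsamples without replacement ``n_iter`` times
    (seeded) and averages, as a cross-check of the closed form.
    """
    counts = np.asarray(
        list(otu_abundances.values()) if isinstance(otu_abundances, Mapping) else otu_abundances,
        dtype=int,
    )
    if np.any(counts <= 0):
        raise ValueError("OTU abundances must be positive")
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds total abundance {total} (ND)")
    if method == "exact":
        def log_choose(n: np.ndarray | int, k: int) -> np.ndarray:
            return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

        expected = 0.0
        for n_i in counts:
            if total - n_i < depth:
                expected += 1.0  # OTU cannot be missed by the subsample
            else:
                expected += 1.0 - float(
                    np.exp(log_choose(total - n_i, depth) - log_choose(total, depth))
                )
        return expected
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(len(counts)), counts)
        seen = [len(np.unique(rng.choice(pool, size=depth, replace=False))) for _ in range(n_iter)]
        return float(np.mean(seen))
    raise ValueError(f"unknown method {method!r}")
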