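"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: plain dynamic programming, exhaustive
enumeration and O(n^3) agglomeration, sharing no code with the package.
"""

from __future__ import annotations

import itertools


def nw_distance(a: str, b: str) -> int:
    """Unit-cost global edit distance by full dynamic programming."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (a[i - 1] != b[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return prev[m]


def hw_distance(query: str, target: str) -> int:
    """Unit-cost distance with free terminal gaps on the target (the query
    aligns anywhere within the target)."""
    n, m = len(query), len(target)
    prev = [0] * (m + 1)  # free leading target overhang
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(
                prev[j - 1] + (query[i - 1] != target[j - 1]),
                prev[j] + 1,
                cur[j - 1] + 1,
            )
        prev = cur
    return min(prev)  # free trailing target overhang


def best_reference(read: str, refs: list[tuple[str, str]]) -> tuple[str, int]:
    """(ref id, distance) minimizing the difference count, first-wins ties."""
    best_id, best_d = None, None
    for rid, rseq in refs:
        d = hw_distance(read, rseq)
        if best_d is None or d < best_d:
            best_id, best_d = rid, d
    return best_id, best_d


def enumerate_chimeras_equal_length(refs: list[str]) -> set[str]:
    """All distinct single-breakpoint products of equal-length parents that
    differ from every parent (substitution-only divergence assumed)."""
    products: set[str] = set()
    parents = set(refs)
    for a, b in itertools.permutations(refs, 2):
        assert len(a) == len(b)
        for k in range(1, len(a)):
            chimera = a[:k] + b[k:]
            if chimera not in parents:
                products.add(chimera)
    return products


def precluster_oracle(entries: dict[str, tuple[str, int]], threshold: int) -> dict[str, int]:
    """Greedy abundance-sorted merge; returns id -> merged abundance.

    Ties in abundance break lexicographically by sequence; each sequence
    merges into the FIRST retained sequence within ``threshold`` differences.
    """
    order = sorted(entries, key=lambda i: (-entries[i][1], entries[i][0]))
    kept: list[str] = []
    abundance: dict[str, int] = {}
    for seq_id in order:
        bases, count = entries[seq_id]
        target = None
        for kept_id in kept:
            if nw_distance(bases, entries[kept_id][0]) <= threshold:
                target = kept_id
                break
        if target is None:
            kept.append(seq_id)
            abundance[seq_id] = count
        else:
            abundance[target] += count
    return abundance


def average_linkage_partition(matrix, cutoff: float) -> set[frozenset[int]]:
    """Naive average-neighbor agglomeration: repeatedly merge the pair of
    clusters with the smallest mean cross-pair distance while it is <= cutoff."""
    n = len(matrix)
    clusters: list[set[int]] = [{i} for i in range(n)]
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = sum(
                    matrix[i][j] for i in clusters[x] for j in clusters[y]
                ) / (len(clusters[x]) * len(clusters[y]))
                if best is None or d < best[0]:
                    best = (d, x, y)
        if best is None or best[0] > cutoff:
            break
        _, x, y = best
        clusters[x] |= clusters[y]
        del clusters[y]
    return {frozenset(c) for c in clusters}
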