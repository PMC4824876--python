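"""Reference-based error profiling, in-silico chimeras and the variant spectrum.

With a mock community the true template of every read is (nearly) known, so
the observed error rate can be measured directly: each read is globally
aligned to every reference with free terminal gaps on the reference, the
reference with the fewest differences wins, and substitutions, insertions and
deletions are counted from the traceback (read-relative: an insertion is a
base present in the read but absent from the reference).

PCR chimeras inflate the apparent error rate, so before profiling, reads are
compared against the exhaustive set of single-breakpoint bimeras constructed
from the references: a read that is ``delta`` (default 3) or more nucleotides
closer to some in-silico chimera than to any non-chimeric reference is
flagged as chimeric.

The variant spectrum groups reads exactly 1 nt away from their best
reference by error signature; recurrent signatures reveal systematic
(non-random) consensus errors.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import binom

from ccs16s._align import align_pair, align_pair_scored, count_events, edit_distance
from ccs16s.seqio import SequenceRecord

BASES = "ACGT"


@dataclass
class AlignmentResult:
    """One read aligned to its best-matching reference."""

    read_id: str
    best_ref_id: str
    aligned_read: str
    aligned_ref: str
    n_match: int
    n_sub: int
    n_ins: int
    n_del: int

    def __post_init__(self) -> None:
        if len(self.aligned_read) != len(self.aligned_ref):
            raise ValueError("aligned strings must have equal length")

    @property
    def n_errors(self) -> int:
        return self.n_sub + self.n_ins + self.n_del

    @property
    def n_columns(self) -> int:
        """Non-terminal alignment columns: the error-rate denominator."""
        return self.n_match + self.n_sub + self.n_ins + self.n_del

    @property
    def error_rate(self) -> float:
        return self.n_errors / self.n_columns if self.n_columns else 0.0


def _as_seq(item: SequenceRecord | str) -> str:
    return item.bases if isinstance(item, SequenceRecord) else item


def _ref_list(refs) -> list[tuple[str, str]]:
    if isinstance(refs, Mapping):
        return [(rid, _as_seq(seq)) for rid, seq in refs.items()]
    out = []
    for i, ref in enumerate(refs):
        if isinstance(ref, SequenceRecord):
            out.append((ref.id, ref.bases))
        else:
            out.append((f"ref_{i}", ref))
    return out


def align_to_best_reference(
    read: SequenceRecord | str,
    refs: Sequence[SequenceRecord | str] | Mapping[str, str],
) -> AlignmentResult:
    """Align a read to every reference; the fewest differences wins.

    Terminal reference overhang is free and excluded from all counts; ties
    are broken by reference input order.
    """
    ref_items = _ref_list(refs)
    if not ref_items:
        raise ValueError("at least one reference is required")
    seq = _as_seq(read)
    read_id = read.id if isinstance(read, SequenceRecord) else "read"

    best_id, best_seq, best_d = None, None, None
    for rid, rseq in ref_items:
        d = edit_distance(seq, rseq, mode="HW", k=-1 if best_d is None else best_d - 1)
        if d >= 0 and (best_d is None or d < best_d):
            best_id, best_seq, best_d = rid, rseq, d
            if best_d == 0:
                break
    assert best_id is not None and best_seq is not None
    aq, at = align_pair(seq, best_seq, mode="HW")
    n_match, n_sub, n_ins, n_del = count_events(aq, at)
    return AlignmentResult(
        read_id=read_id,
        best_ref_id=best_id,
        aligned_read=aq,
        aligned_ref=at,
        n_match=n_match,
        n_sub=n_sub,
        n_ins=n_ins,
        n_del=n_del,
    )


@dataclass
class ErrorProfile:
    """Aggregate error tallies over a set of alignments.

    ``substitution_matrix[ref_base][read_base]`` counts substitutions (the
    diagonal is structurally zero).  ``max_quality_fraction`` holds, per call
    class, the fraction of read positions carrying the maximum quality value;
    it is populated only when qualities are supplied.
    """

    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0
    n_match: int = 0
    substitution_matrix: dict[str, Counter] = field(
        default_factory=lambda: {b: Counter() for b in BASES}
    )
    insertion_bases: Counter = field(default_factory=Counter)
    deletion_bases: Counter = field(default_factory=Counter)
    max_quality_positions: dict[str, int] = field(
        default_factory=lambda: {"correct": 0, "substitution": 0, "insertion": 0}
    )
    quality_positions: dict[str, int] = field(
        default_factory=lambda: {"correct": 0, "substitution": 0, "insertion": 0}
    )

    @property
    def n_errors(self) -> int:
        return self.n_sub + self.n_ins + self.n_del

    @property
    def error_rate(self) -> float:
        total = self.n_match + self.n_errors
        return self.n_errors / total if total else 0.0

    @property
    def type_fractions(self) -> dict[str, float] | None:
        """Fractions of errors by type; ``None`` when there are no errors."""
        if self.n_errors == 0:
            return None
        return {
            "insertion": self.n_ins / self.n_errors,
            "deletion": self.n_del / self.n_errors,
            "substitution": self.n_sub / self.n_errors,
        }

    @property
    def deletion_base_fractions(self) -> dict[str, float] | None:
        total = sum(self.deletion_bases.values())
        if total == 0:
            return None
        return {b: self.deletion_bases.get(b, 0) / total for b in BASES}

    @property
    def max_quality_fraction(self) -> dict[str, float]:
        return {
            cls: (self.max_quality_positions[cls] / n if (n := self.quality_positions[cls]) else float("nan"))
            for cls in self.quality_positions
        }


def tally_errors(
    alignments: Iterable[AlignmentResult],
    quals: Mapping[str, Sequence[int]] | None = None,
    max_quality: int = 93,
) -> ErrorProfile:
    """Aggregate per-type counts, base compositions and the quality cross-tab.

    ``quals`` maps read id to per-base qualities of the *unaligned* read;
    when given, every match/substitution/insertion position contributes to
    the maximum-quality cross-tabulation of its call class.
    """
    profile = ErrorProfile()
    for aln in alignments:
        read_quals = quals.get(aln.read_id) if quals is not None else None
        pos = 0  # index into the ungapped read
        for q, t in zip(aln.aligned_read, aln.aligned_ref):
            if q == "-":
                profile.n_del += 1
                if t in BASES:
                    profile.deletion_bases[t] += 1
                continue
            if t == "-":
                profile.n_ins += 1
                cls = "insertion"
                if q in BASES:
                    profile.insertion_bases[q] += 1
            elif q == t:
                profile.n_match += 1
                cls = "correct"
            else:
                profile.n_sub += 1
                cls = "substitution"
                if t in BASES and q != t:
                    profile.substitution_matrix[t][q] += 1
            if read_quals is not None:
                profile.quality_positions[cls] += 1
                if read_quals[pos] == max_quality:
                    profile.max_quality_positions[cls] += 1
            pos += 1
    return profile


@dataclass(frozen=True)
class ChimeraReference:
    """A single-breakpoint bimera built from two aligned parents."""

    parent_a: str
    parent_b: str
    breakpoint: int  # aligned-column index: columns [0, breakpoint) from a
    bases: str


def enumerate_in_silico_chimeras(
    refs: Sequence[SequenceRecord | str] | Mapping[str, str],
) -> list[ChimeraReference]:
    """All distinct single-breakpoint chimeras between every ordered pair.

    Parents are pairwise aligned; one product is emitted per internal
    breakpoint column and degapped.  Products identical to either parent are
    dropped, and exact duplicate sequences are deduplicated (first occurrence
    kept).
    """
    ref_items = _ref_list(refs)
    chimeras: list[ChimeraReference] = []
    seen: set[str] = set(seq for _, seq in ref_items)
    for ida, seqa in ref_items:
        for idb, seqb in ref_items:
            if ida == idb:
                continue
            aa, ab = align_pair_scored(seqa, seqb)
            for col in range(1, len(aa)):
                product = (aa[:col] + ab[col:]).replace("-", "")
                if product in seen:
                    continue
                seen.add(product)
                chimeras.append(
                    ChimeraReference(parent_a=ida, parent_b=idb, breakpoint=col, bases=product)
                )
    return chimeras


def classify_chimeric(
    read: SequenceRecord | str,
    refs: Sequence[SequenceRecord | str] | Mapping[str, str],
    chimeras: Sequence[ChimeraReference],
    delta: int = 3,
) -> str:
    """``"chimeric"`` iff the read is ``delta`` or more nucleotides closer to
    an in-silico chimera than to any non-chimeric reference, else ``"clean"``.
    """
    seq = _as_seq(read)
    d_ref = min(edit_distance(seq, rseq, mode="HW") for _, rseq in _ref_list(refs))
    if d_ref < delta:
        return "clean"  # no chimera can be delta closer than a d_ref this small
    bound = d_ref - delta  # only chimeras at distance <= d_ref - delta matter
    for chi in chimeras:
        if edit_distance(seq, chi.bases, mode="HW", k=bound) >= 0:
            return "chimeric"
    return "clean"


@dataclass
class VariantSpectrum:
    """Occurrence histogram of distinct 1-nt error signatures."""

    histogram: dict[int, int]  # occurrence count (clipped at max_count) -> number of variants
    n_variants: int
    n_reads: int  # reads at exactly 1 nt from their best reference
    most_abundant_count: int

    def fraction_singletons(self) -> float:
        return self.histogram.get(1, 0) / self.n_variants if self.n_variants else float("nan")


def variant_spectrum(
    reads: Sequence[SequenceRecord | str],
    refs: Sequence[SequenceRecord | str] | Mapping[str, str],
    max_count: int = 10,
) -> VariantSpectrum:
    """Histogram how often each distinct 1-nt variant recurs.

    Reads at exactly one difference from their best reference are grouped by
    error signature (reference, alignment column, error type, bases); the
    histogram counts how many signatures occurred once, twice, ... up to
    ``max_count`` (larger counts are clipped into the top bin).
    """
    signatures: Counter = Counter()
    n_reads = 0
    for read in reads:
        aln = align_to_best_reference(read, refs)
        if aln.n_errors != 1:
            continue
        n_reads += 1
        for col, (q, t) in enumerate(zip(aln.aligned_read, aln.aligned_ref)):
            if q != t:
                if q == "-":
                    kind = "del"
                elif t == "-":
                    kind = "ins"
                else:
                    kind = "sub"
                signatures[(aln.best_ref_id, col, kind, q, t)] += 1
                break
    histogram: dict[int, int] = {}
    for count in signatures.values():
        binned = min(count, max_count)
        histogram[binned] = histogram.get(binned, 0) + 1
    most_abundant = max(signatures.values(), default=0)
    return VariantSpectrum(
        histogram=histogram,
        n_variants=len(signatures),
        n_reads=n_reads,
        most_abundant_count=most_abundant,
    )


def expected_error_free_fraction(p: float, n: int) -> float:
    """(1-p)^n: the binomial probability that an n-nt read has zero errors."""
    if not 0 <= p <= 1:
        raise ValueError("p must be a fraction in [0, 1]")
    if n < 0:
        raise ValueError("n must be non-negative")
    return (1 - p) ** n


def binomial_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p): reads with at least k errors."""
    return float(binom.sf(k - 1, n, p))
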