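"""Demultiplexing, orientation, trimming and read filtering.

A CCS amplicon read carries, in order: forward barcode, forward primer,
insert, reverse-complemented reverse primer, reverse-complemented reverse
barcode.  Because the consensus can be emitted in either strand, trimming
tries both orientations and reports which one matched.

Screening combines a basic screen (homopolymer runs, insert length) with the
three filters that correlate with consensus error: barcode/primer mismatches
(at most 1 each by default), sequencing coverage (at least 10 passes) and the
predicted error rate (at most 0.01%).  A read is kept iff it passes every
enabled filter; the report attributes each removed read to the first filter
it fails, so attrition depends on order but the kept set does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import groupby
from typing import Iterable, Sequence

from ccs16s.design import BarcodePair, RegionDesign, iupac_match
from ccs16s.seqio import SequenceRecord, reverse_complement


@dataclass
class TrimResult:
    """Outcome of barcode/primer location on one read.

    ``record`` holds the primer-free insert when a sample was assigned, else
    the untouched input read.  Mismatch counts are the maximum over the two
    barcodes and over the two primers respectively.
    """

    record: SequenceRecord
    bc_mismatches: int
    primer_mismatches: int
    orientation_flipped: bool
    matched_sample: str | None

    def __post_init__(self) -> None:
        if self.bc_mismatches < 0 or self.primer_mismatches < 0:
            raise ValueError("mismatch counts must be non-negative")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _primer_mismatches(primer: str, window: str) -> int:
    # IUPAC-aware: a degenerate primer base matches any base in its expansion
    return sum(not iupac_match(p, w) for p, w in zip(primer, window))


def _best_5p(seq: str, barcode: str, primer: str, max_shift: int) -> tuple[int, int, int]:
    """Best (bc_mm, primer_mm, end) for barcode+primer within the leading window."""
    best = (len(barcode) + 1, len(primer) + 1, 0)
    pat_len = len(barcode) + len(primer)
    for shift in range(max_shift + 1):
        if shift + pat_len > len(seq):
            break
        bc_mm = _hamming(barcode, seq[shift:shift + len(barcode)])
        pr_mm = _primer_mismatches(primer, seq[shift + len(barcode):shift + pat_len])
        if (bc_mm + pr_mm) < (best[0] + best[1]):
            best = (bc_mm, pr_mm, shift + pat_len)
    return best


def _best_3p(seq: str, barcode_rc: str, primer_rc: str, max_shift: int) -> tuple[int, int, int]:
    """Best (bc_mm, primer_mm, start) for revcomp(primer)+revcomp(barcode)
    ending within ``max_shift`` of the 3' end."""
    best = (len(barcode_rc) + 1, len(primer_rc) + 1, len(seq))
    pat_len = len(primer_rc) + len(barcode_rc)
    for shift in range(max_shift + 1):
        end = len(seq) - shift
        start = end - pat_len
        if start < 0:
            break
        pr_mm = _primer_mismatches(primer_rc, seq[start:start + len(primer_rc)])
        bc_mm = _hamming(barcode_rc, seq[start + len(primer_rc):end])
        if (bc_mm + pr_mm) < (best[0] + best[1]):
            best = (bc_mm, pr_mm, start)
    return best


def find_and_trim(
    record: SequenceRecord,
    barcodes: Sequence[BarcodePair],
    region: RegionDesign,
    max_shift: int = 2,
    max_bc_mismatch: int = 1,
    max_primer_mismatch: int = 1,
) -> TrimResult:
    """Locate barcodes and primers, orient the read and excise the insert.

    The forward orientation is scored first for every barcode pair; if no
    pair satisfies the per-element thresholds, the reverse complement of the
    read is scored.  Among acceptable assignments the one with the fewest
    total mismatches wins.  A read matching no pair in either orientation is
    returned unassigned (``matched_sample`` is ``None``), never raised.
    """
    if not barcodes:
        raise ValueError("at least one barcode pair is required")

    best_overall: tuple[int, TrimResult] | None = None
    for flipped in (False, True):
        oriented = record.reverse_complement() if flipped else record
        seq = oriented.bases
        accepted: tuple[int, TrimResult] | None = None
        for pair in barcodes:
            f_bc, f_pr, insert_start = _best_5p(seq, pair.fwd_barcode, region.fwd_primer, max_shift)
            r_bc, r_pr, insert_end = _best_3p(
                seq,
                reverse_complement(pair.rev_barcode),
                reverse_complement(region.rev_primer),
                max_shift,
            )
            bc_mm = max(f_bc, r_bc)
            pr_mm = max(f_pr, r_pr)
            total = f_bc + r_bc + f_pr + r_pr
            if insert_end < insert_start:
                continue
            trimmed = replace(
                oriented,
                bases=seq[insert_start:insert_end],
                quals=None if oriented.quals is None else oriented.quals[insert_start:insert_end],
            )
            result = TrimResult(
                record=trimmed,
                bc_mismatches=bc_mm,
                primer_mismatches=pr_mm,
                orientation_flipped=flipped,
                matched_sample=pair.sample,
            )
            if bc_mm <= max_bc_mismatch and pr_mm <= max_primer_mismatch:
                if accepted is None or total < accepted[0]:
                    accepted = (total, result)
            if best_overall is None or total < best_overall[0]:
                best_overall = (total, result)
        if accepted is not None:
            return accepted[1]
    # neither orientation met the thresholds: report the closest attempt, unassigned
    assert best_overall is not None
    fallback = best_overall[1]
    return TrimResult(
        record=record,
        bc_mismatches=fallback.bc_mismatches,
        primer_mismatches=fallback.primer_mismatches,
        orientation_flipped=False,
        matched_sample=None,
    )


def max_homopolymer(bases: str) -> int:
    """Length of the longest run of one identical character (0 for empty)."""
    if not bases:
        return 0
    return max(len(list(run)) for _, run in groupby(bases))


def predicted_error_from_quals(quals: Sequence[int]) -> float:
    """Mean per-base error probability implied by Phred qualities.

    A fallback for reads lacking a caller-supplied predicted error rate:
    quality-0 positions are ambiguous calls and are charged probability 0.75
    (a uniform guess over four bases); every other base contributes
    10^(-Q/10).
    """
    if not quals:
        raise ValueError("cannot estimate predicted error from empty qualities")
    return sum(0.75 if q == 0 else 10 ** (-q / 10) for q in quals) / len(quals)


@dataclass
class FilterConfig:
    """Thresholds for the basic screen and the error-correlated filters.

    A threshold of ``None`` disables that filter; ``filter_length`` gates the
    insert-length window, which defaults to the region's expected insert
    length +/- 10% when no explicit window is given.
    """

    max_homopolymer: int | None = 8
    filter_length: bool = True
    insert_length_window: tuple[int, int] | None = None
    max_bc_mismatch: int | None = 1
    max_primer_mismatch: int | None = 1
    min_passes: int | None = 10
    max_predicted_error: float | None = 0.0001  # 0.01%

    def __post_init__(self) -> None:
        for name in ("max_homopolymer", "max_bc_mismatch", "max_primer_mismatch", "min_passes", "max_predicted_error"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def disabled(cls) -> "FilterConfig":
        return cls(
            max_homopolymer=None,
            filter_length=False,
            max_bc_mismatch=None,
            max_primer_mismatch=None,
            min_passes=None,
            max_predicted_error=None,
        )

    @classmethod
    def basic(cls) -> "FilterConfig":
        """Homopolymer + length screen only."""
        return cls(max_bc_mismatch=None, max_primer_mismatch=None, min_passes=None, max_predicted_error=None)


@dataclass
class FilterReport:
    """Per-filter attrition in application order."""

    total: int = 0
    evaluated: dict[str, int] = field(default_factory=dict)
    failed: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    @property
    def fraction_retained(self) -> float:
        return self.retained / self.total if self.total else 1.0

    def check(self) -> None:
        if self.retained + sum(self.failed.values()) != self.total:
            raise AssertionError("report does not partition the input")


FILTER_ORDER = ("homopolymer", "length", "mismatch", "coverage", "predicted_error")


def _filter_checks(config: FilterConfig, region: RegionDesign | None):
    """Yield (name, enabled, predicate) in reporting order; predicates take
    (record, trim) and return True when the read passes."""
    window = config.insert_length_window
    if window is None and region is not None:
        window = region.length_window()

    def homopolymer_ok(rec, trim):
        return max_homopolymer(rec.bases) <= config.max_homopolymer

    def length_ok(rec, trim):
        if window is None:
            raise ValueError("length filter enabled but no window and no region supplied")
        return window[0] <= len(rec.bases) <= window[1]

    def mismatch_ok(rec, trim):
        if trim is None:
            raise ValueError("mismatch filter enabled but inputs carry no trim metadata")
        if trim.matched_sample is None:
            return False
        bc_ok = config.max_bc_mismatch is None or trim.bc_mismatches <= config.max_bc_mismatch
        pr_ok = config.max_primer_mismatch is None or trim.primer_mismatches <= config.max_primer_mismatch
        return bc_ok and pr_ok

    def coverage_ok(rec, trim):
        if rec.passes is None:
            raise ValueError("coverage filter enabled but record has no pass count")
        return rec.passes >= config.min_passes

    def predicted_error_ok(rec, trim):
        pe = rec.predicted_error
        if pe is None:
            if rec.quals is None:
                raise ValueError("predicted-error filter enabled but record has neither a predicted error nor qualities")
            pe = predicted_error_from_quals(rec.quals)
        return pe <= config.max_predicted_error

    yield "homopolymer", config.max_homopolymer is not None, homopolymer_ok
    yield "length", config.filter_length, length_ok
    yield "mismatch", config.max_bc_mismatch is not None or config.max_primer_mismatch is not None, mismatch_ok
    yield "coverage", config.min_passes is not None, coverage_ok
    yield "predicted_error", config.max_predicted_error is not None, predicted_error_ok


def screen(
    items: Iterable[SequenceRecord | TrimResult],
    config: FilterConfig,
    region: RegionDesign | None = None,
) -> tuple[list[SequenceRecord | TrimResult], FilterReport]:
    """Apply every enabled filter conjunctively.

    Accepts raw records or :class:`TrimResult` objects (the latter are needed
    by the mismatch filter); returns the kept items in input order plus a
    :class:`FilterReport`.  The kept set is the same for any filter order;
    the per-filter failure attribution follows ``FILTER_ORDER``.
    """
    checks = [(name, pred) for name, enabled, pred in _filter_checks(config, region) if enabled]
    report = FilterReport()
    for name, _ in checks:
        report.evaluated[name] = 0
        report.failed[name] = 0
    kept: list[SequenceRecord | TrimResult] = []
    for item in items:
        report.total += 1
        trim = item if isinstance(item, TrimResult) else None
        rec = item.record if isinstance(item, TrimResult) else item
        passed = True
        for name, pred in checks:
            report.evaluated[name] += 1
            if not pred(rec, trim):
                report.failed[name] += 1
                passed = False
                break
        if passed:
            kept.append(item)
            report.retained += 1
    report.check()
    return kept, report
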