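"""Sequence I/O with the PacBio CCS FASTQ conventions.

PacBio consensus FASTQ files use a quality score of 0 as a sentinel for an
ambiguous base call; real qualities span 2-93.  ``read_fastq(pacbio_mode=True)``
converts every quality-0 base to ``N`` on input, and ``write_records`` inverts
the rule on output.

Per-read consensus metadata (number of sequencing passes, predicted error
rate) has no standard home in 4-line FASTQ, so it travels in the record id as
``@<id>;np=<int>;pe=<float>``; a sidecar tab-delimited table
(``read_id<TAB>passes<TAB>predicted_error``) is accepted as an alternative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqIO.FastaIO import SimpleFastaParser

MAX_QUALITY = 93

_META_RE = re.compile(r";(np|pe)=([^;]+)")

IUPAC_CHARS = frozenset("ACGTUMRWSYKVHDBN")


@dataclass
class SequenceRecord:
    """One consensus read: bases, per-base qualities and CCS metadata.

    ``quals`` is ``None`` for FASTA input.  ``passes`` is the number of times
    the polymerase traversed the insert (CCS coverage); ``predicted_error`` is
    the per-read error-rate estimate emitted by the consensus caller, as a
    fraction in [0, 1].
    """

    id: str
    bases: str
    quals: list[int] | None = None
    passes: int | None = None
    predicted_error: float | None = None
    orientation_flipped: bool = False

    def __post_init__(self) -> None:
        if self.quals is not None:
            if len(self.quals) != len(self.bases):
                raise ValueError(
                    f"record {self.id!r}: {len(self.bases)} bases but "
                    f"{len(self.quals)} quality values"
                )
            bad = [q for q in self.quals if not 0 <= q <= MAX_QUALITY]
            if bad:
                raise ValueError(
                    f"record {self.id!r}: quality values {bad[:3]} outside [0, {MAX_QUALITY}]"
                )
        if self.passes is not None and self.passes < 0:
            raise ValueError(f"record {self.id!r}: negative pass count")

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "SequenceRecord":
        return replace(
            self,
            bases=reverse_complement(self.bases),
            quals=None if self.quals is None else self.quals[::-1],
            orientation_flipped=not self.orientation_flipped,
        )


_COMPLEMENT = str.maketrans(
    "ACGTUMRWSYKVHDBNacgtumrwsykvhdbn",
    "TGCAAKYWSRMBDHVNtgcaakywsrmbdhvn",
)


def reverse_complement(bases: str) -> str:
    """IUPAC-aware reverse complement."""
    return bases.translate(_COMPLEMENT)[::-1]


def _apply_pacbio_rule(bases: str, quals: list[int]) -> str:
    # quality 0 encodes an ambiguous call; idempotent by construction
    if 0 not in quals:
        return bases
    return "".join("N" if q == 0 else b for b, q in zip(bases, quals))


def _parse_title(title: str) -> tuple[str, int | None, float | None]:
    """Split ``id;np=<int>;pe=<float>`` into its parts.

    The whole first whitespace-delimited token is the id; ``np``/``pe`` keys
    are stripped from it when present.
    """
    token = title.split()[0]
    passes: int | None = None
    pe: float | None = None
    for key, value in _META_RE.findall(token):
        if key == "np":
            passes = int(value)
        else:
            pe = float(value)
    read_id = _META_RE.sub("", token)
    return read_id, passes, pe


def _format_title(rec: SequenceRecord) -> str:
    parts = [rec.id]
    if rec.passes is not None:
        parts.append(f"np={rec.passes}")
    if rec.predicted_error is not None:
        parts.append(f"pe={rec.predicted_error:.6g}")
    return ";".join(parts)


def read_fastq(
    path: str | Path,
    pacbio_mode: bool = False,
    offset: int = 33,
    metadata: Mapping[str, tuple[int, float]] | None = None,
) -> list[SequenceRecord]:
    """Parse a 4-line FASTQ file into :class:`SequenceRecord` objects.

    Parameters
    ----------
    pacbio_mode:
        When true, every base whose quality is 0 is replaced by ``N``
        (the PacBio ambiguity convention).  Off by default.
    offset:
        ASCII quality encoding offset; Phred+33 is the dominant dialect.
    metadata:
        Optional sidecar mapping ``read_id -> (passes, predicted_error)``;
        overrides values parsed from the header.
    """
    records: list[SequenceRecord] = []
    with open(path) as handle:
        for index, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
            read_id, passes, pe = _parse_title(title)
            quals = [ord(c) - offset for c in qual]
            if len(quals) != len(seq):
                raise ValueError(f"record {index} ({read_id!r}): base/quality length mismatch")
            if any(q < 0 or q > MAX_QUALITY for q in quals):
                raise ValueError(f"record {index} ({read_id!r}): quality outside [0, {MAX_QUALITY}]")
            if metadata is not None and read_id in metadata:
                passes, pe = metadata[read_id]
            bases = seq.upper()
            if pacbio_mode:
                bases = _apply_pacbio_rule(bases, quals)
            records.append(
                SequenceRecord(id=read_id, bases=bases, quals=quals, passes=passes, predicted_error=pe)
            )
    return records


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse FASTA into records with no quality information."""
    with open(path) as handle:
        return [
            SequenceRecord(id=title.split()[0], bases=seq.upper())
            for title, seq in SimpleFastaParser(handle)
        ]


def read_metadata_table(path: str | Path) -> dict[str, tuple[int, float]]:
    """Read the sidecar ``read_id<TAB>passes<TAB>predicted_error`` table."""
    table: dict[str, tuple[int, float]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            read_id, passes, pe = line.split("\t")
            table[read_id] = (int(passes), float(pe))
    return table


def write_records(
    records: Iterable[SequenceRecord],
    path: str | Path,
    format: str = "fastq",
    pacbio_mode: bool = False,
    offset: int = 33,
) -> None:
    """Write records as FASTA or FASTQ.

    In ``pacbio_mode`` FASTQ output, ``N`` bases are written with quality 0
    (the inverse of the parsing rule).  Requesting FASTQ for records lacking
    qualities is an error.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    with open(path, "w") as handle:
        for rec in records:
            if format == "fasta":
                handle.write(f">{_format_title(rec)}\n{rec.bases}\n")
                continue
            if rec.quals is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            quals = rec.quals
            if pacbio_mode:
                quals = [0 if b == "N" else q for b, q in zip(rec.bases, quals)]
            qual_str = "".join(chr(q + offset) for q in quals)
            handle.write(f"@{_format_title(rec)}\n{rec.bases}\n+\n{qual_str}\n")


@dataclass
class CountTable:
    """Abundance bookkeeping for unique sequences, per sample.

    ``entries`` maps a unique-sequence id to its representative bases;
    ``counts`` maps the same id to ``{sample: abundance}``.  Abundances are
    positive integers.
    """

    entries: dict[str, str] = field(default_factory=dict)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def add(self, seq_id: str, bases: str, sample: str = "sample", n: int = 1) -> None:
        if n <= 0:
            raise ValueError("abundance increments must be positive")
        if seq_id in self.entries and self.entries[seq_id] != bases:
            raise ValueError(f"id {seq_id!r} already bound to different bases")
        self.entries.setdefault(seq_id, bases)
        per_sample = self.counts.setdefault(seq_id, {})
        per_sample[sample] = per_sample.get(sample, 0) + n

    def abundance(self, seq_id: str) -> int:
        return sum(self.counts[seq_id].values())

    def total(self) -> int:
        return sum(self.abundance(i) for i in self.entries)

    def samples(self) -> list[str]:
        names: set[str] = set()
        for per_sample in self.counts.values():
            names.update(per_sample)
        return sorted(names)

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_records(
        cls, records: Iterable[SequenceRecord], samples: Mapping[str, str] | None = None
    ) -> "CountTable":
        """Collapse identical sequences; ids are taken from the first holder."""
        table = cls()
        seen: dict[str, str] = {}  # bases -> id
        for rec in records:
            sample = samples.get(rec.id, "sample") if samples is not None else "sample"
            seq_id = seen.setdefault(rec.bases, rec.id)
            table.add(seq_id, rec.bases, sample)
        return table

    def write_tsv(self, path: str | Path) -> None:
        samples = self.samples()
        with open(path, "w") as handle:
            handle.write("sequence_id\ttotal\t" + "\t".join(samples) + "\n")
            for seq_id in self.entries:
                row = [seq_id, str(self.abundance(seq_id))]
                row += [str(self.counts[seq_id].get(s, 0)) for s in samples]
                handle.write("\t".join(row) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path, fasta: str | Path) -> "CountTable":
        """Rebuild a table from a count TSV plus the representative FASTA."""
        bases = {rec.id: rec.bases for rec in read_fasta(fasta)}
        table = cls()
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            samples = header[2:]
            for line in handle:
                fields = line.rstrip("\n").split("\t")
                seq_id = fields[0]
                for sample, count in zip(samples, fields[2:]):
                    if int(count) > 0:
                        table.add(seq_id, bases[seq_id], sample, int(count))
        return table
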