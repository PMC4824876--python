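"""Amplicon designs: regions, degenerate primers and paired barcodes.

Six primer pairs spanning nested windows of the 16S rRNA gene (V4 up to the
near-full-length V1-V9) ship as packaged defaults.  Coordinates are 1-based
inclusive positions on the E. coli 16S reference; the insert length is the
amplified span with both primers excluded, so for every region

    insert_length == ref_end - ref_start + 1 - len(fwd_primer) - len(rev_primer)

holds exactly.  Primers use IUPAC ambiguity codes (R = A/G, M = A/C, ...);
barcodes are 16-nt concrete sequences attached symmetrically to both ends of
the amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"),
    "M": frozenset("AC"), "R": frozenset("AG"), "W": frozenset("AT"),
    "S": frozenset("CG"), "Y": frozenset("CT"), "K": frozenset("GT"),
    "V": frozenset("ACG"), "H": frozenset("ACT"), "D": frozenset("AGT"),
    "B": frozenset("CGT"), "N": frozenset("ACGT"),
}


def iupac_match(code_a: str, code_b: str) -> bool:
    """True iff the IUPAC expansion sets of two nucleotide codes intersect."""
    try:
        set_a = IUPAC_SETS[code_a.upper()]
        set_b = IUPAC_SETS[code_b.upper()]
    except KeyError as exc:
        raise ValueError(f"not an IUPAC nucleotide code: {exc.args[0]!r}") from None
    return not set_a.isdisjoint(set_b)


@dataclass(frozen=True)
class RegionDesign:
    """One amplified region: primer pair, reference coordinates, insert length."""

    name: str
    fwd_primer: str
    rev_primer: str
    ref_start: int  # 1-based inclusive, E. coli numbering
    ref_end: int
    expected_insert_len: int

    def __post_init__(self) -> None:
        if self.ref_start >= self.ref_end:
            raise ValueError(f"region {self.name}: ref_start must be < ref_end")
        expected = theoretical_insert_length(self)
        if expected != self.expected_insert_len:
            raise ValueError(
                f"region {self.name}: stated insert length {self.expected_insert_len} "
                f"!= coordinates minus primers ({expected})"
            )

    def length_window(self, tolerance: float = 0.10) -> tuple[int, int]:
        """Acceptable insert-length window, expected length +/- ``tolerance``."""
        low = int(self.expected_insert_len * (1 - tolerance))
        high = int(round(self.expected_insert_len * (1 + tolerance)))
        return low, high


def theoretical_insert_length(region: RegionDesign) -> int:
    """Insert length implied by the coordinates: span minus both primers."""
    length = (
        region.ref_end - region.ref_start + 1
        - len(region.fwd_primer) - len(region.rev_primer)
    )
    if length < 0:
        raise ValueError(f"region {region.name}: primers longer than the amplified span")
    return length


@dataclass(frozen=True)
class BarcodePair:
    """Paired 16-nt symmetric barcodes identifying one sample."""

    sample: str
    fwd_barcode: str
    rev_barcode: str

    def __post_init__(self) -> None:
        for label, barcode in (("fwd", self.fwd_barcode), ("rev", self.rev_barcode)):
            if len(barcode) != 16:
                raise ValueError(
                    f"sample {self.sample}: {label} barcode must be 16 nt, got {len(barcode)}"
                )


def load_region_table(path: str | Path) -> list[RegionDesign]:
    """Load a tab-delimited region table; the insert-length identity is
    checked on every row and a violating row is rejected by name."""
    regions: list[RegionDesign] = []
    with open(path) as handle:
        header = handle.readline()
        if not header:
            return []
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"line {lineno}: expected 6 columns, got {len(fields)}")
            name, fwd, rev, start, end, insert = fields
            try:
                regions.append(
                    RegionDesign(
                        name=name,
                        fwd_primer=fwd.upper(),
                        rev_primer=rev.upper(),
                        ref_start=int(start),
                        ref_end=int(end),
                        expected_insert_len=int(insert),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno} (region {name}): {exc}") from None
    return regions


def load_barcode_table(path: str | Path) -> list[BarcodePair]:
    """Load ``sample<TAB>fwd_barcode<TAB>rev_barcode`` rows."""
    pairs: list[BarcodePair] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("sample\t"):
                continue
            sample, fwd, rev = line.split("\t")
            pairs.append(BarcodePair(sample=sample, fwd_barcode=fwd.upper(), rev_barcode=rev.upper()))
    return pairs


def default_regions() -> dict[str, RegionDesign]:
    """The six packaged region designs, keyed by name (e.g. ``"V1-V9"``)."""
    path = files("ccs16s.data").joinpath("regions.tsv")
    return {r.name: r for r in load_region_table(str(path))}
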