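"""Mock-community CCS read simulator.

Generates consensus amplicon reads whose error structure follows the rates
measured for PacBio CCS 16S data: an average per-base error rate of 0.65%
split into insertions (31.2%), deletions (17.9%) and substitutions (50.9%);
deletions preferentially remove guanines (39.4%) and adenines (24.3%) over
cytosines (18.3%) and thymidines (18.0%); substitution targets and inserted
bases are uniform; and the fraction of bases holding the maximum quality
value (93) is nearly identical for correct calls (80.5%), substitutions
(80.0%) and insertions (80.4%), which is why per-base qualities cannot be
used to screen reads.

Consensus quality varies enormously from read to read (it depends on how many
passes the polymerase completed), so each read draws a lognormal quality
multiplier on the error rate; the caller-style predicted error rate is the
read's latent rate scaled down and perturbed by lognormal noise, giving the
negative predicted-vs-observed correlation seen on real data without
modelling the proprietary estimator.

Every read is recorded in a :class:`TruthTable` (template, injected event
counts, chimera parentage), which is the oracle for all recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ccs16s.design import IUPAC_SETS, BarcodePair, RegionDesign
from ccs16s.seqio import SequenceRecord, reverse_complement

BASES = "ACGT"


@dataclass
class ErrorModel:
    """Parameters of the consensus error process.

    ``per_base_error_rate`` is the population-average rate; each read
    multiplies it by a lognormal factor with unit mean and log-sd
    ``read_rate_sigma``.  ``predicted_error_scale``/``sigma`` shape the
    simulated caller estimate (predicted errors sit well below observed
    errors on the absolute scale, so the 0.01% screening threshold retains
    roughly the better half of the reads).  ``chimera_rate`` is the fraction
    of reads built as single-breakpoint bimeras; ``systematic_variant_rate``
    emits one fixed recurrent 1-nt variant to reproduce the heavy tail of
    the variant spectrum.
    """

    per_base_error_rate: float = 0.0065
    type_mixture: dict[str, float] = field(
        default_factory=lambda: {"insertion": 0.312, "deletion": 0.179, "substitution": 0.509}
    )
    deletion_base_weights: dict[str, float] = field(
        default_factory=lambda: {"G": 0.394, "A": 0.243, "C": 0.183, "T": 0.180}
    )
    max_quality: int = 93
    p_max_quality: dict[str, float] = field(
        default_factory=lambda: {"correct": 0.805, "substitution": 0.800, "insertion": 0.804}
    )
    quality_range: tuple[int, int] = (2, 92)
    passes_range: tuple[int, int] = (3, 25)
    read_rate_sigma: float = 1.0
    predicted_error_scale: float = 0.015
    predicted_error_sigma: float = 0.5
    chimera_rate: float = 0.0
    systematic_variant_rate: float = 0.0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.type_mixture.values()), 1.0, abs_tol=1e-9):
            raise ValueError("type_mixture must sum to 1")
        if not math.isclose(sum(self.deletion_base_weights.values()), 1.0, abs_tol=1e-9):
            raise ValueError("deletion_base_weights must sum to 1")
        for name in ("per_base_error_rate", "chimera_rate", "systematic_variant_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a fraction in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth for one simulated read (whole-read injected events)."""

    read_id: str
    template_id: str
    sample: str
    n_sub: int
    n_ins: int
    n_del: int
    is_chimera: bool = False
    parent_a: str | None = None
    parent_b: str | None = None
    breakpoint: int | None = None
    orientation_flipped: bool = False
    latent_rate: float = 0.0

    @property
    def n_errors(self) -> int:
        return self.n_sub + self.n_ins + self.n_del


@dataclass
class TruthTable:
    records: list[TruthRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def total_errors(self) -> int:
        return sum(r.n_errors for r in self.records)

    def totals_by_type(self) -> dict[str, int]:
        return {
            "substitution": sum(r.n_sub for r in self.records),
            "insertion": sum(r.n_ins for r in self.records),
            "deletion": sum(r.n_del for r in self.records),
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def divergence_to_site_rate(divergence: float) -> float:
    """Per-copy mutation probability giving an expected pairwise divergence.

    Each template copy mutates every ancestor site independently with
    probability q (to a uniformly random different base), so two copies
    differ at a site with probability 2q(1-q) + (2/3)q^2; this inverts that
    relation.
    """
    if not 0 < divergence < 1:
        raise ValueError("divergence must lie in (0, 1)")
    # solve (4/3) q^2 - 2 q + divergence = 0 for the small root
    disc = 4 - (16 / 3) * divergence
    return (2 - math.sqrt(disc)) / (8 / 3)


def expected_pairwise_divergence(q: float) -> float:
    """Expected per-site difference rate between two independently mutated copies."""
    return 2 * q * (1 - q) + (2 / 3) * q * q


def make_mock_references(
    n_templates: int,
    length: int = 1464,
    divergence: float = 0.10,
    seed: int | None = 0,
) -> list[SequenceRecord]:
    """Synthetic mock-community reference amplicons.

    One uniformly random ancestor is mutated independently per template so
    that the expected pairwise divergence between any two templates equals
    ``divergence``.  Deterministic under ``seed``.
    """
    if n_templates < 1:
        raise ValueError("need at least one template")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=length)
    q = divergence_to_site_rate(divergence)
    refs = []
    for i in range(n_templates):
        seq = ancestor.copy()
        hits = np.flatnonzero(rng.random(length) < q)
        # shift by 1..3 mod 4: a uniformly random *different* base
        seq[hits] = (seq[hits] + rng.integers(1, 4, size=hits.size)) % 4
        bases = "".join(BASES[b] for b in seq)
        refs.append(SequenceRecord(id=f"template_{i + 1:03d}", bases=bases))
    return refs


def make_barcodes(samples: Sequence[str], seed: int | None = 0) -> list[BarcodePair]:
    """Random paired 16-nt symmetric barcodes, one pair per sample."""
    rng = np.random.default_rng(seed)
    pairs = []
    for sample in samples:
        fwd = "".join(BASES[b] for b in rng.integers(0, 4, size=16))
        rev = "".join(BASES[b] for b in rng.integers(0, 4, size=16))
        pairs.append(BarcodePair(sample=sample, fwd_barcode=fwd, rev_barcode=rev))
    return pairs


def _resolve_iupac(primer: str, rng: np.random.Generator) -> str:
    """Pick one concrete expansion of a degenerate primer."""
    out = []
    for code in primer:
        options = sorted(IUPAC_SETS[code])
        out.append(options[rng.integers(len(options))] if len(options) > 1 else options[0])
    return "".join(out)


def _choose_weighted(rng: np.random.Generator, items: Sequence[str], weights: Sequence[float]) -> str:
    r = rng.random() * sum(weights)
    acc = 0.0
    for item, w in zip(items, weights):
        acc += w
        if r < acc:
            return item
    return items[-1]


def _inject_errors(
    seq: str,
    rate: float,
    model: ErrorModel,
    rng: np.random.Generator,
    forced_subs: dict[int, str] | None = None,
) -> tuple[str, list[str], int, int, int]:
    """Apply the error process to one assembled read.

    Returns (mutated bases, per-base call classes, n_sub, n_ins, n_del).
    Event positions are i.i.d. uniform; a later event landing on an occupied
    template position is dropped (first-drawn wins).
    """
    length = len(seq)
    subs: dict[int, str] = dict(forced_subs or {})
    dels: set[int] = set()
    ins_at: dict[int, str] = {}
    used: set[int] = set(subs)

    types = list(model.type_mixture)
    type_w = [model.type_mixture[t] for t in types]
    del_bases = list(model.deletion_base_weights)
    del_w = [model.deletion_base_weights[b] for b in del_bases]

    n_events = rng.binomial(length, min(rate, 0.25)) if rate > 0 else 0
    for _ in range(n_events):
        kind = _choose_weighted(rng, types, type_w)
        if kind == "substitution":
            pos = int(rng.integers(length))
            if pos in used:
                continue
            used.add(pos)
            alternatives = [b for b in BASES if b != seq[pos]]
            subs[pos] = alternatives[rng.integers(3)]
        elif kind == "insertion":
            pos = int(rng.integers(length + 1))
            if pos in ins_at:
                continue
            ins_at[pos] = BASES[rng.integers(4)]
        else:  # deletion, victim base drawn from the deletion weights
            base = _choose_weighted(rng, del_bases, del_w)
            candidates = [p for p in range(length) if seq[p] == base and p not in used]
            if not candidates:
                candidates = [p for p in range(length) if p not in used]
                if not candidates:
                    continue
            pos = candidates[rng.integers(len(candidates))]
            used.add(pos)
            dels.add(pos)

    out_bases: list[str] = []
    out_class: list[str] = []
    for pos in range(length + 1):
        if pos in ins_at:
            out_bases.append(ins_at[pos])
            out_class.append("insertion")
        if pos < length and pos not in dels:
            if pos in subs:
                out_bases.append(subs[pos])
                out_class.append("substitution")
            else:
                out_bases.append(seq[pos])
                out_class.append("correct")
    return "".join(out_bases), out_class, len(subs), len(ins_at), len(dels)


def _assign_quals(classes: Sequence[str], model: ErrorModel, rng: np.random.Generator) -> list[int]:
    lo, hi = model.quality_range
    quals = []
    for cls in classes:
        if rng.random() < model.p_max_quality[cls]:
            quals.append(model.max_quality)
        else:
            quals.append(int(rng.integers(lo, hi + 1)))
    return quals


def simulate_ccs_reads(
    refs: Sequence[SequenceRecord],
    n_reads: int,
    model: ErrorModel | None = None,
    abundances: Sequence[float] | None = None,
    barcodes: Sequence[BarcodePair] | None = None,
    region: RegionDesign | None = None,
    seed: int | None = 0,
    p_reverse: float = 0.5,
) -> tuple[list[SequenceRecord], TruthTable]:
    """Simulate consensus reads from mock-community templates.

    Each read picks a template proportionally to ``abundances`` (uniform by
    default) or, with probability ``model.chimera_rate``, is assembled as a
    single-breakpoint bimera of two distinct templates.  When ``barcodes``
    and ``region`` are given, the insert is flanked by the sample's barcodes
    and one concrete expansion of the degenerate primers, and errors are
    injected across the whole assembled read so that barcode/primer
    mismatches correlate with read quality; otherwise bare inserts are
    emitted.  Half the reads (``p_reverse``) are reverse-complemented.
    Deterministic under ``seed``: identical inputs give byte-identical reads
    and truth records.
    """
    if model is None:
        model = ErrorModel()
    if abundances is None:
        abundances = [1.0 / len(refs)] * len(refs)
    if len(abundances) != len(refs):
        raise ValueError("abundances must match the number of references")
    if not math.isclose(sum(abundances), 1.0, abs_tol=1e-6):
        raise ValueError("abundances must sum to 1")
    rng = np.random.default_rng(seed)

    fwd_primer = rev_primer = ""
    if region is not None:
        fwd_primer = _resolve_iupac(region.fwd_primer, rng)
        rev_primer = _resolve_iupac(region.rev_primer, rng)

    # fixed recurrent 1-nt variant (systematic-error mode)
    sys_template = refs[0].bases
    sys_pos = len(sys_template) // 3
    sys_alt = [b for b in BASES if b != sys_template[sys_pos]][0]

    cum = np.cumsum(abundances)
    records: list[SequenceRecord] = []
    truth = TruthTable()
    for i in range(n_reads):
        read_id = f"read_{i + 1:06d}"
        is_chimera = False
        parent_a = parent_b = None
        breakpoint = None
        systematic = rng.random() < model.systematic_variant_rate
        if systematic:
            insert = sys_template
            template_id = refs[0].id
        elif len(refs) > 1 and rng.random() < model.chimera_rate:
            ia, ib = rng.choice(len(refs), size=2, replace=False)
            a, b = refs[int(ia)], refs[int(ib)]
            k = int(rng.integers(1, min(len(a.bases), len(b.bases))))
            insert = a.bases[:k] + b.bases[k:]
            if insert == a.bases or insert == b.bases:
                # breakpoint outside the divergent span: not actually chimeric
                template = a if insert == a.bases else b
                template_id = template.id
            else:
                template_id = f"chimera:{a.id}+{b.id}@{k}"
                is_chimera, parent_a, parent_b, breakpoint = True, a.id, b.id, k
        else:
            idx = int(np.searchsorted(cum, rng.random()))
            template = refs[min(idx, len(refs) - 1)]
            insert = template.bases
            template_id = template.id

        pair = None
        sample = "sample"
        if barcodes:
            pair = barcodes[int(rng.integers(len(barcodes)))]
            sample = pair.sample
        if pair is not None:
            assembled = (
                pair.fwd_barcode + fwd_primer + insert
                + reverse_complement(rev_primer) + reverse_complement(pair.rev_barcode)
            )
        else:
            assembled = insert

        lam = float(rng.lognormal(mean=-model.read_rate_sigma**2 / 2, sigma=model.read_rate_sigma)) \
            if model.read_rate_sigma > 0 else 1.0
        rate_i = model.per_base_error_rate * lam
        if systematic:
            offset = len(pair.fwd_barcode) + len(fwd_primer) if pair is not None else 0
            bases, classes, n_sub, n_ins, n_del = _inject_errors(
                assembled, 0.0, model, rng, forced_subs={offset + sys_pos: sys_alt}
            )
            template_id = refs[0].id
        else:
            bases, classes, n_sub, n_ins, n_del = _inject_errors(assembled, rate_i, model, rng)
        quals = _assign_quals(classes, model, rng)

        pe_noise = float(
            rng.lognormal(
                mean=-model.predicted_error_sigma**2 / 2, sigma=model.predicted_error_sigma
            )
        )
        predicted_error = rate_i * model.predicted_error_scale * pe_noise
        passes = int(rng.integers(model.passes_range[0], model.passes_range[1] + 1))

        flipped = bool(rng.random() < p_reverse)
        if flipped:
            bases = reverse_complement(bases)
            quals = quals[::-1]

        records.append(
            SequenceRecord(
                id=read_id,
                bases=bases,
                quals=quals,
                passes=passes,
                predicted_error=predicted_error,
            )
        )
        truth.records.append(
            TruthRecord(
                read_id=read_id,
                template_id=template_id,
                sample=sample,
                n_sub=n_sub,
                n_ins=n_ins,
                n_del=n_del,
                is_chimera=is_chimera,
                parent_a=parent_a,
                parent_b=parent_b,
                breakpoint=breakpoint,
                orientation_flipped=flipped,
                latent_rate=rate_i,
            )
        )
    return records, truth
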