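"""End-to-end orchestration: simulate -> trim -> screen -> profile -> precluster -> cluster.

``run_pipeline`` reproduces the structure of a mock-community benchmark run:
reads are demultiplexed and trimmed, passed through the basic screen
(homopolymer + insert length), purged of chimeras against the in-silico
chimera set, error-profiled, filtered on the error-correlated metadata
(mismatches, coverage, predicted error), pre-clustered, and finally
clustered into OTUs with rarefied richness.  The report carries the error
rate at the three canonical checkpoints (basic / predicted / precluster),
per-stage read counts, chimera tallies and OTU counts, including the OTU
count under perfect (truth-table) chimera removal when the input was
simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from ccs16s.cluster import average_neighbor, distance_matrix, rarefied_otu_count
from ccs16s.curate import FilterConfig, TrimResult, find_and_trim, screen
from ccs16s.denoise import PreclusterConfig, precluster
from ccs16s.design import BarcodePair, RegionDesign, default_regions
from ccs16s.errprof import (
    AlignmentResult,
    align_to_best_reference,
    classify_chimeric,
    enumerate_in_silico_chimeras,
)
from ccs16s.seqio import CountTable, SequenceRecord
from ccs16s.simulate import ErrorModel, TruthTable, make_barcodes, make_mock_references, simulate_ccs_reads


@dataclass
class PipelineConfig:
    """One reproducible run: simulation inputs, filters and clustering knobs."""

    region_name: str = "V4"
    n_templates: int = 21
    template_divergence: float = 0.10
    n_reads: int = 200
    n_samples: int = 1
    error_model: ErrorModel = field(default_factory=ErrorModel)
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    precluster_config: PreclusterConfig = field(default_factory=PreclusterConfig)
    cluster_cutoff: float = 0.03
    rarefaction_depth: int = 1000
    check_chimeras: bool = True
    chimera_delta: int = 3
    max_shift: int = 2
    seed: int = 0

    def region(self) -> RegionDesign:
        regions = default_regions()
        if self.region_name not in regions:
            raise ValueError(f"unknown region {self.region_name!r}; packaged: {sorted(regions)}")
        return regions[self.region_name]


@dataclass
class RunReport:
    """Consolidated per-stage accounting for one pipeline run."""

    stage_counts: dict[str, int]
    removed_by_stage: dict[str, int]
    error_rates: dict[str, float]
    n_chimeric_flagged: int
    n_chimeric_truth: int | None
    n_otus: int
    n_otus_perfect_chimera_removal: int | None
    rarefied_otus: float | None
    n_unique_after_precluster: int

    @property
    def fraction_retained(self) -> float:
        return self.stage_counts["predicted"] / self.stage_counts["input"]

    def to_dict(self) -> dict:
        out: dict = {}
        for stage, n in self.stage_counts.items():
            out[f"reads_{stage}"] = n
        for stage, n in self.removed_by_stage.items():
            out[f"removed_{stage}"] = n
        for stage, rate in self.error_rates.items():
            out[f"error_rate_{stage}"] = rate
        out.update(
            fraction_retained=self.fraction_retained,
            n_chimeric_flagged=self.n_chimeric_flagged,
            n_chimeric_truth=self.n_chimeric_truth,
            n_otus=self.n_otus,
            n_otus_perfect_chimera_removal=self.n_otus_perfect_chimera_removal,
            rarefied_otus=self.rarefied_otus,
            n_unique_after_precluster=self.n_unique_after_precluster,
        )
        return out

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            for key, value in self.to_dict().items():
                handle.write(f"{key}\t{value}\n")


def _pooled_error_rate(alignments: Sequence[AlignmentResult], weights: Sequence[int] | None = None) -> float:
    if weights is None:
        weights = [1] * len(alignments)
    errors = sum(w * a.n_errors for a, w in zip(alignments, weights))
    columns = sum(w * a.n_columns for a, w in zip(alignments, weights))
    return errors / columns if columns else 0.0


def run_pipeline(
    config: PipelineConfig,
    records: Sequence[SequenceRecord] | None = None,
    refs: Sequence[SequenceRecord] | None = None,
    barcodes: Sequence[BarcodePair] | None = None,
    truth: TruthTable | None = None,
) -> RunReport:
    """Run the full curation pipeline and report per-stage attrition.

    With no ``records`` a mock community is simulated from ``config``.  Read
    counts are non-increasing across stages and every removed read is
    attributed to exactly one stage.
    """
    region = config.region()

    if records is None:
        if refs is None:
            refs = make_mock_references(
                config.n_templates,
                length=region.expected_insert_len,
                divergence=config.template_divergence,
                seed=config.seed,
            )
        if barcodes is None:
            barcodes = make_barcodes(
                [f"S{i + 1}" for i in range(config.n_samples)], seed=config.seed + 1
            )
        records, truth = simulate_ccs_reads(
            refs,
            n_reads=config.n_reads,
            model=config.error_model,
            barcodes=barcodes,
            region=region,
            seed=config.seed + 2,
        )
    if refs is None:
        raise ValueError("references are required when records are supplied directly")
    if barcodes is None:
        raise ValueError("barcodes are required when records are supplied directly")

    truth_by_id = {t.read_id: t for t in truth.records} if truth is not None else {}
    stage_counts: dict[str, int] = {"input": len(records)}
    removed: dict[str, int] = {}

    # 1. demultiplex / orient / trim
    trims = [
        find_and_trim(rec, barcodes, region, max_shift=config.max_shift)
        for rec in records
    ]
    assigned = [t for t in trims if t.matched_sample is not None and len(t.record.bases) > 0]
    removed["trim"] = len(records) - len(assigned)
    stage_counts["trimmed"] = len(assigned)

    # 2. basic screen: homopolymer + insert length
    basic_cfg = FilterConfig(
        max_homopolymer=config.filter_config.max_homopolymer,
        filter_length=config.filter_config.filter_length,
        insert_length_window=config.filter_config.insert_length_window,
        max_bc_mismatch=None,
        max_primer_mismatch=None,
        min_passes=None,
        max_predicted_error=None,
    )
    basic_kept, basic_report = screen(assigned, basic_cfg, region)
    removed["basic_screen"] = len(assigned) - len(basic_kept)
    stage_counts["basic"] = len(basic_kept)

    # 3. chimera removal against the in-silico chimera set
    n_flagged = 0
    if config.check_chimeras:
        chimeras = enumerate_in_silico_chimeras(refs)
        clean: list[TrimResult] = []
        for t in basic_kept:
            verdict = classify_chimeric(t.record.bases, refs, chimeras, delta=config.chimera_delta)
            if verdict == "chimeric":
                n_flagged += 1
            else:
                clean.append(t)
    else:
        clean = list(basic_kept)
    removed["chimera"] = n_flagged
    stage_counts["chimera_screened"] = len(clean)
    n_chimeric_truth = (
        sum(1 for t in basic_kept if truth_by_id[t.record.id].is_chimera)
        if truth_by_id
        else None
    )

    # 4. error rate at the basic checkpoint
    alignments = {t.record.id: align_to_best_reference(t.record, refs) for t in clean}
    error_rates = {"basic": _pooled_error_rate([alignments[t.record.id] for t in clean])}

    # 5. error-correlated filters (mismatch / coverage / predicted error)
    corr_cfg = FilterConfig(
        max_homopolymer=None,
        filter_length=False,
        max_bc_mismatch=config.filter_config.max_bc_mismatch,
        max_primer_mismatch=config.filter_config.max_primer_mismatch,
        min_passes=config.filter_config.min_passes,
        max_predicted_error=config.filter_config.max_predicted_error,
    )
    filtered, corr_report = screen(clean, corr_cfg, region)
    removed["correlated_filters"] = len(clean) - len(filtered)
    stage_counts["predicted"] = len(filtered)
    error_rates["predicted"] = _pooled_error_rate([alignments[t.record.id] for t in filtered])

    # 6. pre-clustering
    table = CountTable.from_records(
        [t.record for t in filtered],
        samples={t.record.id: t.matched_sample for t in filtered},
    )
    threshold = config.precluster_config.threshold_for(region.expected_insert_len)
    denoised = precluster(table, threshold)
    reps = list(denoised.entries)
    rep_weights = [denoised.abundance(i) for i in reps]
    rep_alignments = [alignments[i] for i in reps]
    error_rates["precluster"] = _pooled_error_rate(rep_alignments, rep_weights)
    stage_counts["precluster_reads"] = denoised.total()

    # 7. OTU clustering on the denoised representatives
    rep_records = [SequenceRecord(id=i, bases=denoised.entries[i]) for i in reps]
    if rep_records:
        dm = distance_matrix(rep_records)
        clustering = average_neighbor(dm, cutoff=config.cluster_cutoff, abundances=dict(zip(reps, rep_weights)))
        n_otus = clustering.n_otus
        total = denoised.total()
        rarefied = (
            rarefied_otu_count(clustering.otu_abundances, depth=config.rarefaction_depth)
            if total >= config.rarefaction_depth
            else None
        )
    else:
        n_otus, rarefied = 0, None

    n_otus_perfect = None
    if truth_by_id:
        keep = [i for i in reps if not truth_by_id[i].is_chimera]
        if keep:
            dm_p = distance_matrix([SequenceRecord(id=i, bases=denoised.entries[i]) for i in keep])
            n_otus_perfect = average_neighbor(
                dm_p, cutoff=config.cluster_cutoff,
                abundances={i: denoised.abundance(i) for i in keep},
            ).n_otus
        else:
            n_otus_perfect = 0

    return RunReport(
        stage_counts=stage_counts,
        removed_by_stage=removed,
        error_rates=error_rates,
        n_chimeric_flagged=n_flagged,
        n_chimeric_truth=n_chimeric_truth,
        n_otus=n_otus,
        n_otus_perfect_chimera_removal=n_otus_perfect,
        rarefied_otus=rarefied,
        n_unique_after_precluster=len(denoised),
    )
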