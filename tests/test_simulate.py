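from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from ccs16s.curate import FilterConfig, screen
from ccs16s.errprof import align_to_best_reference, classify_chimeric, enumerate_in_silico_chimeras, tally_errors
from ccs16s.seqio import reverse_complement
from ccs16s.simulate import (
    ErrorModel,
    divergence_to_site_rate,
    expected_pairwise_divergence,
    make_barcodes,
    make_mock_references,
    simulate_ccs_reads,
)


class TestMockReferences:
    def test_single_template(self):
        (ref,) = make_mock_references(1, length=100, divergence=0.1, seed=0)
        assert len(ref.bases) == 100
        assert set(ref.bases) <= set("ACGT")

    def test_deterministic_under_seed(self):
        a = make_mock_references(21, length=300, divergence=0.10, seed=42)
        b = make_mock_references(21, length=300, divergence=0.10, seed=42)
        assert [(r.id, r.bases) for r in a] == [(r.id, r.bases) for r in b]
        c = make_mock_references(21, length=300, divergence=0.10, seed=43)
        assert [r.bases for r in a] != [r.bases for r in c]

    def test_site_rate_inverts_divergence(self):
        for d in (0.03, 0.10, 0.25):
            q = divergence_to_site_rate(d)
            assert expected_pairwise_divergence(q) == pytest.approx(d)

    def test_measured_divergence_matches_analytic_expectation(self):
        length, divergence = 600, 0.10
        refs = make_mock_references(12, length=length, divergence=divergence, seed=5)
        diffs = []
        for i in range(len(refs)):
            for j in range(i + 1, len(refs)):
                diffs.append(
                    sum(a != b for a, b in zip(refs[i].bases, refs[j].bases)) / length
                )
        se_single_pair = math.sqrt(divergence * (1 - divergence) / length)
        assert abs(np.mean(diffs) - divergence) < 3 * se_single_pair


class TestReadSimulation:
    def test_zero_error_rate_reproduces_templates(self, small_refs):
        model = ErrorModel(per_base_error_rate=0.0)
        reads, truth = simulate_ccs_reads(small_refs, n_reads=50, model=model, seed=1, p_reverse=0.0)
        by_id = {r.id: r.bases for r in small_refs}
        for read, t in zip(reads, truth.records):
            assert t.n_errors == 0
            assert read.bases == by_id[t.template_id]

    def test_byte_identical_under_seed(self, small_refs, barcode_pairs, v4_region):
        kwargs = dict(n_reads=40, barcodes=barcode_pairs, region=v4_region, seed=99)
        reads_a, truth_a = simulate_ccs_reads(small_refs, **kwargs)
        reads_b, truth_b = simulate_ccs_reads(small_refs, **kwargs)
        assert [(r.bases, tuple(r.quals), r.passes, r.predicted_error) for r in reads_a] == [
            (r.bases, tuple(r.quals), r.passes, r.predicted_error) for r in reads_b
        ]
        assert truth_a.to_dataframe().equals(truth_b.to_dataframe())

    def test_flipped_reads_marked_and_recoverable(self, small_refs):
        reads, truth = simulate_ccs_reads(small_refs, n_reads=200, seed=3, p_reverse=0.5)
        flipped = [t.orientation_flipped for t in truth.records]
        assert 0.35 < np.mean(flipped) < 0.65
        by_id = {r.id: r.bases for r in small_refs}
        model_free = [
            (r, t) for r, t in zip(reads, truth.records) if t.n_errors == 0 and not t.is_chimera
        ]
        for read, t in model_free[:20]:
            expected = by_id[t.template_id]
            observed = reverse_complement(read.bases) if t.orientation_flipped else read.bases
            assert observed == expected

    def test_passes_within_configured_range(self, small_refs):
        reads, _ = simulate_ccs_reads(small_refs, n_reads=100, seed=4)
        assert all(3 <= r.passes <= 25 for r in reads)

    def test_truth_counts_match_read_reconstruction(self, small_refs):
        """The injected event counts equal the alignment differences for
        unflipped bare reads (collision-free at these rates)."""
        reads, truth = simulate_ccs_reads(small_refs, n_reads=100, seed=6, p_reverse=0.0)
        total_injected = truth.total_errors()
        total_recovered = 0
        by_id = {r.id: r.bases for r in small_refs}
        for read, t in zip(reads, truth.records):
            aln = align_to_best_reference(read.bases, {t.template_id: by_id[t.template_id]})
            total_recovered += aln.n_errors
        # alignment may locally re-explain adjacent events, never inflate far
        assert total_recovered <= total_injected
        assert total_recovered >= 0.95 * total_injected


class TestErrorMixtureTruth:
    def test_injected_type_mixture_matches_configuration(self):
        refs = make_mock_references(6, length=800, divergence=0.1, seed=7)
        reads, truth = simulate_ccs_reads(refs, n_reads=1500, seed=8, p_reverse=0.0)
        totals = truth.totals_by_type()
        n = sum(totals.values())
        assert n > 5000
        for kind, expected in (("substitution", 0.509), ("insertion", 0.312), ("deletion", 0.179)):
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(totals[kind] / n - expected) < 3 * se

    def test_deleted_base_composition_recovered_by_alignment(self):
        refs = make_mock_references(4, length=800, divergence=0.1, seed=9)
        reads, truth = simulate_ccs_reads(refs, n_reads=1500, seed=10, p_reverse=0.0)
        alignments = [align_to_best_reference(r, refs) for r in reads]
        profile = tally_errors(alignments)
        fractions = profile.deletion_base_fractions
        n_del = profile.n_del
        assert n_del > 800
        for base, expected in (("G", 0.394), ("A", 0.243), ("C", 0.183), ("T", 0.180)):
            se = math.sqrt(expected * (1 - expected) / n_del)
            assert abs(fractions[base] - expected) < 4 * se  # alignment re-attribution slack

    def test_max_quality_cross_tab_recovered(self):
        refs = make_mock_references(4, length=300, divergence=0.1, seed=11)
        reads, _ = simulate_ccs_reads(refs, n_reads=600, seed=12, p_reverse=0.0)
        alignments = [align_to_best_reference(r, refs) for r in reads]
        profile = tally_errors(alignments, quals={r.id: r.quals for r in reads})
        observed = profile.max_quality_fraction
        for cls, expected in (("correct", 0.805), ("substitution", 0.800), ("insertion", 0.804)):
            n = profile.quality_positions[cls]
            assert n > 100
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(observed[cls] - expected) < 4 * se


class TestPredictedErrorModel:
    def test_predicted_error_anticorrelates_with_truth(self):
        refs = make_mock_references(4, length=400, divergence=0.1, seed=13)
        reads, truth = simulate_ccs_reads(refs, n_reads=600, seed=14, p_reverse=0.0)
        predicted = [r.predicted_error for r in reads]
        observed = [t.n_errors for t in truth.records]
        rho = spearmanr(predicted, observed).statistic
        assert rho > 0.3  # predicted tracks truth; Fig-style correlation
        # the screening threshold must retain a usable fraction of reads
        passing = np.mean([p <= 1e-4 for p in predicted])
        assert 0.2 < passing < 0.9

    def test_predicted_error_filter_lowers_observed_error_rate(self):
        refs = make_mock_references(4, length=400, divergence=0.1, seed=15)
        reads, _ = simulate_ccs_reads(refs, n_reads=800, seed=16, p_reverse=0.0)
        config = FilterConfig(max_homopolymer=None, filter_length=False, max_bc_mismatch=None,
                              max_primer_mismatch=None, min_passes=None, max_predicted_error=1e-4)
        kept, _ = screen(reads, config)
        assert 0 < len(kept) < len(reads)

        def pooled(records):
            errors = columns = 0
            for rec in records:
                aln = align_to_best_reference(rec, refs)
                errors += aln.n_errors
                columns += aln.n_columns
            return errors / columns

        assert pooled(kept) < pooled(reads)


class TestChimeraSimulation:
    def test_chimeric_reads_flagged_cleanly_at_zero_error(self):
        refs = make_mock_references(5, length=200, divergence=0.10, seed=17)
        model = ErrorModel(per_base_error_rate=0.0, chimera_rate=0.3)
        reads, truth = simulate_ccs_reads(refs, n_reads=150, model=model, seed=18, p_reverse=0.0)
        chimeras = enumerate_in_silico_chimeras(refs)
        by_id = {r.id: r.bases for r in refs}
        n_detectable = n_flagged_detectable = 0
        for read, t in zip(reads, truth.records):
            verdict = classify_chimeric(read.bases, refs, chimeras)
            if not t.is_chimera:
                assert verdict == "clean"
                continue
            left = sum(
                a != b for a, b in zip(by_id[t.parent_a][: t.breakpoint], by_id[t.parent_b][: t.breakpoint])
            )
            right = sum(
                a != b for a, b in zip(by_id[t.parent_a][t.breakpoint:], by_id[t.parent_b][t.breakpoint:])
            )
            if min(left, right) >= 3:  # parents divergent on both sides
                n_detectable += 1
                n_flagged_detectable += verdict == "chimeric"
        assert n_detectable > 10
        assert n_flagged_detectable == n_detectable
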