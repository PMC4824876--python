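from __future__ import annotations

import numpy as np
import pytest

from ccs16s.errprof import (
    align_to_best_reference,
    binomial_tail,
    classify_chimeric,
    enumerate_in_silico_chimeras,
    expected_error_free_fraction,
    tally_errors,
    variant_spectrum,
)
from ccs16s.simulate import ErrorModel, make_mock_references, simulate_ccs_reads

from _oracles import best_reference, enumerate_chimeras_equal_length, hw_distance
from conftest import random_seq


def mutate(rng, seq: str, positions: list[int]) -> str:
    out = list(seq)
    for pos in positions:
        out[pos] = next(b for b in "ACGT" if b != out[pos])
    return "".join(out)


class TestAlignToBestReference:
    def test_identical_read_has_zero_errors(self, small_refs):
        aln = align_to_best_reference(small_refs[2], small_refs)
        assert aln.best_ref_id == small_refs[2].id
        assert aln.n_errors == 0
        assert aln.error_rate == 0.0
        assert aln.n_match == len(small_refs[2].bases)

    def test_one_substitution_in_100nt(self, rng):
        ref = random_seq(rng, 100)
        read = mutate(rng, ref, [40])
        aln = align_to_best_reference(read, [ref])
        assert (aln.n_sub, aln.n_ins, aln.n_del) == (1, 0, 0)
        assert aln.error_rate == pytest.approx(0.01)

    def test_terminal_reference_overhang_is_free(self, rng):
        ref = random_seq(rng, 120)
        read = ref[20:100]  # interior slice aligns with free terminal gaps
        aln = align_to_best_reference(read, [ref])
        assert aln.n_errors == 0
        assert aln.n_columns == 80

    def test_counts_satisfy_read_length_identity(self, rng, small_refs):
        reads, _ = simulate_ccs_reads(small_refs, n_reads=30, seed=9, p_reverse=0.0)
        for read in reads:
            aln = align_to_best_reference(read, small_refs)
            assert aln.n_match + aln.n_sub + aln.n_ins == len(read.bases)

    def test_error_rate_consistent_with_own_alignment_strings(self, rng, small_refs):
        reads, _ = simulate_ccs_reads(small_refs, n_reads=20, seed=10, p_reverse=0.0)
        for read in reads:
            aln = align_to_best_reference(read, small_refs)
            n_err = sum(q != t for q, t in zip(aln.aligned_read, aln.aligned_ref))
            assert n_err == aln.n_errors
            assert aln.error_rate == pytest.approx(n_err / len(aln.aligned_read))

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        refs = [(f"ref_{i}", random_seq(rng, int(rng.integers(50, 80)))) for i in range(3)]
        read = random_seq(rng, 60)
        aln = align_to_best_reference(read, dict(refs))
        oracle_id, oracle_d = best_reference(read, refs)
        assert aln.n_errors == oracle_d
        # the winning reference must achieve the oracle distance (ties may
        # resolve to any minimizer of equal distance, first-wins by contract)
        d_chosen = hw_distance(read, dict(refs)[aln.best_ref_id])
        assert d_chosen == oracle_d
        first_minimizer = next(rid for rid, rseq in refs if hw_distance(read, rseq) == oracle_d)
        assert aln.best_ref_id == first_minimizer == oracle_id


class TestTallyErrors:
    def test_zero_error_set_flagged(self, small_refs):
        alignments = [align_to_best_reference(r, small_refs) for r in small_refs]
        profile = tally_errors(alignments)
        assert profile.n_errors == 0
        assert profile.type_fractions is None
        assert profile.deletion_base_fractions is None

    def test_single_deleted_guanine(self, rng):
        ref = "ACTGCA" + random_seq(rng, 40)
        read = ref[:3] + ref[4:]  # remove the G at position 3
        profile = tally_errors([align_to_best_reference(read, [ref])])
        assert profile.n_del == 1
        assert profile.deletion_bases == {"G": 1}

    def test_substitution_matrix_diagonal_empty(self, rng, small_refs):
        reads, _ = simulate_ccs_reads(small_refs, n_reads=200, seed=12, p_reverse=0.0)
        profile = tally_errors([align_to_best_reference(r, small_refs) for r in reads])
        for base, row in profile.substitution_matrix.items():
            assert base not in row


class TestChimeraEnumeration:
    def test_single_reference_empty(self):
        assert enumerate_in_silico_chimeras(["ACGTACGT"]) == []

    def test_identical_references_yield_nothing(self):
        assert enumerate_in_silico_chimeras({"a": "ACGTACGT", "b": "ACGTACGT"}) == []

    @pytest.mark.parametrize("seed", range(100))
    def test_products_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(1000 + seed)
        parent_a = random_seq(rng, 20)
        n_diffs = int(rng.integers(2, 5))
        # isolated substitutions (spacing >= 3) so no repeat-shift alignment
        # can re-explain them as indels
        positions = sorted(rng.choice(range(0, 20, 3), size=n_diffs, replace=False).tolist())
        parent_b = mutate(rng, parent_a, positions)
        chimeras = enumerate_in_silico_chimeras({"a": parent_a, "b": parent_b})
        got = {c.bases for c in chimeras}
        expected = enumerate_chimeras_equal_length([parent_a, parent_b])
        assert got == expected


@pytest.fixture(scope="module")
def divergent_pair():
    rng = np.random.default_rng(77)
    a = random_seq(rng, 120)
    # 4 differences on each side of the midpoint breakpoint
    left = sorted(rng.choice(range(0, 60), size=4, replace=False).tolist())
    right = sorted(rng.choice(range(60, 120), size=4, replace=False).tolist())
    b = mutate(rng, a, left + right)
    return a, b


class TestChimeraClassification:

    def test_reference_read_is_clean(self, divergent_pair):
        a, b = divergent_pair
        refs = {"a": a, "b": b}
        chimeras = enumerate_in_silico_chimeras(refs)
        assert classify_chimeric(a, refs, chimeras) == "clean"

    def test_perfect_bimera_is_flagged(self, divergent_pair):
        a, b = divergent_pair
        refs = {"a": a, "b": b}
        chimeras = enumerate_in_silico_chimeras(refs)
        read = a[:60] + b[60:]  # 4 nt from either parent
        assert classify_chimeric(read, refs, chimeras) == "chimeric"

    def test_two_nt_parents_stay_clean(self, rng):
        # parents differing by only 2 nt total: d_ref - d_chi <= 2 < 3
        a = random_seq(rng, 100)
        b = mutate(rng, a, [25, 75])
        refs = {"a": a, "b": b}
        chimeras = enumerate_in_silico_chimeras(refs)
        read = a[:50] + b[50:]
        assert classify_chimeric(read, refs, chimeras) == "clean"

    def test_symmetric_in_parent_order(self, divergent_pair):
        a, b = divergent_pair
        read = a[:60] + b[60:]
        for refs in ({"a": a, "b": b}, {"b": b, "a": a}):
            chimeras = enumerate_in_silico_chimeras(refs)
            assert classify_chimeric(read, refs, chimeras) == "chimeric"


class TestVariantSpectrum:
    def test_unique_variants_all_in_bin_one(self, rng, small_refs):
        # three distinct 1-nt substitution variants of one template
        template = small_refs[0].bases
        reads = [mutate(rng, template, [pos]) for pos in (10, 60, 110)]
        spectrum = variant_spectrum(reads, small_refs)
        assert spectrum.histogram == {1: 3}
        assert spectrum.fraction_singletons() == 1.0

    def test_recurrent_variant_binned_by_count(self, rng, small_refs):
        template = small_refs[0].bases
        reads = [mutate(rng, template, [42])] * 3
        spectrum = variant_spectrum(reads, small_refs)
        assert spectrum.histogram == {3: 1}
        assert spectrum.most_abundant_count == 3

    def test_injected_systematic_variant_rate_recovered(self, small_refs):
        model = ErrorModel(systematic_variant_rate=0.02, per_base_error_rate=0.002)
        reads, truth = simulate_ccs_reads(small_refs, n_reads=2000, model=model, seed=21, p_reverse=0.0)
        spectrum = variant_spectrum(reads, small_refs)
        injected = sum(
            1 for t in truth.records
            if t.n_errors == 1 and t.n_sub == 1 and t.template_id == small_refs[0].id
        )
        # the most abundant variant is the systematic one, ~2% of reads
        assert spectrum.most_abundant_count >= 0.8 * 0.02 * len(reads)
        assert spectrum.most_abundant_count <= injected


class TestBinomialErrorModel:
    def test_error_free_certain_at_zero_rate(self):
        assert expected_error_free_fraction(0.0, 1500) == 1.0

    def test_paper_scale_rate_gives_4_3_percent(self):
        # 0.21% per-base error over the full-length 1,500-nt gene
        assert round(expected_error_free_fraction(0.0021, 1500) * 100, 1) == 4.3

    def test_small_closed_form(self):
        assert expected_error_free_fraction(0.01, 2) == pytest.approx(0.9801)

    def test_tail_complements_exact_enumeration(self):
        # P(X >= 1) = 1 - (1-p)^n
        p, n = 0.003, 500
        assert binomial_tail(1, n, p) == pytest.approx(1 - (1 - p) ** n)
        assert binomial_tail(0, n, p) == 1.0
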