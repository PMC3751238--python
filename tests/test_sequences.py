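"""Sequence model, IO round trips, pairwise alignment and difference calling."""

from __future__ import annotations

import pytest
from hypothesis import given, strategies as st

from asebias.sequences import (
    Exome,
    Exon,
    IndelInterval,
    IndelSet,
    PairwiseAlignment,
    Variant,
    VariantSet,
    align_exon_pair,
    apply_variants,
    call_differences,
    diff_exomes,
    dual_masking_intervals,
    mask_indels,
    read_fasta,
    read_indels_tsv,
    read_variants_tsv,
    read_variants_vcf,
    swap_variants,
    write_fasta,
    write_indels_tsv,
    write_variants_tsv,
    write_variants_vcf,
)

from oracles import best_alignment_score


class TestFastaIO:
    def test_single_record(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">e1\nACGT\n")
        exome = read_fasta(p)
        assert len(exome) == 1
        assert exome["e1"].sequence == "ACGT"
        assert exome["e1"].length == 4

    def test_round_trip(self, tmp_path, small_exome):
        p = tmp_path / "rt.fasta"
        write_fasta(small_exome, p)
        assert read_fasta(p) == small_exome

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "lc.fasta"
        p.write_text(">e1\nacgt\n")
        assert read_fasta(p)["e1"].sequence == "ACGT"

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">e1\nACGT\n>e1\nAAAA\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)


class TestVariantIO:
    def test_tsv_round_trip_is_one_based(self, tmp_path):
        vs = VariantSet([Variant("e1", 0, "A", "G"), Variant("e1", 9, "C", "T", alt_pos=7)])
        p = tmp_path / "v.tsv"
        write_variants_tsv(vs, p)
        lines = p.read_text().splitlines()
        assert lines[1].startswith("e1\t1\t")  # 0-based 0 exported as 1
        assert read_variants_tsv(p) == vs

    def test_vcf_round_trip(self, tmp_path, small_exome):
        vs = VariantSet([Variant("e1", 2, "G", "T"), Variant("e2", 5, "G", "A")])
        p = tmp_path / "v.vcf"
        write_variants_vcf(vs, small_exome, p)
        assert read_variants_vcf(p) == vs

    def test_indel_tsv_round_trip(self, tmp_path):
        ivs = IndelSet([IndelInterval("e1", 3, 6, 0), IndelInterval("e2", 2, 2, 4)])
        p = tmp_path / "i.tsv"
        write_indels_tsv(ivs, p)
        assert read_indels_tsv(p) == ivs


class TestApplyVariants:
    def test_single_substitution(self):
        ref = Exome([Exon("e", "ACGT")])
        out = apply_variants(ref, VariantSet([Variant("e", 1, "C", "G")]))
        assert out["e"].sequence == "AGGT"

    def test_empty_set_is_identity(self, small_exome):
        assert apply_variants(small_exome, VariantSet()) == small_exome

    def test_two_variants_differ_at_exactly_two_positions(self):
        ref = Exome([Exon("e", "ACGTACGT")])
        vs = VariantSet([Variant("e", 2, "G", "A"), Variant("e", 6, "G", "C")])
        out = apply_variants(ref, vs)
        diffs = [
            i for i, (a, b) in enumerate(zip(ref["e"].sequence, out["e"].sequence))
            if a != b
        ]
        assert diffs == [2, 6]

    def test_ref_mismatch_names_site(self):
        ref = Exome([Exon("e", "ACGT")])
        with pytest.raises(ValueError, match="e:1"):
            apply_variants(ref, VariantSet([Variant("e", 1, "A", "G")]))

    @given(st.data())
    def test_swapped_variants_recover_reference(self, data):
        seq = data.draw(st.text(alphabet="ACGT", min_size=10, max_size=60))
        n_vars = data.draw(st.integers(0, 5))
        positions = data.draw(
            st.lists(st.integers(0, len(seq) - 1), min_size=n_vars,
                     max_size=n_vars, unique=True)
        )
        variants = []
        for p in positions:
            alt = data.draw(st.sampled_from([b for b in "ACGT" if b != seq[p]]))
            variants.append(Variant("e", p, seq[p], alt))
        ref = Exome([Exon("e", seq)])
        vs = VariantSet(variants)
        alt_exome = apply_variants(ref, vs)
        back = apply_variants(alt_exome, swap_variants(vs))
        assert back == ref


class TestAlignExonPair:
    def test_identical_sequences_gap_free(self):
        aln = align_exon_pair("ACGTACGT", "ACGTACGT")
        assert aln.aligned_a == aln.aligned_b == "ACGTACGT"
        assert aln.score == 8.0

    @pytest.mark.parametrize(
        "a,b",
        [("ACGTT", "ACTT"), ("ACGT", "AGGT"), ("AACCGG", "AAGG"), ("ACG", "TACGT")],
    )
    def test_score_is_optimal_by_enumeration(self, a, b):
        aln = align_exon_pair(a, b)
        assert aln.score == best_alignment_score(a, b)
        assert aln.sequence_a() == a and aln.sequence_b() == b

    def test_one_base_gap_example(self):
        aln = align_exon_pair("ACGTT", "ACTT")
        assert aln.aligned_a == "ACGTT"
        assert aln.aligned_b == "AC-TT"

    def test_mismatch_column_example(self):
        aln = align_exon_pair("ACGT", "AGGT")
        assert (aln.aligned_a, aln.aligned_b) == ("ACGT", "AGGT")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_exon_pair("", "ACGT")


class TestCallDifferences:
    def test_substitution_only(self):
        vs, ivs = call_differences(PairwiseAlignment("ACGT", "AGGT", 2.0), "e")
        assert [(v.pos, v.ref_base, v.alt_base) for v in vs] == [(1, "C", "G")]
        assert len(ivs) == 0

    def test_deletion_interval(self):
        vs, ivs = call_differences(PairwiseAlignment("ACGTT", "AC-TT", 1.0), "e")
        assert len(vs) == 0
        (iv,) = ivs
        assert (iv.start, iv.end, iv.alt_length) == (2, 3, 0)

    def test_identity_alignment_empty(self):
        vs, ivs = call_differences(PairwiseAlignment("ACGT", "ACGT", 4.0), "e")
        assert len(vs) == 0 and len(ivs) == 0

    def test_insertion_records_alt_coordinates(self):
        vs, ivs = call_differences(PairwiseAlignment("AC--GTGT", "ACTTGTCT", 0.0), "e")
        (iv,) = ivs
        assert (iv.start, iv.end, iv.alt_length) == (2, 2, 2)
        (v,) = vs
        assert (v.pos, v.alt_position) == (4, 6)

    def test_alignment_round_trip_recovers_sparse_variants(self, rng):
        """Aligning (ref, ref+SNVs) and calling differences recovers the
        variants exactly when sites are sparse (rate <= 0.02)."""
        for trial in range(10):
            n = 300
            seq = "".join(rng.choice(list("ACGT"), size=n))
            ref = Exome([Exon("e", seq)])
            positions = sorted(
                int(p) for p in rng.choice(n, size=max(1, int(n * 0.02)), replace=False)
            )
            variants = []
            for p in positions:
                alt = rng.choice([b for b in "ACGT" if b != seq[p]])
                variants.append(Variant("e", p, seq[p], str(alt)))
            vs = VariantSet(variants)
            alt_exome = apply_variants(ref, vs)
            got_vs, got_ivs = diff_exomes(ref, alt_exome)
            assert len(got_ivs) == 0
            assert got_vs == vs


class TestMaskIndels:
    def test_interval_masked(self):
        exome = Exome([Exon("e", "ACGTT")])
        out = mask_indels(exome, [IndelInterval("e", 2, 3, 0)])
        assert out["e"].sequence == "ACNTT"

    def test_empty_set_identity(self, small_exome):
        assert mask_indels(small_exome, []) == small_exome

    def test_out_of_bounds_rejected(self):
        exome = Exome([Exon("e", "ACGTT")])
        with pytest.raises(ValueError, match="out of bounds"):
            mask_indels(exome, [IndelInterval("e", 3, 9, 0)])

    def test_masked_position_blocks_exact_alignment(self):
        """N matches nothing: no zero-mismatch read can overlap a mask."""
        from asebias.aligner import find_hits

        exome = Exome([Exon("e", "ACGTTGCAATGC")])
        masked = mask_indels(exome, [IndelInterval("e", 5, 6, 0)])
        read = exome["e"].sequence[2:8]  # overlaps the masked base
        assert find_hits(read, masked, 0) == []
        clear = exome["e"].sequence[6:12]  # beyond the mask
        assert any(h.start == 6 for h in find_hits(clear, masked, 0))


class TestDualMasking:
    def test_deletion_masks_carrier_plus_junction(self):
        ref = Exome([Exon("e", "ACGTACGTACGT")])
        alt = Exome([Exon("e", "ACGTCGTACGT")])  # pos 4 'A' deleted
        indels = IndelSet([IndelInterval("e", 4, 5, 0)])
        ref_iv, alt_iv = dual_masking_intervals(indels, ref, alt)
        assert [(iv.start, iv.end) for iv in ref_iv] == [(4, 6)]
        assert [(iv.start, iv.end) for iv in alt_iv] == [(4, 5)]

    def test_insertion_masks_inserted_bases_plus_junction(self):
        ref = Exome([Exon("e", "ACGTACGT")])
        alt = Exome([Exon("e", "ACGTTTACGT")])  # TT inserted at pos 4
        indels = IndelSet([IndelInterval("e", 4, 4, 2)])
        ref_iv, alt_iv = dual_masking_intervals(indels, ref, alt)
        assert [(iv.start, iv.end) for iv in ref_iv] == [(4, 5)]
        assert [(iv.start, iv.end) for iv in alt_iv] == [(4, 7)]


class TestInvariantsAndValidation:
    def test_variant_set_rejects_duplicates(self):
        with pytest.raises(ValueError, match="duplicate"):
            VariantSet([Variant("e", 1, "A", "G"), Variant("e", 1, "A", "C")])

    def test_alt_position_shifts_across_indels(self):
        indels = IndelSet(
            [IndelInterval("e", 10, 14, 0), IndelInterval("e", 30, 30, 5)]
        )
        assert indels.alt_position("e", 5) == 5
        assert indels.alt_position("e", 20) == 16
        assert indels.alt_position("e", 40) == 41
        with pytest.raises(ValueError, match="inside an indel"):
            indels.alt_position("e", 12)

    def test_alignment_rejects_double_gap_column(self):
        with pytest.raises(ValueError):
            PairwiseAlignment("A-G", "A-G", 0.0)
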