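"""Motif/position/annotation tokenization, dictionaries, negatives and SNV150."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mutatt.encoding import (
    ALL_ANNOTATION_TOKENS,
    ALL_SNV_MOTIFS,
    ALPHABET,
    EncodedMutation,
    MotifToken,
    MUTATION_SYMBOLS,
    TumourCatalogue,
    annotation_token,
    build_dictionaries,
    encode_motif,
    inject_negatives,
    position_token,
    read_catalogue_tsv,
    snv150_features,
    tokenize_catalogue,
    write_catalogue_tsv,
    load_dictionaries,
    save_dictionaries,
    PAD_INDEX,
    UNK_INDEX,
)
from mutatt.variants import ReferenceWindow, SomaticVariant, VariantClass

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _snv(chrom, pos, ref, alt):
    return SomaticVariant("s", chrom, pos, ref, alt, VariantClass.SNV)


class TestMotifEncoding:
    def test_pyrimidine_snv(self):
        motif, ctx, strand = encode_motif(
            _snv("chr1", 11235813, "C", "T"), ReferenceWindow("chr1", 11235812, "ACG")
        )
        assert str(motif) == "A[C>T]G" and ctx == "ACG" and strand == "+"

    def test_purine_snv_is_reverse_complemented(self):
        # context CGT with the central G>A describes the same event as A[C>T]G
        motif, _, strand = encode_motif(
            _snv("chr1", 10, "G", "A"), ReferenceWindow("chr1", 9, "CGT")
        )
        assert str(motif) == "A[C>T]G" and strand == "-"

    def test_diadenine_deletion_preceded_by_cytosine(self):
        variant = SomaticVariant("s", "chr1", 9, "CAA", "C", VariantClass.DEL)
        window = ReferenceWindow("chr1", 6, "TTTCAAGG")  # pos 9 = C, deletes AA at 10-11
        motif, ctx, _ = encode_motif(variant, window)
        assert str(motif) == "C[del A][del A]"

    def test_single_base_deletion_is_centred(self):
        variant = SomaticVariant("s", "chr1", 9, "TC", "T", VariantClass.DEL)
        window = ReferenceWindow("chr1", 7, "ATTCCAA")
        assert str(encode_motif(variant, window)[0]) == "T[del C]C"

    def test_insertion_layouts(self):
        window = ReferenceWindow("chr1", 8, "GTACC")
        one = SomaticVariant("s", "chr1", 9, "T", "TG", VariantClass.INS)
        assert str(encode_motif(one, window)[0]) == "T[ins G]A"
        three = SomaticVariant("s", "chr1", 9, "T", "TTTT", VariantClass.INS)
        assert str(encode_motif(three, window)[0]) == "[ins T][ins T][ins T]"

    def test_sv_breakpoint_with_colocated_substitution(self):
        variant = SomaticVariant("s", "chr1", 10, "A", "<DEL>", VariantClass.SV_DEL)
        window = ReferenceWindow("chr1", 8, "GCACT")  # 3' of breakend: C (pos 11), T (pos 12)
        motif, _, _ = encode_motif(variant, window, colocated={1: "[C>G]"})
        assert str(motif) == "[SV_del][C>G]T"
        plain, _, _ = encode_motif(variant, window)
        assert str(plain) == "[SV_del]CT"

    def test_mnv_prefers_pyrimidine_first_orientation(self):
        # CC>TT qualifies forward (first ref C); reverse (GG>AA) does not
        variant = SomaticVariant("s", "chr1", 10, "CC", "TT", VariantClass.MNV)
        window = ReferenceWindow("chr1", 8, "GCCCTA")
        assert str(encode_motif(variant, window)[0]) == "C[C>T][C>T]"

    def test_mnv_purine_first_uses_reverse_orientation(self):
        # GA>TC forward starts with a purine; reverse complement TC>GA qualifies
        variant = SomaticVariant("s", "chr1", 10, "GA", "TC", VariantClass.MNV)
        window = ReferenceWindow("chr1", 8, "AGGAC")
        motif, _, strand = encode_motif(variant, window)
        assert strand == "-"
        assert str(motif).startswith("G[T>G]")  # rc(GA)=TC -> first sub T>G

    def test_n_in_required_context_raises(self):
        from mutatt.encoding import EncodingError

        with pytest.raises(EncodingError):
            encode_motif(_snv("chr1", 2, "C", "T"), ReferenceWindow("chr1", 1, "NCG"))

    def test_reference_mismatch_raises(self):
        from mutatt.encoding import EncodingError

        with pytest.raises(EncodingError):
            encode_motif(_snv("chr1", 2, "C", "T"), ReferenceWindow("chr1", 1, "AAG"))

    @given(
        left=st.sampled_from("ACGT"),
        right=st.sampled_from("ACGT"),
        ref=st.sampled_from("ACGT"),
        alt_shift=st.integers(1, 3),
    )
    def test_reverse_complement_invariance(self, left, right, ref, alt_shift):
        """The same substitution described on either strand encodes identically."""
        bases = "ACGT"
        alt = bases[(bases.index(ref) + alt_shift) % 4]
        fwd = encode_motif(_snv("chr1", 2, ref, alt), ReferenceWindow("chr1", 1, f"{left}{ref}{right}"))
        rev_window = f"{COMP[right]}{COMP[ref]}{COMP[left]}"
        rev = encode_motif(
            _snv("chr1", 2, COMP[ref], COMP[alt]), ReferenceWindow("chr1", 1, rev_window)
        )
        assert str(fwd[0]) == str(rev[0])

    @given(st.tuples(*[st.sampled_from(ALPHABET)] * 3))
    def test_motif_parse_serialize_roundtrip(self, symbols):
        token = MotifToken(symbols)
        assert MotifToken.parse(str(token)) == token


class TestPositionToken:
    def test_printed_examples(self):
        assert position_token("chr1", 11235813) == "chr1_11"
        assert position_token("chr1", 11000000) == "chr1_11"
        assert position_token("chr1", 11999999) == "chr1_11"
        assert position_token("chr2", 999999) == "chr2_0"

    @given(st.integers(1, 10**9), st.integers(0, 10**6 - 1))
    def test_constant_within_megabase(self, pos, offset):
        bin_start = (pos // 10**6) * 10**6
        other = max(1, bin_start + offset)
        assert position_token("chrX", pos) == position_token("chrX", other)

    @given(st.integers(1, 999))
    def test_changes_exactly_at_megabase_multiples(self, k):
        boundary = k * 10**6
        assert position_token("chr1", boundary - 1) == f"chr1_{k - 1}"
        assert position_token("chr1", boundary) == f"chr1_{k}"


class TestAnnotationToken:
    def test_examples(self):
        assert annotation_token(False, False, set(), "+").endswith("intergenic")
        assert annotation_token(True, True, {"+"}, "+").endswith("same")
        assert annotation_token(True, False, {"+", "-"}, "-").endswith("both")
        assert annotation_token(True, False, {"-"}, "+").endswith("opposite")

    def test_space_has_exactly_16_members(self):
        assert len(ALL_ANNOTATION_TOKENS) == len(set(ALL_ANNOTATION_TOKENS)) == 16

    @given(
        genic=st.booleans(), exonic=st.booleans(),
        strands=st.sets(st.sampled_from("+-")),
        pyr=st.sampled_from("+-"),
    )
    def test_every_generated_token_is_in_the_space(self, genic, exonic, strands, pyr):
        assert annotation_token(genic, exonic, strands if genic else set(), pyr) in ALL_ANNOTATION_TOKENS


def _mutation(motif="A[C>T]G", pos_tok="chr1_0", var_class=VariantClass.SNV, ref_ctx="ACG",
              negative=False):
    return EncodedMutation(motif, pos_tok, ALL_ANNOTATION_TOKENS[0], var_class,
                           is_negative=negative, ref_context=ref_ctx)


class TestDictionaries:
    def test_observed_mode_counts_distinct_tokens(self):
        cat = TumourCatalogue("s", [_mutation(), _mutation()])
        dicts = build_dictionaries([cat])
        assert dicts["motif"].n_real_tokens == 1
        assert dicts["position"].n_real_tokens == 1
        assert dicts["annotation"].n_real_tokens == 16

    def test_enumerate_snv_seeds_96_motifs(self):
        cat = TumourCatalogue("s", [_mutation()])
        dicts = build_dictionaries([cat], mode="enumerate_snv")
        assert dicts["motif"].n_real_tokens == 96
        assert len(ALL_SNV_MOTIFS) == 96

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            build_dictionaries([])
        with pytest.raises(ValueError):
            build_dictionaries([TumourCatalogue("s", [])])

    def test_unseen_tokens_map_to_unk_and_are_counted(self):
        dicts = build_dictionaries([TumourCatalogue("s", [_mutation()])])
        other = TumourCatalogue("t", [_mutation(motif="T[T>A]T", pos_tok="chr9_5")])
        tc = tokenize_catalogue(other, dicts)
        assert tc.motif_idx[0] == UNK_INDEX and tc.position_idx[0] == UNK_INDEX
        assert dicts["motif"].unk_count == 1 and dicts["position"].unk_count == 1

    def test_empty_catalogue_tokenizes_to_empty(self):
        dicts = build_dictionaries([TumourCatalogue("s", [_mutation()])])
        tc = tokenize_catalogue(TumourCatalogue("empty", []), dicts)
        assert len(tc) == 0

    def test_json_roundtrip(self, tmp_path):
        dicts = build_dictionaries([TumourCatalogue("s", [_mutation()])])
        save_dictionaries(dicts, tmp_path / "dicts.json")
        loaded = load_dictionaries(tmp_path / "dicts.json")
        assert {k: d.token_to_index for k, d in loaded.items()} == {
            k: d.token_to_index for k, d in dicts.items()
        }
        assert loaded["motif"].token(PAD_INDEX) == "<PAD>"


class TestInjectNegatives:
    def _cohort(self, snv_counts, indel_counts):
        cats = []
        for i, (ns, ni) in enumerate(zip(snv_counts, indel_counts)):
            muts = [_mutation() for _ in range(ns)]
            muts += [_mutation(motif="T[del C]C", var_class=VariantClass.DEL, ref_ctx="TCC")
                     for _ in range(ni)]
            cats.append(TumourCatalogue(f"s{i}", muts))
        return cats

    def test_sum_of_medians_added_per_tumour(self):
        cats = self._cohort([3, 3, 3], [2, 2, 2])
        out = inject_negatives(cats, seed=0)
        for cat in out:
            negs = [m for m in cat.mutations if m.is_negative]
            assert len(negs) == 5
            assert all(MotifToken.parse(m.motif).is_pure_reference for m in negs)

    def test_negatives_come_from_other_tumours_reference_context(self):
        cats = self._cohort([2, 2], [0, 0])
        out = inject_negatives(cats, seed=1)
        for cat in out:
            for m in cat.mutations:
                if m.is_negative:
                    assert m.motif == m.ref_context == "ACG"

    def test_zero_medians_add_nothing(self):
        cats = [TumourCatalogue("a", []), TumourCatalogue("b", [])]
        out = inject_negatives(cats, seed=0)
        assert all(not c.mutations for c in out)

    def test_single_tumour_dataset_rejected(self):
        with pytest.raises(ValueError):
            inject_negatives([TumourCatalogue("a", [_mutation()])], seed=0)


class TestSnv150:
    def test_single_snv_block_sums(self):
        vec = snv150_features(TumourCatalogue("s", [_mutation()]))
        assert vec.sum() == 4
        assert vec[:6].sum() == 1 and vec[6:54].sum() == 2 and vec[54:].sum() == 1
        assert len(vec) == 150

    def test_empty_catalogue_gives_zero_vector(self):
        assert snv150_features(TumourCatalogue("s", [])).sum() == 0

    def test_non_snvs_and_negatives_excluded(self):
        cat = TumourCatalogue("s", [
            _mutation(),
            _mutation(motif="T[del C]C", var_class=VariantClass.DEL),
            _mutation(negative=True),
        ])
        assert snv150_features(cat)[:6].sum() == 1

    @given(st.lists(st.sampled_from(ALL_SNV_MOTIFS), min_size=0, max_size=40))
    def test_block_sums_scale_with_snv_count(self, motifs):
        cat = TumourCatalogue("s", [_mutation(motif=m) for m in motifs])
        vec = snv150_features(cat)
        n = len(motifs)
        assert vec[:6].sum() == n and vec[6:54].sum() == 2 * n and vec[54:].sum() == n


def test_catalogue_tsv_roundtrip_bit_exact(tmp_path, small_catalogues):
    cat = small_catalogues[0]
    path = tmp_path / "cat.tsv"
    write_catalogue_tsv(cat, path)
    loaded = read_catalogue_tsv(path)
    assert loaded.sample_id == cat.sample_id
    assert loaded.class_label == cat.class_label
    assert loaded.mutations == cat.mutations
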