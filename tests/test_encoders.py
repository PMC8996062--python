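"""Encoder correctness: hand-computed values, oracle equivalence, contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from essmir.encoders import (
    BatchEncodingError,
    EncodingError,
    FeatureMatrix,
    KmerEncoder,
    MismatchEncoder,
    PseDsspcEncoder,
    SubsequenceEncoder,
    TripletEncoder,
    batch_encode,
    kmer_names,
    make_encoder,
)
from essmir.fixtures import hairpin_rna
from essmir.io import RnaSequence
from essmir.structure import SecondaryStructure, assign_status

from oracles import (
    kmer_freq_oracle,
    mismatch_oracle,
    psedsspc_oracle,
    subsequence_oracle,
    triplet_oracle,
)

rna_text = st.text(alphabet="ACGU", min_size=1, max_size=12)


def vec(enc, residues, struct=None):
    return enc.encode(RnaSequence("t", residues), struct)


def named(enc, residues, struct=None):
    return dict(zip(enc.feature_names(), vec(enc, residues, struct)))


class TestKmer:
    def test_uniform_single_coverage(self):
        assert vec(KmerEncoder(k=1), "ACGU").tolist() == [0.25] * 4

    def test_single_type(self):
        v = named(KmerEncoder(k=2), "AAAA")
        assert v["AA"] == 1.0 and sum(v.values()) == 1.0

    def test_hand_enumerated_windows(self):
        v = named(KmerEncoder(k=2), "ACAC")
        assert v["AC"] == pytest.approx(2 / 3)
        assert v["CA"] == pytest.approx(1 / 3)

    def test_too_short_names_id_and_lengths(self):
        with pytest.raises(EncodingError, match=r"'t'.*3.*4"):
            vec(KmerEncoder(k=4), "ACG")

    @given(residues=rna_text, k=st.integers(1, 6))
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_matches_enumeration_oracle(self, residues, k):
        if len(residues) < k:
            return
        got = vec(KmerEncoder(k=k), residues)
        assert np.allclose(got, kmer_freq_oracle(residues, k), atol=1e-12)
        assert got.sum() == pytest.approx(1.0)


class TestMismatch:
    def test_hand_enumerated_two_windows(self):
        v = named(MismatchEncoder(k=2, m=1), "ACG")
        assert v["AC"] == 1.0  # AC exact; CG at distance 2 excluded
        assert v["AG"] == 2.0  # AC and CG each at distance 1

    def test_homopolymer_neighborhood(self):
        v = named(MismatchEncoder(k=2, m=1), "AAAA")
        assert v["AA"] == 3.0
        for t in ("AC", "AG", "AU", "CA", "GA", "UA"):
            assert v[t] == 3.0
        for t in ("CC", "CG", "GU", "UG"):
            assert v[t] == 0.0

    def test_zero_mismatch_equals_kmer_counts_exactly(self, rng):
        from conftest import random_residues
        from oracles import kmer_count_oracle

        for _ in range(20):
            residues = random_residues(rng, int(rng.integers(4, 30)))
            for k in (1, 2, 3):
                counts = vec(MismatchEncoder(k=k, m=0), residues)
                oracle = kmer_count_oracle(residues, k)
                assert counts.tolist() == [oracle[t] for t in sorted(oracle)]

    @given(residues=rna_text, k=st.integers(1, 4), m=st.integers(0, 3))
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_matches_hamming_oracle(self, residues, k, m):
        if len(residues) < k or m > k - 1:
            return
        got = vec(MismatchEncoder(k=k, m=m), residues)
        assert np.allclose(got, mismatch_oracle(residues, k, m), atol=1e-12)

    def test_m_out_of_range(self):
        with pytest.raises(ValueError, match="m must"):
            vec(MismatchEncoder(k=2, m=2), "ACGU")


class TestSubsequence:
    def test_hand_enumerated_tuples(self):
        v = named(SubsequenceEncoder(k=2, delta=0.5), "ACA")
        assert v["AC"] == pytest.approx(1.0)
        assert v["CA"] == pytest.approx(1.0)
        assert v["AA"] == pytest.approx(0.125)  # tuple (1,3), span 3

    def test_gapped_plus_contiguous_accumulation(self):
        v = named(SubsequenceEncoder(k=2, delta=0.5), "AAA")
        assert v["AA"] == pytest.approx(2.125)

    def test_zero_delta_equals_kmer_counts_exactly(self, rng):
        from conftest import random_residues
        from oracles import kmer_count_oracle

        for _ in range(20):
            residues = random_residues(rng, int(rng.integers(4, 25)))
            for k in (2, 3):
                got = vec(SubsequenceEncoder(k=k, delta=0.0), residues)
                oracle = kmer_count_oracle(residues, k)
                assert got.tolist() == [oracle[t] for t in sorted(oracle)]

    @given(
        residues=rna_text,
        k=st.integers(1, 4),
        delta=st.sampled_from([0.0, 0.1, 0.5, 0.9, 1.0]),
    )
    @settings(max_examples=120, derandomize=True, deadline=None)
    def test_matches_tuple_enumeration_oracle(self, residues, k, delta):
        if len(residues) < k:
            return
        got = vec(SubsequenceEncoder(k=k, delta=delta), residues)
        assert np.allclose(got, subsequence_oracle(residues, k, delta), atol=1e-12)

    def test_delta_out_of_range(self):
        with pytest.raises(ValueError, match="delta"):
            vec(SubsequenceEncoder(k=2, delta=1.5), "ACGU")


class TestTriplet:
    def test_all_unpaired_mass(self):
        v = named(TripletEncoder(), "ACGU", SecondaryStructure.from_brackets("...."))
        assert v["C..."] == 0.5 and v["G..."] == 0.5
        assert sum(v.values()) == pytest.approx(1.0)

    def test_hand_enumerated_hairpin_windows(self):
        v = named(TripletEncoder(), "GAAC", SecondaryStructure.from_brackets("(..)"))
        assert v["A(.."] == 0.5  # i=2: pattern (paired, unpaired, unpaired)
        assert v["A..("] == 0.5  # i=3: pattern (unpaired, unpaired, paired)

    def test_dimension_and_unit_sum_on_random_hairpins(self):
        for seed in range(5):
            seq, struct = hairpin_rna(stem_len=5, loop_len=6, seed=seed)
            v = TripletEncoder().encode(seq, struct)
            assert v.shape == (32,)
            assert v.sum() == pytest.approx(1.0)
            assert np.allclose(v, triplet_oracle(seq.residues, struct.brackets), atol=1e-12)

    def test_requires_length_three(self):
        with pytest.raises(EncodingError):
            vec(TripletEncoder(), "AC", SecondaryStructure.from_brackets(".."))


class TestPseDsspc:
    def test_unpaired_homopolymer_hand_computation(self):
        enc = PseDsspcEncoder(d=1, lam=1, w=0.5)
        v = named(enc, "A" * 10, SecondaryStructure.from_brackets("." * 10))
        assert v["A"] == pytest.approx(0.5)
        assert v["A|A@1"] == pytest.approx(0.5)
        assert v["tier1"] == 0.0

    @pytest.mark.parametrize("d,lam,expected", [(5, 5, 515), (1, 1, 111), (10, 20, 1030)])
    def test_dimension_formula(self, d, lam, expected):
        assert PseDsspcEncoder(d=d, lam=lam).dim == expected

    def test_constant_energy_gives_zero_tiers(self):
        enc = PseDsspcEncoder(d=2, lam=3, w=0.3)
        v = named(enc, "ACGUACGUAC", SecondaryStructure.from_brackets("." * 10))
        assert all(v[f"tier{k}"] == 0.0 for k in (1, 2, 3))

    def test_unit_sum_under_weighting(self):
        for seed in range(5):
            seq, struct = hairpin_rna(stem_len=7, loop_len=6, seed=seed)
            v = PseDsspcEncoder(d=3, lam=4, w=0.7).encode(seq, struct)
            assert v.sum() == pytest.approx(1.0)

    def test_matches_direct_oracle_on_hairpins(self):
        for seed in range(8):
            seq, struct = hairpin_rna(stem_len=5, loop_len=5, seed=seed)
            track = assign_status(seq, struct)
            for d, lam, w in [(1, 1, 0.5), (3, 4, 0.2), (5, 2, 0.9)]:
                got = PseDsspcEncoder(d=d, lam=lam, w=w).encode(seq, struct)
                want = psedsspc_oracle(
                    list(track.status), list(track.energy), d, lam, w
                )
                assert np.allclose(got, want, atol=1e-12)

    def test_too_short_for_blocks(self):
        with pytest.raises(EncodingError, match="max"):
            PseDsspcEncoder(d=6, lam=2).encode(
                RnaSequence("t", "ACGUA"), SecondaryStructure.from_brackets(".....")
            )

    def test_w_out_of_range(self):
        with pytest.raises(ValueError, match="w must"):
            PseDsspcEncoder(d=1, lam=1, w=0.0).encode(
                RnaSequence("t", "ACGUACGU"), SecondaryStructure.from_brackets("." * 8)
            )


class TestDimensionContract:
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
    def test_spectrum_dims(self, k):
        assert KmerEncoder(k=k).dim == 4**k == len(kmer_names(k))
        assert MismatchEncoder(k=k, m=0).dim == 4**k
        assert SubsequenceEncoder(k=k, delta=0.5).dim == 4**k

    def test_emitted_vectors_match_dim(self):
        seq, struct = hairpin_rna(stem_len=6, loop_len=6, seed=0)
        for enc in (
            KmerEncoder(k=3),
            MismatchEncoder(k=2, m=1),
            SubsequenceEncoder(k=2, delta=0.9),
            TripletEncoder(),
            PseDsspcEncoder(d=2, lam=2),
        ):
            assert enc.encode(seq, struct).shape == (enc.dim,)
            assert len(enc.feature_names()) == enc.dim


class TestBatchEncode:
    def test_matrix_shape_and_provenance(self, seq_factory):
        seqs = [seq_factory("ACGUACGU", f"s{i}") for i in range(3)]
        mat = batch_encode(seqs, KmerEncoder(k=2))
        assert mat.shape == (3, 16)
        assert mat.ids == ("s0", "s1", "s2")
        assert mat.provenance["scheme"] == "kmer" and mat.provenance["k"] == 2

    def test_short_sequence_fails_batch_naming_id(self, seq_factory):
        seqs = [seq_factory("ACGUACGU", "ok"), seq_factory("AC", "shorty")]
        with pytest.raises(BatchEncodingError, match="shorty"):
            batch_encode(seqs, KmerEncoder(k=3))

    def test_structural_scheme_uses_supplied_structures(self, seq_factory):
        seq, struct = hairpin_rna(stem_len=4, loop_len=4, seed=1, id="h")
        mat = batch_encode([seq], TripletEncoder(), {"h": struct})
        assert mat.shape == (1, 32)

    def test_tsv_roundtrip_of_values(self, tmp_path, seq_factory):
        seqs = [seq_factory("ACGUACGUAC", f"s{i}") for i in range(2)]
        mat = batch_encode(seqs, KmerEncoder(k=2))
        out = tmp_path / "feat.tsv"
        mat.to_tsv(out)
        lines = out.read_text().strip().split("\n")
        assert lines[0].startswith("# provenance:")
        assert lines[1].split("\t")[0] == "id"
        assert len(lines) == 4

    def test_sklearn_transform_surface(self, seq_factory):
        enc = KmerEncoder(k=2).fit()
        X = enc.transform(["ACGUACGU", seq_factory("GGCCGGCC")])
        assert X.shape == (2, 16)
        assert list(enc.get_feature_names_out()) == kmer_names(2)

    def test_make_encoder_validates_scheme(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            make_encoder("protein")
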