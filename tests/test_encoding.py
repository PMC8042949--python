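"""Unit and property tests of the SSC encoder."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sscppi import (
    CNKR1_PREFIX,
    DEFAULT_ALPHABET,
    EncodingConfig,
    NonstandardResidueError,
    STANDARD_RESIDUES,
    SequenceLengthError,
    decode_residue,
    encode_bigram,
    encode_interaction,
    encode_residue,
    encode_sequence_channels,
    one_hot_encode,
    residue_frequencies,
)
from sscppi.encoding import AminoAcidAlphabet

sequences = st.text(alphabet=STANDARD_RESIDUES, min_size=20, max_size=60)


class TestAlphabet:
    def test_alphabetical_ordering_pins_worked_indices(self):
        # M -> 10 and E -> 3 are what make the published M-E / E-M bigram
        # codes come out at 0.5075 / 0.1750
        assert DEFAULT_ALPHABET.index_of("M") == 10
        assert DEFAULT_ALPHABET.index_of("E") == 3
        assert "".join(DEFAULT_ALPHABET.ordered_residues) == "ACDEFGHIKLMNPQRSTVWY"

    def test_rejects_malformed_alphabets(self):
        with pytest.raises(ValueError):
            AminoAcidAlphabet("ACDEF")
        with pytest.raises(ValueError):
            AminoAcidAlphabet("A" * 20)


class TestResidueCodes:
    @pytest.mark.parametrize(
        "residue,expected",
        [("A", 0.0784), ("C", 0.1255), ("Y", 0.9725)],
    )
    def test_published_code_values(self, residue, expected):
        assert round(encode_residue(residue), 4) == expected

    def test_twenty_codes_distinct_increasing_in_unit_interval(self):
        codes = [encode_residue(r) for r in STANDARD_RESIDUES]
        assert len(set(codes)) == 20
        assert codes == sorted(codes)
        assert all(0 < c <= 1 for c in codes)

    def test_round_trip_decoding(self):
        for r in STANDARD_RESIDUES:
            assert decode_residue(encode_residue(r)) == r
        with pytest.raises(ValueError):
            decode_residue(0.0)  # padding is not a residue code

    def test_nonstandard_policy(self):
        with pytest.raises(NonstandardResidueError):
            encode_residue("X")
        assert encode_residue("X", nonstandard_policy="map_to_zero") == 0.0


class TestFrequencies:
    def test_worked_example(self):
        assert residue_frequencies("MEPVE") == {
            "M": 0.2,
            "E": 0.4,
            "P": 0.2,
            "V": 0.2,
        }

    def test_single_residue_sequence(self):
        assert residue_frequencies("AAAA") == {"A": 1.0}

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(SequenceLengthError):
            residue_frequencies("")

    @given(seq=sequences)
    @settings(max_examples=50, deadline=None)
    def test_fractions_sum_to_one(self, seq):
        assert sum(residue_frequencies(seq).values()) == pytest.approx(1.0)


class TestBigrams:
    def test_published_asymmetric_pair(self):
        assert round(encode_bigram("M", "E"), 4) == 0.5075
        assert round(encode_bigram("E", "M"), 4) == 0.1750

    def test_aa_bigram_collides_with_padding_by_design(self):
        assert encode_bigram("A", "A") == 0.0

    def test_400_distinct_ordered_codes(self):
        codes = {
            encode_bigram(x, y)
            for x in STANDARD_RESIDUES
            for y in STANDARD_RESIDUES
        }
        assert len(codes) == 400
        assert all(0 <= c < 1 for c in codes)

    @given(
        x=st.sampled_from(STANDARD_RESIDUES), y=st.sampled_from(STANDARD_RESIDUES)
    )
    @settings(max_examples=100, deadline=None)
    def test_asymmetry_on_distinct_residues(self, x, y):
        if x != y:
            assert encode_bigram(x, y) != encode_bigram(y, x)


class TestSequenceChannels:
    def test_cnkr1_prefix_worked_values(self, small_config):
        vecs = encode_sequence_channels(CNKR1_PREFIX, small_config)
        assert round(vecs[0, 0], 4) == 0.5490  # S1 code of M
        assert round(vecs[2, 0], 4) == 0.5075  # C code of the M-E bigram
        # S2 at position 0 is the frequency of M within the prefix
        assert vecs[1, 0] == pytest.approx(CNKR1_PREFIX.count("M") / 20)

    def test_uniform_sequence_has_unit_frequencies(self, small_config):
        vecs = encode_sequence_channels("A" * 20, small_config)
        assert np.all(vecs[1, :20] == 1.0)
        assert np.all(vecs[:, 20:] == 0.0)

    def test_last_occupied_context_slot_is_zero(self, small_config):
        seq = "MEPVETWTPGKVATWLRGLD"
        vecs = encode_sequence_channels(seq, small_config)
        assert vecs[2, len(seq) - 1] == 0.0
        assert vecs[2, len(seq) - 2] != 0.0

    def test_max_length_sequence_fills_all_slots(self, small_config, rng):
        seq = "".join(rng.choice(list(STANDARD_RESIDUES), size=small_config.max_len))
        vecs = encode_sequence_channels(seq, small_config)
        assert np.all(vecs[0] > 0)  # S1 has no padding at full length

    @pytest.mark.parametrize("n", [3, 33])
    def test_out_of_range_length_names_the_filter(self, small_config, n):
        with pytest.raises(SequenceLengthError, match="length filter"):
            encode_sequence_channels("A" * n, small_config)


class TestInteractionTensor:
    def test_full_grid_from_two_max_length_sequences(self, rng):
        cfg = EncodingConfig()
        a = "".join(rng.choice(list(STANDARD_RESIDUES), size=1800))
        b = "".join(rng.choice(list(STANDARD_RESIDUES), size=1800))
        t = encode_interaction(a, b, cfg)
        assert t.shape == (60, 60, 3)
        assert t.flattened("S1").size == 3600
        assert np.all(t.flattened("S1") > 0)

    def test_pair_swap_centrosymmetry_for_s1_s2_only(self, small_config, rng):
        a = CNKR1_PREFIX
        b = "".join(rng.choice(list(STANDARD_RESIDUES), size=25))
        ab = encode_interaction(a, b, small_config)
        ba = encode_interaction(b, a, small_config)
        for ch in ("S1", "S2"):
            assert np.array_equal(ab.flattened(ch)[::-1], ba.flattened(ch))
        assert not np.array_equal(ab.flattened("C")[::-1], ba.flattened("C"))

    def test_only_degenerate_sequences_preserve_context_symmetry(
        self, small_config, fixtures
    ):
        # ordered bigrams are asymmetric, so even a palindrome breaks the
        # context channel's swap symmetry; the all-'A' homopolymer (every
        # bigram coding to 0) is the degenerate case that preserves it
        poly = fixtures["homopolymer_a"].sequence
        ab = encode_interaction(poly, poly, small_config)
        ba = encode_interaction(poly, poly, small_config)
        assert np.array_equal(ab.flattened("C")[::-1], ba.flattened("C"))
        p = fixtures["palindrome"].sequence
        pp = encode_interaction(p, p, small_config)
        assert not np.array_equal(pp.flattened("C")[::-1], pp.flattened("C"))

    def test_channel_subset_and_order(self, small_config):
        cfg = EncodingConfig(
            max_len=small_config.max_len,
            min_len=small_config.min_len,
            grid_side=small_config.grid_side,
            channels=("C", "S1"),  # canonicalised to (S1, C)
        )
        t = encode_interaction(CNKR1_PREFIX, CNKR1_PREFIX, cfg)
        assert t.channel_order == ("S1", "C")
        assert t.shape == (8, 8, 2)

    def test_length_error_names_offending_protein(self, small_config):
        with pytest.raises(SequenceLengthError, match="bad_prot"):
            encode_interaction(
                CNKR1_PREFIX, "AAA", small_config, pair_ids=("ok", "bad_prot")
            )

    @given(a=sequences, b=sequences)
    @settings(max_examples=25, deadline=None)
    def test_all_cells_in_unit_interval_and_deterministic(self, a, b):
        cfg = EncodingConfig(max_len=72, min_len=4, grid_side=12)
        t1 = encode_interaction(a, b, cfg)
        t2 = encode_interaction(a, b, cfg)
        assert np.array_equal(t1.values, t2.values)
        assert t1.values.min() >= 0.0 and t1.values.max() <= 1.0

    def test_config_invariant_enforced(self):
        with pytest.raises(ValueError):
            EncodingConfig(max_len=100, grid_side=60)
        with pytest.raises(ValueError):
            EncodingConfig(channels=("S2",))


class TestOneHot:
    def test_single_residue(self):
        m = one_hot_encode("A")
        assert m.values.shape == (1, 20)
        assert m.values[0, 0] == 1 and m.values.sum() == 1

    def test_worked_column_indices(self):
        m = one_hot_encode("MEPVE")
        assert np.argmax(m.values, axis=1).tolist() == [10, 3, 12, 17, 3]
        assert np.all(m.values.sum(axis=1) == 1)

    def test_sparsity_is_95_percent(self, rng):
        seq = "".join(rng.choice(list(STANDARD_RESIDUES), size=200))
        m = one_hot_encode(seq)
        assert np.mean(m.values == 0) == pytest.approx(0.95)
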