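"""Encoding schemes: dimensions, worked examples, normalization identities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ptmgan.aadata import AMINO_ACIDS, FOLDAMYLOID_PACKING
from ptmgan.encoders import (
    DEFAULT_PROPERTY_TABLE,
    FeatureEncoder,
    StructureTable,
    STRUCTURE_CHANNELS,
    encode_aaindex,
    encode_binary,
    encode_cksaap,
    encode_foldamyloid,
    encode_pc_pseaac,
    encode_pwm,
    encode_reduced_alphabet,
    encode_sc_pseaac,
    encode_structure,
    fit_pwm,
)
from ptmgan.fragments import Fragment

SEQ = "ACDEFGHIKLMNPQRST"
HOMO_K = "A" * 8 + "K" + "A" * 8

fragment_seqs = st.builds(
    lambda s: s[:8] + "K" + s[9:],
    st.text(alphabet=AMINO_ACIDS, min_size=17, max_size=17),
)


@pytest.mark.parametrize(
    "encode,dim",
    [
        (encode_aaindex, 238),
        (encode_cksaap, 1200),
        (encode_reduced_alphabet, 136),
        (encode_foldamyloid, 17),
        (encode_binary, 340),
        (encode_pc_pseaac, 36),
        (encode_sc_pseaac, 52),
    ],
)
def test_scheme_dimensions(encode, dim):
    block = encode(SEQ)
    assert len(block.values) == dim
    assert len(block.tags) == dim


def test_full_and_sequence_only_dimensions(small_corpus):
    ds, struct = small_corpus
    full = FeatureEncoder(structure=struct).fit_transform(ds.fragments[:3])
    seq_only = FeatureEncoder().fit_transform(ds.fragments[:3])
    assert full.n_features == 2359
    assert seq_only.n_features == 2036
    block_sizes = full.provenance.groupby("scheme").size().to_dict()
    assert block_sizes == {
        "AAindex": 238, "CKSAAP": 1200, "PWM": 17, "ReducedAlphabet": 136,
        "FoldAmyloid": 17, "BE": 340, "PC-PseAAC": 36, "SC-PseAAC": 52,
        "Structure": 323,
    }
    # provenance covers every column exactly once, in fixed scheme order
    assert len(full.provenance) == 2359


class TestAAindex:
    def test_homopolymer_blocks_identical(self):
        vals = encode_aaindex("A" * 17).values.reshape(17, 14)
        assert np.allclose(vals, vals[0])

    def test_property_order_permutes_within_blocks(self):
        table = DEFAULT_PROPERTY_TABLE[list(DEFAULT_PROPERTY_TABLE.columns[::-1])]
        swapped = encode_aaindex(SEQ, table).values.reshape(17, 14)
        orig = encode_aaindex(SEQ).values.reshape(17, 14)
        assert np.allclose(swapped, orig[:, ::-1])

    def test_unknown_residue_errors(self):
        with pytest.raises(ValueError):
            encode_aaindex("X" * 8 + "K" + "A" * 8)


class TestCKSAAP:
    def test_adjacent_pair_frequencies(self):
        block = encode_cksaap(HOMO_K)
        k0 = dict(zip(block.tags[:400], block.values[:400]))
        assert k0["AA"] == pytest.approx(14 / 16)
        assert k0["AK"] == pytest.approx(1 / 16)
        assert k0["KA"] == pytest.approx(1 / 16)

    def test_gap_one_frequencies(self):
        block = encode_cksaap(HOMO_K)
        k1 = dict(zip(block.tags[400:800], block.values[400:800]))
        assert k1["A*A"] == pytest.approx(13 / 15)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(fragment_seqs)
    def test_each_k_block_sums_to_one(self, seq):
        v = encode_cksaap(seq).values
        for k in range(3):
            assert v[k * 400 : (k + 1) * 400].sum() == pytest.approx(1.0, abs=1e-9)

    def test_oversized_gap_errors(self):
        with pytest.raises(ValueError):
            encode_cksaap(SEQ, k_set=(16,))


class TestPWM:
    def test_identical_training_set_encodes_to_ones(self):
        pwm = fit_pwm([SEQ] * 5)
        assert np.allclose(encode_pwm(SEQ, pwm).values, 1.0)

    def test_two_everywhere_different_fragments(self):
        other = "CAEDGFIH" + "K" + "MLPNRQTS"
        assert all(a != b for a, b in zip(SEQ[:8] + SEQ[9:], other[:8] + other[9:]))
        pwm = fit_pwm([SEQ, other])
        vals = encode_pwm(SEQ, pwm).values
        assert np.allclose(np.delete(vals, 8), 0.5)
        assert vals[8] == 1.0  # shared central K

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.lists(fragment_seqs, min_size=1, max_size=8), fragment_seqs)
    def test_columns_sum_to_one_and_values_in_unit_interval(self, train, probe):
        pwm = fit_pwm(train)
        assert np.allclose(pwm.freqs.sum(axis=0), 1.0, atol=1e-9)
        vals = encode_pwm(probe, pwm).values
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            fit_pwm([])


class TestReducedAlphabet:
    def test_one_hot_sums(self):
        vals = encode_reduced_alphabet(SEQ).values
        assert set(np.unique(vals)) <= {0.0, 1.0}
        assert vals.sum() == 17

    def test_aspartate_maps_to_acid_group(self):
        block = encode_reduced_alphabet("D" * 8 + "K" + "D" * 8)
        assert block.values[block.tags.index("acid@-8")] == 1.0

    def test_lysine_and_arginine_share_group(self):
        k_block = encode_reduced_alphabet("K" * 17).values.reshape(17, 8)
        r_block = encode_reduced_alphabet("R" * 8 + "K" + "R" * 8).values.reshape(17, 8)
        assert np.array_equal(k_block[0], r_block[0])


class TestFoldAmyloid:
    def test_interior_positions_constant_on_homopolymer(self):
        vals = encode_foldamyloid("A" * 17).values
        assert np.allclose(vals[2:-2], vals[2])

    def test_window_one_reproduces_scale(self):
        vals = encode_foldamyloid(SEQ, window=1).values
        expected = [FOLDAMYLOID_PACKING[aa] for aa in SEQ]
        assert np.allclose(vals, expected)

    def test_binary_mode_thresholds(self):
        vals = encode_foldamyloid("V" * 8 + "K" + "P" * 8, binary=True).values
        assert set(np.unique(vals)) <= {0.0, 1.0}
        assert vals[0] == 1.0 and vals[-1] == 0.0  # V-rich dense, P-rich not


class TestBinaryEncoding:
    def test_one_hot_sum_and_first_coordinate(self):
        block = encode_binary("A" + "C" * 7 + "K" + "C" * 8)
        assert block.values.sum() == 17
        assert block.values[0] == 1.0  # 'A' alphabetically first at position 1

    def test_single_substitution_changes_two_coordinates(self):
        a = encode_binary(SEQ).values
        b = encode_binary("W" + SEQ[1:]).values
        assert int((a != b).sum()) == 2


class TestPseAAC:
    def test_homopolymer_parallel_correlation(self):
        vals = encode_pc_pseaac("A" * 17).values
        assert vals[0] == pytest.approx(1.0)
        assert np.allclose(vals[1:], 0.0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(fragment_seqs)
    def test_vectors_sum_to_one(self, seq):
        assert encode_pc_pseaac(seq).values.sum() == pytest.approx(1.0, abs=1e-9)
        assert encode_sc_pseaac(seq).values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_weight_recovers_pure_composition(self):
        vals = encode_sc_pseaac(SEQ, w=0.0).values
        assert np.allclose(vals[20:], 0.0)
        assert vals.sum() == pytest.approx(1.0)

    def test_lambda_bound(self):
        with pytest.raises(ValueError):
            encode_pc_pseaac(SEQ, lam=17)


class TestStructure:
    def _table(self, pid="P", n=25, fill=0.0):
        rows = [(pid, i + 1) + (fill,) * 19 for i in range(n)]
        return StructureTable(
            pd.DataFrame(rows, columns=["protein_id", "position", *STRUCTURE_CHANNELS])
        )

    def test_dimension_and_zero_table(self):
        frag = Fragment("P", 12, "A" * 8 + "K" + "A" * 8, frozenset(["Ace"]))
        block = encode_structure(frag, self._table())
        assert len(block.values) == 323
        assert np.allclose(block.values, 0.0)

    def test_missing_row_error_names_position(self):
        frag = Fragment("P", 12, "A" * 8 + "K" + "A" * 8, frozenset(["Ace"]))
        with pytest.raises(KeyError, match="20"):
            encode_structure(frag, self._table(n=19))


def test_encoding_is_pure(small_corpus):
    ds, struct = small_corpus
    enc = FeatureEncoder(structure=struct).fit(ds.fragments[:10])
    a = enc.transform(ds.fragments[:5])
    b = enc.transform(ds.fragments[:5])
    assert np.array_equal(a.X, b.X)
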