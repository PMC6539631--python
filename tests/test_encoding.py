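"""Tri-gram feature extraction: examples, oracle equivalence, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popmgram.encoding import (
    N_FEATURES,
    PopmTrigramEncoder,
    encode_dataset,
    encode_sequence,
    feature_name,
    flat_index,
    triple_from_flat,
    trigram_features,
)
from popmgram.properties import STANDARD_RESIDUES, build_popm

from conftest import random_sequence


def naive_trigram(M: np.ndarray) -> np.ndarray:
    """Independent brute-force evaluation of the tri-gram average."""
    L = M.shape[0]
    out = np.empty(1000)
    pos = 0
    for x in range(10):
        for y in range(10):
            for z in range(10):
                total = 0.0
                for i in range(L - 2):
                    total += M[i, x] * M[i + 1, y] * M[i + 2, z]
                out[pos] = total / (L - 2)
                pos += 1
    return out


def test_repeated_single_property_residue_gives_one_hot():
    # M is hydrophobic only: the (5,5,5) tri-gram is the lone hit
    v = encode_sequence("MMM")
    assert v[flat_index(5, 5, 5)] == 1.0
    assert v.sum() == 1.0


def test_ivl_example_support_and_mass():
    v = encode_sequence("IVL")
    hot = {triple_from_flat(i) for i in np.flatnonzero(v == 1.0)}
    expected = {
        (x, y, z) for x in (5, 6) for y in (5, 6, 8) for z in (5, 6)
    }
    assert hot == expected
    assert len(hot) == 12
    assert v.sum() == 12.0


def test_repeated_residue_with_k_properties_gives_k_cubed_ones():
    # V belongs to 3 groups -> 27 features equal to exactly 1
    v = encode_sequence("V" * 40)
    assert np.count_nonzero(v == 1.0) == 27
    assert np.count_nonzero(v) == 27


def test_too_short_sequence_rejected():
    with pytest.raises(ValueError, match="too short"):
        trigram_features(build_popm("MK", "short"))


@pytest.mark.parametrize(
    "triple, flat",
    [((1, 1, 1), 0), ((10, 10, 10), 999), ((5, 6, 8), 457)],
)
def test_flat_index_lexicographic(triple, flat):
    assert flat_index(*triple) == flat
    assert triple_from_flat(flat) == triple


def test_flat_index_out_of_range():
    with pytest.raises(ValueError):
        flat_index(0, 1, 1)
    with pytest.raises(ValueError):
        flat_index(1, 11, 1)


def test_feature_name_readable():
    assert feature_name(5, 6, 8) == "g_Hydrophobic_Aliphatic_Small"


def test_oracle_equivalence_and_factorization_identity():
    """Vectorized features match brute force; total mass factorizes
    as the mean of products of consecutive row sums."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        seq = random_sequence(rng, int(rng.integers(3, 61)))
        popm = build_popm(seq, "r")
        fast = trigram_features(popm)
        slow = naive_trigram(popm.matrix.astype(float))
        np.testing.assert_allclose(fast, slow, atol=1e-12)
        n = popm.matrix.sum(axis=1).astype(float)
        expected_mass = (n[:-2] * n[1:-1] * n[2:]).sum() / (popm.length - 2)
        assert abs(fast.sum() - expected_mass) < 1e-9


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet=STANDARD_RESIDUES, min_size=3, max_size=120))
def test_features_bounded_in_unit_interval(seq):
    v = encode_sequence(seq)
    assert v.shape == (N_FEATURES,)
    assert (v >= 0).all() and (v <= 1).all()


def test_long_sequence_stays_bounded():
    rng = np.random.default_rng(7)
    v = encode_sequence(random_sequence(rng, 5000))
    assert (v >= 0).all() and (v <= 1).all()


def test_paper_extreme_lengths_encode():
    # benchmark extremes: shortest 76, longest 3037 residues
    rng = np.random.default_rng(8)
    for L in (76, 3037):
        assert encode_sequence(random_sequence(rng, L)).shape == (N_FEATURES,)


def test_encode_dataset_shape_order_and_names(small_dataset):
    features = encode_dataset(small_dataset.sequences()[:5])
    assert features.shape == (5, N_FEATURES)
    assert list(features.index) == [r.id for r in small_dataset.records[:5]]
    assert features.columns[457] == "g_Hydrophobic_Aliphatic_Small"


def test_encode_dataset_row_sums_match_single_sequence_examples():
    features = encode_dataset([("m", "MMM"), ("i", "IVL")])
    np.testing.assert_allclose(features.sum(axis=1).values, [1.0, 12.0])


def test_encode_dataset_names_offending_short_sequence():
    with pytest.raises(ValueError, match="bad_seq"):
        encode_dataset([("ok", "MKLV"), ("bad_seq", "MK")])


def test_encoder_estimator_roundtrip(small_dataset):
    seqs = [r.sequence for r in small_dataset.records[:6]]
    enc = PopmTrigramEncoder().fit(seqs)
    X = enc.transform(seqs)
    assert X.shape == (6, N_FEATURES)
    np.testing.assert_array_equal(X[0], encode_sequence(seqs[0]))
    assert enc.get_feature_names_out()[0] == "g_Polar_Polar_Polar"


def test_encoder_standardize_switch(small_dataset):
    seqs = [r.sequence for r in small_dataset.records[:10]]
    enc = PopmTrigramEncoder(standardize=True).fit(seqs)
    X = enc.transform(seqs)
    varying = X.std(axis=0) > 0
    assert np.allclose(X[:, varying].mean(axis=0), 0, atol=1e-9)
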