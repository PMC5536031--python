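"""Feature encoding: profile x property spreads and sliding windows."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hotspot_rp import (
    AminoAcidIndex,
    PropertyTable,
    encode_dataset,
    encode_window,
    residue_features,
)
from hotspot_rp.encoding import feature_matrix
from hotspot_rp.errors import ConfigError


def brute_force_features(freqs, props):
    """Independent oracle: per-property population std of the 20 products."""
    out = []
    for record in props.indices:
        products = [freqs[i] * record.values[i] for i in range(20)]
        out.append(statistics.pstdev(products))
    return np.array(out)


def make_props(*value_rows):
    records = [
        AminoAcidIndex(f"PROP{i:04d}01", "", tuple(float(v) for v in row))
        for i, row in enumerate(value_rows)
    ]
    return PropertyTable.from_indices(records)


class TestResidueFeatures:
    def test_uniform_profile_constant_property_is_zero(self):
        props = make_props([7.0] * 20)
        features = residue_features(np.full(20, 0.05), props)
        np.testing.assert_allclose(features, [0.0], atol=1e-15)

    def test_delta_profile_matches_pstdev_oracle(self):
        values = list(range(1, 21))
        props = make_props(values)
        freqs = np.zeros(20)
        freqs[0] = 1.0
        expected = statistics.pstdev([values[0]] + [0.0] * 19)
        np.testing.assert_allclose(residue_features(freqs, props), [expected])

    def test_worked_fixture_matches_oracle_exactly(self, worked_corpus):
        sequences, props = worked_corpus
        for seq in sequences:
            for profile in seq.profiles:
                np.testing.assert_allclose(
                    residue_features(profile, props),
                    brute_force_features(profile.freqs, props),
                    rtol=1e-12,
                )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        scale=st.floats(-5, 5, allow_nan=False),
        seed=st.integers(0, 10_000),
    )
    def test_scaling_profile_scales_features_by_abs(self, scale, seed):
        rng = np.random.default_rng(seed)
        props = make_props(rng.standard_normal(20))
        freqs = rng.dirichlet(np.ones(20))
        base = residue_features(freqs, props)
        scaled = residue_features(freqs * scale, props)
        np.testing.assert_allclose(scaled, abs(scale) * base, atol=1e-12)

    def test_feature_matrix_agrees_with_per_residue(self, worked_corpus):
        sequences, props = worked_corpus
        seq = sequences[0]
        stacked = feature_matrix(seq.profile_matrix, props)
        for i, profile in enumerate(seq.profiles):
            np.testing.assert_allclose(stacked[i], residue_features(profile, props))


class TestWindows:
    def test_even_window_rejected(self, worked_corpus):
        sequences, props = worked_corpus
        with pytest.raises(ConfigError):
            encode_window(sequences[0], 1, props, window_length=4)

    def test_window_one_equals_center_features(self, worked_corpus):
        sequences, props = worked_corpus
        seq = sequences[0]
        instance = encode_window(seq, 3, props, window_length=1)
        np.testing.assert_allclose(
            instance.vector, residue_features(seq.profiles[2], props)
        )

    def test_terminal_window_zero_padded(self, worked_corpus):
        sequences, props = worked_corpus
        seq = sequences[0]
        J = props.n_properties
        instance = encode_window(seq, 1, props, window_length=13)
        assert instance.vector.shape == (13 * J,)
        np.testing.assert_array_equal(instance.vector[: 6 * J], 0.0)
        assert np.abs(instance.vector[6 * J :]).sum() > 0

    def test_interior_window_is_concatenation_of_features(self, worked_corpus):
        sequences, props = worked_corpus
        seq = sequences[0]
        instance = encode_window(seq, 8, props, window_length=5)
        expected = np.concatenate(
            [residue_features(seq.profiles[i], props) for i in range(5, 10)]
        )
        np.testing.assert_allclose(instance.vector, expected)


class TestEncodeDataset:
    def test_one_instance_per_residue(self, worked_corpus):
        sequences, props = worked_corpus
        dataset = encode_dataset(sequences, props, window_length=13)
        assert len(dataset) == sum(len(s) for s in sequences) == 30
        assert dataset.X.shape == (30, 13 * props.n_properties)
        assert dataset.y.sum() == 2

    def test_rows_match_encode_window(self, worked_corpus):
        sequences, props = worked_corpus
        dataset = encode_dataset(sequences, props, window_length=13)
        for row in (0, 7, 14, 29):
            seq_id, position = dataset.origins[row]
            seq = next(s for s in sequences if s.id == seq_id)
            instance = encode_window(seq, position, props, window_length=13)
            np.testing.assert_allclose(dataset.X[row], instance.vector)
            assert dataset.y[row] == instance.target

    def test_sequence_permutation_permutes_instances_only(self, worked_corpus):
        sequences, props = worked_corpus
        forward = encode_dataset(sequences, props, window_length=5)
        backward = encode_dataset(sequences[::-1], props, window_length=5)
        by_origin_fwd = dict(zip(forward.origins, map(tuple, forward.X)))
        by_origin_bwd = dict(zip(backward.origins, map(tuple, backward.X)))
        assert by_origin_fwd == by_origin_bwd

    def test_empty_input_gives_empty_output(self, worked_corpus):
        _, props = worked_corpus
        dataset = encode_dataset([], props, window_length=13)
        assert len(dataset) == 0
        assert dataset.X.shape == (0, 13 * props.n_properties)

    def test_feature_dump_roundtrip(self, worked_corpus, tmp_path):
        from hotspot_rp.encoding import read_features, write_features

        sequences, props = worked_corpus
        dataset = encode_dataset(sequences, props, window_length=3)
        path = tmp_path / "features.tsv"
        write_features(dataset, path)
        back = read_features(path)
        np.testing.assert_allclose(back.X, dataset.X, rtol=1e-9)
        np.testing.assert_array_equal(back.y, dataset.y)
        assert back.origins == dataset.origins
        assert back.window_length == 3
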