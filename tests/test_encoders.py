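"""Window geometry, encoder dimensional contracts, and the integrative profile."""

import numpy as np
import pandas as pd
import pytest

from pssmpp.aaindex import CANONICAL_AA_ORDER, PropertyScale, normalize_scale
from pssmpp.encoders import (
    EncoderContractError,
    OUT_OF_SEQUENCE,
    WindowSpec,
    build_feature_matrix,
    encode_binary,
    encode_pp,
    encode_pssm,
    encode_pssm_pp_concat,
    encode_pssmpp,
    encode_sample,
    feature_columns,
    window_positions,
    write_features_tsv,
)
from pssmpp.pssm import PSSMProfile, ResidueSample


def naive_pssmpp(profile, scales, sample, w):
    """Independent naive triple-loop computation of the integrative window."""
    half = w // 2
    vec = []
    for off in range(-half, half + 1):
        pos = sample.position + off
        if 1 <= pos <= profile.length:
            for scale in scales:
                total = 0.0
                for j in range(20):
                    total += scale.normalized_values[j] * profile.scaled[pos - 1, j]
                vec.append(total)
            vec.append(0.0)
        else:
            vec.extend([0.0] * len(scales))
            vec.append(1.0)
    return np.array(vec)


class TestWindowPositions:
    def test_leading_slots_out_of_sequence(self):
        slots = window_positions(1, 17, 100)
        assert slots[:8] == [OUT_OF_SEQUENCE] * 8
        assert slots[8:] == list(range(1, 10))

    def test_interior_window_fully_inside(self):
        assert window_positions(9, 17, 100) == list(range(1, 18))

    def test_trailing_slot_out_of_sequence(self):
        assert window_positions(50, 3, 50) == [49, 50, OUT_OF_SEQUENCE]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            window_positions(5, 4, 50)


@pytest.mark.parametrize("w", [1, 3, 17])
@pytest.mark.parametrize("n_scales", [1, 4])
@pytest.mark.parametrize(
    "encoder,dim",
    [
        ("binary", lambda w, p: 21 * w),
        ("pssm", lambda w, p: 21 * w),
        ("pp", lambda w, p: (p + 1) * w),
        ("pssmpp", lambda w, p: (p + 1) * w),
        ("pssm_pp_concat", lambda w, p: (20 + p + 1) * w),
    ],
)
def test_dimensional_contract(tiny_dataset, encoder, dim, w, n_scales):
    scales = tiny_dataset.scales[:n_scales]
    sample = tiny_dataset.samples[len(tiny_dataset.samples) // 2]
    profile = tiny_dataset.profiles[sample.chain_id]
    vec = encode_sample(encoder, profile, sample, WindowSpec(w), scales)
    expected = dim(w, n_scales)
    assert vec.shape == (expected,)
    assert feature_columns(encoder, WindowSpec(w), scales) == \
        feature_columns(encoder, WindowSpec(w), scales)
    assert len(feature_columns(encoder, WindowSpec(w), scales)) == expected


class TestPadding:
    def test_terminal_slot_all_zero_with_bit(self, tiny_dataset, four_scales):
        chain_id, profile = next(iter(tiny_dataset.profiles.items()))
        first = ResidueSample(chain_id, 1, 0)
        vec = encode_pssm(profile, first, WindowSpec(3))
        assert np.all(vec[:20] == 0.0) and vec[20] == 1.0
        vec = encode_pssmpp(profile, four_scales, first, WindowSpec(3))
        assert np.all(vec[:4] == 0.0) and vec[4] == 1.0
        vec = encode_pp(profile, four_scales, first, WindowSpec(3))
        assert np.all(vec[:4] == 0.0) and vec[4] == 1.0

    def test_in_sequence_slot_has_bit_zero(self, tiny_dataset):
        sample = tiny_dataset.samples[30]
        profile = tiny_dataset.profiles[sample.chain_id]
        vec = encode_pssm(profile, sample, WindowSpec(1))
        assert vec[20] == 0.0
        assert np.array_equal(vec[:20], profile.scaled[sample.position - 1])


class TestBinary:
    def test_one_hot_per_slot(self, tiny_dataset):
        sample = tiny_dataset.samples[40]
        profile = tiny_dataset.profiles[sample.chain_id]
        vec = encode_binary(profile, sample, WindowSpec(1))
        assert vec[:20].sum() == 1.0
        hot = int(np.argmax(vec[:20]))
        assert CANONICAL_AA_ORDER[hot] == profile.sequence[sample.position - 1]
        assert vec[20] == 0.0


class TestIntegrativeProfile:
    def test_two_scale_w1_toy_matches_direct_summation(self):
        log_odds = np.arange(20.0).reshape(1, 20) - 10.0
        profile = PSSMProfile.from_log_odds("toy", "A", log_odds)
        scales = [
            PropertyScale("TSTSYN0001", "t", np.arange(20.0),
                          normalize_scale(np.arange(20.0)), True),
            PropertyScale("TSTSYN0002", "t", np.arange(20.0)[::-1].copy(),
                          normalize_scale(np.arange(20.0)[::-1]), True),
        ]
        sample = ResidueSample("toy", 1, 0)
        vec = encode_pssmpp(profile, scales, sample, WindowSpec(1))
        for p, scale in enumerate(scales):
            direct = sum(
                scale.normalized_values[j] * profile.scaled[0, j] for j in range(20)
            )
            assert vec[p] == pytest.approx(direct, abs=1e-12)
        assert vec[2] == 0.0

    def test_uniform_scaled_row_yields_zero(self, four_scales):
        # constant log-odds row -> constant scaled row -> F_ip = c * sum(w_pj) ~ 0
        profile = PSSMProfile.from_log_odds("u", "G", np.full((1, 20), 2.0))
        vec = encode_pssmpp(profile, four_scales, ResidueSample("u", 1, 0), WindowSpec(1))
        assert np.all(np.abs(vec[:4]) < 1e-12)

    def test_matches_naive_triple_loop_on_random_fixtures(self, tiny_dataset):
        rng = np.random.default_rng(9)
        samples = list(tiny_dataset.samples)
        for _ in range(30):
            sample = samples[int(rng.integers(len(samples)))]
            profile = tiny_dataset.profiles[sample.chain_id]
            n_sc = int(rng.integers(1, 5))
            scales = tiny_dataset.scales[:n_sc]
            w = int(rng.choice([1, 3, 5, 17]))
            vec = encode_pssmpp(profile, scales, sample, WindowSpec(w))
            assert np.allclose(vec, naive_pssmpp(profile, scales, sample, w), atol=1e-12)

    def test_unnormalized_scale_rejected(self, tiny_dataset):
        raw = PropertyScale("TSTSYN0009", "raw", np.arange(20.0),
                            np.arange(20.0), True)  # not normalized
        sample = tiny_dataset.samples[0]
        profile = tiny_dataset.profiles[sample.chain_id]
        with pytest.raises(EncoderContractError):
            encode_pssmpp(profile, [raw], sample, WindowSpec(3))


def test_concat_equals_interleaved_sub_encoders(tiny_dataset, four_scales):
    sample = tiny_dataset.samples[25]
    profile = tiny_dataset.profiles[sample.chain_id]
    spec = WindowSpec(5)
    concat = encode_pssm_pp_concat(profile, four_scales, sample, spec)
    pssm = encode_pssm(profile, sample, spec)
    pp = encode_pp(profile, four_scales, sample, spec)
    P, width = 4, 25
    for k in range(spec.window_size):
        slot = concat[k * width:(k + 1) * width]
        assert np.array_equal(slot[:20], pssm[k * 21:k * 21 + 20])
        assert np.array_equal(slot[20:20 + P], pp[k * (P + 1):k * (P + 1) + P])
        assert slot[-1] == pssm[k * 21 + 20] == pp[k * (P + 1) + P]


def test_window_shift_moves_slot_blocks(tiny_dataset, four_scales):
    """Shifting the centre by one shifts slot blocks by one block width."""
    chain_id, profile = next(iter(tiny_dataset.profiles.items()))
    spec = WindowSpec(5)
    center = profile.length // 2
    a = encode_pssmpp(profile, four_scales, ResidueSample(chain_id, center, 0), spec)
    b = encode_pssmpp(profile, four_scales, ResidueSample(chain_id, center + 1, 0), spec)
    block = 5  # P + 1
    assert np.array_equal(a[block:], b[:-block])


def test_fast_matrix_path_matches_per_sample_encoders(tiny_dataset, four_scales):
    sub = tiny_dataset.samples[::17]
    spec = WindowSpec(9)
    for encoder, scales in [("binary", None), ("pssm", None), ("pp", four_scales),
                            ("pssmpp", four_scales), ("pssm_pp_concat", four_scales)]:
        fm = build_feature_matrix(encoder, tiny_dataset.profiles, sub, spec, scales)
        ref = np.vstack([
            encode_sample(encoder, tiny_dataset.profiles[s.chain_id], s, spec, scales)
            for s in sub
        ])
        assert np.allclose(fm.values, ref, atol=1e-12)
        assert fm.n_features == ref.shape[1]


def test_feature_tsv_round_trip(tiny_dataset, four_scales, tmp_path):
    sub = tiny_dataset.samples[:20]
    fm = build_feature_matrix("pssmpp", tiny_dataset.profiles, sub, WindowSpec(3), four_scales)
    path = tmp_path / "features.tsv"
    write_features_tsv(fm, path)
    df = pd.read_csv(path, sep="\t")
    assert list(df.columns[3:]) == fm.columns
    assert np.allclose(df[fm.columns].to_numpy(), fm.values, atol=1e-5)
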