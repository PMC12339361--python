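import numpy as np
import pytest
import scipy.ndimage as ndi

from nisseq import (
    CrosstalkMatrix,
    CycleStack,
    PipelineParams,
    SimConfig,
    SpotProfile,
    call_bases,
    call_stack,
    detect_spots,
    estimate_crosstalk,
    extract_profiles,
    frequency_filter,
    render_nis_scene,
    simulate_library,
    simulate_profiles,
    unmix,
)


def stack_from_channels(channels, nuclear=None):
    channels = np.asarray(channels, dtype=float)
    if nuclear is None:
        nuclear = np.zeros((channels.shape[0],) + channels.shape[2:])
        nuclear[:, ::16, ::16] = 1.0
    return CycleStack(nuclear=nuclear, channels=channels)


class TestFrequencyFilter:
    def test_constant_highpass_is_zero(self):
        out = frequency_filter(np.full((32, 32), 7.0), sigma=3, mode="highpass")
        assert np.allclose(out, 0)

    def test_impulse_lowpass_conserves_sum(self):
        img = np.zeros((65, 65))
        img[32, 32] = 10.0
        out = frequency_filter(img, sigma=3, mode="lowpass")
        assert abs(out.sum() - 10.0) / 10.0 < 0.01
        assert out[32, 32] == out.max()

    def test_impulse_on_offset_matches_direct_convolution_oracle(self):
        img = np.full((65, 65), 5.0)
        img[32, 32] += 40.0
        out = frequency_filter(img, sigma=3, mode="highpass")
        expected = np.clip(img - ndi.gaussian_filter(img, 3), 0, None)
        np.testing.assert_allclose(out, expected)
        assert out[32, 32] > 30  # peak retained
        assert out[0, 0] < 1e-6  # offset removed

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            frequency_filter(np.zeros((8, 8)), sigma=0)


def planted_spot_stack(positions, amp=1e5, shape=(128, 128), n_cycles=3):
    """Spots bright in channel 0 at every cycle."""
    channels = np.zeros((n_cycles, 3) + shape)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for r, c in positions:
        g = amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 1.5**2))
        channels[:, 0] += g
    return stack_from_channels(channels)


class TestDetectSpots:
    def test_blank_stack_yields_none(self):
        stack = stack_from_channels(np.zeros((3, 3, 64, 64)))
        assert detect_spots(stack) == []

    def test_single_planted_spot_found(self):
        stack = planted_spot_stack([(40, 60)])
        spots = detect_spots(stack)
        assert len(spots) == 1
        r, c = spots[0]
        assert abs(r - 40) <= 1 and abs(c - 60) <= 1

    def test_fifty_planted_spots_found_within_1px(self):
        rng = np.random.default_rng(0)
        positions = []
        while len(positions) < 50:
            r, c = rng.integers(10, 246, 2)
            if all(max(abs(r - a), abs(c - b)) > 10 for a, b in positions):
                positions.append((int(r), int(c)))
        stack = planted_spot_stack(positions, shape=(256, 256))
        spots = detect_spots(stack)
        assert len(spots) == 50
        for r, c in positions:
            assert any(abs(r - a) <= 1 and abs(c - b) <= 1 for a, b in spots)

    def test_detection_equivariant_under_roll(self):
        stack = planted_spot_stack([(40, 60), (80, 30)], shape=(128, 128))
        rolled = stack_from_channels(
            np.roll(np.roll(stack.channels, 5, axis=2), -3, axis=3)
        )
        a = sorted(detect_spots(stack))
        b = sorted(detect_spots(rolled))
        assert [(r + 5, c - 3) for r, c in a] == b


class TestExtractProfiles:
    def test_blank_channel_gives_zero_row(self):
        stack = planted_spot_stack([(40, 60)])
        profiles = extract_profiles(stack, [(40, 60)])
        assert np.allclose(profiles[0].raw[:, 1], 0)
        assert np.allclose(profiles[0].raw[:, 2], 0)

    def test_integrated_intensity_matches_direct_summation_oracle(self):
        stack = planted_spot_stack([(40, 60)], amp=1e5)
        params = PipelineParams()
        profiles = extract_profiles(stack, [(40, 60)], params)
        hp = frequency_filter(
            stack.channels[0, 0], params.highpass_sigma, "highpass"
        )
        expected = hp[38:43, 58:63].sum()
        assert abs(profiles[0].raw[0, 0] - expected) / expected < 0.05
        assert not profiles[0].edge_flag

    def test_border_spot_sets_edge_flag(self):
        stack = planted_spot_stack([(1, 1)], shape=(100, 100))
        profiles = extract_profiles(stack, [(1, 1)])
        assert profiles[0].edge_flag


class TestCrosstalk:
    def planted_profiles(self, M, n=300, noise=0.0, seed=0):
        lib = simulate_library(30, 2, 4, seed=seed)
        return simulate_profiles(
            lib, n, n_cycles=8, crosstalk=M, noise_sd=noise, seed=seed
        )[0]

    def test_identity_recovered_within_2pct(self):
        profiles = self.planted_profiles(np.eye(3), noise=10.0)
        M = estimate_crosstalk(profiles)
        assert np.abs(M.M - np.eye(3)).max() < 0.02

    def test_planted_bleed_recovered_within_5pct(self):
        planted = np.eye(3) + 0.2 * (np.ones((3, 3)) - np.eye(3))
        planted /= planted.max(axis=0)
        profiles = self.planted_profiles(planted, noise=10.0, seed=1)
        M = estimate_crosstalk(profiles)
        assert np.abs(M.M - planted).max() < 0.05

    def test_single_base_library_is_degenerate(self):
        raw = np.zeros((4, 3))
        raw[:, 0] = 100.0
        profiles = [SpotProfile(i, (0, 0), raw.copy()) for i in range(40)]
        with pytest.raises(ValueError, match="insufficient base diversity"):
            estimate_crosstalk(profiles)


class TestUnmix:
    def test_identity_matrix_is_noop(self):
        p = SpotProfile(0, (0, 0), np.array([[10.0, 5.0, 1.0]]))
        unmix(p, CrosstalkMatrix.identity())
        np.testing.assert_allclose(p.unmixed, p.raw)

    def test_linear_solve_oracle(self):
        M = CrosstalkMatrix(np.array([[1, 0.3, 0.1], [0.2, 1, 0.2], [0.1, 0.3, 1]]))
        true = np.array([100.0, 0.0, 0.0])
        p = SpotProfile(0, (0, 0), (M.M @ true)[None, :])
        unmix(p, M)
        np.testing.assert_allclose(p.unmixed[0], true, atol=1e-9)

    def test_zero_vector_stays_zero(self):
        p = SpotProfile(0, (0, 0), np.zeros((3, 3)))
        M = CrosstalkMatrix(np.array([[1, 0.3, 0.1], [0.2, 1, 0.2], [0.1, 0.3, 1]]))
        unmix(p, M)
        assert np.allclose(p.unmixed, 0)

    def test_singular_matrix_rejected(self):
        M = CrosstalkMatrix(np.ones((3, 3)))
        p = SpotProfile(0, (0, 0), np.ones((2, 3)))
        with pytest.raises(ValueError, match="ill-conditioned"):
            unmix(p, M)

    def test_unmix_inverts_mixing_for_random_profiles(self):
        rng = np.random.default_rng(2)
        M = CrosstalkMatrix(np.eye(3) + 0.25 * rng.random((3, 3)))
        orig = rng.random((6, 3)) * 100
        p = SpotProfile(0, (0, 0), orig @ M.M.T)
        unmix(p, M)
        np.testing.assert_allclose(p.unmixed, orig, rtol=1e-6)


class TestCallBases:
    def make_profile(self, unmixed):
        unmixed = np.asarray(unmixed, dtype=float)
        p = SpotProfile(0, (0, 0), np.clip(unmixed, 0, None))
        p.unmixed = unmixed
        p.max_unmixed = float(unmixed.max())
        return p

    def test_rule_application_with_dark_g(self):
        p = self.make_profile(
            [[100, 5, 5], [5, 5, 90], [4, 80, 5], [3, 2, 1]]
        )
        call_bases(p)
        assert p.sequence == "ATCG"

    def test_exact_tie_calls_n(self):
        p = self.make_profile([[50, 50, 1]])
        call_bases(p)
        assert p.sequence == "N"

    def test_no_signal_calls_all_n(self):
        p = self.make_profile(np.zeros((5, 3)))
        call_bases(p)
        assert p.sequence == "NNNNN"

    def test_scale_invariance(self):
        u = np.array([[100.0, 5, 5], [5, 5, 90], [1, 2, 3], [3, 2, 1]])
        a = self.make_profile(u)
        b = self.make_profile(u * 37.5)
        call_bases(a)
        call_bases(b)
        assert a.sequence == b.sequence

    def test_noiseless_planted_sequences_called_perfectly(self):
        lib = simulate_library(50, 2, 4, seed=3)
        profiles, truth = simulate_profiles(lib, 300, n_cycles=10, seed=3)
        M = estimate_crosstalk(profiles)
        for p, t in zip(profiles, truth.itertuples()):
            unmix(p, M)
            call_bases(p)
            assert p.sequence == t.detect_seq


def test_end_to_end_calls_on_rendered_scene(small_library):
    cfg = SimConfig(n_nuclei=40, n_cycles=6, seed=13)
    stack, truth = render_nis_scene(small_library, cfg)
    profiles, _ = call_stack(stack)
    by_pos = {
        (int(r.row), int(r.col)): r.detect_seq for r in truth.spots.itertuples()
    }
    matched = 0
    for p in profiles:
        seq = by_pos.get(p.position)
        if seq is not None:
            matched += 1
            assert p.sequence == seq
    assert matched >= 0.9 * len(truth.spots)
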