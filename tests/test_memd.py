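"""MEMD: direction sampling, envelopes, sifting, alignment, scales."""

import numpy as np
import pytest

from gaitmmse.memd import (CumulativeScale, InsufficientExtremaError,
                           add_noise_channels, cumulative_scales,
                           generate_directions, local_mean, memd, project,
                           sift_mode, strip_noise_channels)
from gaitmmse.signal import MultichannelSignal

from _oracles import classic_emd


class TestDirections:
    def test_unit_norm_and_deterministic(self):
        for n_dim, count in [(2, 4), (3, 64), (22, 64)]:
            d1 = generate_directions(n_dim, count)
            d2 = generate_directions(n_dim, count)
            assert d1.vectors.shape == (count, n_dim)
            np.testing.assert_allclose(
                np.linalg.norm(d1.vectors, axis=1), 1.0, atol=1e-12
            )
            np.testing.assert_array_equal(d1.vectors, d2.vectors)

    def test_univariate_input_rejected(self):
        with pytest.raises(ValueError, match="univariate"):
            generate_directions(1, 8)

    def test_more_even_than_random_on_sphere(self):
        """Quasi-uniform sampling spreads more evenly than random draws.

        Compared via the coefficient of variation of the nearest-neighbour
        angular spacing on the 2-sphere, against 100 random direction sets.
        """

        def nn_cv(vectors):
            cosines = np.clip(vectors @ vectors.T, -1, 1)
            np.fill_diagonal(cosines, -1)
            nn_angle = np.arccos(cosines.max(axis=1))
            return np.std(nn_angle) / np.mean(nn_angle)

        ours = nn_cv(generate_directions(3, 64).vectors)
        rng = np.random.default_rng(0)
        random_cvs = []
        for _ in range(100):
            v = rng.standard_normal((64, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            random_cvs.append(nn_cv(v))
        assert ours < np.mean(random_cvs)


class TestProject:
    def test_axis_aligned_identity(self, rng):
        values = rng.standard_normal((50, 3))
        sig = MultichannelSignal(values, 100.0)
        for j in range(3):
            e = np.zeros(3)
            e[j] = 1.0
            np.testing.assert_array_equal(project(sig, e), values[:, j])

    def test_equal_channels_closed_form(self, rng):
        x = rng.standard_normal(40)
        sig = MultichannelSignal(np.column_stack([x, x]), 100.0)
        d = np.array([1.0, 1.0]) / np.sqrt(2)
        np.testing.assert_allclose(project(sig, d), np.sqrt(2) * x, rtol=1e-12)

    def test_matches_elementwise_loop(self, rng):
        values = rng.standard_normal((30, 4))
        d = rng.standard_normal(4)
        d /= np.linalg.norm(d)
        expected = np.array(
            [sum(values[t, c] * d[c] for c in range(4)) for t in range(30)]
        )
        np.testing.assert_allclose(project(values, d), expected, atol=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="channel count"):
            project(rng.standard_normal((30, 4)), np.ones(3))


class TestLocalMean:
    def test_constant_signal_mean_is_constant(self):
        values = np.full((200, 2), 3.5)
        # give the projections structure via a tiny ripple on one channel
        values[:, 0] += 1e-9 * np.sin(np.linspace(0, 40 * np.pi, 200))
        d = generate_directions(2, 8)
        m = local_mean(values, d)
        np.testing.assert_allclose(m, 3.5, atol=1e-6)

    def test_monotonic_signal_raises(self):
        values = np.column_stack([np.linspace(0, 1, 100), np.linspace(2, 0, 100)])
        d = generate_directions(2, 8)
        with pytest.raises(InsufficientExtremaError):
            local_mean(values, d)

    def test_sinusoid_mean_near_zero(self):
        # 20 periods of unit 2-channel quadrature tones: every envelope mean
        # should hover near zero away from the ends
        t = np.linspace(0, 20, 2000, endpoint=False)
        values = np.column_stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)])
        d = generate_directions(2, 64)
        m = local_mean(values, d)
        interior = slice(200, 1800)
        assert np.max(np.abs(m[interior])) < 0.05


class TestSifting:
    def test_infinite_threshold_single_iteration(self, rng):
        values = np.column_stack([
            np.sin(np.linspace(0, 30 * np.pi, 600)),
            np.cos(np.linspace(0, 22 * np.pi, 600)),
        ]) + 0.1 * rng.standard_normal((600, 2))
        d = generate_directions(2, 16)
        mode, remainder = sift_mode(values, d, sd_threshold=np.inf)
        expected = values - local_mean(values, d)
        np.testing.assert_array_equal(mode, expected)
        np.testing.assert_allclose(mode + remainder, values, atol=1e-12)

    def test_mode_plus_remainder_is_input(self, rng):
        values = rng.standard_normal((400, 3)).cumsum(axis=0)
        values -= values.mean(axis=0)
        values += 0.5 * np.sin(np.linspace(0, 40 * np.pi, 400))[:, None]
        d = generate_directions(3, 16)
        mode, remainder = sift_mode(values, d)
        np.testing.assert_allclose(mode + remainder, values, atol=1e-12)


class TestMEMD:
    def test_tone_separation(self, tone_pair_signal):
        sig, fast, slow = tone_pair_signal
        dec = memd(sig, n_directions=64, max_modes=6)
        corr_fast = max(
            abs(np.corrcoef(m[:, 0], fast)[0, 1]) for m in dec.imfs
        )
        corr_slow = max(
            abs(np.corrcoef(m[:, 0], slow)[0, 1]) for m in dec.imfs
        )
        assert corr_fast > 0.95
        assert corr_slow > 0.95
        # fine-to-coarse ordering: the fast tone lives in an earlier mode
        i_fast = int(np.argmax([abs(np.corrcoef(m[:, 0], fast)[0, 1]) for m in dec.imfs]))
        i_slow = int(np.argmax([abs(np.corrcoef(m[:, 0], slow)[0, 1]) for m in dec.imfs]))
        assert i_fast < i_slow

    def test_reconstruction_and_alignment_random_signals(self, rng):
        for _ in range(5):
            t_len = int(rng.integers(300, 600))
            n_chan = int(rng.integers(2, 5))
            base = rng.standard_normal((t_len, n_chan))
            sig = MultichannelSignal(base, 500.0)
            dec = memd(sig, n_directions=16, max_modes=5)
            rel = np.linalg.norm(dec.reconstruct() - base) / np.linalg.norm(base)
            assert rel < 1e-10
            assert dec.residual.shape == base.shape
            for m in dec.imfs:
                assert m.shape == base.shape  # joint sifting => aligned modes

    def test_non_finite_input_rejected(self):
        bad = np.ones((100, 2))
        bad[3, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            MultichannelSignal(bad, 100.0)

    def test_univariate_limit_matches_classic_emd(self):
        fs = 100.0
        t = np.arange(int(25 * fs)) / fs
        x = np.sin(2 * np.pi * 5.0 * t) + np.sin(2 * np.pi * 0.4 * t)
        dec = memd(MultichannelSignal(x[:, None], fs), max_modes=4)
        ref_imfs, _ = classic_emd(x, max_modes=4)
        assert dec.n_modes >= 2 and len(ref_imfs) >= 2
        for ours, ref in zip(dec.imfs[:2], ref_imfs[:2]):
            c = abs(np.corrcoef(ours[:, 0], ref)[0, 1])
            assert c > 0.95


class TestNoiseChannels:
    def test_counts_and_labels(self, rng):
        sig = MultichannelSignal(rng.standard_normal((500, 16)), 1000.0)
        out = add_noise_channels(sig, n_noise=6, seed=3)
        assert out.n_channels == 22
        assert out.labels[16:] == [f"WN{i}" for i in range(1, 7)]
        np.testing.assert_array_equal(out.values[:, :16], sig.values)

    def test_zero_noise_is_identity(self, rng):
        sig = MultichannelSignal(rng.standard_normal((100, 4)), 1000.0)
        assert add_noise_channels(sig, n_noise=0, seed=1) is sig

    def test_seed_reproducibility_and_scaling(self, rng):
        sig = MultichannelSignal(5.0 * rng.standard_normal((2000, 4)), 1000.0)
        a = add_noise_channels(sig, n_noise=2, seed=9)
        b = add_noise_channels(sig, n_noise=2, seed=9)
        np.testing.assert_array_equal(a.values, b.values)
        noise_sd = a.values[:, 4:].std(axis=0)
        target = np.mean(sig.values.std(axis=0))
        np.testing.assert_allclose(noise_sd, target, rtol=0.1)

    def test_strip_restores_channel_set(self, rng):
        sig = MultichannelSignal(rng.standard_normal((400, 4)), 500.0)
        aug = add_noise_channels(sig, n_noise=2, seed=0)
        dec = memd(aug, n_directions=16, max_modes=4)
        stripped = strip_noise_channels(dec, 2)
        assert stripped.n_channels == 4
        assert stripped.n_modes == dec.n_modes
        rel = np.linalg.norm(stripped.reconstruct() - sig.values) / np.linalg.norm(sig.values)
        assert rel < 1e-10
        with pytest.raises(ValueError):
            strip_noise_channels(dec, 6)


class TestCumulativeScales:
    @pytest.fixture()
    def dec(self, tone_pair_signal):
        sig, _, _ = tone_pair_signal
        return memd(sig, n_directions=32, max_modes=4), sig

    def test_scale_one_reconstructs_input(self, dec):
        d, sig = dec
        scales = cumulative_scales(d, d.n_modes + 1)
        rel = np.linalg.norm(scales[0].values - sig.values) / np.linalg.norm(sig.values)
        assert rel < 1e-10

    def test_exact_telescoping(self, dec):
        d, _ = dec
        scales = cumulative_scales(d, d.n_modes + 1)
        for n in range(len(scales) - 1):
            np.testing.assert_array_equal(
                scales[n].values, scales[n + 1].values + d.imfs[n]
            )

    def test_last_scale_is_residual(self, dec):
        d, _ = dec
        scales = cumulative_scales(d, d.n_modes + 1)
        np.testing.assert_array_equal(scales[-1].values, d.residual)
        assert [s.scale_factor for s in scales] == list(range(1, d.n_modes + 2))

    def test_bounds(self, dec):
        d, _ = dec
        with pytest.raises(ValueError):
            cumulative_scales(d, 0)
        with pytest.raises(ValueError):
            cumulative_scales(d, d.n_modes + 2)
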