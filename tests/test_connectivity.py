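"""WPLI estimators: formula oracle, constructed limits, invariances."""

import numpy as np
import pytest

import eegpls as e
from eegpls.connectivity import CrossSpectrumSet, morlet_cross_spectra


def _cs_from_imag(im_values):
    """Build a 1-frequency, 1-pair observation set with given Im parts."""
    vals = (1j * np.asarray(im_values, dtype=float)).reshape(-1, 1, 1)
    valid = np.ones((len(im_values), 1), dtype=bool)
    grid = e.fourier_grid(10.0, 10.0, 0.5)
    return CrossSpectrumSet(vals, valid, grid, [("A", "B")], "epoch-taper")


def sinusoid_pair(freq=10.0, lag=np.pi / 2, n_epochs=10, n=1000, fs=500.0,
                  noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    eps = []
    for _ in range(n_epochs):
        phi = rng.uniform(0, 2 * np.pi)
        eps.append(np.stack([np.sin(2 * np.pi * freq * t + phi),
                             np.sin(2 * np.pi * freq * t + phi + lag)])
                   + noise * rng.standard_normal((2, n)))
    return np.array(eps)


class TestPairEnumeration:
    @pytest.mark.parametrize("n,expected", [(28, 378), (2, 1), (5, 10)])
    def test_pair_counts(self, n, expected):
        labels = [f"ch{i}" for i in range(n)]
        pairs = e.enumerate_pairs(labels)
        assert len(pairs) == expected
        assert pairs == sorted(pairs, key=lambda p: (labels.index(p[0]),
                                                     labels.index(p[1])))

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            e.enumerate_pairs(["A", "A", "B"])


class TestWpliFormula:
    def test_hand_example(self):
        """Im values {+1, +1, -1} -> |1| / 3 = 1/3."""
        cm = e.wpli_from_cross_spectra(_cs_from_imag([1.0, 1.0, -1.0]))
        assert cm.values[0, 0] == pytest.approx(1 / 3)

    def test_consistent_sign_gives_one(self):
        cm = e.wpli_from_cross_spectra(_cs_from_imag([0.5, 2.0, 1.2]))
        assert cm.values[0, 0] == pytest.approx(1.0)

    def test_zero_imaginary_flagged_zero(self):
        """Zero-lag coupling: all-real cross-spectra -> 0 with flag."""
        cm = e.wpli_from_cross_spectra(_cs_from_imag([0.0, 0.0, 0.0]))
        assert cm.values[0, 0] == 0.0
        assert cm.denominator_zero[0, 0]

    def test_matches_literal_transcription(self, rng):
        """Random small observation sets agree with |sum Im| / sum |Im|
        computed independently."""
        for _ in range(50):
            im = rng.normal(size=rng.integers(3, 9))
            expected = abs(im.sum()) / np.abs(im).sum()
            cm = e.wpli_from_cross_spectra(_cs_from_imag(im))
            assert cm.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_empty_and_single_observation_rejected(self):
        with pytest.raises(ValueError):
            e.wpli_from_cross_spectra(_cs_from_imag([]))
        with pytest.raises(ValueError):
            e.wpli_from_cross_spectra(_cs_from_imag([1.0]))


class TestFourierRoute:
    def test_constant_lag_sign_consistency(self):
        """A pi/2-lagged sinusoid pair: Im of the cross-spectrum at the
        driven bin keeps one sign across epochs, and WPLI is exactly 1."""
        data = sinusoid_pair(noise=1e-9)
        grid = e.fourier_grid(4.0, 20.0, 0.5)
        cs = e.fourier_cross_spectra(data, 500.0, grid, ["A", "B"])
        i10 = int(np.argmin(np.abs(grid.freqs - 10.0)))
        im = np.imag(cs.values[cs.valid[:, i10], i10, 0])
        assert np.all(im > 0) or np.all(im < 0)
        cm = e.wpli_from_cross_spectra(cs)
        assert cm.values[i10, 0] == pytest.approx(1.0, abs=1e-10)

    def test_dpss_band_detects_high_frequency_coupling(self):
        """40 Hz coupling lands in the multitaper band and is recovered."""
        data = sinusoid_pair(freq=40.0, noise=0.05)
        grid = e.fourier_grid(30.0, 50.0, 0.5)
        cs = e.fourier_cross_spectra(data, 500.0, grid, ["A", "B"])
        assert cs.valid.sum(axis=0).max() == data.shape[0] * 7  # 7 dpss tapers
        cm = e.wpli_from_cross_spectra(cs)
        i40 = int(np.argmin(np.abs(grid.freqs - 40.0)))
        assert cm.values[i40, 0] > 0.95

    def test_identical_channels_give_real_cross_spectrum(self):
        """A channel crossed with itself has a real autospectrum: zero
        imaginary part everywhere, flagged WPLI 0."""
        one = sinusoid_pair(noise=0.0)[:, :1, :]
        data = np.concatenate([one, one], axis=1)
        grid = e.fourier_grid(4.0, 20.0, 0.5)
        cs = e.fourier_cross_spectra(data, 500.0, grid, ["A", "B"])
        assert np.max(np.abs(np.imag(cs.values))) < 1e-4 * np.max(np.abs(cs.values))

    def test_white_noise_imag_centered_at_zero(self):
        """Monte-Carlo null: over 100 epochs the mean normalized Im stays
        within 3 standard errors of zero at every bin."""
        rng = np.random.default_rng(2)
        data = rng.standard_normal((100, 2, 1000))
        grid = e.fourier_grid(4.0, 20.0, 0.5)
        cs = e.fourier_cross_spectra(data, 500.0, grid, ["A", "B"])
        ratio = np.imag(cs.values[:, :, 0]) / np.abs(cs.values[:, :, 0])
        m = ratio.mean(axis=0)
        se = ratio.std(axis=0) / np.sqrt(ratio.shape[0])
        assert np.all(np.abs(m) < 3.5 * se + 1e-12)

    def test_grid_spacing_must_match_epoch_length(self):
        data = np.zeros((3, 2, 900)) + np.random.default_rng(0).normal(size=(3, 2, 900))
        with pytest.raises(ValueError):
            e.fourier_cross_spectra(data, 500.0, e.fourier_grid(4, 20, 0.5),
                                    ["A", "B"])


class TestMorletRoute:
    @pytest.mark.parametrize("f,c", [(4.0, 3.0), (27.0, 5.0), (50.0, 7.0)])
    def test_cycle_interpolation(self, f, c):
        assert e.morlet_cycles(np.array([f]))[0] == pytest.approx(c)

    def test_sub_4hz_frequencies_rejected(self):
        """2-s epochs are too short below 4 Hz; the Morlet route refuses."""
        grid = e.FrequencyGrid(np.array([3.0]), "morlet", np.array([3.0]))
        with pytest.raises(ValueError):
            morlet_cross_spectra(np.zeros((2, 1000)), 500.0, grid, ["A", "B"])

    def test_constant_lag_phase_per_time_point(self):
        """pi/2-lagged 10 Hz pair: the per-time-point phase difference at
        the 10 Hz row is pi/2 at all valid points."""
        epoch = sinusoid_pair(noise=0.0, n_epochs=1)[0]
        grid = e.morlet_grid(8.0, 12.0, 1.0)
        cs = morlet_cross_spectra(epoch, 500.0, grid, ["A", "B"])
        i10 = int(np.argmin(np.abs(grid.freqs - 10.0)))
        ang = np.angle(cs.values[cs.valid[:, i10], i10, 0])
        assert np.allclose(np.abs(ang), np.pi / 2, atol=0.02)
        cm = e.wpli_from_cross_spectra(cs)
        assert cm.values[i10, 0] == pytest.approx(1.0, abs=1e-10)

    def test_single_epoch_bookkeeping_and_average(self, coupled_recording):
        """n epochs in -> n per-epoch matrices plus one average that equals
        their element-wise mean."""
        grid = e.morlet_grid(8.0, 12.0, 1.0)
        per, avg = e.wpli_single_epoch(coupled_recording, grid)
        assert len(per) == coupled_recording.data.shape[0]
        np.testing.assert_allclose(
            avg.values, np.mean([m.values for m in per], axis=0), atol=1e-12)

    def test_coupled_exceeds_uncoupled_bias(self):
        """Within-epoch WPLI has positive small-sample bias on noise, but a
        coupling-dominated pair sits far above it (difference > 0.3)."""
        grid = e.morlet_grid(8.0, 12.0, 1.0)
        i10 = int(np.argmin(np.abs(grid.freqs - 10.0)))
        rng = np.random.default_rng(3)
        coupled = sinusoid_pair(noise=0.2, n_epochs=15)
        noise = rng.standard_normal((15, 2, 1000))
        vals = {}
        for name, data in (("coupled", coupled), ("noise", noise)):
            rec = e.EpochedRecording("p", "responder", "baseline", "EC", 30.0,
                                     data, 500.0, ("A", "B"))
            vals[name] = e.wpli_single_epoch(rec, grid)[1].values[i10, 0]
        assert vals["noise"] > 0.05  # biased above zero
        assert vals["coupled"] - vals["noise"] > 0.3


class TestInvariances:
    def test_values_in_unit_interval(self, coupled_recording):
        cm = e.wpli_across_epochs(coupled_recording, e.fourier_grid(4, 40, 0.5))
        assert np.all(cm.values >= 0) and np.all(cm.values <= 1)

    def test_amplitude_invariance(self, coupled_recording):
        """Scaling any channel by a positive constant leaves WPLI unchanged."""
        grid = e.fourier_grid(4.0, 20.0, 0.5)
        cm1 = e.wpli_across_epochs(coupled_recording, grid)
        scaled = coupled_recording.data.copy()
        scaled[:, 1, :] *= 37.5
        rec2 = e.EpochedRecording("p", "responder", "baseline", "EC", 30.0,
                                  scaled, 500.0, ("A", "B"))
        cm2 = e.wpli_across_epochs(rec2, grid)
        np.testing.assert_allclose(cm1.values, cm2.values, atol=1e-10)

    def test_channel_order_symmetry(self, coupled_recording):
        """Reversing channel order leaves the (canonically ordered) WPLI
        values identical up to the pair relabeling."""
        grid = e.fourier_grid(4.0, 20.0, 0.5)
        cm1 = e.wpli_across_epochs(coupled_recording, grid)
        rec2 = e.EpochedRecording("p", "responder", "baseline", "EC", 30.0,
                                  coupled_recording.data[:, ::-1, :], 500.0,
                                  ("B", "A"))
        cm2 = e.wpli_across_epochs(rec2, grid)
        np.testing.assert_allclose(cm1.values, cm2.values, atol=1e-10)

    def test_zero_lag_source_changes_little(self):
        """Adding a common zero-lag source to independent noise shifts the
        pair-mean across-epoch WPLI by < 0.05 at every frequency (the source
        reweights the sampling noise but carries no phase-lag consistency)."""
        rng = np.random.default_rng(17)
        labels = [f"c{i}" for i in range(16)]  # 120 pairs
        noise = rng.standard_normal((100, 16, 1000))
        common = rng.standard_normal((100, 1, 1000))
        grid = e.fourier_grid(4.0, 40.0, 0.5)
        cm_a = e.wpli_from_cross_spectra(
            e.fourier_cross_spectra(noise, 500.0, grid, labels))
        cm_b = e.wpli_from_cross_spectra(
            e.fourier_cross_spectra(noise + common, 500.0, grid, labels))
        per_freq_shift = cm_b.values.mean(axis=1) - cm_a.values.mean(axis=1)
        assert np.all(np.abs(per_freq_shift) < 0.05)
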