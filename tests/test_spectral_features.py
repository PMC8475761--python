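import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

import eegid as eg
from eegid.errors import ConfigError, StateError
from eegid.preprocess import EpochArray
from eegid.spectral_features import (
    COH,
    PSD,
    XSPEC_AMP,
    XSPEC_PHASE,
    channel_pairs,
    concat_tensors,
)

from conftest import random_epochs


class TestModifiedPeriodogram:
    def test_zero_segment_gives_zero_spectrum(self):
        freqs, power = eg.modified_periodogram(np.zeros(100), "boxcar")
        np.testing.assert_array_equal(power, 0.0)

    def test_sinusoid_peaks_at_its_bin_and_matches_dft(self):
        """Rectangular-window periodogram equals (dt/N)|DFT|^2 exactly."""
        t = np.arange(100) / 100.0
        x = np.sin(2 * np.pi * 10.0 * t)
        freqs, power = eg.modified_periodogram(x, "boxcar", nfft=100, fs=100.0)
        oracle = (0.01 / 100) * np.abs(np.fft.fft(x, 100)) ** 2
        np.testing.assert_allclose(power, oracle, atol=1e-10)
        pos = freqs >= 0
        assert freqs[pos][np.argmax(power[pos])] == 10.0

    def test_window_power_normalization(self):
        """Hamming and rectangular tapers agree on white-noise band power."""
        rng = np.random.default_rng(0)
        tot_ham, tot_rect = 0.0, 0.0
        for _ in range(1000):
            x = rng.standard_normal(100)
            _, p_h = eg.modified_periodogram(x, "hamming")
            _, p_r = eg.modified_periodogram(x, "boxcar")
            tot_ham += p_h.sum()
            tot_rect += p_r.sum()
        assert abs(tot_ham / tot_rect - 1) < 0.05

    def test_parseval_energy_consistency(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.standard_normal(100)
            _, power = eg.modified_periodogram(x, "boxcar", nfft=100, fs=100.0)
            assert abs(power.sum() * 1.0 - np.mean(x**2)) < 1e-8

    def test_input_validation(self):
        with pytest.raises(ValueError):
            eg.modified_periodogram(np.array([]))
        with pytest.raises(ValueError):
            eg.modified_periodogram(np.zeros(200), nfft=100)


class TestWelchPsd:
    def test_shape_contract_full_run(self):
        ep = random_epochs(n_epochs=450, n_channels=18, seed=2)
        psd = eg.welch_psd(ep)
        assert psd.data.shape == (450, 18, 40)
        assert psd.kind == PSD
        assert np.all(psd.data >= 0)

    def test_single_rect_segment_equals_dft_oracle(self):
        """Degenerate Welch (one full-length rectangular segment) = periodogram."""
        ep = random_epochs(n_epochs=100, n_channels=2, seed=3)
        cfg = eg.WelchConfig(window="boxcar", segment_len=100, overlap_frac=0.0)
        psd = eg.welch_psd(ep, cfg)
        dft = np.abs(np.fft.fft(ep.epochs, n=100, axis=-1)) ** 2 * (0.01 / 100)
        np.testing.assert_allclose(psd.data, dft[..., 1:41], atol=1e-10)

    def test_matches_scipy_welch(self):
        """Independent oracle: scipy's Welch estimator, same configuration."""
        ep = random_epochs(n_epochs=5, n_channels=3, seed=4)
        psd = eg.welch_psd(ep)
        f, p = sps.welch(
            ep.epochs, fs=100.0, window="hamming", nperseg=50, noverlap=25,
            nfft=100, detrend=False, return_onesided=False, scaling="density",
        )
        sel = np.isin(np.round(f).astype(int), np.arange(1, 41)) & (f > 0)
        np.testing.assert_allclose(psd.data, p[..., sel], rtol=1e-9)

    def test_variance_reduction_vs_single_periodogram(self):
        ep = random_epochs(n_epochs=500, n_channels=1, seed=5)
        welch = eg.welch_psd(ep)
        single = eg.welch_psd(
            ep, eg.WelchConfig(window="boxcar", segment_len=100, overlap_frac=0.0)
        )
        assert welch.data.var(axis=0).mean() < single.data.var(axis=0).mean()

    def test_white_noise_spectrum_flat(self):
        ep = random_epochs(n_epochs=1000, n_channels=1, seed=6)
        mean_spec = eg.welch_psd(ep).data.mean(axis=0)[0]
        assert np.all(np.abs(mean_spec / mean_spec.mean() - 1) < 0.1)


class TestCrossSpectrum:
    def test_shapes_and_pair_counts(self):
        ep = random_epochs(n_epochs=10, n_channels=18, seed=7)
        xs = eg.cross_spectrum(ep)
        amp, phase = eg.amplitude_and_phase(xs)
        coh = eg.coherence(ep)
        assert xs.data.shape == (10, 171, 40)
        assert amp.data.shape == (10, 171, 40)
        assert phase.data.shape == (10, 171, 40)
        assert coh.data.shape == (10, 153, 40)
        assert len(channel_pairs(18, True)) == 171
        assert len(channel_pairs(18, False)) == 153

    def test_self_pair_equals_psd(self):
        ep = random_epochs(n_epochs=8, n_channels=3, seed=8)
        xs = eg.cross_spectrum(ep)
        psd = eg.welch_psd(ep)
        self_rows = [i for i, (a, b) in enumerate(xs.axis1_labels) if a == b]
        np.testing.assert_allclose(
            xs.data[:, self_rows, :].real, psd.data, atol=1e-12
        )
        np.testing.assert_allclose(xs.data[:, self_rows, :].imag, 0.0, atol=1e-12)

    def test_matches_scipy_csd(self):
        ep = random_epochs(n_epochs=4, n_channels=2, seed=9)
        xs = eg.cross_spectrum(ep)
        row = xs.axis1_labels.index(("ch0", "ch1"))
        f, p = sps.csd(
            ep.epochs[:, 0], ep.epochs[:, 1], fs=100.0, window="hamming",
            nperseg=50, noverlap=25, nfft=100, detrend=False,
            return_onesided=False, scaling="density",
        )
        sel = np.isin(np.round(f).astype(int), np.arange(1, 41)) & (f > 0)
        # scipy computes conj(X)*Y; this package uses X*conj(Y) (so a positive
        # phase means the second channel lags) — complex conjugates of each other
        np.testing.assert_allclose(xs.data[:, row, :], np.conj(p[..., sel]), rtol=1e-9)

    def test_pair_reversal_conjugates(self):
        """Swapping channel order conjugates the cross-spectrum (phase flips)."""
        ep = random_epochs(n_epochs=4, n_channels=2, seed=10)
        swapped = EpochArray(
            subject_id=ep.subject_id, run_id=ep.run_id, condition=ep.condition,
            fs=ep.fs, channel_labels=("ch1", "ch0"),
            epochs=ep.epochs[:, ::-1, :],
        )
        a = eg.cross_spectrum(ep)
        b = eg.cross_spectrum(swapped)
        row_ab = a.axis1_labels.index(("ch0", "ch1"))
        row_ba = b.axis1_labels.index(("ch1", "ch0"))
        np.testing.assert_allclose(
            a.data[:, row_ab], np.conj(b.data[:, row_ba]), atol=1e-12
        )

    def test_self_pair_phase_zero(self):
        ep = random_epochs(n_epochs=5, n_channels=3, seed=11)
        _, phase = eg.amplitude_and_phase(eg.cross_spectrum(ep))
        self_rows = [i for i, (a, b) in enumerate(phase.axis1_labels) if a == b]
        np.testing.assert_array_equal(phase.data[:, self_rows, :], 0.0)

    def test_pure_delay_phase(self):
        """Two copies of a tone with delay tau give phase 2*pi*f*tau."""
        fs, f0, tau = 100.0, 10.0, 0.01
        t = np.arange(4000) / fs
        src = np.sin(2 * np.pi * f0 * t)
        delayed = np.sin(2 * np.pi * f0 * (t - tau))
        data = np.stack([src, delayed]).reshape(2, 40, 100).transpose(1, 0, 2)
        ep = EpochArray(
            subject_id="s", run_id="r", condition="REO", fs=fs,
            channel_labels=("a", "b"), epochs=data,
        )
        _, phase = eg.amplitude_and_phase(eg.cross_spectrum(ep))
        row = phase.axis1_labels.index(("a", "b"))
        f_idx = list(phase.freqs).index(10)
        measured = phase.data[:, row, f_idx].mean()
        assert abs(measured - 2 * np.pi * f0 * tau) < 0.05


class TestCoherence:
    def test_bounds_on_random_epochs(self):
        ep = random_epochs(n_epochs=200, n_channels=4, seed=12)
        coh = eg.coherence(ep)
        assert coh.data.min() >= 0.0
        assert coh.data.max() <= 1.0

    def test_duplicated_channel_gives_unit_coherence(self):
        ep = random_epochs(n_epochs=10, n_channels=1, seed=13)
        dup = EpochArray(
            subject_id="s", run_id="r", condition="REO", fs=100.0,
            channel_labels=("a", "b"),
            epochs=np.repeat(ep.epochs, 2, axis=1),
        )
        coh = eg.coherence(dup)
        np.testing.assert_allclose(coh.data, 1.0, atol=1e-10)

    def test_scale_invariance(self):
        ep = random_epochs(n_epochs=6, n_channels=3, seed=14)
        scaled = EpochArray(
            subject_id="s", run_id="r", condition="REO", fs=100.0,
            channel_labels=ep.channel_labels,
            epochs=ep.epochs * np.array([3.7, 1.0, 0.01])[None, :, None],
        )
        np.testing.assert_allclose(
            eg.coherence(ep).data, eg.coherence(scaled).data, atol=1e-10
        )

    def test_single_segment_config_rejected(self):
        ep = random_epochs(n_epochs=3, n_channels=2, seed=15)
        cfg = eg.WelchConfig(segment_len=100, overlap_frac=0.0)
        with pytest.raises(ConfigError, match="degenerate"):
            eg.coherence(ep, cfg)

    def test_independent_channels_show_finite_segment_bias(self):
        """Mean MSC of independent noise shrinks as segments increase.

        With L independent segments the null expectation of magnitude-squared
        coherence is about 1/L.
        """
        means = {}
        for n_samp, seg in ((100, 50), (400, 50)):
            ep = random_epochs(n_epochs=300, n_channels=2, n_samples=n_samp, seed=16)
            cfg = eg.WelchConfig(segment_len=seg, overlap_frac=0.0)
            means[n_samp] = eg.coherence(ep, cfg).data.mean()
        # 2 segments -> ~1/2; 8 segments -> ~1/8
        assert abs(means[100] - 0.5) < 0.1
        assert abs(means[400] - 0.125) < 0.05
        assert means[400] < means[100]


class TestTransformsAndBlocks:
    def _tensor(self, kind, data):
        n = data.shape[0]
        return eg.FeatureTensor(
            kind=kind, data=data,
            subjects=np.repeat("S01", n), runs=np.repeat("RUN1", n),
            conditions=np.repeat("REO", n),
            freqs=np.arange(1, data.shape[2] + 1),
            axis1_labels=tuple(f"r{i}" for i in range(data.shape[1])),
        )

    def test_log_transform_of_psd(self):
        t = self._tensor(PSD, np.ones((2, 3, 4)))
        out = eg.transform_features(t)
        np.testing.assert_array_equal(out.data, 0.0)  # log10(1) = 0
        assert out.transform_state == "transformed"

    def test_fisher_z_of_coherence(self):
        t = self._tensor(COH, np.array([[[0.0, 0.5]]]))
        out = eg.transform_features(t)
        assert out.data[0, 0, 0] == 0.0
        assert abs(out.data[0, 0, 1] - 0.8813735870195432) < 1e-12

    def test_phase_passes_through(self):
        vals = np.linspace(-3, 3, 24).reshape(2, 3, 4)
        out = eg.transform_features(self._tensor(XSPEC_PHASE, vals.copy()))
        np.testing.assert_array_equal(out.data, vals)

    def test_double_transform_rejected(self):
        t = eg.transform_features(self._tensor(PSD, np.ones((2, 3, 4))))
        with pytest.raises(StateError):
            eg.transform_features(t)

    def test_block_average_counts(self):
        t = self._tensor(PSD, np.random.default_rng(17).random((450, 2, 3)))
        out = eg.block_average(t, 5)
        assert out.n_trials == 90
        assert out.block_averaged

    def test_block_one_is_identity(self):
        t = self._tensor(PSD, np.random.default_rng(18).random((10, 2, 3)))
        np.testing.assert_array_equal(eg.block_average(t, 1).data, t.data)

    def test_constant_trials_unchanged(self):
        t = self._tensor(PSD, np.full((10, 2, 3), 2.5))
        np.testing.assert_allclose(eg.block_average(t, 5).data, 2.5)

    def test_remainder_dropped_with_warning(self):
        t = self._tensor(PSD, np.ones((13, 2, 3)))
        with pytest.warns(UserWarning, match="trailing"):
            out = eg.block_average(t, 5)
        assert out.n_trials == 2

    def test_blocks_respect_group_boundaries(self):
        a = self._tensor(PSD, np.zeros((5, 2, 3)))
        b = self._tensor(PSD, np.ones((5, 2, 3)))
        b.subjects = np.repeat("S02", 5)
        merged = concat_tensors([a, b])
        out = eg.block_average(merged, 5)
        assert out.n_trials == 2
        np.testing.assert_array_equal(out.data[0], 0.0)
        np.testing.assert_array_equal(out.data[1], 1.0)
        assert list(out.subjects) == ["S01", "S02"]


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 100.0))
def test_coherence_scale_invariance_property(seed, factor):
    ep = random_epochs(n_epochs=3, n_channels=2, seed=seed)
    scaled = EpochArray(
        subject_id="s", run_id="r", condition="REO", fs=100.0,
        channel_labels=ep.channel_labels,
        epochs=ep.epochs * np.array([factor, 1.0])[None, :, None],
    )
    np.testing.assert_allclose(
        eg.coherence(ep).data, eg.coherence(scaled).data, atol=1e-9
    )


def test_config_validation():
    with pytest.raises(ConfigError):
        eg.WelchConfig(overlap_frac=1.0)
    with pytest.raises(ConfigError):
        eg.WelchConfig(segment_len=200, nfft=100)
    with pytest.raises(ConfigError):
        eg.WelchConfig(nfft=64, fs=100.0)  # 1 Hz bins not on the grid
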