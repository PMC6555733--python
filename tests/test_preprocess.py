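"""Filter chains, heel-strike detection, and both segmentation schemes.

Filter magnitude checks are validated against an independent frequency-
response oracle (``scipy.signal.sosfreqz`` evaluated at the test frequency,
squared for the forward-backward pass) rather than against the filtering
routine itself.
"""

import numpy as np
import pytest
from scipy import signal as sps

from gaitpower.preprocess import (ConfigError, EMG_BANDPASS, GRF_LOWPASS,
                                  compute_emg_normalizer, detect_heel_strikes,
                                  emg_envelope, filter_grf, process_emg,
                                  segment_fixed_windows, segment_gait_cycles)

FS = 2000.0


def _oracle_gain(spec, freq_hz, fs=FS):
    """Independent two-pass magnitude response at one frequency."""
    btype = "low" if spec.kind == "lowpass" else "bandpass"
    wn = spec.cutoffs[0] if spec.kind == "lowpass" else list(spec.cutoffs)
    sos = sps.butter(spec.order, wn, btype=btype, fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return np.abs(h[0]) ** 2  # forward-backward squares the magnitude


def _mid_amplitude(x):
    n = len(x)
    return np.abs(x[n // 4: 3 * n // 4]).max()


class TestGrfFilter:
    def test_dc_passes_at_unit_gain(self, channel_factory):
        ch = channel_factory("grf_r_z", np.full(4000, 500.0))
        np.testing.assert_allclose(filter_grf(ch).samples, 500.0, rtol=1e-9)

    @pytest.mark.parametrize("freq,check", [(500.0, "stop"), (5.0, "pass")])
    def test_magnitude_matches_independent_oracle(self, channel_factory, freq, check):
        t = np.arange(8000) / FS
        ch = channel_factory("grf_r_z", 100.0 * np.sin(2 * np.pi * freq * t))
        out = _mid_amplitude(filter_grf(ch).samples) / 100.0
        gain = _oracle_gain(GRF_LOWPASS, freq)
        if check == "stop":
            assert gain < 0.01 and out < 0.01
        else:
            assert gain > 0.98 and out == pytest.approx(gain, abs=0.02)

    def test_cutoff_above_nyquist_rejected(self, channel_factory):
        ch = channel_factory("grf_r_z", np.zeros(100), rate=50.0)
        with pytest.raises(ConfigError):
            filter_grf(ch)


class TestEmgChain:
    def test_zero_in_zero_out(self, channel_factory):
        ch = channel_factory("emg_r_soleus", np.zeros(4000))
        np.testing.assert_array_equal(process_emg(ch, 1.0).samples, 0.0)

    def test_dc_is_rejected(self, channel_factory):
        ch = channel_factory("emg_r_soleus", np.full(8000, 2.0))
        out = process_emg(ch, 1.0).samples
        mid = out[2000:-2000]
        assert np.abs(mid).max() < 1e-6 * 2.0

    def test_self_normalization_peaks_at_one(self, channel_factory):
        t = np.arange(8000) / FS
        ch = channel_factory("emg_r_soleus", 3.0 * np.sin(2 * np.pi * 100 * t))
        env_max = emg_envelope(ch).max()
        assert process_emg(ch, env_max).samples.max() == pytest.approx(1.0, abs=1e-9)

    def test_low_sampling_rate_rejected(self, channel_factory):
        ch = channel_factory("emg_r_soleus", np.zeros(2000), rate=800.0)
        with pytest.raises(ConfigError, match="band-pass"):
            process_emg(ch, 1.0)

    def test_nonpositive_normalizer_rejected(self, channel_factory):
        ch = channel_factory("emg_r_soleus", np.ones(2000))
        with pytest.raises(ValueError, match="normalizer"):
            process_emg(ch, 0.0)


class TestEmgNormalizer:
    def test_per_muscle_envelope_maxima(self, trial_factory, channel_factory):
        t = np.arange(8000) / FS
        trial = trial_factory(channels=[
            channel_factory("grf_r_z", np.zeros(8000)),
            channel_factory("emg_r_soleus", 2.0 * np.sin(2 * np.pi * 100 * t)),
            channel_factory("emg_r_vastus", 0.5 * np.sin(2 * np.pi * 150 * t))])
        norms = compute_emg_normalizer(trial)
        assert set(norms) == {"emg_r_soleus", "emg_r_vastus"}
        assert norms["emg_r_soleus"] == pytest.approx(emg_envelope(trial.channel("emg_r_soleus")).max())
        assert norms["emg_r_soleus"] > norms["emg_r_vastus"] > 0

    def test_all_zero_emg_rejected(self, trial_factory, channel_factory):
        trial = trial_factory(channels=[
            channel_factory("grf_r_z", np.zeros(4000)),
            channel_factory("emg_r_soleus", np.zeros(4000))])
        with pytest.raises(ValueError, match="peak"):
            compute_emg_normalizer(trial)

    def test_non_baseline_trial_rejected(self, trial_factory, channel_factory):
        trial = trial_factory(baseline=False, channels=[
            channel_factory("grf_r_z", np.zeros(4000)),
            channel_factory("emg_r_soleus", np.ones(4000))])
        with pytest.raises(ValueError, match="baseline"):
            compute_emg_normalizer(trial)


def _pulse_signal(n, starts, width=600, amp=700.0):
    x = np.zeros(n)
    for s in starts:
        x[s:s + width] = amp * np.sin(np.pi * np.arange(width) / width) ** 2
        x[s] = amp * 0.2  # steep onset
    return x


def _brute_force_strikes(x, threshold, refractory_samples):
    """Reference scan implementing the crossing + refractory rule directly."""
    out = []
    for i in range(1, len(x)):
        if x[i - 1] < threshold <= x[i] and (not out or i - out[-1] >= refractory_samples):
            out.append(i)
    return out


class TestHeelStrikes:
    def test_zero_force_gives_no_strikes(self, channel_factory):
        ch = channel_factory("grf_r_z", np.zeros(5000))
        assert detect_heel_strikes(ch).size == 0

    def test_planted_pulses_recovered_exactly(self, channel_factory):
        starts = [1000, 3100, 5150]
        ch = channel_factory("grf_r_z", _pulse_signal(7000, starts))
        assert detect_heel_strikes(ch, threshold=30.0).tolist() == starts

    def test_chatter_respects_refractory(self, channel_factory):
        # Oscillation around the threshold within 0.1 s, refractory 0.5 s.
        x = np.zeros(4000)
        for k in range(5):
            x[1000 + 40 * k: 1000 + 40 * k + 20] = 35.0
        ch = channel_factory("grf_r_z", x)
        got = detect_heel_strikes(ch, threshold=30.0, refractory=0.5).tolist()
        assert got == _brute_force_strikes(x, 30.0, int(0.5 * FS)) == [1000]

    def test_matches_brute_force_on_random_signal(self, channel_factory):
        rng = np.random.default_rng(3)
        x = np.abs(rng.normal(0, 40, 6000))
        ch = channel_factory("grf_r_z", x)
        got = detect_heel_strikes(ch, threshold=30.0, refractory=0.25).tolist()
        assert got == _brute_force_strikes(x, 30.0, int(0.25 * FS))


class TestGaitCycleSegmentation:
    def test_half_open_segments_between_strikes(self, trial_factory):
        trial = trial_factory(n_samples=600)
        segs = segment_gait_cycles(trial, [100, 300, 520])
        assert [(s.start_index, s.end_index) for s in segs] == [(100, 300), (300, 520)]
        assert [len(s) for s in segs] == [200, 220]

    def test_fewer_than_two_strikes_yields_empty(self, trial_factory):
        assert segment_gait_cycles(trial_factory(), [50]) == []

    def test_slices_concatenate_to_original_span(self, trial_factory, channel_factory):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        trial = trial_factory(channels=[channel_factory("grf_r_z", x)])
        segs = segment_gait_cycles(trial, [100, 450, 900])
        joined = np.concatenate([s.channel_slices["grf_r_z"] for s in segs])
        np.testing.assert_array_equal(joined, x[100:900])


class TestFixedWindows:
    def test_four_seconds_at_2000hz_gives_250_steps(self, trial_factory):
        windows = segment_fixed_windows(trial_factory(n_samples=8000))
        assert len(windows) == 1 and windows[0].matrix.shape == (250, 1)

    def test_trailing_partial_window_discarded(self, trial_factory):
        assert len(segment_fixed_windows(trial_factory(n_samples=16500))) == 2

    def test_constant_channel_preserved(self, trial_factory, channel_factory):
        trial = trial_factory(channels=[channel_factory("grf_r_z", np.full(8000, 3.25))])
        np.testing.assert_array_equal(segment_fixed_windows(trial)[0].matrix, 3.25)

    def test_block_average_preserves_window_mean(self, trial_factory, channel_factory):
        rng = np.random.default_rng(2)
        x = rng.normal(size=8000)
        trial = trial_factory(channels=[channel_factory("grf_r_z", x)])
        mat = segment_fixed_windows(trial)[0].matrix
        assert mat.mean() == pytest.approx(x.mean(), rel=1e-12)

    def test_short_trial_yields_empty(self, trial_factory):
        assert segment_fixed_windows(trial_factory(n_samples=4000)) == []

    def test_indivisible_block_rejected(self, trial_factory):
        with pytest.raises(ConfigError, match="divisible"):
            segment_fixed_windows(trial_factory(n_samples=8000), block=33)


class TestFilterProperties:
    def test_linearity(self, channel_factory):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=4000), rng.normal(size=4000)
        f = lambda arr: filter_grf(channel_factory("grf_r_z", arr)).samples
        combo = f(2.0 * x + 3.0 * y)
        np.testing.assert_allclose(combo, 2.0 * f(x) + 3.0 * f(y),
                                   rtol=1e-9, atol=1e-9 * np.abs(combo).max())

    def test_zero_phase_pulse_has_no_lag(self, channel_factory):
        # Band-limited pulse: the filtered output's cross-correlation with the
        # input must peak at zero lag.
        t = np.arange(4000) / FS
        x = np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2)
        out = filter_grf(channel_factory("grf_r_z", x)).samples
        lags = sps.correlation_lags(len(out), len(x))
        assert lags[np.argmax(sps.correlate(out, x))] == 0
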