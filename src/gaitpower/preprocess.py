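"""Signal conditioning and segmentation for walking trials.

Force channels get a 4th-order Butterworth low-pass at 30 Hz; EMG channels a
30-500 Hz band-pass, full-wave rectification, a 6 Hz low-pass envelope, and
normalization by the envelope maximum of the subject's normal-walking trial.
All filters are applied zero-phase (forward-backward), the standard choice in
gait analysis where timing alignment across channels matters; the effective
stop-band attenuation is therefore the squared single-pass response.

Two segmentation schemes are provided: heel-strike-to-heel-strike gait cycles
detected from the right vertical ground reaction force, and fixed 4-second
windows block-averaged down to 250 time steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io_dataset import RIGHT_VERTICAL_GRF, SignalChannel, TrialRecording

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "FilterSpec",
    "GaitCycleSegment",
    "FixedWindow",
    "GRF_LOWPASS",
    "EMG_BANDPASS",
    "EMG_ENVELOPE_LOWPASS",
    "HEEL_STRIKE_THRESHOLD_N",
    "HEEL_STRIKE_REFRACTORY_S",
    "filter_grf",
    "process_emg",
    "emg_envelope",
    "compute_emg_normalizer",
    "detect_heel_strikes",
    "segment_gait_cycles",
    "segment_fixed_windows",
    "preprocess_trial",
]


class ConfigError(ValueError):
    """A filter or segmentation parameter is infeasible for the signal."""


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth filter: order, kind, cutoff(s) in Hz, zero-phase flag."""

    order: int
    kind: str  # "lowpass" | "bandpass"
    cutoffs: tuple[float, ...]
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ConfigError("filter order must be >= 1")
        if self.kind not in ("lowpass", "bandpass"):
            raise ConfigError(f"unknown filter kind {self.kind!r}")
        if any(c <= 0 for c in self.cutoffs):
            raise ConfigError("cutoffs must be strictly positive")
        if self.kind == "lowpass" and len(self.cutoffs) != 1:
            raise ConfigError("lowpass takes exactly one cutoff")
        if self.kind == "bandpass":
            if len(self.cutoffs) != 2:
                raise ConfigError("bandpass takes exactly two cutoffs")
            if not self.cutoffs[0] < self.cutoffs[1]:
                raise ConfigError("bandpass requires low < high cutoff")

    def apply(self, x: np.ndarray, sampling_rate: float) -> np.ndarray:
        nyquist = sampling_rate / 2.0
        if max(self.cutoffs) >= nyquist:
            raise ConfigError(
                f"cutoff {max(self.cutoffs)} Hz >= Nyquist {nyquist} Hz at fs={sampling_rate} Hz")
        btype = "low" if self.kind == "lowpass" else "bandpass"
        wn = self.cutoffs[0] if self.kind == "lowpass" else list(self.cutoffs)
        sos = sps.butter(self.order, wn, btype=btype, fs=sampling_rate, output="sos")
        if self.zero_phase:
            return sps.sosfiltfilt(sos, x)
        return sps.sosfilt(sos, x)


#: Default conditioning chain parameters.
GRF_LOWPASS = FilterSpec(order=4, kind="lowpass", cutoffs=(30.0,))
EMG_BANDPASS = FilterSpec(order=4, kind="bandpass", cutoffs=(30.0, 500.0))
EMG_ENVELOPE_LOWPASS = FilterSpec(order=4, kind="lowpass", cutoffs=(6.0,))

#: Heel-strike detector defaults: well above the filtered-noise floor and well
#: below bodyweight; the refractory period excludes within-stance chatter at
#: walking cadences.
HEEL_STRIKE_THRESHOLD_N = 30.0
HEEL_STRIKE_REFRACTORY_S = 0.5


@dataclass
class GaitCycleSegment:
    """All channels of one heel-strike-to-heel-strike slice, half-open."""

    start_index: int
    end_index: int
    channel_slices: dict[str, np.ndarray]
    subject_id: str
    condition_id: str

    def __post_init__(self) -> None:
        if not self.end_index > self.start_index:
            raise ValueError("segment end_index must exceed start_index")

    def __len__(self) -> int:
        return self.end_index - self.start_index


@dataclass
class FixedWindow:
    """One block-averaged fixed-duration window: (time steps x channels)."""

    matrix: np.ndarray
    subject_id: str
    condition_id: str
    channel_names: list[str]
    label: float | None = None  # condition steady-state power, W


def filter_grf(channel: SignalChannel, spec: FilterSpec = GRF_LOWPASS) -> SignalChannel:
    """Low-pass a ground-reaction-force channel (default 30 Hz, 4th order)."""
    if channel.kind != "grf":
        raise ValueError(f"filter_grf expects a grf channel, got {channel.name} ({channel.kind})")
    if channel.sampling_rate <= 2 * max(spec.cutoffs):
        raise ConfigError(
            f"{channel.name}: sampling rate {channel.sampling_rate} Hz too low for "
            f"{max(spec.cutoffs)} Hz cutoff")
    return replace(channel, samples=spec.apply(channel.samples, channel.sampling_rate))


def emg_envelope(channel: SignalChannel,
                 bandpass: FilterSpec = EMG_BANDPASS,
                 lowpass: FilterSpec = EMG_ENVELOPE_LOWPASS) -> np.ndarray:
    """Unnormalized EMG linear envelope: band-pass, rectify, low-pass."""
    if channel.kind != "emg":
        raise ValueError(f"emg processing expects an emg channel, got {channel.name}")
    if channel.sampling_rate <= 2 * max(bandpass.cutoffs):
        raise ConfigError(
            f"{channel.name}: sampling rate {channel.sampling_rate} Hz must exceed twice the "
            f"band-pass upper cutoff {max(bandpass.cutoffs)} Hz")
    x = bandpass.apply(channel.samples, channel.sampling_rate)
    x = np.abs(x)
    return lowpass.apply(x, channel.sampling_rate)


def process_emg(channel: SignalChannel, normalizer: float) -> SignalChannel:
    """Full EMG chain: band-pass, rectify, envelope low-pass, divide by max.

    ``normalizer`` is the envelope maximum of the same muscle in the subject's
    normal-walking trial (see :func:`compute_emg_normalizer`).
    """
    if not normalizer > 0:
        raise ValueError(f"{channel.name}: EMG normalizer must be > 0, got {normalizer}")
    return replace(channel, samples=emg_envelope(channel) / normalizer)


def compute_emg_normalizer(baseline_trial: TrialRecording) -> dict[str, float]:
    """Per-muscle envelope maxima from the normal-walking (baseline) trial."""
    if not baseline_trial.condition.is_baseline_normal_walk:
        raise ValueError(
            f"condition {baseline_trial.condition.condition_id} is not the baseline normal walk")
    out: dict[str, float] = {}
    for ch in baseline_trial.channels:
        if ch.kind != "emg":
            continue
        peak = float(np.max(emg_envelope(ch)))
        if not peak > 0:
            raise ValueError(f"{ch.name}: baseline envelope peak is not positive; cannot normalize")
        out[ch.name] = peak
    if not out:
        raise ValueError("baseline trial has no EMG channels")
    return out


def detect_heel_strikes(vertical_grf: SignalChannel,
                        threshold: float = HEEL_STRIKE_THRESHOLD_N,
                        refractory: float = HEEL_STRIKE_REFRACTORY_S) -> np.ndarray:
    """Indices of upward threshold crossings of the vertical GRF.

    A strike is a sample ``i`` with ``x[i-1] < threshold <= x[i]``; crossings
    closer than ``refractory`` seconds to the previous accepted strike are
    discarded.  Returns a sorted integer array (possibly empty).
    """
    if vertical_grf.kind != "grf":
        raise ValueError("heel-strike detection requires a grf channel")
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    x = vertical_grf.samples
    crossings = np.flatnonzero((x[:-1] < threshold) & (x[1:] >= threshold)) + 1
    if crossings.size == 0:
        return crossings
    min_gap = int(round(refractory * vertical_grf.sampling_rate))
    accepted = [int(crossings[0])]
    for idx in crossings[1:]:
        if idx - accepted[-1] >= min_gap:
            accepted.append(int(idx))
    return np.asarray(accepted, dtype=int)


def segment_gait_cycles(trial: TrialRecording, heel_strikes) -> list[GaitCycleSegment]:
    """One half-open segment per consecutive heel-strike pair."""
    heel_strikes = np.asarray(heel_strikes, dtype=int)
    if heel_strikes.size < 2:
        logger.warning("trial %s/%s: %d heel strike(s), no gait cycles",
                       trial.subject.subject_id, trial.condition.condition_id, heel_strikes.size)
        return []
    segments = []
    for start, end in zip(heel_strikes[:-1], heel_strikes[1:]):
        segments.append(GaitCycleSegment(
            start_index=int(start), end_index=int(end),
            channel_slices={ch.name: ch.samples[start:end] for ch in trial.channels},
            subject_id=trial.subject.subject_id,
            condition_id=trial.condition.condition_id))
    return segments


def segment_fixed_windows(trial: TrialRecording, window_s: float = 4.0,
                          block: int = 32) -> list[FixedWindow]:
    """Non-overlapping ``window_s`` spans block-averaged every ``block`` samples.

    At the defaults (4 s at 2000 Hz, block 32) each window has exactly 250
    time steps.  A trailing partial span is discarded.
    """
    fs = trial.sampling_rate
    window_len = window_s * fs
    if abs(window_len - round(window_len)) > 1e-9 or round(window_len) % block != 0:
        raise ConfigError(
            f"window of {window_s} s at {fs} Hz ({window_len} samples) is not divisible by block {block}")
    window_len = int(round(window_len))
    n_steps = window_len // block
    n_windows = trial.n_samples // window_len
    if n_windows == 0:
        logger.warning("trial %s/%s shorter than one %g s window",
                       trial.subject.subject_id, trial.condition.condition_id, window_s)
        return []
    names = trial.channel_names()
    data = np.column_stack([ch.samples for ch in trial.channels])
    windows = []
    for w in range(n_windows):
        chunk = data[w * window_len:(w + 1) * window_len]
        mat = chunk.reshape(n_steps, block, len(names)).mean(axis=1)
        windows.append(FixedWindow(matrix=mat, subject_id=trial.subject.subject_id,
                                   condition_id=trial.condition.condition_id,
                                   channel_names=list(names)))
    return windows


def preprocess_trial(trial: TrialRecording,
                     emg_normalizers: dict[str, float] | None,
                     raw_mode: bool = False) -> TrialRecording:
    """Apply the per-channel conditioning chains to a whole trial.

    In raw mode no filtering is applied at all; EMG channels are only
    full-wave rectified (and not normalized), emulating unprocessed wearable
    input.
    """
    processed = []
    for ch in trial.channels:
        if raw_mode:
            processed.append(replace(ch, samples=np.abs(ch.samples)) if ch.kind == "emg" else ch)
        elif ch.kind == "grf":
            processed.append(filter_grf(ch))
        else:
            if emg_normalizers is None or ch.name not in emg_normalizers:
                raise ValueError(f"no EMG normalizer for channel {ch.name}")
            processed.append(process_emg(ch, emg_normalizers[ch.name]))
    return trial.with_channels(processed)
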