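"""Fixed-length feature vectors and labeled windows for the estimators.

Each gait cycle becomes a vector of 30 bin means per channel, concatenated in
channel order (length 30 x C).  Bin b of an L-sample channel averages samples
in [round(b*L/30), round((b+1)*L/30)) with half-up rounding, which keeps bin
widths within one sample of each other and tiles the cycle exactly.  Every
cycle or window of a condition inherits that condition's steady-state power
as its label; there is no per-cycle ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .io_dataset import TrialRecording
from .preprocess import (FixedWindow, GaitCycleSegment, compute_emg_normalizer,
                         detect_heel_strikes, filter_grf, preprocess_trial,
                         segment_fixed_windows, segment_gait_cycles)

logger = logging.getLogger(__name__)

__all__ = [
    "N_BINS",
    "ChannelSubset",
    "FeatureVector",
    "bin_cycle",
    "bin_boundaries",
    "select_channels",
    "assemble_features",
    "assemble_windows",
    "compute_condition_labels",
]

#: Number of bins per channel per gait cycle.
N_BINS = 30

#: Key type for condition labels: (subject_id, condition_id) -> power in W.
LabelMap = Mapping[tuple[str, str], float]


class ChannelSubset(str, Enum):
    """Which input signals feed the model."""

    ALL = "all"
    VERTICAL_FORCE_PLUS_EMG = "vertical_force_plus_emg"
    FORCES_ONLY = "forces_only"
    EMG_ONLY = "emg_only"


@dataclass
class FeatureVector:
    """One gait cycle's binned features with its condition-level label."""

    x: np.ndarray  # length N_BINS * C
    y: float  # steady-state power, W
    subject_id: str
    condition_id: str
    mass: float  # kg

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if not self.y > 0:
            raise ValueError("feature label y must be > 0 W")


def select_channels(names: Sequence[str], subset: ChannelSubset) -> list[str]:
    """Channel names retained under a subset mode, preserving order."""
    def keep(name: str) -> bool:
        kind = name.split("_", 1)[0]
        if subset is ChannelSubset.ALL:
            return True
        if subset is ChannelSubset.FORCES_ONLY:
            return kind == "grf"
        if subset is ChannelSubset.EMG_ONLY:
            return kind == "emg"
        if subset is ChannelSubset.VERTICAL_FORCE_PLUS_EMG:
            return kind == "emg" or (kind == "grf" and name.endswith("_z"))
        raise ValueError(f"unknown subset {subset}")
    selected = [n for n in names if keep(n)]
    if not selected:
        raise ValueError(f"channel subset {subset.value} selects no channels from {list(names)}")
    return selected


def bin_boundaries(length: int, n_bins: int = N_BINS) -> np.ndarray:
    """Half-up-rounded bin edges: edge b = floor(b*L/n + 0.5)."""
    b = np.arange(n_bins + 1)
    return np.floor(b * length / n_bins + 0.5).astype(int)


def bin_cycle(segment: GaitCycleSegment, n_bins: int = N_BINS) -> np.ndarray:
    """Concatenated per-channel bin means for one gait cycle."""
    length = len(segment)
    if length < n_bins:
        raise ValueError(
            f"segment [{segment.start_index},{segment.end_index}) of "
            f"{segment.subject_id}/{segment.condition_id} has {length} samples < {n_bins} bins")
    edges = bin_boundaries(length, n_bins)
    parts = []
    for name, samples in segment.channel_slices.items():
        sums = np.add.reduceat(samples, edges[:-1])
        parts.append(sums / np.diff(edges))
    return np.concatenate(parts)


def _baseline_normalizers(trials: Sequence[TrialRecording]) -> dict[str, dict[str, float]]:
    """Per-subject EMG normalizers from each subject's normal-walking trial."""
    normalizers: dict[str, dict[str, float]] = {}
    for trial in trials:
        if trial.condition.is_baseline_normal_walk:
            sid = trial.subject.subject_id
            if sid in normalizers:
                raise ValueError(f"subject {sid} has more than one baseline normal-walk trial")
            if any(ch.kind == "emg" for ch in trial.channels):
                normalizers[sid] = compute_emg_normalizer(trial)
            else:
                normalizers[sid] = {}
    return normalizers


def _prepare(trial: TrialRecording, normalizers: dict[str, dict[str, float]],
             subset: ChannelSubset, raw_mode: bool) -> TrialRecording:
    sid = trial.subject.subject_id
    if not raw_mode and sid not in normalizers and any(ch.kind == "emg" for ch in trial.channels):
        raise ValueError(f"subject {sid} has no baseline normal-walk trial for EMG normalization")
    processed = preprocess_trial(trial, normalizers.get(sid), raw_mode=raw_mode)
    names = select_channels(processed.channel_names(), subset)
    return processed.with_channels([processed.channel(n) for n in names])


def _label_for(trial: TrialRecording, labels: LabelMap) -> float:
    key = (trial.subject.subject_id, trial.condition.condition_id)
    if key not in labels:
        raise ValueError(f"no steady-state label for subject/condition {key}")
    return labels[key]


def assemble_features(trials: Sequence[TrialRecording], labels: LabelMap,
                      subset: ChannelSubset = ChannelSubset.ALL,
                      raw_mode: bool = False,
                      n_bins: int = N_BINS) -> list[FeatureVector]:
    """Run the per-gait-cycle pipeline over a dataset.

    Per trial: condition (or raw-rectify) the channels, detect right heel
    strikes on the vertical GRF, slice gait cycles, bin each cycle, and label
    every cycle with the condition's steady-state power.
    """
    normalizers = _baseline_normalizers(trials)
    out: list[FeatureVector] = []
    for trial in trials:
        y = _label_for(trial, labels)
        prepared = _prepare(trial, normalizers, subset, raw_mode)
        # Strikes always come from the right vertical GRF of the full trial
        # (filtered unless in raw mode), even when the feature subset drops it.
        grf_z = trial.channel("grf_r_z")
        strikes = detect_heel_strikes(grf_z if raw_mode else filter_grf(grf_z))
        for segment in segment_gait_cycles(prepared, strikes):
            out.append(FeatureVector(x=bin_cycle(segment, n_bins), y=y,
                                     subject_id=trial.subject.subject_id,
                                     condition_id=trial.condition.condition_id,
                                     mass=trial.subject.mass))
    return out


def assemble_windows(trials: Sequence[TrialRecording], labels: LabelMap,
                     subset: ChannelSubset = ChannelSubset.ALL,
                     raw_mode: bool = False,
                     window_s: float = 4.0, block: int = 32) -> list[FixedWindow]:
    """Run the fixed-interval pipeline: labeled block-averaged windows."""
    normalizers = _baseline_normalizers(trials)
    out: list[FixedWindow] = []
    for trial in trials:
        y = _label_for(trial, labels)
        prepared = _prepare(trial, normalizers, subset, raw_mode)
        for window in segment_fixed_windows(prepared, window_s=window_s, block=block):
            window.label = y
            out.append(window)
    if not out:
        logger.warning("no windows assembled (all trials shorter than %g s?)", window_s)
    return out


def compute_condition_labels(trials: Sequence[TrialRecording]) -> dict[tuple[str, str], float]:
    """Steady-state power per (subject, condition) from each trial's breaths."""
    from .calorimetry import steady_state_ee

    return {(t.subject.subject_id, t.condition.condition_id): steady_state_ee(t.breaths)
            for t in trials}
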