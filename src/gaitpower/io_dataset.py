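"""On-disk dataset layout and validated in-memory records for walking trials.

A dataset is a directory tree with one leaf directory per subject x condition:

    root/<subject_id>/<condition_id>/
        signals.csv   one column per signal channel; header row names channels
        breaths.csv   columns time, vo2, vco2 (s, L/min, L/min)
        meta.json     subject metadata, condition metadata, sampling_rate

Channel names follow the convention ``<kind>_<side>_<axis|muscle>``, e.g.
``grf_r_z`` (right-foot vertical ground reaction force, N) or
``emg_r_soleus`` (right soleus EMG, arbitrary units).  Numbers are serialized
at full double precision so filter outputs survive a round trip.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "SignalChannel",
    "BreathSample",
    "SubjectMeta",
    "ConditionMeta",
    "TrialRecording",
    "write_trial",
    "read_trial",
    "load_dataset",
    "channel_name",
]

SIGNALS_FILE = "signals.csv"
BREATHS_FILE = "breaths.csv"
META_FILE = "meta.json"

#: Canonical name of the channel used for gait-cycle segmentation.
RIGHT_VERTICAL_GRF = "grf_r_z"


class ValidationError(ValueError):
    """An in-memory record violates a dataset invariant."""


class ParseError(ValueError):
    """On-disk content does not conform to the documented schema."""


def channel_name(kind: str, side: str, axis_or_muscle: str) -> str:
    """Build a channel name from its parts, e.g. ``("grf", "r", "z")``."""
    return f"{kind}_{side}_{axis_or_muscle}"


@dataclass
class SignalChannel:
    """One synchronized signal channel of a trial.

    Parameters
    ----------
    name:
        Channel name following ``<kind>_<side>_<axis|muscle>``.
    kind:
        ``"grf"`` (ground reaction force, N) or ``"emg"`` (arbitrary units).
    axis_or_muscle:
        Force axis (``x``/``y``/``z``) or muscle name.
    samples:
        The signal itself, one value per sample.
    sampling_rate:
        Sampling frequency in Hz; shared by all channels of a trial.
    """

    name: str
    kind: str
    axis_or_muscle: str
    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.kind not in ("grf", "emg"):
            raise ValidationError(f"channel {self.name}: kind must be 'grf' or 'emg', got {self.kind!r}")
        if not self.sampling_rate > 0:
            raise ValidationError(f"channel {self.name}: sampling_rate must be > 0")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValidationError(f"channel {self.name}: samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"channel {self.name}: samples contain non-finite values")

    @classmethod
    def from_name(cls, name: str, samples, sampling_rate: float) -> "SignalChannel":
        """Construct a channel, deriving kind and axis/muscle from its name."""
        parts = name.split("_", 2)
        if len(parts) != 3:
            raise ParseError(f"channel name {name!r} does not follow '<kind>_<side>_<axis|muscle>'")
        kind, _side, axis_or_muscle = parts
        return cls(name=name, kind=kind, axis_or_muscle=axis_or_muscle,
                   samples=samples, sampling_rate=sampling_rate)

    @property
    def side(self) -> str:
        return self.name.split("_", 2)[1]


@dataclass(frozen=True)
class BreathSample:
    """One breath-by-breath gas-exchange record (time s, VO2 and VCO2 L/min)."""

    time: float
    vo2: float
    vco2: float

    def __post_init__(self) -> None:
        if self.vo2 < 0 or self.vco2 < 0:
            raise ValidationError("breath gas rates must be non-negative")


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    mass: float  # kg
    leg_length: float | None = None  # m

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ValidationError(f"subject {self.subject_id}: mass must be > 0")


@dataclass(frozen=True)
class ConditionMeta:
    condition_id: str
    incline_grade: float = 0.0  # fraction (0.10 = 10% grade)
    load_fraction: float = 0.0  # fraction of bodyweight carried
    assistance_work: float = 0.0  # J per gait cycle, 0 if unassisted
    is_baseline_normal_walk: bool = False

    def __post_init__(self) -> None:
        if self.load_fraction < 0:
            raise ValidationError(f"condition {self.condition_id}: load_fraction must be >= 0")


@dataclass
class TrialRecording:
    """One subject x condition recording: signals, breaths, and metadata."""

    subject: SubjectMeta
    condition: ConditionMeta
    channels: list[SignalChannel]
    breaths: list[BreathSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.channels:
            raise ValidationError("trial has no channels")
        length = self.channels[0].samples.size
        rate = self.channels[0].sampling_rate
        for ch in self.channels:
            if ch.samples.size != length:
                raise ValidationError(
                    f"channel {ch.name}: length {ch.samples.size} != {length} of {self.channels[0].name}")
            if ch.sampling_rate != rate:
                raise ValidationError(f"channel {ch.name}: sampling_rate differs across channels")
        if RIGHT_VERTICAL_GRF not in {ch.name for ch in self.channels}:
            raise ValidationError(f"trial must contain a right-foot vertical GRF channel '{RIGHT_VERTICAL_GRF}'")
        times = [b.time for b in self.breaths]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("breath times must be strictly increasing")

    @property
    def sampling_rate(self) -> float:
        return self.channels[0].sampling_rate

    @property
    def n_samples(self) -> int:
        return self.channels[0].samples.size

    def channel(self, name: str) -> SignalChannel:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(f"no channel named {name!r}")

    def channel_names(self) -> list[str]:
        return [ch.name for ch in self.channels]

    def with_channels(self, channels: Sequence[SignalChannel]) -> "TrialRecording":
        """Copy of this trial with the channel list replaced."""
        return TrialRecording(subject=self.subject, condition=self.condition,
                              channels=list(channels), breaths=list(self.breaths))


def _trial_dir(root: Path, trial: TrialRecording) -> Path:
    return Path(root) / trial.subject.subject_id / trial.condition.condition_id


def write_trial(trial: TrialRecording, root) -> Path:
    """Write one trial under ``root/subject_id/condition_id/``.

    Returns the trial directory.  Values round-trip losslessly (printed with
    17 significant digits).
    """
    trial.validate()
    out = _trial_dir(Path(root), trial)
    out.mkdir(parents=True, exist_ok=True)

    signals = pd.DataFrame({ch.name: ch.samples for ch in trial.channels})
    signals.to_csv(out / SIGNALS_FILE, index=False, float_format="%.17g")

    breaths = pd.DataFrame(
        {"time": [b.time for b in trial.breaths],
         "vo2": [b.vo2 for b in trial.breaths],
         "vco2": [b.vco2 for b in trial.breaths]})
    breaths.to_csv(out / BREATHS_FILE, index=False, float_format="%.17g")

    meta = {
        "subject": {"subject_id": trial.subject.subject_id,
                    "mass": trial.subject.mass,
                    "leg_length": trial.subject.leg_length},
        "condition": {"condition_id": trial.condition.condition_id,
                      "incline_grade": trial.condition.incline_grade,
                      "load_fraction": trial.condition.load_fraction,
                      "assistance_work": trial.condition.assistance_work,
                      "is_baseline_normal_walk": trial.condition.is_baseline_normal_walk},
        "sampling_rate": trial.sampling_rate,
    }
    (out / META_FILE).write_text(json.dumps(meta, indent=1))
    return out


def _require(mapping: dict, key: str, where: str):
    if key not in mapping or mapping[key] is None:
        raise ParseError(f"{where}: missing required field {key!r}")
    return mapping[key]


def read_trial(path) -> TrialRecording:
    """Read one trial directory written by :func:`write_trial`."""
    path = Path(path)
    for fname in (SIGNALS_FILE, BREATHS_FILE, META_FILE):
        if not (path / fname).is_file():
            raise ParseError(f"{path}: missing {fname}")

    try:
        meta = json.loads((path / META_FILE).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path / META_FILE}: invalid JSON ({exc})") from exc
    subj_raw = _require(meta, "subject", str(path / META_FILE))
    cond_raw = _require(meta, "condition", str(path / META_FILE))
    rate = float(_require(meta, "sampling_rate", str(path / META_FILE)))
    subject = SubjectMeta(
        subject_id=str(_require(subj_raw, "subject_id", str(path / META_FILE))),
        mass=float(_require(subj_raw, "mass", str(path / META_FILE))),
        leg_length=subj_raw.get("leg_length"))
    condition = ConditionMeta(
        condition_id=str(_require(cond_raw, "condition_id", str(path / META_FILE))),
        incline_grade=float(cond_raw.get("incline_grade", 0.0)),
        load_fraction=float(cond_raw.get("load_fraction", 0.0)),
        assistance_work=float(cond_raw.get("assistance_work", 0.0)),
        is_baseline_normal_walk=bool(cond_raw.get("is_baseline_normal_walk", False)))

    signals = pd.read_csv(path / SIGNALS_FILE)
    channels = []
    for name in signals.columns:
        try:
            channels.append(SignalChannel.from_name(name, signals[name].to_numpy(float), rate))
        except (ParseError, ValidationError) as exc:
            raise ParseError(f"{path / SIGNALS_FILE}: {exc}") from exc

    breaths_df = pd.read_csv(path / BREATHS_FILE)
    expected = ["time", "vo2", "vco2"]
    if list(breaths_df.columns) != expected:
        raise ParseError(f"{path / BREATHS_FILE}: columns {list(breaths_df.columns)} != {expected}")
    breaths = [BreathSample(float(t), float(o), float(c))
               for t, o, c in breaths_df.itertuples(index=False)]

    try:
        return TrialRecording(subject=subject, condition=condition,
                              channels=channels, breaths=breaths)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def load_dataset(root) -> list[TrialRecording]:
    """Load every trial under ``root``, ordered by subject then condition id."""
    root = Path(root)
    if not root.is_dir():
        raise ParseError(f"dataset root {root} is not a directory")
    trial_dirs = sorted(
        (d for d in root.glob("*/*") if d.is_dir() and (d / META_FILE).is_file()),
        key=lambda d: (d.parent.name, d.name))
    if not trial_dirs:
        raise ParseError(f"dataset root {root} contains no trial directories")
    trials = []
    for d in trial_dirs:
        try:
            trials.append(read_trial(d))
        except ParseError as exc:
            raise ParseError(f"malformed trial at {d}: {exc}") from exc
    n_subjects = len({t.subject.subject_id for t in trials})
    n_conditions = len({t.condition.condition_id for t in trials})
    logger.info("loaded %d trials: %d subjects, %d condition ids", len(trials), n_subjects, n_conditions)
    return trials
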