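"""Synthetic multi-subject walking datasets with known energy expenditure.

The generator emulates the structure of the two treadmill study designs the
estimation pipeline targets:

* ``assisted`` — unilateral ankle-assistance walking: 22 channels (3-axis
  ground reaction forces per foot plus 8 muscles on each leg) across 9
  assistance strategies spanning roughly 270-420 W of metabolic power.
* ``incline_load`` — walking with a weighted vest on a graded treadmill:
  14 channels (6 GRF + 8 right-leg muscles), 4 loads (0-30% bodyweight) x
  3 inclines (0/5/10% grade) = 12 conditions per subject, spanning roughly
  190-890 W.

Signals are built from analytic waveforms so every downstream stage has an
oracle: the vertical GRF is a double-peaked stance waveform whose first
stance sample already exceeds the heel-strike threshold (strike indices are
therefore recoverable exactly), shear axes are phase-locked low-amplitude
waveforms, and EMG channels are band-limited carriers amplitude-modulated by
Gaussian activation bursts that strengthen with incline and load and weaken
with assistance.  Breath records are produced by inverting the Brockway
equation at a fixed respiratory exchange ratio.  True metabolic power follows
a physiological linear model in mass, grade, load, and assistance work, plus
an optional per-subject offset that makes novel-subject estimation measurably
harder than novel-condition estimation.

With ``planted_linear=True`` (and the noise-free factory defaults) the true
power is an exact linear function of the noiseless binned features, so
ordinary least squares must recover it to numerical precision on every
cross-validation split — a full-pipeline correctness oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .calorimetry import (BROCKWAY_CO2_KJ_PER_L, BROCKWAY_O2_KJ_PER_L)
from .io_dataset import (BreathSample, ConditionMeta, SignalChannel, SubjectMeta,
                         TrialRecording, channel_name)

__all__ = [
    "EEModel",
    "GeneratorConfig",
    "GroundTruthRecord",
    "assisted_conditions",
    "incline_load_conditions",
    "generate_dataset",
    "invert_brockway",
]

GRAVITY = 9.81  # m/s^2

#: Muscles instrumented in each design (8 per leg).
ASSISTED_MUSCLES = ("soleus_med", "soleus_lat", "gastroc_med", "gastroc_lat",
                    "tibialis_ant", "vastus_med", "biceps_fem", "rectus_fem")
INCLINE_MUSCLES = ("soleus", "gastroc_med", "tibialis_ant", "hamstring_med",
                   "hamstring_lat", "vastus_med", "vastus_lat", "rectus_fem")

#: Per-muscle activation burst (phase in the gait cycle, width, base amplitude).
_BURSTS = {
    "soleus": (0.42, 0.08, 0.9), "soleus_med": (0.42, 0.08, 0.9),
    "soleus_lat": (0.44, 0.08, 0.8), "gastroc_med": (0.40, 0.09, 0.85),
    "gastroc_lat": (0.41, 0.09, 0.7), "tibialis_ant": (0.02, 0.06, 0.6),
    "vastus_med": (0.10, 0.07, 0.7), "vastus_lat": (0.11, 0.07, 0.7),
    "biceps_fem": (0.90, 0.08, 0.6), "hamstring_med": (0.90, 0.08, 0.6),
    "hamstring_lat": (0.92, 0.08, 0.55), "rectus_fem": (0.62, 0.09, 0.5),
}

#: Per-muscle amplitude response to (incline grade, load fraction, assistance
#: work J/cycle).  Muscle groups respond differently, so incline, load, and
#: assistance are separately identifiable from the EMG envelopes.
_RESPONSE = {
    "soleus": (3.5, 1.0, -0.006), "soleus_med": (3.5, 1.0, -0.006),
    "soleus_lat": (3.2, 0.9, -0.005), "gastroc_med": (3.0, 1.0, -0.005),
    "gastroc_lat": (2.8, 0.9, -0.004), "tibialis_ant": (1.0, 0.5, -0.001),
    "vastus_med": (1.5, 1.8, -0.002), "vastus_lat": (1.4, 1.9, -0.002),
    "biceps_fem": (2.0, 1.2, -0.002), "hamstring_med": (2.0, 1.2, -0.002),
    "hamstring_lat": (1.9, 1.1, -0.002), "rectus_fem": (1.5, 1.6, -0.002),
}


def _muscle_gain(muscle: str, cond: ConditionMeta) -> float:
    a_i, b_l, c_w = _RESPONSE[muscle]
    return (1.0 + a_i * cond.incline_grade + b_l * cond.load_fraction
            + c_w * cond.assistance_work)

STANCE_FRACTION = 0.62
#: Vertical stance waveform floor: the first stance sample is this fraction of
#: the peak, far above the 30 N detection threshold, so planted strike indices
#: are exactly the detector's rising crossings.
STANCE_ONSET = 0.15


@dataclass(frozen=True)
class EEModel:
    """Linear physiological model of steady-state metabolic power.

    ``P = mass*(base + incline*grade + load*load_fraction)
    + assist*assistance_work + subject_offset`` with the offset drawn once per
    subject from N(0, subject_offset_sd).
    """

    base_w_per_kg: float
    incline_w_per_kg: float = 0.0  # W/kg per unit grade
    load_w_per_kg: float = 0.0  # W/kg per unit load fraction
    assist_w_per_j: float = 0.0  # W per J/cycle of assistance work
    subject_offset_sd: float = 0.0  # W

    def power(self, mass: float, condition: ConditionMeta, offset: float = 0.0) -> float:
        return (mass * (self.base_w_per_kg
                        + self.incline_w_per_kg * condition.incline_grade
                        + self.load_w_per_kg * condition.load_fraction)
                + self.assist_w_per_j * condition.assistance_work + offset)


def assisted_conditions() -> list[ConditionMeta]:
    """Nine assistance strategies; zero-work condition is the baseline walk."""
    works = [-40.0, -30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0, 40.0]
    return [ConditionMeta(condition_id=f"assist{k:02d}", assistance_work=w,
                          is_baseline_normal_walk=(w == 0.0))
            for k, w in enumerate(works)]


def incline_load_conditions() -> list[ConditionMeta]:
    """4 loads x 3 inclines; unloaded level walking is the baseline."""
    out = []
    for load in (0.0, 0.10, 0.20, 0.30):
        for grade in (0.0, 0.05, 0.10):
            out.append(ConditionMeta(
                condition_id=f"load{int(round(load * 100)):02d}_inc{int(round(grade * 100)):02d}",
                incline_grade=grade, load_fraction=load,
                is_baseline_normal_walk=(load == 0.0 and grade == 0.0)))
    return out


@dataclass
class GeneratorConfig:
    """Everything that determines a synthetic dataset (fully seeded)."""

    design: str = "assisted"  # "assisted" | "incline_load"
    n_subjects: int = 6
    conditions: list[ConditionMeta] = field(default_factory=list)
    trial_s: float = 20.0
    sampling_rate: float = 2000.0
    cadence_hz: float = 0.93  # strides per second
    stride_jitter_s: float = 0.02
    grf_sd: float = 4.0  # N
    emg_sd: float = 0.02  # a.u.
    breath_cv: float = 0.03
    breath_interval_s: float = 3.5
    rer: float = 0.85
    mass_mean: float = 77.5
    mass_sd: float = 5.6
    ee_model: EEModel = field(default_factory=lambda: EEModel(
        base_w_per_kg=4.43, assist_w_per_j=-1.9, subject_offset_sd=27.4))
    planted_linear: bool = False
    #: (intercept W, incline W/grade, load W/fraction, assistance W per J/cycle).
    #: In planted mode the GRF amplitude is held constant across subjects and
    #: conditions so gait-cycle boundaries are identical in every trial; the
    #: planted power therefore depends on the condition parameters, which the
    #: EMG envelopes encode exactly linearly.
    planted_weights: tuple[float, float, float, float] = (300.0, 1200.0, 250.0, -1.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("assisted", "incline_load"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not self.sampling_rate > 1000:
            raise ValueError("sampling_rate must exceed 1000 Hz (EMG band-pass Nyquist)")
        if min(self.grf_sd, self.emg_sd, self.breath_cv) < 0:
            raise ValueError("noise levels must be >= 0")
        if not self.conditions:
            self.conditions = (assisted_conditions() if self.design == "assisted"
                               else incline_load_conditions())
        if self.trial_s * self.cadence_hz < 2.5:
            raise ValueError("trial too short for two heel strikes at this cadence")

    @classmethod
    def incline_load(cls, n_subjects: int = 13, **kw) -> "GeneratorConfig":
        kw.setdefault("mass_mean", 68.8)
        kw.setdefault("mass_sd", 11.5)
        kw.setdefault("ee_model", EEModel(base_w_per_kg=2.7, incline_w_per_kg=50.0,
                                          load_w_per_kg=15.0, subject_offset_sd=38.0))
        return cls(design="incline_load", n_subjects=n_subjects, **kw)

    @classmethod
    def planted(cls, design: str = "assisted", n_subjects: int = 6, **kw) -> "GeneratorConfig":
        """Noise-free planted-linear configuration: the full-pipeline oracle."""
        base = dict(design=design, n_subjects=n_subjects, planted_linear=True,
                    stride_jitter_s=0.0, grf_sd=0.0, emg_sd=0.0, breath_cv=0.0)
        base.update(kw)
        if design == "incline_load":
            base.setdefault("mass_mean", 68.8)
            base.setdefault("mass_sd", 11.5)
        cfg = cls(**base)
        cfg.ee_model = EEModel(base_w_per_kg=cfg.ee_model.base_w_per_kg)  # unused fields zeroed
        return cfg


@dataclass
class GroundTruthRecord:
    """Oracle payload stored alongside a generated dataset."""

    true_power: dict[tuple[str, str], float]
    heel_strikes: dict[tuple[str, str], np.ndarray]
    subject_offsets: dict[str, float]
    planted_weights: tuple[float, ...] | None = None

    def save(self, path) -> None:
        payload = {
            "true_power": {f"{s}/{c}": p for (s, c), p in self.true_power.items()},
            "heel_strikes": {f"{s}/{c}": v.tolist() for (s, c), v in self.heel_strikes.items()},
            "subject_offsets": self.subject_offsets,
            "planted_weights": list(self.planted_weights) if self.planted_weights else None,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "GroundTruthRecord":
        payload = json.loads(Path(path).read_text())
        split = lambda k: tuple(k.split("/", 1))
        return cls(
            true_power={split(k): v for k, v in payload["true_power"].items()},
            heel_strikes={split(k): np.asarray(v, dtype=int)
                          for k, v in payload["heel_strikes"].items()},
            subject_offsets=payload["subject_offsets"],
            planted_weights=tuple(payload["planted_weights"]) if payload["planted_weights"] else None)


def invert_brockway(target_power: float, rer: float = 0.85) -> tuple[float, float]:
    """VO2, VCO2 (L/min) whose Brockway power equals ``target_power`` W.

    VCO2 = rer * VO2 with RER restricted to the aerobic range [0.7, 1.1].
    """
    if target_power < 0:
        raise ValueError("target power must be >= 0")
    if not 0.7 <= rer <= 1.1:
        raise ValueError(f"respiratory exchange ratio {rer} outside [0.7, 1.1]")
    vo2 = 60.0 * target_power / (1000.0 * (BROCKWAY_O2_KJ_PER_L + BROCKWAY_CO2_KJ_PER_L * rer))
    return vo2, rer * vo2


def _stance_shape(n: int) -> np.ndarray:
    """Double-peaked vertical stance waveform with a steep onset (peak 1)."""
    u = np.arange(n) / n
    f = np.sin(np.pi * u) ** 2 * (1 + 0.25 * np.cos(2 * np.pi * u))
    return STANCE_ONSET + (1 - STANCE_ONSET) * f / f.max()


def _clipped_normal(rng: np.random.Generator, sd: float, size) -> np.ndarray:
    """Gaussian noise truncated at 4 sigma (keeps swing noise below threshold)."""
    if sd == 0:
        return np.zeros(size)
    return np.clip(rng.normal(0.0, sd, size), -4 * sd, 4 * sd)


def _plant_strikes(n_samples: int, period: int, jitter_sd: float, fs: float,
                   offset: int, rng: np.random.Generator) -> np.ndarray:
    strikes = []
    pos = offset
    while pos < n_samples - 2:
        strikes.append(pos)
        step = period
        if jitter_sd > 0:
            step += int(round(rng.normal(0.0, jitter_sd * fs)))
        pos += max(step, int(0.5 * period))
    return np.asarray(strikes, dtype=int)


def _foot_grf(n_samples: int, strikes: np.ndarray, peak: float, stance_len: int,
              grf_sd: float, rng: np.random.Generator):
    """Vertical + shear waveforms for one foot given its strike indices."""
    z = np.zeros(n_samples)
    x = np.zeros(n_samples)
    y = np.zeros(n_samples)
    shape = _stance_shape(stance_len)
    u = np.arange(stance_len) / stance_len
    shear_ap = -np.sin(2 * np.pi * u) * shape  # braking then propulsion
    shear_ml = 0.4 * np.sin(np.pi * u) * shape
    for s in strikes:
        end = min(s + stance_len, n_samples)
        z[s:end] = peak * shape[:end - s]
        y[s:end] = 0.17 * peak * shear_ap[:end - s]
        x[s:end] = 0.05 * peak * shear_ml[:end - s]
    z += _clipped_normal(rng, grf_sd, n_samples)
    x += _clipped_normal(rng, 0.3 * grf_sd, n_samples)
    y += _clipped_normal(rng, 0.5 * grf_sd, n_samples)
    return x, y, z


def _emg_signal(n_samples: int, strikes: np.ndarray, period: int, amp: float,
                phase: float, width: float, fs: float, emg_sd: float,
                planted: bool, rng: np.random.Generator) -> np.ndarray:
    """Carrier modulated by a Gaussian activation burst at a gait phase.

    Phase is always normalized by the nominal distance to the next strike, so
    an end-of-trial truncated segment carries the same phase-locked waveform
    as complete cycles.
    """
    envelope = np.full(n_samples, 0.08 * amp)
    starts = [int(s) for s in strikes]
    for idx, s in enumerate(starts):
        nominal_end = starts[idx + 1] if idx + 1 < len(starts) else s + period
        e = min(nominal_end, n_samples)
        u = np.arange(e - s) / max(nominal_end - s, 1)
        d = np.minimum(np.abs(u - phase), 1 - np.abs(u - phase))  # circular distance
        envelope[s:e] = amp * (0.08 + np.exp(-0.5 * (d / width) ** 2))
        if planted:
            # Deterministic phase-locked carrier: identical every cycle.
            n_osc = max(1, int(round(150.0 * (nominal_end - s) / fs)))
            envelope[s:e] *= np.sin(2 * np.pi * n_osc * u)
    if planted:
        return envelope
    white = rng.normal(0.0, 1.0, n_samples)
    sos = sps.butter(4, [30.0, 500.0], btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfilt(sos, white)
    carrier /= max(carrier.std(), 1e-12)
    return envelope * carrier + _clipped_normal(rng, emg_sd, n_samples)


def _true_power(cfg: GeneratorConfig, mass: float, cond: ConditionMeta, offset: float) -> float:
    if cfg.planted_linear:
        c0, ci, cl, cw = cfg.planted_weights
        return (c0 + ci * cond.incline_grade + cl * cond.load_fraction
                + cw * cond.assistance_work)
    return cfg.ee_model.power(mass, cond, offset)


def _emg_channels(cfg: GeneratorConfig) -> list[tuple[str, str]]:
    if cfg.design == "assisted":
        return [(side, m) for side in ("r", "l") for m in ASSISTED_MUSCLES]
    return [("r", m) for m in INCLINE_MUSCLES]


def generate_dataset(cfg: GeneratorConfig) -> tuple[list[TrialRecording], GroundTruthRecord]:
    """Generate one dataset: a list of trials plus its ground-truth record."""
    root_ss = np.random.SeedSequence(cfg.seed)
    subject_seeds = root_ss.spawn(cfg.n_subjects)
    fs = cfg.sampling_rate
    n_samples = int(round(cfg.trial_s * fs))
    period = int(round(fs / cfg.cadence_hz))
    stance_len = int(round(STANCE_FRACTION * period))

    trials: list[TrialRecording] = []
    truth: dict[tuple[str, str], float] = {}
    strikes_record: dict[tuple[str, str], np.ndarray] = {}
    offsets: dict[str, float] = {}

    for si, subject_ss in enumerate(subject_seeds):
        subject_rng = np.random.default_rng(subject_ss)
        sid = f"S{si:02d}"
        mass = float(np.clip(subject_rng.normal(cfg.mass_mean, cfg.mass_sd), 45.0, None))
        offset = (float(subject_rng.normal(0.0, cfg.ee_model.subject_offset_sd))
                  if not cfg.planted_linear and cfg.ee_model.subject_offset_sd > 0 else 0.0)
        offsets[sid] = offset
        subject = SubjectMeta(subject_id=sid, mass=mass, leg_length=0.89)
        cond_seeds = subject_ss.spawn(len(cfg.conditions))

        for cond, cond_ss in zip(cfg.conditions, cond_seeds):
            rng = np.random.default_rng(cond_ss)
            power = _true_power(cfg, mass, cond, offset)
            if not power > 0:
                raise ValueError(f"non-positive true power {power} W for {sid}/{cond.condition_id}")

            r_strikes = _plant_strikes(n_samples, period, cfg.stride_jitter_s, fs,
                                       offset=int(0.3 * period), rng=rng)
            l_strikes = _plant_strikes(n_samples, period, cfg.stride_jitter_s, fs,
                                       offset=int(0.8 * period), rng=rng)
            if len(r_strikes) < 2:
                raise ValueError("trial too short: fewer than two right heel strikes")
            # Constant amplitude in planted mode: identical waveforms give
            # identical detected cycle boundaries in every trial, keeping the
            # binned features an exactly linear encoding of the condition.
            peak = (800.0 if cfg.planted_linear
                    else 1.05 * (1.0 + cond.load_fraction) * mass * GRAVITY)

            channels = []
            for side, strikes in (("r", r_strikes), ("l", l_strikes)):
                x, y, z = _foot_grf(n_samples, strikes, peak, stance_len, cfg.grf_sd, rng)
                for axis, samples in (("x", x), ("y", y), ("z", z)):
                    channels.append(SignalChannel(
                        name=channel_name("grf", side, axis), kind="grf",
                        axis_or_muscle=axis, samples=samples, sampling_rate=fs))
            for side, muscle in _emg_channels(cfg):
                phase, width, base = _BURSTS[muscle]
                strikes = r_strikes if side == "r" else l_strikes
                amp = base * _muscle_gain(muscle, cond)
                if not amp > 0:
                    raise ValueError(f"non-positive EMG amplitude for {muscle} in "
                                     f"{cond.condition_id}")
                samples = _emg_signal(n_samples, strikes, period, amp,
                                      phase, width, fs, cfg.emg_sd, cfg.planted_linear, rng)
                channels.append(SignalChannel(
                    name=channel_name("emg", side, muscle), kind="emg",
                    axis_or_muscle=muscle, samples=samples, sampling_rate=fs))

            breaths = []
            t = cfg.breath_interval_s * (0.5 + 0.2 * rng.random())
            while t < cfg.trial_s:
                noisy = power * max(1.0 + (float(rng.normal(0.0, cfg.breath_cv))
                                           if cfg.breath_cv > 0 else 0.0), 0.05)
                vo2, vco2 = invert_brockway(noisy, cfg.rer)
                breaths.append(BreathSample(time=t, vo2=vo2, vco2=vco2))
                t += cfg.breath_interval_s * (1.0 + 0.1 * rng.random())
            if not breaths:
                vo2, vco2 = invert_brockway(power, cfg.rer)
                breaths.append(BreathSample(time=0.9 * cfg.trial_s, vo2=vo2, vco2=vco2))

            trials.append(TrialRecording(subject=subject, condition=cond,
                                         channels=channels, breaths=breaths))
            truth[(sid, cond.condition_id)] = power
            strikes_record[(sid, cond.condition_id)] = r_strikes

    record = GroundTruthRecord(
        true_power=truth, heel_strikes=strikes_record, subject_offsets=offsets,
        planted_weights=cfg.planted_weights if cfg.planted_linear else None)
    return trials, record
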