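"""Ground-truth metabolic power from breath-by-breath gas exchange.

Metabolic power is computed with the Brockway equation using the gaseous
terms only, E = 16.58 * VO2 + 4.51 * VCO2 in kJ/min for rates in L/min (the
urinary-nitrogen term cannot be measured from gas exchange and is neglected,
as is conventional in exercise physiology).  The steady-state power of a
condition is the unweighted mean of per-breath power over the final two
minutes of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_dataset import BreathSample

__all__ = [
    "BROCKWAY_O2_KJ_PER_L",
    "BROCKWAY_CO2_KJ_PER_L",
    "ConditionLabel",
    "brockway_power",
    "steady_state_ee",
]

#: Brockway (1987) energy equivalents, kJ per litre of gas exchanged.
BROCKWAY_O2_KJ_PER_L = 16.58
BROCKWAY_CO2_KJ_PER_L = 4.51

#: Length of the terminal averaging window, s ("last two minutes").
STEADY_STATE_WINDOW_S = 120.0


@dataclass(frozen=True)
class ConditionLabel:
    """Steady-state metabolic power (W) assigned to one condition."""

    condition_id: str
    steady_state_power: float

    def __post_init__(self) -> None:
        if not self.steady_state_power > 0:
            raise ValueError(f"condition {self.condition_id}: steady_state_power must be > 0")


def brockway_power(vo2: float, vco2: float) -> float:
    """Metabolic power in W from VO2 and VCO2 rates in L/min.

    ``W = (16.58 * vo2 + 4.51 * vco2) * 1000 / 60``.
    """
    if vo2 < 0 or vco2 < 0:
        raise ValueError("gas exchange rates must be non-negative")
    return (BROCKWAY_O2_KJ_PER_L * vo2 + BROCKWAY_CO2_KJ_PER_L * vco2) * 1000.0 / 60.0


def steady_state_ee(breaths: Sequence[BreathSample],
                    window_s: float = STEADY_STATE_WINDOW_S) -> float:
    """Mean per-breath Brockway power over the final ``window_s`` seconds.

    Breaths at time strictly greater than ``t_end - window_s`` contribute,
    each with equal weight.
    """
    if not breaths:
        raise ValueError("no breaths recorded")
    t_end = breaths[-1].time
    in_window = [b for b in breaths if b.time > t_end - window_s]
    if not in_window:
        raise ValueError(f"no breaths within the final {window_s} s")
    powers = [brockway_power(b.vo2, b.vco2) for b in in_window]
    return sum(powers) / len(powers)
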