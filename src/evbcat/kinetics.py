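"""Transition-state-theory conversions between barriers and rate constants.

The Eyring-Polanyi equation, k = (k_B*T/h) * exp(-dG/RT), links an
activation free energy to a first-order rate constant; the WT/mutant
rate-constant ratio depends only on the barrier difference,
k_WT/k_MUT = exp((dG_MUT - dG_WT)/RT).  The transmission coefficient is
fixed at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import KB_OVER_H, R_KCAL, S_PER_MIN

__all__ = [
    "RateResult",
    "rate_from_barrier",
    "barrier_from_rate",
    "rate_ratio",
    "per_minute_to_per_second",
    "per_second_to_per_minute",
]


@dataclass(frozen=True)
class RateResult:
    """A rate constant with the barrier and prefactor that produced it."""

    rate: float  # s^-1
    barrier: float  # kcal/mol
    temperature: float  # K
    prefactor: float  # k_B*T/h, s^-1

    @property
    def rate_per_minute(self) -> float:
        return self.rate * S_PER_MIN


def _check_temperature(temperature: float) -> float:
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature


def rate_from_barrier(barrier: float, temperature: float = 300.0) -> RateResult:
    """Eyring rate constant (s^-1) for a free-energy barrier in kcal/mol."""
    rt = _check_temperature(temperature)
    prefactor = KB_OVER_H * temperature
    return RateResult(
        rate=prefactor * math.exp(-barrier / rt),
        barrier=barrier,
        temperature=temperature,
        prefactor=prefactor,
    )


def barrier_from_rate(rate: float, temperature: float = 300.0) -> float:
    """Invert Eyring: dG = RT * ln((k_B*T/h) / k), rate in s^-1, result kcal/mol."""
    rt = _check_temperature(temperature)
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    return rt * math.log(KB_OVER_H * temperature / rate)


def rate_ratio(barrier_wt: float, barrier_mut: float, temperature: float = 300.0) -> float:
    """Fold-change k_WT/k_MUT implied by two barriers; prefactor cancels."""
    rt = _check_temperature(temperature)
    return math.exp((barrier_mut - barrier_wt) / rt)


def per_minute_to_per_second(rate_per_min: float) -> float:
    return rate_per_min / S_PER_MIN


def per_second_to_per_minute(rate_per_s: float) -> float:
    return rate_per_s * S_PER_MIN
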