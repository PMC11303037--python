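"""Idealized lunar-phase arithmetic.

Phase advances linearly with time at ``360 / synodic_length`` degrees per
day; 0 degrees is a new moon and 180 degrees a full moon. A table of
observed new-moon times may be supplied for real-data use, in which case
phase is interpolated piecewise-linearly between consecutive new moons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "SYNODIC_LENGTH",
    "LunarQuarter",
    "LunarCalendar",
    "phase_angle",
    "nearest_quarter",
    "days_from_new_moon",
    "theta",
]

#: Mean synodic month in days.
SYNODIC_LENGTH = 29.53


class LunarQuarter(Enum):
    """The four principal lunar phases, cyclically ordered."""

    NEW = 0
    WAXING = 1
    FULL = 2
    WANING = 3

    @property
    def neighbors(self) -> tuple["LunarQuarter", "LunarQuarter"]:
        """The two cyclically adjacent quarters."""
        order = list(LunarQuarter)
        i = order.index(self)
        return order[(i - 1) % 4], order[(i + 1) % 4]

    def is_adjacent(self, other: "LunarQuarter") -> bool:
        return other in self.neighbors


#: Fixed class order used for deterministic tie-breaking downstream.
QUARTER_ORDER: tuple[LunarQuarter, ...] = (
    LunarQuarter.NEW,
    LunarQuarter.WAXING,
    LunarQuarter.FULL,
    LunarQuarter.WANING,
)


@dataclass(frozen=True)
class LunarCalendar:
    """Reference frame for lunar-phase computations.

    Parameters
    ----------
    epoch_new_moon : float
        Time (continuous day) of a reference new moon.
    synodic_length : float
        Length of the synodic month in days (default 29.53).
    new_moon_table : tuple of float, optional
        Sorted times of observed new moons. When provided, phase is
        interpolated between consecutive entries instead of using the
        constant-rate clock (extrapolation outside the table falls back
        to the constant-rate clock anchored at the nearest entry).
    """

    epoch_new_moon: float = 0.0
    synodic_length: float = SYNODIC_LENGTH
    new_moon_table: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.synodic_length > 0:
            raise ValueError(f"synodic_length must be > 0, got {self.synodic_length}")
        if self.new_moon_table:
            tbl = tuple(float(t) for t in self.new_moon_table)
            if any(b <= a for a, b in zip(tbl, tbl[1:])):
                raise ValueError("new_moon_table must be strictly increasing")
            object.__setattr__(self, "new_moon_table", tbl)

    def _cycle_position(self, t):
        """Fraction of the cycle elapsed since the preceding new moon, in [0, 1)."""
        t = np.asarray(t, dtype=float)
        if self.new_moon_table:
            tbl = np.asarray(self.new_moon_table)
            idx = np.clip(np.searchsorted(tbl, t, side="right") - 1, 0, len(tbl) - 2)
            lo, hi = tbl[idx], tbl[idx + 1]
            frac = (t - lo) / (hi - lo)
            # outside the table: constant-rate clock from the nearest edge
            below = t < tbl[0]
            above = t >= tbl[-1]
            frac = np.where(below, (t - tbl[0]) / self.synodic_length, frac)
            frac = np.where(above, (t - tbl[-1]) / self.synodic_length, frac)
            return np.mod(frac, 1.0)
        return np.mod((t - self.epoch_new_moon) / self.synodic_length, 1.0)


def phase_angle(t, cal: LunarCalendar | None = None):
    """Lunar phase angle in degrees at time ``t`` (0 = new, 180 = full).

    Accepts scalars or arrays; returns values in ``[0, 360)``.
    """
    cal = cal or LunarCalendar()
    out = cal._cycle_position(t) * 360.0
    # guard against 360.0 from floating roundoff at cycle boundaries
    out = np.where(out >= 360.0, out - 360.0, out)
    return out if np.ndim(out) else float(out)


def nearest_quarter(angle: float) -> LunarQuarter:
    """Bin a phase angle (degrees, in [0, 360)) to the nearest lunar quarter.

    Windows are +/-45 degrees around the principal phases; boundary angles
    assign to the higher window (45 -> WAXING, 135 -> FULL, ...).
    """
    if not (0.0 <= angle < 360.0):
        raise ValueError(f"phase angle must be in [0, 360), got {angle}")
    if angle < 45.0 or angle >= 315.0:
        return LunarQuarter.NEW
    if angle < 135.0:
        return LunarQuarter.WAXING
    if angle < 225.0:
        return LunarQuarter.FULL
    return LunarQuarter.WANING


def days_from_new_moon(t, cal: LunarCalendar | None = None):
    """Signed offset (days) from ``t`` to the nearest new moon.

    Negative values mean ``t`` precedes that new moon. Result lies in
    ``(-synodic/2, synodic/2]``.
    """
    cal = cal or LunarCalendar()
    frac = cal._cycle_position(t)
    d = frac * cal.synodic_length
    half = cal.synodic_length / 2.0
    out = np.where(d > half, d - cal.synodic_length, d)
    return out if np.ndim(out) else float(out)


def theta(age_dph, birth_angle, cal: LunarCalendar | None = None):
    """Lunar phase angle (degrees) of a fish at a given larval age.

    ``birth_angle`` is the phase angle at hatch; the angle advances at
    ``360 / synodic_length`` degrees per day of age.
    """
    cal = cal or LunarCalendar()
    age = np.asarray(age_dph, dtype=float)
    if np.any(age < 0):
        raise ValueError("age_dph must be >= 0")
    out = np.mod(birth_angle + age * 360.0 / cal.synodic_length, 360.0)
    return out if np.ndim(out) else float(out)
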