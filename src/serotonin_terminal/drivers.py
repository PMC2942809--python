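"""Exogenous time functions driving the terminal model.

Three drivers enter the differential equations: the firing rate ``fire(t)``
(per hour; 1/hr baseline means the vesicular pool turns over once per hour
under tonic firing), the unblocked-SERT fraction ``fluox(t)`` (1 = no SSRI,
0 = full blockade/knockout), and the serum tryptophan concentration
``btrp(t)`` in μM.  Time is measured in hours throughout.

Each composed driver also declares its non-smooth time points
(``breakpoints``) so the stiff integrator can be restarted there instead of
relying on step-size heuristics to find a sub-second pulse edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = [
    "Drivers",
    "fluox_dose",
    "make_fluox_dose",
    "square_pulse_fire",
    "make_square_pulse",
    "meal_profile",
    "make_meal_profile",
    "make_suppressed_fire",
    "occupancy_profile",
]

#: hours in 0.2 seconds, the stimulation-pulse duration
PULSE_DURATION_HR = 1.0 / 18000.0


@dataclass(frozen=True)
class Drivers:
    """The three exogenous time functions plus declared discontinuities.

    Parameters
    ----------
    fire : callable
        Firing rate in 1/hr as a function of time in hours.
    fluox : callable
        Fraction of SERTs left unblocked, in [0, 1].
    btrp : callable
        Serum tryptophan in μM.
    breakpoints : tuple of float
        Times (hours) where any driver is non-smooth; the integrator is
        restarted at each of these.
    """

    fire: Callable[[float], float]
    fluox: Callable[[float], float]
    btrp: Callable[[float], float]
    breakpoints: tuple[float, ...] = field(default_factory=tuple)

    @classmethod
    def constant(cls, fire: float = 1.0, fluox: float = 1.0,
                 btrp: float = 96.0) -> "Drivers":
        """Constant drivers (the baseline steady-state condition)."""
        if fire < 0:
            raise ValueError(f"fire must be >= 0, got {fire}")
        if not 0.0 <= fluox <= 1.0:
            raise ValueError(f"fluox must lie in [0, 1], got {fluox}")
        if btrp < 0:
            raise ValueError(f"btrp must be >= 0, got {btrp}")
        return cls(fire=lambda t: fire, fluox=lambda t: fluox,
                   btrp=lambda t: btrp, breakpoints=())


def fluox_dose(t: float, dose_time: float = 1.0, depth: float = 0.95,
               washout_hr: float = 37.0) -> float:
    """Unblocked-SERT fraction after a single SSRI dose at ``dose_time``.

    Before the dose the fraction is 1.  Afterwards the blockade rises on a
    ~1.4 hr squared-saturation time course to a maximum depth and washes out
    exponentially with time constant ``washout_hr`` (37 hr corresponds to a
    drug half-life of a little more than a day, appropriate for fluoxetine).
    The function is continuous at the dose time and returns to 1 as t → ∞.
    """
    if t <= dose_time:
        return 1.0
    s = t - dose_time
    return 1.0 - depth * s * s / (2.04 + s * s) * math.exp(-s / washout_hr)


def make_fluox_dose(dose_time: float = 1.0, depth: float = 0.95,
                    washout_hr: float = 37.0):
    """Return (callable, breakpoints) for a single SSRI dose."""
    def f(t: float) -> float:
        return fluox_dose(t, dose_time=dose_time, depth=depth,
                          washout_hr=washout_hr)
    return f, (dose_time,)


def occupancy_profile(t: float, dose_time: float = 1.0, depth: float = 0.95,
                      washout_hr: float = 2.0) -> float:
    """Receptor-occupancy curve used for agonist firing suppression.

    Same shape as the SSRI blockade (1 - fluox_dose) but with a faster
    washout (default 2 hr), since agonists used in microdialysis work clear
    much faster than fluoxetine.
    """
    return 1.0 - fluox_dose(t, dose_time=dose_time, depth=depth,
                            washout_hr=washout_hr)


def square_pulse_fire(t: float, t_on: float, base: float = 1.0,
                      pulse: float = 5000.0,
                      duration: float = PULSE_DURATION_HR) -> float:
    """Firing rate with a square stimulation pulse.

    ``base`` outside [t_on, t_on + duration), ``pulse`` inside.  The default
    amplitude 5000/hr sustained for 0.2 s emulates 1/5 s of 100 Hz electrical
    stimulation.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if t_on <= t < t_on + duration:
        return pulse
    return base


def make_square_pulse(t_on: float, base: float = 1.0, pulse: float = 5000.0,
                      duration: float = PULSE_DURATION_HR):
    """Return (callable, breakpoints) for a square firing pulse."""
    def f(t: float) -> float:
        return square_pulse_fire(t, t_on=t_on, base=base, pulse=pulse,
                                 duration=duration)
    return f, (t_on, t_on + duration)


def _meal_bump(s: float, rise_hr: float, relax_hr: float) -> float:
    """Unit-amplitude raised-cosine bump: 0→1 over the rise, 1→0 by relax."""
    if s < 0.0 or s >= relax_hr:
        return 0.0
    if s < rise_hr:
        return 0.5 * (1.0 - math.cos(math.pi * s / rise_hr))
    return 0.5 * (1.0 + math.cos(math.pi * (s - rise_hr) / (relax_hr - rise_hr)))


def meal_profile(t: float, meal_starts: Sequence[float] = (7.0, 12.0, 18.0),
                 rise_hr: float = 3.0, relax_hr: float = 6.0,
                 baseline: float = 96.0, peak_factor: float = 2.0) -> float:
    """Serum tryptophan over a day with three meals.

    Each meal adds a smooth bump to the fasted baseline: three hours of
    rising input up to ``baseline * peak_factor``, then relaxation back to
    baseline six hours after the meal starts.  Bumps add where they overlap
    and the whole profile repeats with a 24-hour period.
    """
    if peak_factor < 1.0:
        raise ValueError(f"peak_factor must be >= 1, got {peak_factor}")
    tday = t % 24.0
    excess = baseline * (peak_factor - 1.0)
    total = baseline
    for start in meal_starts:
        # check the adjacent day too so bumps straddling midnight wrap
        for shift in (-24.0, 0.0, 24.0):
            total += excess * _meal_bump(tday - start + shift, rise_hr, relax_hr)
    return total


def make_meal_profile(meal_starts: Sequence[float] = (7.0, 12.0, 18.0),
                      rise_hr: float = 3.0, relax_hr: float = 6.0,
                      baseline: float = 96.0, peak_factor: float = 2.0,
                      n_days: int = 2):
    """Return (callable, breakpoints) for the meal-driven serum tryptophan.

    The raised-cosine bumps are C¹ except at the meal start, the rise→relax
    corner, and the return to baseline; those knots are declared as
    breakpoints for every simulated day.
    """
    def f(t: float) -> float:
        return meal_profile(t, meal_starts=meal_starts, rise_hr=rise_hr,
                            relax_hr=relax_hr, baseline=baseline,
                            peak_factor=peak_factor)
    knots = []
    for day in range(n_days):
        for start in meal_starts:
            for s in (0.0, rise_hr, relax_hr):
                knots.append(24.0 * day + start + s)
    return f, tuple(sorted(set(knots)))


def make_suppressed_fire(f_min: float,
                         blockade: Callable[[float], float],
                         t_max_search: float = 200.0,
                         base: float = 1.0):
    """Firing rate lowered in proportion to a drug blockade/occupancy curve.

    The suppression is tied to the blockade profile so that the two share a
    single timescale: fire(t) = base·(1 − (1 − f_min)·blockade(t)/max(blockade)).
    At peak blockade the firing rate is exactly ``f_min``·base, and it
    recovers to ``base`` as the profile washes out.
    """
    if not 0.0 < f_min <= 1.0:
        raise ValueError(f"f_min must lie in (0, 1], got {f_min}")
    # dense grid to locate the blockade maximum; the profiles used here are
    # unimodal so this is plenty
    peak = max(blockade(t_max_search * i / 20000.0) for i in range(20001))
    if peak <= 0.0:
        raise ValueError("blockade profile is identically zero")

    def fire(t: float) -> float:
        return base * (1.0 - (1.0 - f_min) * blockade(t) / peak)

    return fire
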