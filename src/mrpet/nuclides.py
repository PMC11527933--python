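"""Radionuclide decay mathematics and activity-unit plumbing.

Everything downstream (TAC simulation, HPLC fraction accounting, residence
times) needs consistent decay correction.  Canonical internal units are
minutes for within-scan time, hours for rate constants and MBq for
administered activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

__all__ = [
    "Nuclide",
    "ActivityValue",
    "C11",
    "NUCLIDES",
    "load_nuclide_registry",
    "decay_factor",
    "decay_correct",
    "decay_uncorrect",
    "physical_lambda_per_h",
    "suv",
]

#: exact powers of ten relative to Bq
_UNIT_SCALE = {"Bq": 1.0, "kBq": 1e3, "MBq": 1e6}


@dataclass(frozen=True)
class Nuclide:
    """A radionuclide, identified by name and physical half-life.

    Parameters
    ----------
    name : str
        Conventional nuclide label, e.g. ``"C-11"``.
    half_life_min : float
        Physical half-life in minutes; must be positive.
    """

    name: str
    half_life_min: float

    def __post_init__(self) -> None:
        if not self.half_life_min > 0:
            raise ValueError(f"half-life must be positive, got {self.half_life_min}")

    @property
    def decay_constant_per_min(self) -> float:
        """lambda = ln(2) / T_half, in 1/min."""
        return math.log(2.0) / self.half_life_min

    @property
    def decay_constant_per_h(self) -> float:
        return 60.0 * self.decay_constant_per_min


#: Carbon-11, the positron emitter labelling the tracer.  The half-life is
#: the standard physical constant (20.364 min).
C11 = Nuclide("C-11", 20.364)

NUCLIDES: dict[str, Nuclide] = {C11.name: C11}


def load_nuclide_registry(path: str | Path) -> dict[str, Nuclide]:
    """Load additional nuclides from a small YAML config.

    The file maps names to half-lives in minutes::

        C-11: 20.364
        F-18: 109.771
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    registry = dict(NUCLIDES)
    for name, half_life in raw.items():
        registry[str(name)] = Nuclide(str(name), float(half_life))
    return registry


@dataclass(frozen=True)
class ActivityValue:
    """A measured activity with its reference time and correction state.

    ``reference_time_min`` is minutes post injection.  ``decay_corrected``
    records whether the value has already been referred back to injection
    time; double correction is an error.
    """

    value: float
    unit: str = "MBq"
    reference_time_min: float = 0.0
    decay_corrected: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("activity cannot be negative")
        if self.unit not in _UNIT_SCALE:
            raise ValueError(f"unknown unit {self.unit!r}; use one of {sorted(_UNIT_SCALE)}")

    def to_unit(self, unit: str) -> "ActivityValue":
        if unit not in _UNIT_SCALE:
            raise ValueError(f"unknown unit {unit!r}")
        scale = _UNIT_SCALE[self.unit] / _UNIT_SCALE[unit]
        return replace(self, value=self.value * scale, unit=unit)


def decay_factor(nuclide: Nuclide, t_min: float) -> float:
    """Fraction of activity remaining after ``t_min`` minutes: exp(-lambda t).

    Lies in (0, 1] for t >= 0; ``t_min`` must be non-negative.
    """
    if t_min < 0:
        raise ValueError(f"elapsed time must be non-negative, got {t_min}")
    return math.exp(-nuclide.decay_constant_per_min * t_min)


def physical_lambda_per_h(nuclide: Nuclide) -> float:
    """Physical decay constant in 1/h (ln 2 / half-life)."""
    return nuclide.decay_constant_per_h


def decay_correct(a: ActivityValue, nuclide: Nuclide, to_time_min: float = 0.0) -> ActivityValue:
    """Refer a measured (uncorrected) activity to ``to_time_min``.

    Correcting a measurement at time t back to an earlier reference divides
    by the decay factor over the elapsed interval; correcting to the
    measurement's own time is the identity.
    """
    if a.decay_corrected:
        raise ValueError("activity is already decay-corrected")
    dt = a.reference_time_min - to_time_min
    if dt >= 0:
        value = a.value / decay_factor(nuclide, dt)
    else:  # reference earlier than target: decay forward
        value = a.value * decay_factor(nuclide, -dt)
    return replace(a, value=value, reference_time_min=to_time_min, decay_corrected=True)


def decay_uncorrect(a: ActivityValue, nuclide: Nuclide, at_time_min: float) -> ActivityValue:
    """Inverse of :func:`decay_correct`: the physical activity at ``at_time_min``."""
    if not a.decay_corrected:
        raise ValueError("activity is not decay-corrected")
    dt = at_time_min - a.reference_time_min
    if dt >= 0:
        value = a.value * decay_factor(nuclide, dt)
    else:
        value = a.value / decay_factor(nuclide, -dt)
    return replace(a, value=value, reference_time_min=at_time_min, decay_corrected=False)


def suv(conc_kbq_per_ml: float, weight_kg: float, injected_mbq: float) -> float:
    """Standardised uptake value for an activity concentration.

    SUV = concentration [kBq/ml] * body weight [g] / injected activity [kBq],
    assuming tissue density 1 g/ml; dimensionless.
    """
    if weight_kg <= 0:
        raise ValueError("body weight must be positive")
    if injected_mbq <= 0:
        raise ValueError("injected activity must be positive")
    if conc_kbq_per_ml < 0:
        raise ValueError("activity concentration cannot be negative")
    return conc_kbq_per_ml * (weight_kg * 1000.0) / (injected_mbq * 1000.0)


def suv_to_concentration(suv_value: float, weight_kg: float, injected_mbq: float) -> float:
    """Invert :func:`suv`: activity concentration in kBq/ml."""
    if weight_kg <= 0 or injected_mbq <= 0:
        raise ValueError("weight and injected activity must be positive")
    return suv_value * (injected_mbq * 1000.0) / (weight_kg * 1000.0)
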