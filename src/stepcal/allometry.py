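"""Allometric (body-mass power-law) transfer of parameter values.

Physiological quantities scale across organisms of different size as
Z = a * M^b (Kleiber's law: metabolic rate scales with exponent b = 3/4).
During multi-scale calibration this links the in vitro and in vivo values
of one parameter instead of calibrating them independently: the allometric
coefficient a is calibrated at a reference mass, and the power law then
yields the value at any other body mass.

The exponent b is determined by the physical dimension of the parameter.
The standard quarter-power table is used (extensible via ``extra`` /
config):

    ============================  ======
    dimension                     b
    ============================  ======
    dimensionless                 0
    time (day)                    1/4
    rate (1/day)                  -1/4
    flux (quantity/day)           3/4
    ============================  ======

Reference masses follow the emulated study design: 2.63 g for the in vitro
scale and 23 g for a mouse xenograft.
"""

from __future__ import annotations

from stepcal.errors import ConfigurationError

#: Reference body masses in grams.
IN_VITRO_MASS_G = 2.63
MOUSE_MASS_G = 23.0

#: Physical dimension -> allometric exponent b.
EXPONENT_TABLE: dict[str, float] = {
    "dimensionless": 0.0,
    "": 0.0,
    "day": 0.25,
    "time": 0.25,
    "1/day": -0.25,
    "per_time": -0.25,
    "quantity/day": 0.75,
    "flux": 0.75,
    "cells": 0.0,
    "um": 0.0,
    "nM": 0.0,
}


def exponent_from_unit(unit: str, extra: dict[str, float] | None = None) -> float:
    """Allometric exponent for a physical dimension descriptor."""
    table = dict(EXPONENT_TABLE)
    if extra:
        table.update(extra)
    try:
        return table[unit]
    except KeyError:
        raise ConfigurationError(
            f"no allometric exponent for unit {unit!r}; supported: "
            f"{sorted(k for k in table if k)}"
        ) from None


def scale_parameter(
    value_at_ref: float, m_ref: float, m_target: float, b: float
) -> float:
    """Transfer a value from reference mass to target mass: v * (M/M_ref)^b."""
    if m_ref <= 0 or m_target <= 0:
        raise ConfigurationError("body masses must be positive")
    return value_at_ref * (m_target / m_ref) ** b


def coefficient_from_calibration(value_at_ref: float, m_ref: float, b: float) -> float:
    """Allometric coefficient a such that a * M_ref^b = value_at_ref."""
    if m_ref <= 0:
        raise ConfigurationError("body mass must be positive")
    return value_at_ref / m_ref**b
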