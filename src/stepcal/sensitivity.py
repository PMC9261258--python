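"""Pre-calibration parameter-space screening with regular factorial designs.

Before optimizing, large parameter ranges are explored on a full factorial
grid; rows that crash the integrator or violate literature-derived
aberrance rules (binary constraints) are discarded, and the surviving rows
define a reduced, axis-aligned plausible box handed to the optimizer.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from stepcal.cmaes import ParameterSpec
from stepcal.errors import ConfigurationError, SimulationError
from stepcal.scoring import BinaryConstraint, score_binary
from stepcal.stepwise import SimulateFn

log = logging.getLogger(__name__)

MAX_ROWS = 10**6
DEFAULT_LEVELS = 3

STATUS_OK = "ok"
STATUS_NUMERICAL = "numerical_error"
STATUS_ABERRANT = "aberrant"


@dataclass
class FactorialDesign:
    parameters: list[ParameterSpec]
    levels: int
    matrix: np.ndarray  # rows of raw parameter vectors, lexicographic order

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def factorial_design(
    parameters: Sequence[ParameterSpec], levels: int = DEFAULT_LEVELS
) -> FactorialDesign:
    """Full factorial grid of equally spaced levels per parameter.

    Levels are linearly spaced within each parameter's bounds
    (geometrically for log-scaled parameters) and always include the
    endpoints.  Row order is lexicographic in the parameter order.
    """
    if levels < 2:
        raise ConfigurationError("factorial designs need at least 2 levels")
    if not parameters:
        raise ConfigurationError("factorial design needs at least one parameter")
    n_rows = levels ** len(parameters)
    if n_rows > MAX_ROWS:
        raise ConfigurationError(
            f"{levels}^{len(parameters)} = {n_rows} rows exceeds {MAX_ROWS}; "
            f"use fewer levels or parameters"
        )
    axes = []
    for p in parameters:
        if p.log_scale:
            axes.append(np.geomspace(p.lower, p.upper, levels))
        else:
            axes.append(np.linspace(p.lower, p.upper, levels))
    matrix = np.array(list(itertools.product(*axes)), dtype=float)
    return FactorialDesign(parameters=list(parameters), levels=levels, matrix=matrix)


@dataclass
class ScreenResult:
    design: FactorialDesign
    table: pd.DataFrame  # parameter columns + "status"
    reduced_ranges: dict[str, tuple[float, float]]
    blocking: list[str] = field(default_factory=list)

    def reduced_parameters(self) -> list[ParameterSpec]:
        """Parameter specs shrunk to the screened plausible box."""
        out = []
        for p in self.design.parameters:
            lo, hi = self.reduced_ranges[p.name]
            guess = min(max(p.initial_guess, lo), hi)
            out.append(replace(p, lower=lo, upper=hi, initial_guess=guess))
        return out


def screen(
    design: FactorialDesign,
    simulate_fn: SimulateFn,
    scenario,
    aberrance_rules: Sequence[BinaryConstraint],
    base_params: Mapping[str, float] | None = None,
) -> ScreenResult:
    """Simulate every design row and classify it.

    Rows where the integration fails are ``numerical_error``; rows where
    any aberrance rule (a binary constraint encoding "this behaviour is
    biologically absurd") is violated are ``aberrant``; the rest are
    ``ok``.  The reduced range of each parameter is the [min, max] of its
    values over ok rows; a parameter with no ok rows is reported as
    blocking.  Classification is deterministic.
    """
    if design.matrix.size == 0:
        raise ConfigurationError("empty factorial design")
    statuses = []
    for row in design.matrix:
        params = dict(base_params or {})
        params.update(zip(design.names, map(float, row)))
        try:
            trajectory = simulate_fn(params, scenario)
        except SimulationError:
            statuses.append(STATUS_NUMERICAL)
            continue
        if all(score_binary(rule, trajectory) == 1.0 for rule in aberrance_rules):
            statuses.append(STATUS_OK)
        else:
            statuses.append(STATUS_ABERRANT)
    table = design.to_frame()
    table["status"] = statuses
    ok = table[table["status"] == STATUS_OK]
    reduced: dict[str, tuple[float, float]] = {}
    blocking: list[str] = []
    for p in design.parameters:
        if len(ok):
            reduced[p.name] = (float(ok[p.name].min()), float(ok[p.name].max()))
        else:
            reduced[p.name] = (p.lower, p.upper)
            blocking.append(p.name)
    if blocking:
        log.warning("no admissible rows; blocking parameters: %s", blocking)
    return ScreenResult(
        design=design, table=table, reduced_ranges=reduced, blocking=blocking
    )
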