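"""Sequential (stepwise) calibration engine.

A calibration plan is an ordered list of steps.  Each step maximizes one
weighted constraint objective over a subset of free parameters via CMA-ES,
then freezes the solved values for the following steps, so the plausible
parameter space shrinks step by step.  Constraints from earlier steps must
remain satisfied: after every step the engine re-simulates the earlier
scenarios with the merged parameter set and fails loudly if a carried-over
constraint score drops below a configurable floor.

A step may deliberately re-free a parameter frozen by an earlier step
(e.g. a clearance rate that the earlier data could not identify); the
carry-over check then guards the earlier constraints against the new value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from stepcal.cmaes import (
    CalibrationResult,
    ParameterSpec,
    SearchSpec,
    maximize,
)
from stepcal.errors import ConfigurationError
from stepcal.scoring import ObjectiveSpec, objective
from stepcal.trajectory import Trajectory

log = logging.getLogger(__name__)

#: Minimum acceptable score for a re-verified earlier constraint.
DEFAULT_CARRYOVER_FLOOR = 0.8

#: Default number of CMA-ES repeats per step (best-of-N is kept).
DEFAULT_REPEATS = 3

SimulateFn = Callable[[dict, object], Trajectory]


class CarryoverViolation(RuntimeError):
    """A constraint from an earlier step no longer holds."""


@dataclass
class CalibrationStep:
    """One step of a calibration plan.

    ``scenarios`` maps scenario labels (referenced by constraint
    ``scenario`` fields) to scenario objects understood by the simulate
    function.  ``multistart`` optionally lists alternative initial-guess
    overrides (name -> value) cycled across the repeated CMA-ES runs, so
    a multimodal step explores several starting regimes instead of
    re-rolling the dice from one point.  ``ordering_hints`` is advisory
    metadata (how well documented the phenomena are, their granularity
    and connectivity) that documents why the plan is ordered the way it
    is; it is not enforced.
    """

    name: str
    scenarios: Mapping[str, object]
    free_parameters: Sequence[ParameterSpec]
    constraints: ObjectiveSpec
    stop_threshold: float = 0.999
    population_size: int | str = "auto"
    max_generations: int = 200
    stagnation_window: int = 30
    stagnation_tol: float = 1e-6
    repeats: int = DEFAULT_REPEATS
    multistart: Sequence[Mapping[str, float]] = ()
    ordering_hints: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.constraints.constraints:
            raise ConfigurationError(f"step {self.name!r} defines no constraints")
        if not self.free_parameters:
            raise ConfigurationError(f"step {self.name!r} frees no parameters")
        if self.repeats < 1:
            raise ConfigurationError("repeats must be >= 1")
        names = [p.name for p in self.free_parameters]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"step {self.name!r} repeats a free parameter")
        labels = {c.scenario for c in self.constraints.constraints} - {None}
        missing = labels - set(self.scenarios)
        if missing:
            raise ConfigurationError(
                f"step {self.name!r}: constraints reference unknown scenarios "
                f"{sorted(missing)}"
            )


@dataclass
class StepResult:
    name: str
    best_params: dict[str, float]
    best_objective: float
    stop_reason: str
    unconverged: bool
    cma: CalibrationResult
    carryover: dict[str, tuple[float, bool]] = field(default_factory=dict)


@dataclass
class PlanResult:
    steps: list[StepResult]
    final_params: dict[str, float]
    seed: int

    @property
    def objectives(self) -> dict[str, float]:
        return {s.name: s.best_objective for s in self.steps}


def _step_seed(master_seed: int, step_index: int, repeat: int) -> int:
    """Deterministic per-(step, repeat) seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(step_index, repeat))
    return int(ss.generate_state(1)[0] % (2**31))


def run_step(
    step: CalibrationStep,
    simulate_fn: SimulateFn,
    frozen: Mapping[str, float],
    seeds: Sequence[int],
) -> StepResult:
    """Maximize one step objective; best-of-``seeds`` CMA-ES runs."""
    names = [p.name for p in step.free_parameters]

    def step_objective(x: np.ndarray) -> float:
        merged = dict(frozen)
        merged.update(zip(names, map(float, x)))
        trajectories = {
            label: simulate_fn(merged, scen) for label, scen in step.scenarios.items()
        }
        return objective(step.constraints, trajectories)

    best: CalibrationResult | None = None
    for r, s in enumerate(seeds):
        parameters = list(step.free_parameters)
        if step.multistart:
            # cycle through alternative starting regimes across repeats
            overrides = step.multistart[r % len(step.multistart)]
            unknown = set(overrides) - {p.name for p in parameters}
            if unknown:
                raise ConfigurationError(
                    f"step {step.name!r}: multistart overrides unknown "
                    f"parameters {sorted(unknown)}"
                )
            parameters = [
                replace(p, initial_guess=float(overrides[p.name]))
                if p.name in overrides
                else p
                for p in parameters
            ]
        spec = SearchSpec(
            parameters=parameters,
            population_size=step.population_size,
            stop_threshold=step.stop_threshold,
            stagnation_window=step.stagnation_window,
            stagnation_tol=step.stagnation_tol,
            max_generations=step.max_generations,
            seed=s,
        )
        result = maximize(step_objective, spec)
        log.info(
            "step %s seed %d: objective %.4f (%s)",
            step.name,
            s,
            result.best_value,
            result.stop_reason,
        )
        if best is None or result.best_value > best.best_value:
            best = result
        if result.best_value >= step.stop_threshold:
            break  # already good enough; further repeats cannot help
    assert best is not None
    unconverged = best.stop_reason == "budget" and best.best_value < step.stop_threshold
    if unconverged:
        log.warning(
            "step %s hit the generation budget at objective %.4f < %.4f",
            step.name,
            best.best_value,
            step.stop_threshold,
        )
    return StepResult(
        name=step.name,
        best_params=best.best_dict(),
        best_objective=best.best_value,
        stop_reason=best.stop_reason,
        unconverged=unconverged,
        cma=best,
    )


def verify_carryover(
    merged_params: Mapping[str, float],
    earlier_constraints: ObjectiveSpec,
    scenarios: Mapping[str, object],
    simulate_fn: SimulateFn,
    floor: float = DEFAULT_CARRYOVER_FLOOR,
) -> dict[str, tuple[float, bool]]:
    """Re-simulate earlier scenarios and re-score their constraints.

    Returns ``{constraint name: (score, passed)}`` with ``passed`` meaning
    score >= floor.
    """
    if not earlier_constraints.constraints:
        return {}
    labels = {c.scenario for c in earlier_constraints.constraints} - {None}
    missing = labels - set(scenarios)
    if missing:
        raise ConfigurationError(
            f"carry-over check needs scenarios {sorted(missing)} which are "
            f"not available"
        )
    trajectories = {
        label: simulate_fn(dict(merged_params), scen)
        for label, scen in scenarios.items()
    }
    scores = earlier_constraints.scores(trajectories)
    return {name: (s, s >= floor) for name, s in scores.items()}


def run_plan(
    plan: Sequence[CalibrationStep],
    simulate_fn: SimulateFn,
    base_params: Mapping[str, float],
    seed: int = 0,
    carryover_floor: float = DEFAULT_CARRYOVER_FLOOR,
) -> PlanResult:
    """Execute an ordered calibration plan.

    ``base_params`` supplies defaults for every parameter the model needs;
    each step's solved values overwrite them for all later steps.  After
    each step the constraints of all *earlier* steps are re-verified with
    the merged parameter set; a score below ``carryover_floor`` aborts the
    plan with a diagnostic.
    """
    if not plan:
        raise ConfigurationError("empty calibration plan")
    known = set(base_params)
    for step in plan:
        unknown = {p.name for p in step.free_parameters} - known
        if unknown:
            raise ConfigurationError(
                f"step {step.name!r} frees unknown parameters {sorted(unknown)}"
            )

    frozen: dict[str, float] = dict(base_params)
    results: list[StepResult] = []
    for i, step in enumerate(plan):
        seeds = [_step_seed(seed, i, r) for r in range(step.repeats)]
        step_result = run_step(step, simulate_fn, frozen, seeds)
        frozen.update(step_result.best_params)

        if i > 0:
            earlier = ObjectiveSpec(
                [c for prev in plan[:i] for c in prev.constraints.constraints]
            )
            earlier_scenarios: dict[str, object] = {}
            for prev in plan[:i]:
                earlier_scenarios.update(prev.scenarios)
            report = verify_carryover(
                frozen, earlier, earlier_scenarios, simulate_fn, carryover_floor
            )
            step_result.carryover = report
            failed = sorted(name for name, (_, ok) in report.items() if not ok)
            if failed:
                raise CarryoverViolation(
                    f"after step {step.name!r}, earlier constraints {failed} "
                    f"scored below the carry-over floor {carryover_floor}: "
                    + ", ".join(
                        f"{n}={report[n][0]:.3f}" for n in failed
                    )
                )
        results.append(step_result)
    return PlanResult(steps=results, final_params=frozen, seed=seed)


def narrow_ranges(
    free_parameters: Sequence[ParameterSpec],
    step_result: StepResult,
    strategy: str = "freeze",
    k: float = 3.0,
) -> list[ParameterSpec]:
    """Shrink parameter definitions after a completed step.

    ``freeze`` pins each parameter to its solved value (degenerate
    interval).  ``interval`` keeps a range of best +- k * (final search
    std), intersected with the original bounds; for log-scaled parameters
    the band is multiplicative.  A degenerate interval falls back to a
    freeze.
    """
    if strategy not in ("freeze", "interval"):
        raise ConfigurationError(f"unknown narrowing strategy {strategy!r}")
    out: list[ParameterSpec] = []
    stds = dict(
        zip(step_result.cma.parameter_names, step_result.cma.final_std)
        if step_result.cma.final_std is not None
        else []
    )
    for p in free_parameters:
        best = step_result.best_params[p.name]
        if strategy == "freeze":
            out.append(replace(p, lower=best, upper=best, initial_guess=best))
            continue
        std = stds.get(p.name, 0.0)
        if p.log_scale:
            lo = max(p.lower, best * np.exp(-k * std))
            hi = min(p.upper, best * np.exp(k * std))
        else:
            lo = max(p.lower, best - k * std)
            hi = min(p.upper, best + k * std)
        if hi <= lo or std == 0.0:
            lo = hi = best
        out.append(
            replace(p, lower=lo, upper=hi, initial_guess=min(max(best, lo), hi))
        )
    return out
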