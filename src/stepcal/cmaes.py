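"""(mu/mu_w, lambda) CMA-ES maximizer for bounded calibration problems.

The Covariance Matrix Adaptation Evolution Strategy samples each generation
of candidate parameter vectors from a multivariate normal distribution whose
mean, covariance and global step size adapt to the best-scoring candidates
("survival of the fittest").  This implementation follows the standard
Hansen formulation: weighted recombination of the mu = floor(p/2) best
candidates with logarithmic weights, cumulative step-size adaptation (CSA)
on the conjugate evolution path, and a rank-one plus rank-mu covariance
update.  The exact update equations are documented in docs/methods.md.

Conventions
-----------
* The optimizer *maximizes* the objective (calibration scores live in
  [0, 1] with 1 = all constraints satisfied).
* The search runs in normalized coordinates: every free parameter is mapped
  onto [0, 1] (through log space when ``log_scale`` is set) so the
  covariance stays well conditioned across parameters with wildly different
  physical units.
* Population size defaults to p = 4 + floor(3 ln d).
* Initial covariance is diagonal with sqrt(C_kk) equal to half the k-th
  search-interval width (overridable per parameter), the initial mean is
  the vector of initial guesses, and sigma = 1.
* Out-of-bounds draws are resampled up to 100 times, then clipped to the
  boundary — simple and deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from stepcal.errors import ConfigurationError

log = logging.getLogger(__name__)

_EIG_FLOOR = 1e-12
_RESAMPLE_LIMIT = 100


@dataclass(frozen=True)
class ParameterSpec:
    """One calibratable parameter.

    ``unit`` is a physical-dimension descriptor consumed by the allometry
    module (e.g. ``"1/day"``); ``allometric`` marks the parameter for
    body-mass rescaling.  ``init_std`` optionally overrides the default
    initial standard deviation (half the interval width) and is given in
    raw parameter units (log-units for log-scaled parameters).
    """

    name: str
    lower: float
    upper: float
    initial_guess: float | None = None
    unit: str = "dimensionless"
    log_scale: bool = False
    allometric: bool = False
    init_std: float | None = None

    def __post_init__(self) -> None:
        if self.upper < self.lower:
            raise ConfigurationError(
                f"parameter {self.name!r}: lower bound exceeds upper bound"
            )
        if self.initial_guess is None:
            guess = (
                math.sqrt(self.lower * self.upper)
                if self.log_scale and self.lower > 0
                else 0.5 * (self.lower + self.upper)
            )
            object.__setattr__(self, "initial_guess", guess)
        if not self.lower <= self.initial_guess <= self.upper:
            raise ConfigurationError(
                f"parameter {self.name!r}: initial guess {self.initial_guess} "
                f"outside [{self.lower}, {self.upper}]"
            )
        if self.log_scale and self.lower <= 0:
            raise ConfigurationError(
                f"parameter {self.name!r}: log scale needs a positive lower bound"
            )

    @property
    def frozen(self) -> bool:
        """Degenerate intervals are auto-frozen and excluded from the search."""
        return self.upper == self.lower

    # --- normalized [0, 1] coordinate maps ------------------------------
    def to_unit(self, x: float | np.ndarray) -> float | np.ndarray:
        if self.frozen:
            return np.zeros_like(np.asarray(x, dtype=float))
        if self.log_scale:
            return (np.log(x) - math.log(self.lower)) / (
                math.log(self.upper) - math.log(self.lower)
            )
        return (x - self.lower) / (self.upper - self.lower)

    def from_unit(self, z: float | np.ndarray) -> float | np.ndarray:
        if self.frozen:
            return self.lower + np.zeros_like(np.asarray(z, dtype=float))
        if self.log_scale:
            return np.exp(
                math.log(self.lower)
                + z * (math.log(self.upper) - math.log(self.lower))
            )
        return self.lower + z * (self.upper - self.lower)

    def unit_init_std(self) -> float:
        """Initial sqrt(C_kk) in normalized coordinates."""
        if self.init_std is None:
            return 0.5
        width = (
            math.log(self.upper) - math.log(self.lower)
            if self.log_scale
            else self.upper - self.lower
        )
        return float(self.init_std) / width


@dataclass
class SearchSpec:
    """Search definition: parameters, population rule and stop criteria."""

    parameters: Sequence[ParameterSpec]
    population_size: int | str = "auto"
    stop_threshold: float = 0.999
    stagnation_window: int = 30
    stagnation_tol: float = 1e-6
    max_generations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.stop_threshold <= 1):
            raise ConfigurationError("stop_threshold must lie in (0, 1]")
        if self.stagnation_window < 1 or self.stagnation_tol <= 0:
            raise ConfigurationError("invalid stagnation settings")
        if self.max_generations < 1:
            raise ConfigurationError("max_generations must be >= 1")

    @property
    def free(self) -> list[ParameterSpec]:
        return [p for p in self.parameters if not p.frozen]

    @property
    def dimension(self) -> int:
        return len(self.free)

    def resolved_population_size(self) -> int:
        if self.population_size == "auto":
            return default_population_size(self.dimension)
        p = int(self.population_size)
        if p < 2:
            raise ConfigurationError("population_size must be >= 2")
        return p

    def to_raw(self, z: np.ndarray) -> np.ndarray:
        return np.array([p.from_unit(zi) for p, zi in zip(self.free, z)])

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        return np.array([p.to_unit(xi) for p, xi in zip(self.free, x)])


def default_population_size(d: int) -> int:
    """Population rule p = 4 + floor(3 ln d)."""
    if d < 1:
        raise ConfigurationError("need at least one free parameter (d >= 1)")
    return 4 + int(math.floor(3.0 * math.log(d)))


@dataclass
class CMAState:
    """Evolving sampling-distribution state (normalized coordinates)."""

    mean: np.ndarray
    C: np.ndarray
    sigma: float
    p_sigma: np.ndarray
    p_c: np.ndarray
    generation: int = 0
    best_so_far: tuple[np.ndarray, float] | None = None  # raw coords, value


def init_state(spec: SearchSpec) -> CMAState:
    """Initial state: mean at the guesses, diagonal C from half interval widths."""
    free = spec.free
    if not free:
        raise ConfigurationError("all parameters are frozen; nothing to optimize")
    d = len(free)
    mean = np.array([p.to_unit(p.initial_guess) for p in free], dtype=float)
    stds = np.array([p.unit_init_std() for p in free], dtype=float)
    return CMAState(
        mean=mean,
        C=np.diag(stds**2),
        sigma=1.0,
        p_sigma=np.zeros(d),
        p_c=np.zeros(d),
    )


def _decompose(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition with floor repair for non-positive-definite C."""
    C = 0.5 * (C + C.T)
    vals, vecs = np.linalg.eigh(C)
    if np.any(vals < _EIG_FLOOR):
        log.warning(
            "covariance repaired: flooring %d eigenvalue(s) at %g",
            int(np.sum(vals < _EIG_FLOOR)),
            _EIG_FLOOR,
        )
        vals = np.maximum(vals, _EIG_FLOOR)
    return vals, vecs


def sample_generation(
    state: CMAState, spec: SearchSpec, rng: np.random.Generator
) -> np.ndarray:
    """Draw a generation of p candidates (normalized coords, inside [0, 1]^d).

    Candidates are i.i.d. Normal(mean, sigma^2 C); out-of-bounds draws are
    resampled up to 100 times, then clipped to the boundary.
    """
    p = spec.resolved_population_size()
    d = state.mean.size
    vals, vecs = _decompose(state.C)
    scale = vecs * np.sqrt(vals)  # B D
    out = np.empty((p, d))
    for i in range(p):
        z = state.mean + state.sigma * (scale @ rng.standard_normal(d))
        tries = 0
        while np.any((z < 0.0) | (z > 1.0)) and tries < _RESAMPLE_LIMIT:
            z = state.mean + state.sigma * (scale @ rng.standard_normal(d))
            tries += 1
        out[i] = np.clip(z, 0.0, 1.0)
    return out


def _strategy_constants(d: int, p: int):
    mu = p // 2
    raw = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w = raw / raw.sum()
    mu_eff = 1.0 / np.sum(w**2)
    c_sigma = (mu_eff + 2.0) / (d + mu_eff + 5.0)
    d_sigma = 1.0 + 2.0 * max(0.0, math.sqrt((mu_eff - 1.0) / (d + 1.0)) - 1.0) + c_sigma
    c_c = (4.0 + mu_eff / d) / (d + 4.0 + 2.0 * mu_eff / d)
    c_1 = 2.0 / ((d + 1.3) ** 2 + mu_eff)
    c_mu = min(
        1.0 - c_1,
        2.0 * (mu_eff - 2.0 + 1.0 / mu_eff) / ((d + 2.0) ** 2 + mu_eff),
    )
    chi_d = math.sqrt(d) * (1.0 - 1.0 / (4.0 * d) + 1.0 / (21.0 * d * d))
    return mu, w, mu_eff, c_sigma, d_sigma, c_c, c_1, c_mu, chi_d


def update(
    state: CMAState,
    spec: SearchSpec,
    candidates: np.ndarray,
    objective_values: Sequence[float],
) -> CMAState:
    """One CMA-ES update from an evaluated generation (maximization).

    Selects the mu = floor(p/2) best candidates (descending objective, ties
    broken by candidate index), recombines with logarithmic weights, and
    applies CSA step-size control plus the rank-one/rank-mu covariance
    update.  Non-finite objective values are demoted to 0 (worst).
    """
    candidates = np.asarray(candidates, dtype=float)
    values = np.asarray(objective_values, dtype=float).copy()
    if candidates.shape[0] != values.size:
        raise ConfigurationError("candidates and objective_values length mismatch")
    bad = ~np.isfinite(values)
    if np.any(bad):
        log.warning("%d non-finite objective value(s) scored as 0", int(bad.sum()))
        values[bad] = 0.0

    d = state.mean.size
    p = candidates.shape[0]
    mu, w, mu_eff, c_sigma, d_sigma, c_c, c_1, c_mu, chi_d = _strategy_constants(d, p)

    order = np.argsort(-values, kind="stable")
    elite = candidates[order[:mu]]

    m_old = state.mean
    y = (elite - m_old) / state.sigma
    y_w = w @ y
    mean = m_old + state.sigma * y_w

    vals, vecs = _decompose(state.C)
    inv_sqrt = vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T
    p_sigma = (1.0 - c_sigma) * state.p_sigma + math.sqrt(
        c_sigma * (2.0 - c_sigma) * mu_eff
    ) * (inv_sqrt @ y_w)

    g = state.generation + 1
    norm_ps = float(np.linalg.norm(p_sigma))
    h_sigma = norm_ps / math.sqrt(1.0 - (1.0 - c_sigma) ** (2 * g)) < (
        1.4 + 2.0 / (d + 1.0)
    ) * chi_d
    p_c = (1.0 - c_c) * state.p_c + (
        math.sqrt(c_c * (2.0 - c_c) * mu_eff) * y_w if h_sigma else 0.0
    )

    rank_mu = (y.T * w) @ y
    C = (
        (1.0 - c_1 - c_mu) * state.C
        + c_1 * (np.outer(p_c, p_c) + (0.0 if h_sigma else c_c * (2.0 - c_c)) * state.C)
        + c_mu * rank_mu
    )
    C = 0.5 * (C + C.T)

    sigma = state.sigma * math.exp((c_sigma / d_sigma) * (norm_ps / chi_d - 1.0))

    best_so_far = state.best_so_far
    gen_best_idx = int(order[0])
    gen_best_val = float(values[gen_best_idx])
    if best_so_far is None or gen_best_val > best_so_far[1]:
        best_so_far = (spec.to_raw(candidates[gen_best_idx]), gen_best_val)

    return CMAState(
        mean=mean,
        C=C,
        sigma=sigma,
        p_sigma=p_sigma,
        p_c=p_c,
        generation=g,
        best_so_far=best_so_far,
    )


def should_stop(
    state: CMAState, history: Sequence[float], spec: SearchSpec
) -> str | None:
    """Stop reason ("threshold" | "stagnation" | "budget") or None.

    * threshold — the best objective reached the user-defined target
      (typically close to 1);
    * stagnation — the running best improved by less than ``stagnation_tol``
      over the last ``stagnation_window`` generations;
    * budget — ``max_generations`` reached.
    """
    if state.best_so_far is not None and state.best_so_far[1] >= spec.stop_threshold:
        return "threshold"
    w = spec.stagnation_window
    if len(history) > w:
        running = np.maximum.accumulate(np.asarray(history, dtype=float))
        if running[-1] - running[-1 - w] < spec.stagnation_tol:
            return "stagnation"
    if state.generation >= spec.max_generations:
        return "budget"
    return None


@dataclass
class CalibrationResult:
    """Outcome of one CMA-ES run."""

    best_params: np.ndarray
    best_value: float
    history: pd.DataFrame
    stop_reason: str
    seed: int
    parameter_names: list[str] = field(default_factory=list)
    final_std: np.ndarray | None = None  # raw-unit search std per free parameter

    def best_dict(self) -> dict[str, float]:
        return dict(zip(self.parameter_names, map(float, self.best_params)))


def maximize(
    objective_fn: Callable[[np.ndarray], float], spec: SearchSpec
) -> CalibrationResult:
    """Full CMA-ES loop: sample -> evaluate -> update -> stop check.

    ``objective_fn`` receives a raw-unit parameter vector (free parameters,
    in spec order) and returns a score in [0, 1].  A candidate whose
    evaluation raises is scored 0 and the run continues.  The run is
    bit-reproducible under a fixed ``spec.seed``.
    """
    state = init_state(spec)
    rng = np.random.default_rng(spec.seed)
    gen_best: list[float] = []
    rows = []
    reason = None
    while reason is None:
        candidates = sample_generation(state, spec, rng)
        values = np.empty(candidates.shape[0])
        for i, z in enumerate(candidates):
            try:
                values[i] = objective_fn(spec.to_raw(z))
            except Exception as exc:  # noqa: BLE001 - a failing candidate is just unfit
                log.debug("objective raised (%s); candidate scored 0", exc)
                values[i] = 0.0
        state = update(state, spec, candidates, values)
        finite = values[np.isfinite(values)]
        gen_best.append(float(finite.max()) if finite.size else 0.0)
        rows.append(
            {
                "generation": state.generation,
                "best": gen_best[-1],
                "worst": float(finite.min()) if finite.size else 0.0,
                "mean": float(finite.mean()) if finite.size else 0.0,
                "best_so_far": state.best_so_far[1],
            }
        )
        reason = should_stop(state, gen_best, spec)

    # Search spread in raw units: sigma * sqrt(diag(C)) times interval width.
    widths = np.array(
        [
            (math.log(p.upper) - math.log(p.lower)) if p.log_scale else (p.upper - p.lower)
            for p in spec.free
        ]
    )
    final_std = state.sigma * np.sqrt(np.diag(state.C)) * widths

    best_x, best_f = state.best_so_far
    log.info(
        "CMA-ES stopped (%s) after %d generations, best objective %.4f",
        reason,
        state.generation,
        best_f,
    )
    return CalibrationResult(
        best_params=best_x,
        best_value=best_f,
        history=pd.DataFrame(rows),
        stop_reason=reason,
        seed=spec.seed,
        parameter_names=[p.name for p in spec.free],
        final_std=final_std,
    )
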