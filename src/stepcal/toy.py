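"""Synthetic two-parameter calibration benchmark.

One continuous score g (the negated six-hump-camel function, rescaled to
[0, 1]) is combined with equal weight with one binary score h (a half-plane
membership rule):

    f(x1, x2) = g(x1, x2) / 2 + h(x1, x2) / 2

over the box [-2, 2] x [-1, 1].  The camel function has two global maxima of
1.0316 at (+-0.0898, -+0.7126); the half-plane rule x2 <= x1 keeps exactly
one of them feasible, so f has a unique global maximum of 1 near
(0.0898, -0.7126).  This makes the benchmark a miniature of a real
calibration: a smooth data-fit score plus a hard knowledge rule.
"""

from __future__ import annotations

import numpy as np

from stepcal.cmaes import CalibrationResult, ParameterSpec, SearchSpec, maximize

#: Magnitude of the camel optimum, used to rescale g onto [0, 1].
CAMEL_MAX = 1.0316
#: The h-feasible global maximizer of the combined objective.
GLOBAL_MAXIMIZER = (0.0898, -0.7126)
#: Search box.
BOUNDS = ((-2.0, 2.0), (-1.0, 1.0))


def camel_raw(x1, x2):
    """Negated six-hump camel: maxima ~1.0316 at (+-0.0898, -+0.7126).

    Even under joint negation: camel_raw(x1, x2) == camel_raw(-x1, -x2).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return -(
        (4.0 - 2.1 * x1**2 + x1**4 / 3.0) * x1**2
        + x1 * x2
        + (-4.0 + 4.0 * x2**2) * x2**2
    )


def rescale_u(v):
    """Rescale onto [0, 1] by the known optimum magnitude, clipping below 0.

    Monotone nondecreasing, so the argmax of the camel score is preserved
    and the global maxima map to exactly 1.
    """
    return np.clip(np.asarray(v, dtype=float) / CAMEL_MAX, 0.0, 1.0)


def camel_score(x1, x2):
    """Continuous sub-score g in [0, 1]."""
    return rescale_u(camel_raw(x1, x2))


def halfplane_h(x1, x2):
    """Binary sub-score h: 1 iff x2 <= x1 (boundary included)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return (x2 <= x1).astype(float)


def toy_objective(x1, x2):
    """Equal-weight combination f = g/2 + h/2, in [0, 1]."""
    return 0.5 * camel_score(x1, x2) + 0.5 * halfplane_h(x1, x2)


def toy_search_spec(seed: int = 0, **overrides) -> SearchSpec:
    """Benchmark settings: start (-2, 1), per-axis std 0.5, population 20."""
    params = [
        ParameterSpec("x1", *BOUNDS[0], initial_guess=-2.0, init_std=0.5),
        ParameterSpec("x2", *BOUNDS[1], initial_guess=1.0, init_std=0.5),
    ]
    kw = dict(
        parameters=params,
        population_size=20,
        stop_threshold=0.9999,
        stagnation_window=30,
        stagnation_tol=1e-6,
        max_generations=300,
        seed=seed,
    )
    kw.update(overrides)
    return SearchSpec(**kw)


def run_toy(seed: int = 0, **overrides) -> CalibrationResult:
    """Maximize the benchmark objective with CMA-ES under a fixed seed."""
    spec = toy_search_spec(seed=seed, **overrides)
    return maximize(lambda x: float(toy_objective(x[0], x[1])), spec)


def run_toy_best_of(seeds) -> CalibrationResult:
    """Run one CMA-ES per seed and return the best result."""
    results = [run_toy(seed=s) for s in seeds]
    return max(results, key=lambda r: r.best_value)


def grid_search(n: int = 1001) -> tuple[float, tuple[float, float]]:
    """Brute-force oracle: dense grid maximum of the objective over the box.

    Returns (max value, (x1, x2) at the max).
    """
    x1 = np.linspace(*BOUNDS[0], n)
    x2 = np.linspace(*BOUNDS[1], n)
    X1, X2 = np.meshgrid(x1, x2, indexing="ij")
    F = toy_objective(X1, X2)
    i, j = np.unravel_index(np.argmax(F), F.shape)
    return float(F[i, j]), (float(x1[i]), float(x2[j]))
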