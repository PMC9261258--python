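"""Constraint scoring: map heterogeneous biological constraints to [0, 1].

Two kinds of computational constraint are supported, mirroring how literature
evidence comes packaged:

* :class:`BinaryConstraint` — a knowledge rule ("the quantity stays above a
  threshold"), scored 0 or 1.
* :class:`DataConstraint` — a measured time series with standard deviations,
  scored continuously in [0, 1] by how closely the simulated output tracks
  the measurements.

All sub-scores s_k are combined into the single calibration objective

    f(theta) = sum_k w_k * s_k / sum_k w_k

which is the quantity the optimizer maximizes.  Scores on a common scale are
what make a count of cells, a radius in micrometres and a qualitative rule
commensurable inside one objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from stepcal.errors import ConfigurationError
from stepcal.trajectory import Trajectory

log = logging.getLogger(__name__)

COMPARATORS = ("greater", "less", "between")

#: Relative fallback when a data point has no (or zero) standard deviation.
DEFAULT_SD_FRACTION = 0.1
#: Absolute fallback when additionally the mean itself is zero.
DEFAULT_SD_ABSOLUTE = 1.0


@dataclass
class BinaryConstraint:
    """Knowledge-based rule scored 0/1 against a simulated trajectory.

    The rule must hold at *every* trajectory sample inside ``time_window``
    (days); the window ``"final"`` checks the last sample only.  Comparators
    are strict, so boundary equality scores 0 — a deterministic tie-break.
    """

    name: str
    variable: str
    comparator: str
    threshold: Union[float, tuple[float, float]]
    time_window: Union[str, tuple[float, float]] = "final"
    weight: float = 1.0
    scenario: str | None = None

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ConfigurationError(
                f"comparator must be one of {COMPARATORS}, got {self.comparator!r}"
            )
        if self.weight < 0:
            raise ConfigurationError("constraint weight must be >= 0")
        if self.comparator == "between":
            lo, hi = self.threshold  # type: ignore[misc]
            if not lo < hi:
                raise ConfigurationError(
                    f"'between' needs lower < upper, got ({lo}, {hi})"
                )
        else:
            self.threshold = float(self.threshold)  # type: ignore[arg-type]
        if self.time_window != "final":
            t0, t1 = self.time_window  # type: ignore[misc]
            if t1 < t0:
                raise ConfigurationError("time_window must satisfy t_start <= t_end")

    def holds(self, values: np.ndarray) -> bool:
        v = np.asarray(values, dtype=float)
        if self.comparator == "greater":
            return bool(np.all(v > self.threshold))
        if self.comparator == "less":
            return bool(np.all(v < self.threshold))
        lo, hi = self.threshold  # type: ignore[misc]
        return bool(np.all((v > lo) & (v < hi)))


@dataclass
class DataConstraint:
    """Experimental time series (time, mean, sd) scored continuously.

    The model output is linearly interpolated onto the data times (the data
    times are the observables; the simulation grid is an implementation
    detail).  Each point contributes

        phi(r) = 1            if r <= 1
                 exp(1 - r)   otherwise,   r = |y_model - mean| / (2 sd)

    and the score is the mean of phi over points.  A model within two
    standard deviations of every measurement — the acceptance language used
    for tumor growth curves — therefore scores exactly 1, with a smooth
    exponential penalty outside the band.  Zero or missing SDs fall back to
    ``sd_fraction * |mean|`` (and 1.0 absolute at mean 0).
    """

    name: str
    variable: str
    times: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    weight: float = 1.0
    sd_fraction: float = DEFAULT_SD_FRACTION
    scenario: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.times.size == 0:
            raise ConfigurationError("data constraint needs at least one point")
        if not (self.times.shape == self.means.shape == self.sds.shape):
            raise ConfigurationError("times, means and sds must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("data times must be strictly increasing")
        if np.any(self.sds < 0):
            raise ConfigurationError("standard deviations must be >= 0")
        if self.weight < 0:
            raise ConfigurationError("constraint weight must be >= 0")

    @classmethod
    def from_frame(cls, name: str, variable: str, frame: pd.DataFrame, **kw):
        missing = {"time", "mean", "sd"} - set(frame.columns)
        if missing:
            raise ConfigurationError(f"data table missing columns {sorted(missing)}")
        return cls(
            name=name,
            variable=variable,
            times=frame["time"].to_numpy(),
            means=frame["mean"].to_numpy(),
            sds=frame["sd"].to_numpy(),
            **kw,
        )

    @classmethod
    def from_csv(cls, name: str, variable: str, path: str | Path, **kw):
        """Load a `time,mean,sd` CSV (times in days)."""
        return cls.from_frame(name, variable, pd.read_csv(path), **kw)

    def effective_sds(self) -> np.ndarray:
        sds = self.sds.copy()
        fallback = np.where(
            self.means != 0.0, self.sd_fraction * np.abs(self.means), DEFAULT_SD_ABSOLUTE
        )
        return np.where(sds > 0.0, sds, fallback)


Constraint = Union[BinaryConstraint, DataConstraint]


def point_score(r: np.ndarray) -> np.ndarray:
    """Per-point score phi(r): 1 inside the 2-SD band, exp(1 - r) outside."""
    r = np.asarray(r, dtype=float)
    return np.where(r <= 1.0, 1.0, np.exp(np.clip(1.0 - r, -700.0, 0.0)))


def score_binary(constraint: BinaryConstraint, trajectory: Trajectory) -> float:
    """Score a knowledge rule: 1 if it holds over its whole window, else 0."""
    if constraint.time_window == "final":
        values = np.array([trajectory.final(constraint.variable)])
    else:
        t0, t1 = constraint.time_window  # type: ignore[misc]
        values = trajectory.window(constraint.variable, t0, t1)
    return 1.0 if constraint.holds(values) else 0.0


def score_continuous(constraint: DataConstraint, trajectory: Trajectory) -> float:
    """Score a data-fit rule: mean phi over data points, in [0, 1]."""
    model = trajectory.at(constraint.variable, constraint.times)
    sds = constraint.effective_sds()
    r = np.abs(model - constraint.means) / (2.0 * sds)
    return float(np.mean(point_score(r)))


def score(constraint: Constraint, trajectory: Trajectory) -> float:
    if isinstance(constraint, BinaryConstraint):
        return score_binary(constraint, trajectory)
    return score_continuous(constraint, trajectory)


@dataclass
class ObjectiveSpec:
    """A weighted set of constraints defining one calibration objective."""

    constraints: list[Constraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.constraints and self.total_weight() <= 0:
            raise ConfigurationError("sum of constraint weights must be > 0")

    def total_weight(self) -> float:
        return float(sum(c.weight for c in self.constraints))

    def scores(self, trajectories) -> dict[str, float]:
        """Per-constraint sub-scores.

        ``trajectories`` is either a single :class:`Trajectory` (applied to
        all constraints) or a mapping scenario-label -> Trajectory for
        multi-scenario objectives.
        """
        out: dict[str, float] = {}
        for c in self.constraints:
            traj = self._resolve(c, trajectories)
            out[c.name] = score(c, traj)
        return out

    @staticmethod
    def _resolve(constraint: Constraint, trajectories) -> Trajectory:
        if isinstance(trajectories, Trajectory):
            return trajectories
        label = constraint.scenario
        if label is None:
            if len(trajectories) == 1:
                return next(iter(trajectories.values()))
            raise ConfigurationError(
                f"constraint {constraint.name!r} has no scenario label but "
                f"{len(trajectories)} trajectories were supplied"
            )
        try:
            return trajectories[label]
        except KeyError:
            raise ConfigurationError(
                f"constraint {constraint.name!r} references unknown scenario "
                f"{label!r}"
            ) from None


def objective(spec: ObjectiveSpec, trajectories) -> float:
    """Weighted objective f = sum w_k s_k / sum w_k, in [0, 1]."""
    total = spec.total_weight()
    if total <= 0:
        raise ConfigurationError("sum of constraint weights must be > 0")
    scores = spec.scores(trajectories)
    f = sum(c.weight * scores[c.name] for c in spec.constraints) / total
    if log.isEnabledFor(logging.DEBUG):
        detail = ", ".join(f"{k}={v:.4f}" for k, v in scores.items())
        log.debug("objective f=%.4f (%s)", f, detail)
    return float(f)


def constraints_from_config(entries: Sequence[dict], base_dir: str | Path = ".") -> list[Constraint]:
    """Build constraints from parsed config entries (YAML/JSON dialect).

    Each entry carries ``kind: binary | data``.  Binary entries give
    ``variable``, ``comparator``, ``threshold`` (scalar, or [lo, hi] for
    "between") and optional ``window`` ([t0, t1] in days, or "final").
    Data entries give ``variable`` and ``csv`` (path with header
    time,mean,sd, relative to the config file) or an inline ``series`` list
    of [time, mean, sd] rows.
    """
    base = Path(base_dir)
    out: list[Constraint] = []
    for i, entry in enumerate(entries):
        e = dict(entry)
        kind = e.pop("kind", None)
        name = e.pop("name", f"constraint_{i}")
        weight = float(e.pop("weight", 1.0))
        scenario = e.pop("scenario", None)
        if kind == "binary":
            threshold = e.pop("threshold")
            if isinstance(threshold, (list, tuple)):
                threshold = tuple(float(x) for x in threshold)
            window = e.pop("window", "final")
            if isinstance(window, (list, tuple)):
                window = tuple(float(x) for x in window)
            out.append(
                BinaryConstraint(
                    name=name,
                    variable=e.pop("variable"),
                    comparator=e.pop("comparator"),
                    threshold=threshold,
                    time_window=window,
                    weight=weight,
                    scenario=scenario,
                )
            )
        elif kind == "data":
            variable = e.pop("variable")
            kw = {"weight": weight, "scenario": scenario}
            if "sd_fraction" in e:
                kw["sd_fraction"] = float(e.pop("sd_fraction"))
            if "csv" in e:
                out.append(
                    DataConstraint.from_csv(name, variable, base / e.pop("csv"), **kw)
                )
            elif "series" in e:
                rows = np.asarray(e.pop("series"), dtype=float)
                if rows.ndim != 2 or rows.shape[1] != 3:
                    raise ConfigurationError(
                        f"constraint {name!r}: series rows must be [time, mean, sd]"
                    )
                out.append(
                    DataConstraint(
                        name, variable, rows[:, 0], rows[:, 1], rows[:, 2], **kw
                    )
                )
            else:
                raise ConfigurationError(
                    f"data constraint {name!r} needs 'csv' or 'series'"
                )
        else:
            raise ConfigurationError(
                f"constraint {name!r}: kind must be 'binary' or 'data', got {kind!r}"
            )
        e.pop("comment", None)
        if e:
            raise ConfigurationError(
                f"constraint {name!r}: unknown keys {sorted(e)}"
            )
    return out
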