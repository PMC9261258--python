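"""Simulated time-series container used by scoring and the growth model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stepcal.errors import ConfigurationError


@dataclass
class Trajectory:
    """Model output sampled on a time grid.

    Parameters
    ----------
    times
        Strictly increasing sample times in days.
    variables
        Mapping from output-variable name (e.g. ``"tumor_radius_um"``) to an
        array of values aligned with ``times``.
    """

    times: np.ndarray
    variables: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or self.times.size == 0:
            raise ConfigurationError("trajectory needs a non-empty 1-D time grid")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("trajectory times must be strictly increasing")
        self.variables = {
            k: np.asarray(v, dtype=float) for k, v in self.variables.items()
        }
        for name, vals in self.variables.items():
            if vals.shape != self.times.shape:
                raise ConfigurationError(
                    f"variable {name!r} has {vals.size} samples for "
                    f"{self.times.size} time points"
                )

    @property
    def horizon(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def values(self, variable: str) -> np.ndarray:
        try:
            return self.variables[variable]
        except KeyError:
            raise ConfigurationError(
                f"unknown trajectory variable {variable!r}; "
                f"available: {sorted(self.variables)}"
            ) from None

    def at(self, variable: str, times) -> np.ndarray:
        """Linearly interpolate ``variable`` onto the requested times.

        Times outside the simulated horizon are a configuration error: data
        points must be covered by the simulation, never extrapolated.
        """
        t = np.atleast_1d(np.asarray(times, dtype=float))
        t0, t1 = self.horizon
        if np.any(t < t0 - 1e-9) or np.any(t > t1 + 1e-9):
            raise ConfigurationError(
                f"requested times outside simulation horizon [{t0}, {t1}]"
            )
        return np.interp(t, self.times, self.values(variable))

    def window(self, variable: str, t_start: float, t_end: float) -> np.ndarray:
        """Samples of ``variable`` at grid points within [t_start, t_end]."""
        if t_end < t_start:
            raise ConfigurationError("time window must satisfy t_start <= t_end")
        t0, t1 = self.horizon
        if t_start < t0 - 1e-9 or t_end > t1 + 1e-9:
            raise ConfigurationError(
                f"window [{t_start}, {t_end}] outside horizon [{t0}, {t1}]"
            )
        mask = (self.times >= t_start - 1e-12) & (self.times <= t_end + 1e-12)
        vals = self.values(variable)[mask]
        if vals.size == 0:
            raise ConfigurationError(
                f"no trajectory samples inside window [{t_start}, {t_end}]"
            )
        return vals

    def final(self, variable: str) -> float:
        return float(self.values(variable)[-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.times})
        for name, vals in self.variables.items():
            df[name] = vals
        return df
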