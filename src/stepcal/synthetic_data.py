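"""Synthetic calibration datasets for the growth-model example.

The original spheroid and xenograft measurement tables are not available,
so the calibration is exercised against synthetic series that reproduce the
published growth behaviours:

* in vitro spheroid radius: +12.5 um/day over the first 20 days, reaching
  400 um, then approaching a plateau;
* xenograft volume, EGFR-exon-19-deletion line, placebo: +20 mm^3/day over
  the first 20 days;
* same line under gefitinib 25 mg/kg: -16 mm^3/day over the first 10 days,
  then a plateau;
* EGFR+PIK3CA line, placebo or gefitinib: +7.5 mm^3/day over the first
  20 days (gefitinib has no effect — the resistant genotype).

Each dataset carries per-point standard deviations (a fixed fraction of the
mean) and seeded Gaussian noise (sd/4) on the means.  The trend slopes are
exact before noise; plateaus are smooth exponential saturations matched to
the trend slope at onset, so the mean curve is C^1.  Initial sizes, noise
levels and sampling grids are design choices echoed in the manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from stepcal.errors import ConfigurationError
from stepcal.scoring import DataConstraint

XENOGRAFT_ARMS = (
    "egfr_placebo",
    "egfr_gefitinib",
    "egfr_pik3ca_placebo",
    "egfr_pik3ca_gefitinib",
)

#: Design constants of the spheroid series (radius, um).
SPHEROID_DESIGN = {
    "baseline": 150.0,      # radius at day 0 (um)
    "slope": 12.5,          # um/day over the linear window
    "onset": 20.0,          # day the plateau approach starts
    "plateau": 450.0,       # asymptotic radius (um)
    "sd_fraction": 0.08,
    "days": (0.0, 30.0, 2.0),   # start, stop, step
}

#: Design constants per xenograft arm (volume, mm^3, from 200 mm^3).
XENOGRAFT_DESIGN = {
    "egfr_placebo": {"slope": 20.0, "onset": 20.0, "plateau": 680.0},
    "egfr_gefitinib": {"slope": -16.0, "onset": 10.0, "plateau": 30.0},
    "egfr_pik3ca_placebo": {"slope": 7.5, "onset": 20.0, "plateau": 380.0},
    "egfr_pik3ca_gefitinib": {"slope": 7.5, "onset": 20.0, "plateau": 380.0},
}
XENOGRAFT_BASELINE = 200.0
XENOGRAFT_SD_FRACTION = 0.10
XENOGRAFT_SAMPLING_DAYS = 3.5  # twice weekly
XENOGRAFT_HORIZON = 30.0


@dataclass
class SyntheticDataset:
    """One generated measurement series with its generating design."""

    label: str
    times: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    truth: dict = field(default_factory=dict)
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "mean": self.means, "sd": self.sds})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def manifest(self) -> dict:
        return {"label": self.label, "seed": self.seed, "design": dict(self.truth)}

    def write(self, directory: str | Path) -> Path:
        """Write `<label>.csv` plus `<label>.manifest.json`; returns csv path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = directory / f"{self.label}.csv"
        self.to_csv(csv_path)
        (directory / f"{self.label}.manifest.json").write_text(
            json.dumps(self.manifest(), indent=2)
        )
        return csv_path

    def as_constraint(self, variable: str, weight: float = 1.0, scenario: str | None = None) -> DataConstraint:
        return DataConstraint(
            name=self.label,
            variable=variable,
            times=self.times,
            means=self.means,
            sds=self.sds,
            weight=weight,
            scenario=scenario,
        )


def piecewise_trend(t: np.ndarray, baseline: float, slope: float, onset: float, plateau: float) -> np.ndarray:
    """Linear trend up to ``onset``, then C^1 exponential approach to ``plateau``."""
    t = np.asarray(t, dtype=float)
    v_onset = baseline + slope * onset
    gap = plateau - v_onset
    if gap == 0.0 or slope == 0.0:
        return np.where(t <= onset, baseline + slope * t, v_onset)
    if np.sign(gap) != np.sign(slope):
        raise ConfigurationError("plateau must lie beyond the linear trend end")
    k = slope / gap  # matches the trend slope at onset
    tail = plateau - gap * np.exp(-k * np.maximum(t - onset, 0.0))
    return np.where(t <= onset, baseline + slope * t, tail)


def _noisy(means: np.ndarray, sds: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return means + rng.normal(0.0, sds / 4.0)


def spheroid_trend(t) -> np.ndarray:
    d = SPHEROID_DESIGN
    return piecewise_trend(t, d["baseline"], d["slope"], d["onset"], d["plateau"])


def generate_spheroid_series(seed: int = 0) -> SyntheticDataset:
    """In vitro spheroid radius series (um), days 0..30 every 2 days."""
    d = SPHEROID_DESIGN
    start, stop, step = d["days"]
    times = np.arange(start, stop + 1e-9, step)
    trend = spheroid_trend(times)
    sds = d["sd_fraction"] * trend
    rng = np.random.default_rng([seed, 0])
    return SyntheticDataset(
        label="spheroid_radius",
        times=times,
        means=_noisy(trend, sds, rng),
        sds=sds,
        truth={
            "variable": "radius_um",
            **{k: d[k] for k in ("baseline", "slope", "onset", "plateau", "sd_fraction")},
            "slope_window": [0.0, d["onset"]],
        },
        seed=seed,
    )


def xenograft_trend(arm: str, t) -> np.ndarray:
    if arm not in XENOGRAFT_ARMS:
        raise ConfigurationError(f"unknown xenograft arm {arm!r}; choose from {XENOGRAFT_ARMS}")
    d = XENOGRAFT_DESIGN[arm]
    return piecewise_trend(t, XENOGRAFT_BASELINE, d["slope"], d["onset"], d["plateau"])


def generate_xenograft_series(arm: str, seed: int = 0) -> SyntheticDataset:
    """One xenograft tumor-volume arm (mm^3), sampled twice weekly."""
    trend_fn = xenograft_trend  # validates the arm
    times = np.arange(0.0, XENOGRAFT_HORIZON + 1e-9, XENOGRAFT_SAMPLING_DAYS)
    trend = trend_fn(arm, times)
    sds = XENOGRAFT_SD_FRACTION * trend
    rng = np.random.default_rng([seed, 1 + XENOGRAFT_ARMS.index(arm)])
    d = XENOGRAFT_DESIGN[arm]
    return SyntheticDataset(
        label=arm,
        times=times,
        means=_noisy(trend, sds, rng),
        sds=sds,
        truth={
            "variable": "volume_mm3",
            "baseline": XENOGRAFT_BASELINE,
            "slope": d["slope"],
            "onset": d["onset"],
            "plateau": d["plateau"],
            "sd_fraction": XENOGRAFT_SD_FRACTION,
            "slope_window": [0.0, d["onset"]],
        },
        seed=seed,
    )


def generate_all(seed: int = 0) -> dict[str, SyntheticDataset]:
    """The full calibration fixture: spheroid series plus the four arms."""
    out = {"spheroid_radius": generate_spheroid_series(seed)}
    for arm in XENOGRAFT_ARMS:
        out[arm] = generate_xenograft_series(arm, seed)
    return out


def fitted_slope(times, values, window: tuple[float, float]) -> float:
    """Least-squares slope of ``values`` against ``times`` inside ``window``."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if mask.sum() < 2:
        raise ConfigurationError("slope window must contain at least two samples")
    return float(np.polyfit(t[mask], v[mask], 1)[0])
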