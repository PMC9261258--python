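"""Config-file loading helpers (YAML dialect) shared by the CLI."""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml

from stepcal.cmaes import ParameterSpec
from stepcal.errors import ConfigurationError
from stepcal.growth_model import MutationProfile, Scenario


def load_yaml(path: str | Path) -> dict:
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"top level of {path} must be a mapping")
    return data


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def parameter_from_config(entry: dict) -> ParameterSpec:
    e = dict(entry)
    try:
        name = e.pop("name")
        bounds = e.pop("bounds")
    except KeyError as exc:
        raise ConfigurationError(f"parameter entry missing key {exc}") from None
    lo, hi = (float(b) for b in bounds)
    kw = {}
    for key in ("initial_guess", "init_std"):
        if key in e:
            kw[key] = float(e.pop(key))
    for key in ("log_scale", "allometric"):
        if key in e:
            kw[key] = bool(e.pop(key))
    if "unit" in e:
        kw["unit"] = str(e.pop(key := "unit") or "dimensionless")
    if e:
        raise ConfigurationError(f"parameter {name!r}: unknown keys {sorted(e)}")
    return ParameterSpec(name, lo, hi, **kw)


def scenario_from_config(entry: dict) -> Scenario:
    e = dict(entry)
    mut = e.pop("mutations", {}) or {}
    unknown = set(mut) - {"kras", "egfr_ex19del", "pik3ca"}
    if unknown:
        raise ConfigurationError(f"unknown mutation flags {sorted(unknown)}")
    profile = MutationProfile(**{k: bool(v) for k, v in mut.items()})
    allowed = {
        "mode",
        "dosing",
        "dose_mg_per_kg",
        "body_mass_g",
        "horizon_days",
        "output_step_days",
        "initial_radius_um",
        "initial_volume_mm3",
        "label",
    }
    unknown = set(e) - allowed
    if unknown:
        raise ConfigurationError(f"unknown scenario keys {sorted(unknown)}")
    return Scenario(mutations=profile, **e)
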