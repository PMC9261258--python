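"""Surrogate lung-adenocarcinoma growth model (rim-structured ODE).

This module is a self-contained, openly specified tumor-growth core in the
Greenspan tradition: the tumor is a perfect sphere of constant cell density
partitioned into a proliferating outer rim, a quiescent shell and a necrotic
core.  It exposes the five phenomena a xenograft calibration needs — tumor
cell proliferation, tumor cell death, neoangiogenesis, immune-mediated
killing and EGFR-inhibitor treatment — together with genotype effects of
the KRAS, EGFR-exon-19-deletion and PIK3CA mutations parameterized from
published constants.

Geometry (the direct model outputs):

    tumor_volume = (nb_pc + nb_qc + nb_nc) / cancer_cd
    tumor_radius = (3 * tumor_volume / (4 pi))^(1/3)

with nb_pc / nb_qc / nb_nc the proliferating / quiescent / necrotic cell
counts and cancer_cd = 2.8e8 cells/cm^3 the (constant) packing density.

Dynamics.  With R the current radius (um), A >= 0 the dimensionless
vascular support and A_fac = 1 + a_ang * A, the shell geometry factors

    g_q(R) = ((R - L_p * A_fac)_+ / R)^3     quiescent fraction depth
    g_n(R) = ((R - L_v * A_fac)_+ / R)^3     necrotic fraction depth

drive the transitions (rates in 1/day):

    d nb_pc / dt = k_div * drive * (1 - I) * nb_pc - k_q * g_q * nb_pc
                   - e_imm * nb_pc - k_kill * I * nb_pc
    d nb_qc / dt = k_q * g_q * nb_pc - k_n * g_n * nb_qc - e_imm * nb_qc
    d nb_nc / dt = k_n * g_n * nb_qc - k_lys * nb_nc
    d A     / dt = k_ang * nb_pc / (n_half + nb_pc) - d_ang * A   (xenograft)

In vitro (avascular spheroid) mode has no vasculature and no immune system:
A == 0 and e_imm := 0.  Vascularization relaxes both nutrient limits: the
proliferative and viable rim depths are stretched by the same factor
A_fac, which is what lets a vascularized xenograft grow far beyond the
avascular plateau radius.  I is the gefitinib proliferation inhibition
(see :func:`gefitinib_inhibition`) and ``drive`` collects genotype
multipliers.  Treatment acts both cytostatically ((1 - I) on division) and
cytotoxically (k_kill * I on cycling cells); quiescent cells are
drug-tolerant persisters, which is what makes a treated tumor shrink fast
and then plateau instead of vanishing.

Rates are stored at the in vitro reference mass (2.63 g) and rescaled
allometrically to the scenario body mass before integration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from stepcal import allometry
from stepcal.errors import ConfigurationError, SimulationError
from stepcal.trajectory import Trajectory

#: Cancer cell packing density (cells/cm^3), constant in space and time.
CANCER_CELL_DENSITY = 2.8e8

#: Published mutation-effect constants (stored verbatim).
LITERATURE_CONSTANTS = {
    # KRAS mutation: 97-99% (rounded to 98%) reduction of GTP hydrolysis,
    # keeping KRAS in its active form.
    "kras_hydrolysis_reduction": 0.98,
    # EGFR exon 19 deletion: ATP affinity (Km) shifts from ~5.0 to 129 uM...
    "egfr_atp_km_wt_uM": 5.0,
    "egfr_atp_km_mut_uM": 129.0,
    # ...and gefitinib inhibition constant from ~16.4 nM to an estimated
    # 0.833 nM (derived from an IC50 of 6 nM), conferring drug sensitivity.
    "gefitinib_ki_wt_nM": 16.4,
    "gefitinib_ki_mut_nM": 0.833,
    "gefitinib_ic50_mut_nM": 6.0,
    # PIK3CA mutation: ~2.7-fold increase of PI3K complex activity,
    # conferring gefitinib resistance downstream of EGFR.
    "pik3ca_pi3k_fold": 2.7,
}

#: Rate parameters rescaled with body mass (exponent from their 1/day unit).
ALLOMETRIC_RATES = ("k_div", "k_q", "k_n", "k_lys", "k_ang", "d_ang", "e_imm", "k_kill")


@dataclass(frozen=True)
class MutationProfile:
    """Genotype flags of the tumor line."""

    kras: bool = False
    egfr_ex19del: bool = False
    pik3ca: bool = False


@dataclass
class GrowthParams:
    """Calibratable growth-model parameters (rates at the 2.63 g reference)."""

    k_div: float = 0.6        # division rate of proliferating cells (1/day)
    k_q: float = 0.7          # proliferation -> quiescence transition (1/day)
    k_n: float = 0.3          # quiescence -> necrosis transition (1/day)
    k_lys: float = 0.05       # necrotic clearance (1/day)
    L_p: float = 25.0         # proliferative rim depth (um)
    L_v: float = 120.0        # viable rim depth (um)
    k_ang: float = 0.4        # vascular support production (1/day)
    d_ang: float = 0.05       # vascular support decay (1/day)
    a_ang: float = 1.0        # rim stretch per unit vascular support (-)
    n_half: float = 1e6       # half-saturation cell count for angiogenesis
    e_imm: float = 0.0        # immune kill rate of viable cells (1/day)
    k_kill: float = 0.3       # gefitinib-induced apoptosis of cycling cells (1/day)
    i_max: float = 0.9        # maximal gefitinib proliferation inhibition (-)
    c_gef: float = 50.0       # effective gefitinib exposure while dosed (nM)
    growth_pik: float = 1.0   # relative proliferative fitness, PIK3CA line (-)
    cancer_cd: float = CANCER_CELL_DENSITY  # cells/cm^3
    n0: float = 4000.0        # inoculum (cells) if the scenario sets no size

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ConfigurationError(f"parameter {f.name!r} must be >= 0")
        if self.L_p > self.L_v:
            raise ConfigurationError("proliferative rim L_p must not exceed L_v")
        if self.i_max > 1:
            raise ConfigurationError("i_max must lie in [0, 1]")

    @classmethod
    def from_dict(cls, values: dict, base: "GrowthParams | None" = None):
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ConfigurationError(f"unknown growth parameters: {sorted(unknown)}")
        start = base if base is not None else cls()
        return replace(start, **{k: float(v) for k, v in values.items()})


@dataclass(frozen=True)
class Scenario:
    """Experimental context for one simulation."""

    mode: str = "in_vitro"  # "in_vitro" | "xenograft"
    mutations: MutationProfile = field(default_factory=MutationProfile)
    dosing: str = "none"  # "none" | "gefitinib"
    dose_mg_per_kg: float = 25.0
    body_mass_g: float | None = None  # default 2.63 (in vitro) / 23 (xenograft)
    horizon_days: float = 30.0
    output_step_days: float = 0.5
    initial_radius_um: float | None = None   # in vitro default 150 um
    initial_volume_mm3: float | None = None  # xenograft default 200 mm^3
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode not in ("in_vitro", "xenograft"):
            raise ConfigurationError(f"unknown scenario mode {self.mode!r}")
        if self.dosing not in ("none", "gefitinib"):
            raise ConfigurationError(f"unknown dosing {self.dosing!r}")
        if self.horizon_days <= 0 or self.output_step_days <= 0:
            raise ConfigurationError("horizon and output step must be positive")

    @property
    def mass_g(self) -> float:
        if self.body_mass_g is not None:
            return self.body_mass_g
        return (
            allometry.IN_VITRO_MASS_G
            if self.mode == "in_vitro"
            else allometry.MOUSE_MASS_G
        )

    def output_grid(self) -> np.ndarray:
        n = int(round(self.horizon_days / self.output_step_days))
        return np.linspace(0.0, self.horizon_days, n + 1)


def tumor_volume(nb_pc: float, nb_qc: float, nb_nc: float, cancer_cd: float = CANCER_CELL_DENSITY):
    """Tumor volume (cm^3) = total cell count / packing density."""
    if np.any(np.asarray(cancer_cd) <= 0):
        raise ConfigurationError("cancer cell density must be > 0")
    return (np.asarray(nb_pc) + np.asarray(nb_qc) + np.asarray(nb_nc)) / cancer_cd


def tumor_radius(volume_cm3):
    """Sphere-equivalent radius (cm) of a tumor volume (cm^3)."""
    v = np.asarray(volume_cm3, dtype=float)
    if np.any(v < 0):
        raise ConfigurationError("tumor volume must be >= 0")
    return (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class EffectiveProfile:
    """Genotype-resolved pharmacodynamic constants."""

    ki_nM: float
    b_res: float
    drive: float
    gefitinib_sensitive: bool
    literature: dict = field(default_factory=lambda: dict(LITERATURE_CONSTANTS))


def apply_mutations(params: GrowthParams, profile: MutationProfile) -> EffectiveProfile:
    """Resolve genotype flags into effective PD constants.

    * EGFR exon 19 deletion switches the gefitinib inhibition constant from
      the wild-type 16.4 nM to the mutant 0.833 nM and marks the line
      drug-sensitive.
    * PIK3CA raises PI3K activity 2.7-fold; the excess constitutive
      activity (fold - 1 = 1.7x the EGFR-dependent baseline) keeps the
      downstream pathway saturated regardless of receptor inhibition, so
      the resistance factor is min(1, fold - 1) — here full bypass.
    * KRAS locked in its active form (98% hydrolysis reduction) sustains
      pathway activation, mapped to a proliferation-drive multiplier
      1 + reduction.

    The published constants are returned verbatim for inspection.
    """
    lit = LITERATURE_CONSTANTS
    ki = lit["gefitinib_ki_mut_nM"] if profile.egfr_ex19del else lit["gefitinib_ki_wt_nM"]
    b_res = min(1.0, lit["pik3ca_pi3k_fold"] - 1.0) if profile.pik3ca else 0.0
    drive = 1.0 + lit["kras_hydrolysis_reduction"] if profile.kras else 1.0
    if profile.pik3ca:
        drive *= params.growth_pik
    return EffectiveProfile(
        ki_nM=ki,
        b_res=b_res,
        drive=drive,
        gefitinib_sensitive=profile.egfr_ex19del and not profile.pik3ca,
    )


def gefitinib_inhibition(c_nM: float, ki_nM: float, b_res: float, i_max: float) -> float:
    """Fractional proliferation inhibition I in [0, 1].

    Saturable receptor occupancy scaled by the maximal effect and blunted
    by downstream resistance: I = i_max * (1 - b_res) * C / (C + Ki).
    """
    if c_nM < 0 or ki_nM < 0:
        raise ConfigurationError("concentration and Ki must be >= 0")
    if c_nM == 0.0:
        return 0.0
    return float(i_max * (1.0 - b_res) * c_nM / (c_nM + ki_nM))


def _initial_state(params: GrowthParams, scenario: Scenario, a_init: float):
    """Partition the initial cell count into shells at the starting radius."""
    if scenario.mode == "in_vitro":
        r0_um = (
            scenario.initial_radius_um if scenario.initial_radius_um is not None else 150.0
        )
        v0_cm3 = 4.0 / 3.0 * math.pi * (r0_um * 1e-4) ** 3
        n_total = v0_cm3 * params.cancer_cd
    else:
        v0_mm3 = (
            scenario.initial_volume_mm3
            if scenario.initial_volume_mm3 is not None
            else 200.0
        )
        v0_cm3 = v0_mm3 * 1e-3
        n_total = v0_cm3 * params.cancer_cd
        r0_um = tumor_radius(v0_cm3) * 1e4
    a_fac = 1.0 + params.a_ang * a_init
    gq = max(0.0, (r0_um - params.L_p * a_fac) / r0_um) ** 3 if r0_um > 0 else 0.0
    gn = max(0.0, (r0_um - params.L_v * a_fac) / r0_um) ** 3 if r0_um > 0 else 0.0
    nc = n_total * gn
    qc = n_total * max(0.0, gq - gn)
    pc = n_total - qc - nc
    return np.array([pc, qc, nc, a_init])


def simulate(params: GrowthParams | dict, scenario: Scenario) -> Trajectory:
    """Integrate the growth model for one scenario.

    Rates are rescaled allometrically from the 2.63 g reference to the
    scenario body mass before integration.  Output variables: ``nb_pc``,
    ``nb_qc``, ``nb_nc``, ``A``, ``volume_mm3``, ``radius_um`` and
    ``prolif_fraction`` on the scenario output grid.
    """
    if isinstance(params, dict):
        params = GrowthParams.from_dict(params)
    p = _rescaled(params, scenario.mass_g)
    profile = apply_mutations(p, scenario.mutations)

    inhibition = 0.0
    if scenario.dosing == "gefitinib":
        inhibition = gefitinib_inhibition(p.c_gef, profile.ki_nM, profile.b_res, p.i_max)

    xeno = scenario.mode == "xenograft"
    e_imm = p.e_imm if xeno else 0.0
    a_init = (p.k_ang / p.d_ang if p.d_ang > 0 else 0.0) if xeno else 0.0
    growth = p.k_div * profile.drive * (1.0 - inhibition)
    cd = p.cancer_cd

    def rhs(_t, y):
        pc, qc, nc, a = (max(v, 0.0) for v in y)
        total = pc + qc + nc
        r_um = tumor_radius(total / cd) * 1e4 if total > 0 else 0.0
        if r_um > 0:
            a_fac = 1.0 + p.a_ang * a
            gq = max(0.0, (r_um - p.L_p * a_fac) / r_um) ** 3
            gn = max(0.0, (r_um - p.L_v * a_fac) / r_um) ** 3
        else:
            gq = gn = 0.0
        dpc = growth * pc - p.k_q * gq * pc - e_imm * pc - p.k_kill * inhibition * pc
        dqc = p.k_q * gq * pc - p.k_n * gn * qc - e_imm * qc
        dnc = p.k_n * gn * qc - p.k_lys * nc
        da = (p.k_ang * pc / (p.n_half + pc) - p.d_ang * a) if xeno else 0.0
        return (dpc, dqc, dnc, da)

    grid = scenario.output_grid()
    y0 = _initial_state(p, scenario, a_init)
    sol = solve_ivp(
        rhs,
        (0.0, scenario.horizon_days),
        y0,
        method="LSODA",
        t_eval=grid,
        rtol=1e-8,
        atol=1e-3,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SimulationError(
            f"integration failed for scenario {scenario.label or scenario.mode!r}: "
            f"{sol.message}",
            params=_as_dict(params),
        )
    pc, qc, nc, a = (np.maximum(sol.y[i], 0.0) for i in range(4))
    vol_cm3 = tumor_volume(pc, qc, nc, cd)
    total = pc + qc + nc
    with np.errstate(invalid="ignore", divide="ignore"):
        prolif = np.where(total > 0, pc / np.maximum(total, 1e-300), 0.0)
    return Trajectory(
        times=sol.t,
        variables={
            "nb_pc": pc,
            "nb_qc": qc,
            "nb_nc": nc,
            "A": a,
            "volume_mm3": vol_cm3 * 1e3,
            "radius_um": tumor_radius(vol_cm3) * 1e4,
            "prolif_fraction": prolif,
        },
    )


def _rescaled(params: GrowthParams, body_mass_g: float) -> GrowthParams:
    """Allometric transfer of all rate parameters to the scenario body mass."""
    b = allometry.exponent_from_unit("1/day")
    updates = {
        name: allometry.scale_parameter(
            getattr(params, name), allometry.IN_VITRO_MASS_G, body_mass_g, b
        )
        for name in ALLOMETRIC_RATES
    }
    return replace(params, **updates)


def _as_dict(params: GrowthParams) -> dict:
    return {f.name: getattr(params, f.name) for f in fields(params)}


TRAJECTORY_CSV_COLUMNS = [
    "t",
    "nb_pc",
    "nb_qc",
    "nb_nc",
    "A",
    "volume_mm3",
    "radius_um",
    "prolif_fraction",
]


def export_trajectory_csv(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV with the canonical column order."""
    df = trajectory.to_frame()[TRAJECTORY_CSV_COLUMNS]
    df.to_csv(path, index=False)
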