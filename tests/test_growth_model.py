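"""Surrogate growth model: geometry, genotype effects, dynamics, integrator."""

import math

import numpy as np
import pytest

from stepcal import allometry
from stepcal.errors import ConfigurationError
from stepcal.growth_model import (
    CANCER_CELL_DENSITY,
    LITERATURE_CONSTANTS,
    GrowthParams,
    MutationProfile,
    Scenario,
    apply_mutations,
    gefitinib_inhibition,
    simulate,
    tumor_radius,
    tumor_volume,
)


class TestGeometry:
    def test_count_equal_to_density_gives_unit_volume(self):
        assert tumor_volume(2.8e8, 0.0, 0.0, 2.8e8) == pytest.approx(1.0)

    def test_empty_tumor(self):
        assert tumor_volume(0, 0, 0, CANCER_CELL_DENSITY) == 0.0
        assert tumor_radius(0.0) == 0.0

    def test_volume_additivity(self):
        a, b = 1.7e7, 9.3e6
        assert tumor_volume(a + b, 0, 0, CANCER_CELL_DENSITY) == pytest.approx(
            tumor_volume(a, 0, 0, CANCER_CELL_DENSITY)
            + tumor_volume(b, 0, 0, CANCER_CELL_DENSITY)
        )

    def test_unit_sphere_radius(self):
        assert tumor_radius(4.0 * math.pi / 3.0) == pytest.approx(1.0)

    def test_cube_root_scaling(self):
        v = 0.37
        assert tumor_radius(8 * v) == pytest.approx(2 * tumor_radius(v))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            tumor_volume(1.0, 0.0, 0.0, 0.0)
        with pytest.raises(ConfigurationError):
            tumor_radius(-1.0)


class TestParameterization:
    """The published mutation constants are stored verbatim."""

    @pytest.mark.parametrize(
        "key,value",
        [
            ("kras_hydrolysis_reduction", 0.98),
            ("egfr_atp_km_wt_uM", 5.0),
            ("egfr_atp_km_mut_uM", 129.0),
            ("gefitinib_ki_wt_nM", 16.4),
            ("gefitinib_ki_mut_nM", 0.833),
            ("gefitinib_ic50_mut_nM", 6.0),
            ("pik3ca_pi3k_fold", 2.7),
        ],
    )
    def test_literature_constants(self, key, value):
        assert LITERATURE_CONSTANTS[key] == value

    def test_egfr_mutation_switches_ki_and_sensitivity(self):
        p = GrowthParams()
        eff = apply_mutations(p, MutationProfile(egfr_ex19del=True))
        assert eff.ki_nM == 0.833
        assert eff.gefitinib_sensitive
        wt = apply_mutations(p, MutationProfile())
        assert wt.ki_nM == 16.4
        assert not wt.gefitinib_sensitive

    def test_pik3ca_confers_full_bypass_resistance(self):
        eff = apply_mutations(GrowthParams(), MutationProfile(egfr_ex19del=True, pik3ca=True))
        assert eff.b_res == 1.0
        assert not eff.gefitinib_sensitive
        assert eff.literature["pik3ca_pi3k_fold"] == 2.7

    def test_kras_drive_multiplier_from_hydrolysis_reduction(self):
        eff = apply_mutations(GrowthParams(), MutationProfile(kras=True))
        assert eff.drive == pytest.approx(1.98)
        assert eff.literature["kras_hydrolysis_reduction"] == 0.98


class TestInhibition:
    def test_zero_concentration_means_no_inhibition(self):
        assert gefitinib_inhibition(0.0, 0.833, 0.0, 0.9) == 0.0

    def test_half_saturation(self):
        assert gefitinib_inhibition(0.833, 0.833, 0.0, 0.8) == pytest.approx(0.4)

    def test_full_resistance_blocks_any_concentration(self):
        assert gefitinib_inhibition(1e6, 0.833, 1.0, 1.0) == 0.0

    def test_bounded_by_i_max(self):
        assert gefitinib_inhibition(1e9, 0.833, 0.0, 0.85) <= 0.85


def in_vitro(**kw):
    return Scenario(mode="in_vitro", **kw)


class TestDynamics:
    def test_unlimited_in_vitro_growth_is_exponential(self):
        """With no rim limits and no losses the reduced ODE is linear:
        nb_pc grows at exactly k_div and the radius as exp(k_div t / 3)."""
        p = GrowthParams(
            k_div=0.3, k_q=0.5, k_n=0.2, k_lys=0.0, L_p=1e6, L_v=1e6, e_imm=0.0
        )
        traj = simulate(p, in_vitro(initial_radius_um=100.0, horizon_days=10.0))
        t = traj.times
        pc = traj.values("nb_pc")
        assert pc[1:] == pytest.approx(pc[0] * np.exp(0.3 * t[1:]), rel=1e-5)
        r = traj.values("radius_um")
        assert r[1:] == pytest.approx(r[0] * np.exp(0.3 * t[1:] / 3.0), rel=1e-5)
        assert np.all(traj.values("prolif_fraction") == pytest.approx(1.0, abs=1e-9))

    def test_all_rates_zero_keeps_state_constant(self):
        p = GrowthParams(
            k_div=0.0, k_q=0.0, k_n=0.0, k_lys=0.0, k_ang=0.0, d_ang=0.0, e_imm=0.0
        )
        traj = simulate(p, in_vitro(horizon_days=5.0))
        for name in ("nb_pc", "nb_qc", "nb_nc", "volume_mm3"):
            v = traj.values(name)
            assert v == pytest.approx(np.full_like(v, v[0]), rel=1e-9, abs=1e-9)

    def test_in_vitro_has_no_vasculature_and_no_immune_kill(self):
        p = GrowthParams(k_ang=2.0, d_ang=0.1, e_imm=0.4)
        traj = simulate(p, in_vitro(horizon_days=10.0))
        assert np.all(traj.values("A") == 0.0)
        # immune term off: with huge rims the growth is pure k_div
        p2 = GrowthParams(k_div=0.2, k_q=0.0, k_n=0.0, k_lys=0.0, L_p=1e6, L_v=1e6, e_imm=0.9)
        tr2 = simulate(p2, in_vitro(horizon_days=5.0))
        assert tr2.values("nb_pc")[-1] > tr2.values("nb_pc")[0]

    def test_nonnegative_compartments(self):
        p = GrowthParams(k_div=0.8, k_q=2.5, k_n=0.9, k_lys=1.5, L_p=10.0, L_v=60.0)
        traj = simulate(p, in_vitro(horizon_days=30.0))
        for name in ("nb_pc", "nb_qc", "nb_nc", "volume_mm3", "radius_um"):
            assert np.all(traj.values(name) >= 0.0)

    def test_without_loss_pathways_total_count_is_nondecreasing(self):
        p = GrowthParams(k_div=0.4, k_q=0.9, k_n=0.5, k_lys=0.0, e_imm=0.0)
        traj = simulate(p, in_vitro(horizon_days=30.0))
        total = traj.values("nb_pc") + traj.values("nb_qc") + traj.values("nb_nc")
        assert np.all(np.diff(total) >= -1e-6 * total[:-1])
        # radius is a monotone function of the total count
        assert np.all(np.diff(traj.values("radius_um")) >= -1e-6)

    def test_xenograft_gefitinib_shrinks_sensitive_tumor_only(self):
        p = GrowthParams(e_imm=0.01, c_gef=50.0, k_kill=0.5, i_max=0.95)
        egfr = MutationProfile(egfr_ex19del=True)
        pik = MutationProfile(egfr_ex19del=True, pik3ca=True)
        treated = simulate(p, Scenario(mode="xenograft", mutations=egfr, dosing="gefitinib", horizon_days=10.0))
        placebo = simulate(p, Scenario(mode="xenograft", mutations=egfr, dosing="none", horizon_days=10.0))
        assert treated.final("volume_mm3") < placebo.final("volume_mm3")
        resistant_treated = simulate(p, Scenario(mode="xenograft", mutations=pik, dosing="gefitinib", horizon_days=10.0))
        resistant_placebo = simulate(p, Scenario(mode="xenograft", mutations=pik, dosing="none", horizon_days=10.0))
        assert resistant_treated.values("volume_mm3") == pytest.approx(
            resistant_placebo.values("volume_mm3"), rel=1e-9
        )


class TestAllometricConsistency:
    def test_prescaled_rates_match_internal_scaling(self):
        """Scaling rates by hand to mouse mass and simulating at the
        reference mass must equal simulating the stored values at mouse
        mass (the model rescales internally)."""
        params = GrowthParams(e_imm=0.02)
        scen_mouse = Scenario(mode="xenograft", horizon_days=15.0)
        internal = simulate(params, scen_mouse)

        b = allometry.exponent_from_unit("1/day")
        factor = (allometry.MOUSE_MASS_G / allometry.IN_VITRO_MASS_G) ** b
        from stepcal.growth_model import ALLOMETRIC_RATES, _as_dict

        pre = _as_dict(params)
        for name in ALLOMETRIC_RATES:
            pre[name] = pre[name] * factor
        # body mass equal to the reference disables internal rescaling
        scen_ref_mass = Scenario(
            mode="xenograft", horizon_days=15.0, body_mass_g=allometry.IN_VITRO_MASS_G
        )
        manual = simulate(GrowthParams.from_dict(pre), scen_ref_mass)
        assert manual.values("volume_mm3") == pytest.approx(
            internal.values("volume_mm3"), rel=1e-6
        )


class TestIntegratorOracle:
    def test_adaptive_solution_matches_fixed_step_rk4(self):
        """Independent fixed-step RK4 at dt = 1e-3 day agrees to 0.1%."""
        p = GrowthParams(k_div=0.25, k_q=0.6, k_n=0.3, k_lys=0.05, L_p=30.0, L_v=150.0)
        scen = in_vitro(horizon_days=30.0, output_step_days=1.0)
        traj = simulate(p, scen)

        # re-state the in vitro RHS independently of the model module
        cd = CANCER_CELL_DENSITY

        def rhs(y):
            pc, qc, nc = np.maximum(y, 0.0)
            total = pc + qc + nc
            r_um = (3.0 * (total / cd) / (4.0 * math.pi)) ** (1.0 / 3.0) * 1e4
            gq = max(0.0, (r_um - p.L_p) / r_um) ** 3 if r_um > 0 else 0.0
            gn = max(0.0, (r_um - p.L_v) / r_um) ** 3 if r_um > 0 else 0.0
            return np.array(
                [
                    p.k_div * pc - p.k_q * gq * pc,
                    p.k_q * gq * pc - p.k_n * gn * qc,
                    p.k_n * gn * qc - p.k_lys * nc,
                ]
            )

        dt = 1e-3
        y = np.array([traj.values(k)[0] for k in ("nb_pc", "nb_qc", "nb_nc")])
        times = traj.times
        out = [y.copy()]
        t = 0.0
        for target in times[1:]:
            while t < target - dt / 2:
                k1 = rhs(y)
                k2 = rhs(y + dt / 2 * k1)
                k3 = rhs(y + dt / 2 * k2)
                k4 = rhs(y + dt * k3)
                y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                t += dt
            out.append(y.copy())
        rk4 = np.array(out)
        model_total = (
            traj.values("nb_pc") + traj.values("nb_qc") + traj.values("nb_nc")
        )
        assert np.max(np.abs(rk4.sum(axis=1) - model_total) / model_total) < 1e-3
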