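import math

import numpy as np
import pytest
from scipy.constants import Boltzmann as K_B
from scipy.constants import elementary_charge as E_CHARGE
from scipy.constants import epsilon_0 as EPS_0

from molsynapse import pnp
from molsynapse.errors import ConfigurationError, DomainError, SolverError


class TestConfig:
    def test_degenerate_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            pnp.PNPConfig(n_grid=8)

    def test_invalid_eps(self):
        with pytest.raises(ConfigurationError):
            pnp.PNPConfig(eps_r=0.5)

    def test_defaults_match_material_constants(self):
        cfg = pnp.PNPConfig()
        assert cfg.L == pytest.approx(4e-9)
        assert cfg.eps_r == pytest.approx(4.0)
        assert cfg.D_n == pytest.approx(1e-18)
        assert cfg.junction_area == pytest.approx(math.pi * (10e-6) ** 2)


class TestDiffusionSchedule:
    def test_initial_value(self):
        sched = pnp.DiffusionSchedule()
        assert pnp.diffusion_coefficient(0.0, sched) == pytest.approx(1e-17)

    def test_end_of_potentiation_enhancement(self):
        sched = pnp.DiffusionSchedule()
        d = pnp.diffusion_coefficient(sched.t_p - 1e-9, sched)
        # closed form A*exp(a*t_p) ~ 2.996e-16, ~30x and ~B
        assert d == pytest.approx(1e-17 * math.exp(6.8 * 0.5), rel=1e-6)
        assert d / sched.A == pytest.approx(30.0, rel=0.01)
        assert d == pytest.approx(sched.B, rel=0.01)

    def test_zero_rates_step_schedule(self):
        sched = pnp.DiffusionSchedule(a=0.0, b=0.0, c=0.0)
        assert pnp.diffusion_coefficient(0.2, sched) == pytest.approx(sched.A)
        assert pnp.diffusion_coefficient(0.6, sched) == pytest.approx(sched.B)
        assert pnp.diffusion_coefficient(1.4, sched) == pytest.approx(sched.B)

    def test_domain_error(self):
        sched = pnp.DiffusionSchedule()
        with pytest.raises(DomainError):
            pnp.diffusion_coefficient(-0.1, sched)
        with pytest.raises(DomainError):
            pnp.diffusion_coefficient(sched.t_end + 0.1, sched)

    def test_branches_join_continuously(self):
        sched = pnp.DiffusionSchedule()
        t_b = sched.t_p + 0.1 * sched.t_d
        before = pnp.diffusion_coefficient(t_b - 1e-9, sched)
        after = pnp.diffusion_coefficient(t_b + 1e-9, sched)
        assert after == pytest.approx(before, rel=1e-6)

    def test_voltage_scaling_recovers_reference(self):
        sched = pnp.DiffusionSchedule()
        scaled = sched.for_voltage(-1.3)
        assert scaled.a == pytest.approx(sched.a)
        assert scaled.b == pytest.approx(sched.b)

    def test_voltage_scaling_below_threshold_rejected(self):
        with pytest.raises(DomainError):
            pnp.DiffusionSchedule().for_voltage(-0.2)


class TestPoisson:
    def test_laplace_linear_ramp(self):
        cfg = pnp.PNPConfig(n_grid=64)
        zeros = np.zeros(64)
        phi = pnp.solve_poisson(zeros, zeros, (0.0, -1.3), cfg)
        expected = np.linspace(0.0, -1.3, 64)
        assert np.allclose(phi, expected, atol=1e-12)

    def test_uniform_charge_parabola(self):
        # analytic: -phi'' = rho/(eps0 epsr), grounded -> midpoint rho L^2/8eps
        cfg = pnp.PNPConfig(n_grid=256)
        c_n = np.full(256, 1e24)
        phi = pnp.solve_poisson(c_n, np.zeros(256), (0.0, 0.0), cfg)
        x = cfg.x
        pref = E_CHARGE * 1e24 / (EPS_0 * cfg.eps_r)
        analytic = pref * x * (cfg.L - x) / 2.0
        mid = pref * cfg.L**2 / 8.0
        assert np.max(np.abs(phi - analytic)) / mid < 1e-6
        assert phi[128] == pytest.approx(mid, rel=1e-3)

    def test_charge_neutrality_gives_laplace(self):
        cfg = pnp.PNPConfig(n_grid=64)
        c = np.full(64, 3e24)
        phi = pnp.solve_poisson(c, c, (0.0, 0.5), cfg)
        assert np.allclose(phi, np.linspace(0.0, 0.5, 64), atol=1e-12)

    def test_tiny_system_rejected(self):
        cfg = pnp.PNPConfig()
        with pytest.raises(ConfigurationError):
            pnp.solve_poisson(np.zeros(2), np.zeros(2), (0.0, 0.0), cfg)


class TestTransportStep:
    def test_neutral_uniform_equilibrium(self):
        cfg = pnp.PNPConfig(n_grid=48, ion_bc="sealed", C_e0=1e24)
        f = pnp.initial_fields(cfg)
        f.C_n = np.full(48, 1e24)  # exactly neutralizes the electrons
        f.C_e = np.full(48, 1e24)
        f2 = pnp.step_transport(f, 0.0, 0.0, cfg.dt, None, cfg, D_e=1e-17)
        assert np.allclose(f2.C_n, f.C_n, rtol=1e-10)
        assert np.allclose(f2.C_e, f.C_e, rtol=1e-10)

    def test_ion_mass_conserved_sealed(self):
        cfg = pnp.PNPConfig(n_grid=48, ion_bc="sealed")
        f = pnp.initial_fields(cfg)
        f.C_n = 1e24 * np.exp(-(((cfg.x - cfg.L / 2) / (cfg.L / 8)) ** 2))
        m0 = pnp.total_ion_content(f, cfg)
        for _ in range(200):
            f = pnp.step_transport(f, -0.2, 0.0, cfg.dt, None, cfg, D_e=1e-17)
        assert abs(pnp.total_ion_content(f, cfg) - m0) / m0 < 1e-10

    def test_boltzmann_equilibrium_profile(self):
        # frozen linear potential (coupling off), sealed ions -> C ~ exp(-psi)
        cfg = pnp.PNPConfig(n_grid=48, ion_bc="sealed", dt=2e-2, coupling_scale=0.0)
        f = pnp.initial_fields(cfg)
        f.C_n = np.full(48, 1e24)
        for _ in range(1500):
            f = pnp.step_transport(f, -0.2, 0.0, cfg.dt, None, cfg, D_e=1e-17)
        psi = f.phi * E_CHARGE / (K_B * cfg.T)
        expected = np.exp(-psi)
        ref = pnp.PNPFields(f.x, expected, f.C_e, f.phi)
        expected *= pnp.total_ion_content(f, cfg) / pnp.total_ion_content(ref, cfg)
        assert np.max(np.abs(f.C_n - expected) / expected) < 1e-4

    def test_injection_boundary_honoured(self, coarse_pnp_config):
        f = pnp.initial_fields(coarse_pnp_config)
        f = pnp.step_transport(f, -1.3, 0.0, 1e-3, None, coarse_pnp_config, D_e=1e-17)
        assert f.C_n[0] == pytest.approx(coarse_pnp_config.C0)

    def test_outflow_boundary_during_depression(self, coarse_pnp_config):
        f = pnp.initial_fields(coarse_pnp_config)
        f.C_n = np.full(coarse_pnp_config.n_grid, 1e24)
        f = pnp.step_transport(f, 0.1, 0.0, 1e-3, None, coarse_pnp_config, D_e=1e-17)
        assert f.C_n[0] == pytest.approx(0.0, abs=1e10)

    def test_nonconvergence_raises_with_history(self):
        cfg = pnp.PNPConfig(n_grid=48, gummel_maxiter=1, gummel_tol=1e-14)
        f = pnp.initial_fields(cfg)
        with pytest.raises(SolverError) as exc:
            pnp.step_transport(f, -1.3, 0.0, 1e-3, None, cfg, D_e=1e-16)
        assert len(exc.value.residual_history) == 1


class TestJunctionCurrent:
    def test_zero_fields_zero_current(self):
        cfg = pnp.PNPConfig(n_grid=48)
        f = pnp.PNPFields(cfg.x, np.zeros(48), np.full(48, 1e24), np.zeros(48), D_e=1e-17)
        assert pnp.junction_current(f, 0.0, cfg) == pytest.approx(0.0, abs=1e-30)

    def test_ficks_law_oracle(self):
        # pure diffusion on a linear electron profile: |I| = e D dC/dx A
        cfg = pnp.PNPConfig(n_grid=48)
        c_e = np.linspace(2e24, 1e24, 48)
        f = pnp.PNPFields(cfg.x, np.zeros(48), c_e, np.zeros(48), D_e=1e-17)
        expected = E_CHARGE * 1e-17 * (1e24 / cfg.L) * cfg.junction_area
        assert abs(pnp.junction_current(f, 0.0, cfg)) == pytest.approx(expected, rel=1e-9)

    def test_area_linearity(self):
        cfg1 = pnp.PNPConfig(n_grid=48)
        cfg2 = pnp.PNPConfig(n_grid=48, junction_area=2 * cfg1.junction_area)
        c_e = np.linspace(2e24, 1e24, 48)
        f = pnp.PNPFields(cfg1.x, np.zeros(48), c_e, np.zeros(48), D_e=1e-17)
        i1 = pnp.junction_current(f, 0.0, cfg1)
        i2 = pnp.junction_current(f, 0.0, cfg2)
        assert i2 == pytest.approx(2 * i1, rel=1e-12)


class TestSimulate:
    def test_polarity_convention_enforced(self, coarse_pnp_config):
        with pytest.raises(DomainError):
            pnp.simulate_potentiation_depression(
                coarse_pnp_config, pnp.DiffusionSchedule(), V_pot=+1.3
            )

    def test_potentiation_rises_depression_decays(self, coarse_pnp_config):
        pot, dep = pnp.simulate_potentiation_depression(
            coarse_pnp_config, pnp.DiffusionSchedule()
        )
        n_tr = max(2, len(pot) // 10)
        assert np.all(np.diff(pot.current[n_tr:]) >= -1e-9 * abs(pot.current[-1]))
        assert np.all(np.diff(dep.current) <= 1e-9 * dep.current[0])
        assert pot.current[-1] > 5 * pot.current[n_tr]

    def test_metadata_flags_extension(self, coarse_pnp_config):
        pot, dep = pnp.simulate_potentiation_depression(
            coarse_pnp_config, pnp.DiffusionSchedule()
        )
        assert pot.meta["voltage_scaled_schedule"] is True
        assert dep.meta["phase"] == "depression"

    def test_no_injection_flat(self, coarse_pnp_config):
        from dataclasses import replace

        cfg = replace(coarse_pnp_config, injection_enabled=False)
        pot, dep = pnp.simulate_potentiation_depression(cfg, pnp.DiffusionSchedule())
        tail_p = pot.current[len(pot) // 2 :]
        tail_d = dep.current[len(dep) // 2 :]
        assert np.ptp(tail_p) / abs(np.mean(tail_p)) < 1e-3
        assert np.ptp(tail_d) / abs(np.mean(tail_d)) < 1e-3

    def test_zero_potentiation_matches_unpotentiated_baseline(self, coarse_pnp_config):
        _, dep0 = pnp.simulate_potentiation_depression(
            coarse_pnp_config, pnp.DiffusionSchedule(), t_pot=0.0
        )
        from dataclasses import replace

        cfg = replace(coarse_pnp_config, injection_enabled=False)
        _, dep_ctrl = pnp.simulate_potentiation_depression(
            cfg, pnp.DiffusionSchedule(), t_pot=0.0
        )
        # without potentiation, late-time depression current sits at the
        # same baseline scale as the injection-free control
        assert dep0.current[-1] == pytest.approx(dep_ctrl.current[-1], rel=0.3)

    def test_stronger_bias_never_smaller_end_current(self, coarse_pnp_config):
        ends = []
        for v in (-0.8, -1.15, -1.5):
            pot, _ = pnp.simulate_potentiation_depression(
                coarse_pnp_config, pnp.DiffusionSchedule(), V_pot=v
            )
            ends.append(pot.current[-1])
        assert np.all(np.diff(ends) > 0)


class TestGridConvergence:
    def test_refinement_changes_end_current_below_1pct(self):
        base = pnp.PNPConfig(n_grid=128, dt=1e-3)
        fine = pnp.PNPConfig(n_grid=255, dt=5e-4)
        end = []
        for cfg in (base, fine):
            pot, _ = pnp.simulate_potentiation_depression(
                cfg, pnp.DiffusionSchedule(), t_dep=0.1
            )
            end.append(pot.current[-1])
        assert abs(end[1] - end[0]) / end[1] < 0.01


class TestVoltageSweep:
    def test_single_voltage_single_row(self, coarse_pnp_config):
        df = pnp.voltage_sweep_relaxation(coarse_pnp_config, pnp.DiffusionSchedule(), [-1.3])
        assert len(df) == 1
        assert df.fit_ok.all()

    def test_duplicate_voltages_identical(self, coarse_pnp_config):
        df = pnp.voltage_sweep_relaxation(
            coarse_pnp_config, pnp.DiffusionSchedule(), [-1.0, -1.0]
        )
        assert df.tau1.iloc[0] == df.tau1.iloc[1]
        assert df.tau2.iloc[0] == df.tau2.iloc[1]

    def test_positive_voltage_rejected(self, coarse_pnp_config):
        with pytest.raises(DomainError):
            pnp.voltage_sweep_relaxation(coarse_pnp_config, pnp.DiffusionSchedule(), [0.5])

    def test_failures_flagged_per_row(self):
        cfg = pnp.PNPConfig(n_grid=48, gummel_maxiter=1, gummel_tol=1e-14)
        df = pnp.voltage_sweep_relaxation(cfg, pnp.DiffusionSchedule(), [-1.0, -1.2])
        assert len(df) == 2
        assert (~df.fit_ok).all()
        assert df.message.str.contains("SolverError").all()
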