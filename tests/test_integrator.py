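"""Propagator properties: reduction to Verlet, conservation, time
reversibility, symplecticness, implicit-solver residuals, second-order
convergence, the uniform-scaling constraint, and Boltzmann momenta."""

import numpy as np
import pytest

from mtmd.forcefield import DoubleWellBondForceField
from mtmd.integrator import (IntegratorConfig, Stepper, SystemState,
                             boltzmann_momenta, conserved_quantity,
                             project_uniform_scaling, run_md, StabilityError)
from mtmd.kinetics import Kinetics
from mtmd.massmatrix import ConstantMassModel, DiatomicMassModel
from mtmd.topology import build_topology
from mtmd.units import KB, TIME_FS

M_N = 14.007


def _state(n2_pair, model, T=80.0, seed=2):
    rng = np.random.default_rng(seed)
    ps = boltzmann_momenta(n2_pair["topo"], T, model, n2_pair["s"],
                           n2_pair["h"], rng)
    return SystemState(n2_pair["s"].copy(), n2_pair["h"].copy(), ps,
                       np.zeros((3, 3)))


class TestReductionToVerlet:
    def test_constant_mass_fixed_cell_matches_hand_verlet(self, n2_pair):
        cm = ConstantMassModel.physical(n2_pair["topo"])
        cfg = IntegratorConfig(dt_fs=1.0, fix_cell=True, pressure_gpa=0.0)
        st = _state(n2_pair, cm)
        stepper = Stepper(n2_pair["topo"], n2_pair["ff"], cm, cfg)
        nxt = stepper.step(st.copy())

        h, m = n2_pair["h"], n2_pair["topo"].masses[:, None]
        dt = cfg.dt
        Xc = st.s @ h.T
        Vc = (st.ps @ np.linalg.inv(h)) / m

        def force(X):
            return -n2_pair["ff"].cart_energy_grad(X, h)[1]

        Vh = Vc + 0.5 * dt * force(Xc) / m
        X1 = Xc + dt * Vh
        V1 = Vh + 0.5 * dt * force(X1) / m
        np.testing.assert_allclose(nxt.s, X1 @ np.linalg.inv(h).T,
                                   atol=1e-13)
        np.testing.assert_allclose(nxt.ps, (V1 * m) @ h, atol=1e-12)

    def test_free_streaming(self, n2_pair, diatomic_model):
        class NullFF:
            def energy_forces(self, s, h):
                from mtmd.forcefield import EnergyForces
                return EnergyForces(0.0, np.zeros_like(np.atleast_2d(s)),
                                    np.zeros((3, 3)))

        cfg = IntegratorConfig(dt_fs=2.0, fix_cell=True, pressure_gpa=0.0)
        cm = ConstantMassModel.physical(n2_pair["topo"])
        st = _state(n2_pair, cm)
        stepper = Stepper(n2_pair["topo"], NullFF(), cm, cfg)
        kin = stepper.kinetics.evaluate(st.s, st.h)
        v = kin.velocity(st.ps)
        nxt = stepper.step(st.copy())
        np.testing.assert_allclose(nxt.s, st.s + cfg.dt * v, atol=1e-13)
        np.testing.assert_allclose(nxt.ps, st.ps, atol=1e-14)


class TestImplicitSolvers:
    def test_momentum_half_step_satisfies_residual(self, n2_pair,
                                                   diatomic_model):
        from mtmd.integrator import StepStats
        cfg = IntegratorConfig(dt_fs=8.0)
        st = _state(n2_pair, diatomic_model)
        stepper = Stepper(n2_pair["topo"], n2_pair["ff"], diatomic_model, cfg)
        stats = StepStats()
        ps_half, _ = stepper.momentum_half_step(st, stats)
        kin = stepper.kinetics.evaluate(st.s, st.h)
        f_s, _, _ = kin.kinetic_forces(kin.velocity(ps_half))
        ef = n2_pair["ff"].energy_forces(st.s, st.h)
        resid = ps_half - st.ps - 0.5 * cfg.dt * (f_s - ef.dU_ds)
        assert np.abs(resid).max() < 1e-10
        assert stats.fp_iters > 1

    def test_position_step_satisfies_residual(self, n2_pair, diatomic_model):
        from mtmd.integrator import StepStats
        cfg = IntegratorConfig(dt_fs=8.0)
        st = _state(n2_pair, diatomic_model)
        stepper = Stepper(n2_pair["topo"], n2_pair["ff"], diatomic_model, cfg)
        stats = StepStats()
        ps_half, ph_half = stepper.momentum_half_step(st, stats)
        s1, h1, kin1 = stepper.position_full_step(st, ps_half, ph_half, stats)
        kin0 = stepper.kinetics.evaluate(st.s, st.h)
        v0 = kin0.velocity(ps_half)
        v1 = kin1.velocity(ps_half)
        resid = s1 - st.s - 0.5 * cfg.dt * (v0 + v1)
        assert np.abs(resid).max() < 1e-11
        np.testing.assert_allclose(h1, st.h + cfg.dt * ph_half / cfg.W,
                                   atol=1e-14)


class TestConservationAndReversibility:
    def test_conserved_quantity_at_rest_is_potential_plus_pv(self, n2_pair):
        cm = ConstantMassModel.physical(n2_pair["topo"])
        cfg = IntegratorConfig(dt_fs=1.0, pressure_gpa=0.0)
        st = SystemState(n2_pair["s"], n2_pair["h"],
                         np.zeros_like(n2_pair["s"]), np.zeros((3, 3)))
        U = n2_pair["ff"].energy_forces(st.s, st.h).U
        E = conserved_quantity(st, n2_pair["topo"], n2_pair["ff"], cm, cfg)
        assert E == pytest.approx(U, abs=1e-14)

    def test_kinetic_term_matches_cartesian_form(self, n2_pair):
        cm = ConstantMassModel.physical(n2_pair["topo"])
        kin = Kinetics(n2_pair["topo"], cm).evaluate(n2_pair["s"],
                                                     n2_pair["h"])
        rng = np.random.default_rng(0)
        v_cart = rng.normal(size=n2_pair["s"].shape)
        ps = kin.ps_from_cart_velocity(v_cart)
        ke = kin.kinetic_energy(ps)
        expect = 0.5 * float(np.sum(n2_pair["topo"].masses[:, None]
                                    * v_cart ** 2))
        assert ke == pytest.approx(expect, rel=1e-12)

    def test_long_run_conservation_and_c_unity_for_diatomic(self, n2_pair,
                                                            diatomic_model):
        cfg = IntegratorConfig(dt_fs=4.0)
        st = _state(n2_pair, diatomic_model)
        _, traj = run_md(st, n2_pair["topo"], n2_pair["ff"], diatomic_model,
                         cfg, 800)
        E = traj.conserved
        assert E.max() - E.min() < 1e-3          # eV, 4 atoms
        np.testing.assert_allclose(traj.c_factor, 1.0, atol=1e-12)

    def test_time_reversal_recovers_initial_state(self, n2_pair,
                                                  diatomic_model):
        cfg = IntegratorConfig(dt_fs=4.0)
        st = _state(n2_pair, diatomic_model)
        end, _ = run_md(st, n2_pair["topo"], n2_pair["ff"], diatomic_model,
                        cfg, 200)
        rev = SystemState(end.s, end.h, -end.ps, -end.ph)
        back, _ = run_md(rev, n2_pair["topo"], n2_pair["ff"], diatomic_model,
                         cfg, 200)
        np.testing.assert_allclose(back.s, st.s, atol=1e-10)
        np.testing.assert_allclose(back.ps, -st.ps, atol=1e-8)
        np.testing.assert_allclose(back.h, st.h, atol=1e-10)

    def test_divergence_detection_aborts(self, n2_pair, diatomic_model):
        cfg = IntegratorConfig(dt_fs=4.0)
        st = _state(n2_pair, diatomic_model)
        with pytest.raises(StabilityError):
            run_md(st, n2_pair["topo"], n2_pair["ff"], diatomic_model, cfg,
                   500, abort_band=1e-9)


class TestSymplectic:
    def test_jacobian_preserves_canonical_form(self, n2_pair,
                                               diatomic_model):
        # full variable-cell phase space (s, h, ps, ph), no constraint
        cfg = IntegratorConfig(dt_fs=2.0, uniform_scaling=False,
                               pressure_gpa=0.0001)
        st = _state(n2_pair, diatomic_model)
        n_s = st.s.size
        n = n_s + 9

        def pack(state):
            return np.concatenate([state.s.reshape(-1), state.h.reshape(-1),
                                   state.ps.reshape(-1),
                                   state.ph.reshape(-1)])

        def one_step(z):
            stz = SystemState(z[:n_s].reshape(-1, 3),
                              z[n_s:n].reshape(3, 3),
                              z[n:n + n_s].reshape(-1, 3),
                              z[n + n_s:].reshape(3, 3))
            stepper = Stepper(n2_pair["topo"], n2_pair["ff"], diatomic_model,
                              cfg)
            return pack(stepper.step(stz))

        z0 = pack(st)
        eps = 1e-6
        J = np.empty((2 * n, 2 * n))
        for k in range(2 * n):
            zp, zm = z0.copy(), z0.copy()
            zp[k] += eps
            zm[k] -= eps
            J[:, k] = (one_step(zp) - one_step(zm)) / (2 * eps)
        Om = np.block([[np.zeros((n, n)), np.eye(n)],
                       [-np.eye(n), np.zeros((n, n))]])
        assert np.abs(J.T @ Om @ J - Om).max() < 1e-6

    def test_energy_error_scales_as_dt_squared(self, n2_pair,
                                               diatomic_model):
        horizon_fs = 800.0
        bands = []
        dts = [1.0, 2.0, 4.0]
        for dt in dts:
            cfg = IntegratorConfig(dt_fs=dt, fix_cell=True,
                                   pressure_gpa=0.0)
            st = _state(n2_pair, diatomic_model, seed=5)
            _, traj = run_md(st, n2_pair["topo"], n2_pair["ff"],
                             diatomic_model, cfg, int(horizon_fs / dt))
            E = traj.conserved
            bands.append(E.max() - E.min())
        slope = np.polyfit(np.log(dts), np.log(bands), 1)[0]
        assert 1.8 <= slope <= 2.2


class TestUniformScaling:
    def test_projection_identity_on_multiples_of_h(self, rng):
        h = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        np.testing.assert_allclose(project_uniform_scaling(2.7 * h, h),
                                   2.7 * h, atol=1e-12)

    def test_traceless_shear_of_cubic_cell_projects_to_zero(self):
        h = 5.0 * np.eye(3)
        shear = np.array([[0, 1.0, 0], [1.0, 0, 0], [0, 0, 0]])
        np.testing.assert_allclose(project_uniform_scaling(shear, h), 0,
                                   atol=1e-14)

    def test_idempotent(self, rng):
        h = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        x = rng.normal(size=(3, 3))
        p1 = project_uniform_scaling(x, h)
        np.testing.assert_allclose(project_uniform_scaling(p1, h), p1,
                                   atol=1e-13)

    def test_cell_stays_cubic_under_constraint(self, n2_pair,
                                               diatomic_model):
        cfg = IntegratorConfig(dt_fs=4.0, uniform_scaling=True)
        st = _state(n2_pair, diatomic_model, T=120.0)
        end, traj = run_md(st, n2_pair["topo"], n2_pair["ff"],
                           diatomic_model, cfg, 300)
        ratio = end.h / st.h[0, 0]
        np.testing.assert_allclose(ratio, ratio[0, 0] * np.eye(3),
                                   atol=1e-12)
        assert abs(ratio[0, 0] - 1.0) > 1e-8     # the cell did move


class TestBoltzmann:
    def test_zero_temperature_gives_zero_momenta(self, n2_pair,
                                                 diatomic_model):
        ps = boltzmann_momenta(n2_pair["topo"], 0.0, diatomic_model,
                               n2_pair["s"], n2_pair["h"],
                               np.random.default_rng(0))
        np.testing.assert_allclose(ps, 0)

    def test_net_momentum_removed(self, n2_pair, diatomic_model):
        ps = boltzmann_momenta(n2_pair["topo"], 300.0, diatomic_model,
                               n2_pair["s"], n2_pair["h"],
                               np.random.default_rng(3))
        kin = Kinetics(n2_pair["topo"], diatomic_model).evaluate(
            n2_pair["s"], n2_pair["h"])
        p_cart = kin.apply_M(kin.cart_velocity(ps))
        np.testing.assert_allclose(p_cart.sum(axis=0), 0, atol=1e-12)


class TestExplicitVariant:
    def test_coincides_with_symplectic_for_constant_mass(self, n2_pair):
        from mtmd.integrator import ExplicitStepper
        cm = ConstantMassModel.physical(n2_pair["topo"])
        cfg = IntegratorConfig(dt_fs=1.0, fix_cell=True, pressure_gpa=0.0)
        st = _state(n2_pair, cm)
        sym = Stepper(n2_pair["topo"], n2_pair["ff"], cm, cfg).step(st.copy())
        kin = Kinetics(n2_pair["topo"], cm).evaluate(st.s, st.h)
        st_v = SystemState(st.s.copy(), st.h.copy(), kin.velocity(st.ps),
                           np.zeros((3, 3)))
        exp = ExplicitStepper(n2_pair["topo"], n2_pair["ff"], cm,
                              cfg).step(st_v)
        np.testing.assert_allclose(exp.s, sym.s, atol=1e-12)
        kin1 = Kinetics(n2_pair["topo"], cm).evaluate(sym.s, sym.h)
        np.testing.assert_allclose(exp.ps, kin1.velocity(sym.ps), atol=1e-12)


def test_double_well_ensemble_preserved_by_mass_modification():
    """Configurational statistics of a double-well bond are unchanged when
    the vibrational mass is scaled (determinant-constrained mass matrix).

    Sampler: segments of Hamiltonian dynamics with periodic momentum
    redraws from N(0, k_B T M(q)^-1) — a scheme whose stationary
    configurational law is exp(-beta U) exactly when det M is constant, so
    any ensemble distortion by the mass model would shift the bond-length
    histogram.  Tolerances reflect the replica scatter of the sampler at
    this length."""
    import dataclasses
    X = np.array([[0.0, 0, 0], [0, 0, 1.32]]) + 5.0
    topo = build_topology(X, ["N", "N"])
    ff = DoubleWellBondForceField(topo, A=80.0, r0=1.2, d=0.12)
    h = 20.0 * np.eye(3)
    s0 = X @ np.linalg.inv(h).T
    T = 250.0

    def sample(model, seed, dt_fs, time_ps=60.0, seg_ps=0.15):
        cfg = IntegratorConfig(dt_fs=dt_fs, fix_cell=True, pressure_gpa=0.0)
        seg_steps = max(1, int(seg_ps * 1e3 / dt_fs))
        rng = np.random.default_rng(seed)
        st = SystemState(s0.copy(), h.copy(), np.zeros_like(s0),
                         np.zeros((3, 3)))
        rs = []
        for _ in range(int(time_ps / seg_ps)):
            st.ps = boltzmann_momenta(topo, T, model, st.s, st.h, rng,
                                      remove_net_momentum=False)
            st, traj = run_md(st, topo, ff, model, cfg, seg_steps,
                              sample_stride=5)
            X_t = traj.positions()
            rs.append(np.linalg.norm(X_t[1:, 1] - X_t[1:, 0], axis=1))
        return np.concatenate(rs)

    r_md = sample(ConstantMassModel.physical(topo), 1, 1.0)
    r_mtmd = sample(DiatomicMassModel(M_N, M_N, 25 * M_N), 4, 4.0)
    assert abs(r_md.mean() - r_mtmd.mean()) < 0.03
    assert abs((r_md < 1.2).mean() - (r_mtmd < 1.2).mean()) < 0.13
    assert abs(r_md.std() / r_mtmd.std() - 1.0) < 0.10
    for r in (r_md, r_mtmd):                     # both wells well populated
        assert (r < 1.2).mean() > 0.2
        assert (r > 1.2).mean() > 0.2
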