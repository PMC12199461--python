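"""Analysis machinery: spectral peak location, mass-weighted frequencies,
stability scan, RDF, diffusion, transition detection."""

import numpy as np
import pytest

from mtmd.analysis import (MoleculeAxesSpec, diffusion_fit,
                           mass_weighted_frequencies, max_stable_dt,
                           mode_filtered_spectrum, msd, rdf,
                           transition_detector)
from mtmd.analysis.frequencies import dt_rule_fs, generalized_frequencies
from mtmd.analysis.spectra import signal_power_spectrum
from mtmd.integrator import (IntegratorConfig, SystemState, Trajectory,
                             boltzmann_momenta, run_md)
from mtmd.massmatrix import ConstantMassModel, DiatomicMassModel
from mtmd.forcefield import N2ForceField
from mtmd.topology import build_topology
from mtmd.units import TIME_FS

M_N = 14.007
KR = 138.331
R0 = 1.0977

#: analytic harmonic stretch frequency of N2, ps⁻¹
F_N2 = np.sqrt(KR / (M_N / 2)) / (2 * np.pi) * 1e3 / TIME_FS


def _mock_traj(signals_h, dt_fs, topo=None, h=None):
    """Trajectory carrying fabricated positions (diatomic along z)."""
    F = signals_h.shape[-1]
    n_mol = 1
    s = np.zeros((F, 2, 3))
    s[:, 1, 2] = signals_h / 10.0       # bond length via z offset, box 10
    return Trajectory(topo, sample_dt_fs=dt_fs, s=s,
                      h=np.tile(10.0 * np.eye(3), (F, 1, 1)),
                      ps=np.zeros((F, 2, 3)), t_fs=np.arange(F) * dt_fs,
                      conserved=np.zeros(F), c_factor=np.ones(F),
                      temperature=np.zeros(F))


class TestSpectra:
    def test_pure_tone_peak_location(self):
        f0 = 10.0       # ps⁻¹
        dt = 2.0        # fs
        t = np.arange(4096) * dt
        sig = np.cos(2 * np.pi * f0 * 1e-3 * t)
        freq, power = signal_power_spectrum(sig, dt)
        assert freq[np.argmax(power)] == pytest.approx(f0, abs=freq[1])

    @pytest.mark.parametrize("dt_fs", [1.0, 3.0])
    def test_tone_peak_for_any_sampling_interval(self, dt_fs):
        f0 = 21.0
        t = np.arange(2048) * dt_fs
        sig = np.sin(2 * np.pi * f0 * 1e-3 * t + 0.3)
        freq, power = signal_power_spectrum(sig, dt_fs)
        assert freq[np.argmax(power)] == pytest.approx(f0, abs=freq[1])

    def test_isolated_n2_vibrational_peak_matches_harmonic_frequency(self):
        res = self._n2_spectrum(ConstantMassModel)
        assert res == pytest.approx(F_N2, rel=0.02)

    def test_hundredfold_vibrational_mass_shifts_peak_tenfold(self):
        res = self._n2_spectrum("mtmd")
        assert res == pytest.approx(F_N2 / 10.0, rel=0.02)

    @staticmethod
    def _n2_spectrum(kind):
        h = 20.0 * np.eye(3)
        X = np.array([[5.0, 5, 5], [5, 5, 5 + R0 + 0.01]])
        topo = build_topology(X, ["N", "N"])
        ff = N2ForceField(topo, cutoff=5.0)
        model = (DiatomicMassModel(M_N, M_N, 100 * M_N) if kind == "mtmd"
                 else ConstantMassModel.physical(topo))
        s = X @ np.linalg.inv(h).T
        rng = np.random.default_rng(4)
        ps = boltzmann_momenta(topo, 50.0, model, s, h, rng)
        st = SystemState(s, h, ps, np.zeros((3, 3)))
        dt = 1.0 if kind != "mtmd" else 4.0
        cfg = IntegratorConfig(dt_fs=dt, fix_cell=True, pressure_gpa=0.0)
        _, traj = run_md(st, topo, ff, model, cfg, 2048)
        return mode_filtered_spectrum(traj, topo, "vib").peak_frequency

    def test_too_few_frames_rejected(self, n2_pair):
        traj = Trajectory(n2_pair["topo"], 1.0, s=np.zeros((10, 4, 3)),
                          h=np.tile(np.eye(3), (10, 1, 1)),
                          ps=np.zeros((10, 4, 3)), t_fs=np.arange(10.0),
                          conserved=np.zeros(10), c_factor=np.ones(10),
                          temperature=np.zeros(10))
        with pytest.raises(ValueError, match="frames"):
            mode_filtered_spectrum(traj, n2_pair["topo"], "vib")


class TestMassWeightedFrequencies:
    def test_scalar_case(self):
        rep = mass_weighted_frequencies(5.0 * np.eye(6), 2.0 * np.eye(6))
        np.testing.assert_allclose(rep.omega, np.sqrt(2.5), atol=1e-12)
        assert rep.n_imaginary == 0

    def test_mass_proportional_to_hessian_equalizes_frequencies(self, rng):
        A = rng.normal(size=(9, 9))
        H = A @ A.T + 9 * np.eye(9)
        lam = 4.0
        rep = mass_weighted_frequencies(H, H / lam)
        np.testing.assert_allclose(rep.omega, np.sqrt(lam), rtol=1e-10)

    def test_matches_generalized_eigensolver(self, rng):
        A = rng.normal(size=(12, 12))
        H = 0.5 * (A + A.T)
        B = rng.normal(size=(12, 12))
        M = B @ B.T + 12 * np.eye(12)
        rep = mass_weighted_frequencies(H, M)
        ref = generalized_frequencies(H, M)
        np.testing.assert_allclose(np.sort(rep.omega), np.sort(ref),
                                   atol=1e-9)

    def test_negative_modes_counted(self):
        H = np.diag([4.0, -1.0, 2.0])
        rep = mass_weighted_frequencies(H, np.eye(3))
        assert rep.n_imaginary == 1

    def test_dt_rule_is_tenth_of_fastest_period(self):
        assert dt_rule_fs(70.0) == pytest.approx(1e3 / 70.0 / 10.0)


class TestMaxStableDt:
    def test_verlet_bound_on_harmonic_oscillator(self):
        """Isolated N2: stability bound ω·dt < 2 located within one grid
        step (ω is the bond-stretch angular frequency)."""
        h = 20.0 * np.eye(3)
        X = np.array([[5.0, 5, 5], [5, 5, 5 + R0]])
        topo = build_topology(X, ["N", "N"])
        ff = N2ForceField(topo, cutoff=5.0)
        model = ConstantMassModel.physical(topo)
        s = X @ np.linalg.inv(h).T
        omega = np.sqrt(2 * KR / M_N) / TIME_FS     # fs⁻¹
        dt_crit = 2.0 / omega

        def run_fn(dt_fs, n_steps, abort_band):
            rng = np.random.default_rng(9)
            ps = boltzmann_momenta(topo, 50.0, model, s, h, rng)
            st = SystemState(s.copy(), h.copy(), ps, np.zeros((3, 3)))
            cfg = IntegratorConfig(dt_fs=dt_fs, fix_cell=True,
                                   pressure_gpa=0.0)
            _, traj = run_md(st, topo, ff, model, cfg, n_steps,
                             abort_band=abort_band)
            return traj

        grid = list(np.arange(0.25, 1.3 * dt_crit, 0.25))
        res = max_stable_dt(run_fn, grid, 2000, n_atoms=2)
        assert abs(res.max_stable_dt_fs - dt_crit) <= 0.25 + 1e-9

    def test_low_grid_fully_stable(self, n2_pair, diatomic_model):
        def run_fn(dt_fs, n_steps, abort_band):
            st = SystemState(n2_pair["s"].copy(), n2_pair["h"].copy(),
                             boltzmann_momenta(n2_pair["topo"], 60.0,
                                               diatomic_model, n2_pair["s"],
                                               n2_pair["h"],
                                               np.random.default_rng(1)),
                             np.zeros((3, 3)))
            cfg = IntegratorConfig(dt_fs=dt_fs)
            _, traj = run_md(st, n2_pair["topo"], n2_pair["ff"],
                             diatomic_model, cfg, n_steps,
                             abort_band=abort_band)
            return traj

        res = max_stable_dt(run_fn, [1.0, 2.0], 400,
                            n_atoms=n2_pair["topo"].n_atoms)
        assert res.max_stable_dt_fs == 2.0


class TestRdf:
    def _traj_from_positions(self, X, h, frames=1):
        s = X @ np.linalg.inv(h).T
        F = frames
        return Trajectory(None, 1.0, s=np.tile(s, (F, 1, 1)),
                          h=np.tile(h, (F, 1, 1)),
                          ps=np.zeros((F,) + X.shape),
                          t_fs=np.arange(F, dtype=float),
                          conserved=np.zeros(F), c_factor=np.ones(F),
                          temperature=np.zeros(F))

    def test_ideal_gas_is_flat(self, rng):
        h = 12.0 * np.eye(3)
        frames = []
        for _ in range(40):
            frames.append(rng.uniform(0, 12, size=(60, 3)))
        X = np.array(frames)
        traj = Trajectory(None, 1.0, s=X / 12.0,
                          h=np.tile(h, (40, 1, 1)), ps=np.zeros_like(X),
                          t_fs=np.arange(40.0), conserved=np.zeros(40),
                          c_factor=np.ones(40), temperature=np.zeros(40))
        r, g = rdf(traj, n_bins=30)
        assert abs(np.mean(g[5:]) - 1.0) < 0.05

    def test_simple_cubic_first_peak_at_lattice_constant(self):
        a = 3.0
        pts = np.array([(i, j, k) for i in range(4) for j in range(4)
                        for k in range(4)], float) * a
        h = 12.0 * np.eye(3)
        traj = self._traj_from_positions(pts, h)
        r, g = rdf(traj, n_bins=60)
        first = np.flatnonzero(g > 0)[0]
        assert r[first] == pytest.approx(a, abs=r[1] - r[0])

    def test_counting_normalization(self, rng):
        # ∫ g(r) 4πr²ρ dr over r<r_max counts the neighbors inside r_max
        h = 10.0 * np.eye(3)
        X = rng.uniform(0, 10, size=(50, 3))
        traj = self._traj_from_positions(X, h)
        r, g = rdf(traj, n_bins=50, r_max=4.8)
        rho = (50 - 1) / 1000.0       # finite-N pair density
        dr = r[1] - r[0]
        integral = np.sum(g * 4 * np.pi * r ** 2 * rho * dr)
        s = X @ np.linalg.inv(h).T
        iu, ju = np.triu_indices(50, 1)
        ds = s[iu] - s[ju]
        ds -= np.round(ds)
        d = np.linalg.norm(ds @ h.T, axis=1)
        expected = 2.0 * np.sum(d < 4.8) / 50       # neighbors per atom
        assert integral == pytest.approx(expected, rel=0.02)


class TestDiffusion:
    def _brownian_traj(self, D, n_walkers, n_frames, dt_fs, rng):
        # increments with variance 2 D dt per dimension (D in Å²/ps)
        sig = np.sqrt(2 * D * dt_fs * 1e-3)
        steps = rng.normal(scale=sig, size=(n_frames - 1, n_walkers, 3))
        X = np.concatenate([np.zeros((1, n_walkers, 3)),
                            np.cumsum(steps, axis=0)], axis=0)
        h = 1000.0 * np.eye(3)
        return Trajectory(None, dt_fs, s=X / 1000.0,
                          h=np.tile(h, (n_frames, 1, 1)),
                          ps=np.zeros_like(X),
                          t_fs=np.arange(n_frames) * dt_fs,
                          conserved=np.zeros(n_frames),
                          c_factor=np.ones(n_frames),
                          temperature=np.zeros(n_frames))

    def test_brownian_diffusion_recovered(self, rng):
        D = 0.15
        traj = self._brownian_traj(D, 64, 1000, 10.0, rng)
        fit = diffusion_fit(traj)
        assert fit.D == pytest.approx(D, rel=0.10)
        assert not fit.ballistic

    def test_frozen_atoms_give_zero(self):
        traj = self._brownian_traj(0.0, 8, 200, 10.0,
                                   np.random.default_rng(0))
        fit = diffusion_fit(traj)
        assert fit.D == pytest.approx(0.0, abs=1e-12)

    def test_ballistic_motion_flagged(self):
        n = 400
        X = np.zeros((n, 4, 3))
        X[:, :, 0] = np.outer(np.arange(n) * 0.01, np.ones(4))
        traj = Trajectory(None, 10.0, s=X / 1000.0,
                          h=np.tile(1000.0 * np.eye(3), (n, 1, 1)),
                          ps=np.zeros_like(X), t_fs=np.arange(n) * 10.0,
                          conserved=np.zeros(n), c_factor=np.ones(n),
                          temperature=np.zeros(n))
        assert diffusion_fit(traj).ballistic

    def test_msd_matches_direct_computation(self, rng):
        traj = self._brownian_traj(0.2, 5, 60, 5.0, rng)
        lags, m = msd(traj)
        X = traj.positions()
        k = 7
        direct = np.mean([np.sum((X[t + k] - X[t]) ** 2, axis=1).mean()
                          for t in range(60 - k)])
        assert m[k] == pytest.approx(direct, rel=1e-10)


class TestTransitions:
    def _traj(self, angles_deg, kink_deg=None):
        F = len(angles_deg)
        X = np.zeros((F, 8, 3))
        # molecule A along x, fixed
        X[:, 0] = [0, 0, 0]
        X[:, 1] = [1, 0, 0]
        X[:, 2] = [2, 0, 0]
        X[:, 3] = [3, 0, 0]
        th = np.radians(angles_deg)
        # molecule B rotated in the xy plane, offset in z
        base = np.stack([np.cos(th), np.sin(th), np.zeros(F)], axis=1)
        if kink_deg is None:
            kink = np.zeros(F)
        else:
            kink = np.radians(kink_deg)
        X[:, 4] = [0, 0, 3]
        X[:, 5] = X[:, 4] + base
        X[:, 6] = X[:, 5] + base
        kdir = np.stack([np.cos(th + kink), np.sin(th + kink),
                         np.zeros(F)], axis=1)
        X[:, 7] = X[:, 6] + kdir
        h = 50.0 * np.eye(3)
        return Trajectory(None, 1.0, s=X / 50.0, h=np.tile(h, (F, 1, 1)),
                          ps=np.zeros_like(X), t_fs=np.arange(F, dtype=float),
                          conserved=np.zeros(F), c_factor=np.ones(F),
                          temperature=np.zeros(F))

    spec_a = MoleculeAxesSpec(main=([0, 1], [2, 3]))
    spec_b = MoleculeAxesSpec(main=([4, 5], [6, 7]),
                              kink=(([4], [5, 6]), ([6], [7])))

    def test_parallel_axes_give_no_events(self):
        traj = self._traj(np.zeros(600))
        rep = transition_detector(traj, self.spec_a, self.spec_b, window=100)
        assert rep.events == [] and rep.excluded == []

    def test_ramp_crossing_detected_once_near_crossing_frame(self):
        angles = np.concatenate([np.linspace(0, 90, 500),
                                 np.full(200, 90.0)])
        traj = self._traj(angles)
        rep = transition_detector(traj, self.spec_a, self.spec_b, window=100)
        assert len(rep.events) == 1
        frame = rep.events[0][0]
        crossing = int(np.argmax(angles > 80))
        assert abs(frame - crossing) <= 50 + 1     # within window/2

    def test_kinked_molecule_excluded(self):
        angles = np.concatenate([np.linspace(0, 90, 500),
                                 np.full(200, 90.0)])
        traj = self._traj(angles, kink_deg=np.full(700, 35.0))
        rep = transition_detector(traj, self.spec_a, self.spec_b, window=100)
        assert rep.events == []
        assert len(rep.excluded) == 1 and rep.excluded[0][2] == "kink"

    def test_cell_predicate_exclusion(self):
        angles = np.concatenate([np.linspace(0, 90, 500),
                                 np.full(200, 90.0)])
        traj = self._traj(angles)
        rep = transition_detector(traj, self.spec_a, self.spec_b, window=100,
                                  cell_predicate=lambda h: False)
        assert rep.events == []
        assert rep.excluded[0][2] == "cell-shape mismatch"
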