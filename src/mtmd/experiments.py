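"""Study protocols: end-to-end runs that produce the package's headline
numbers (spectral peak shifts and maximum stable time steps of the N₂
benchmark, and the symplectic-vs-explicit drift comparison on the toy
crystal).

Each protocol builds its fixture, runs the dynamics, and measures the
result from scratch; problem sizes default to a 64-molecule box — the
reference density of 512 molecules per (32 Å)³ is preserved by scaling the
box — which is large enough for liquid-state spectra while keeping every
protocol in the minutes range on one core.
"""

from __future__ import annotations

import numpy as np

from .analysis.spectra import mode_filtered_spectrum
from .analysis.stability import ScanResult, max_stable_dt
from .fixtures import build_n2_liquid, build_n2_gas, build_toy_crystal
from .forcefield import N2ForceField
from .integrator import (IntegratorConfig, SystemState, boltzmann_momenta,
                         run_md)
from .massmatrix import (ConstantMassModel, DiatomicMassModel,
                         InternalHessianMassModel)
from .topology import ATOMIC_MASSES

__all__ = ["N2Study", "vibrational_peaks", "stability_scan",
           "drift_comparison"]

M_N = ATOMIC_MASSES["N"]

#: per-mode mass multipliers of the accelerated N₂ study
VIB_FACTOR = 100.0
ROT_FACTOR = 4.0


def _lj_cutoff(box_len: float) -> float:
    return min(10.0, 0.45 * box_len)


class N2Study:
    """A nitrogen box (liquid or gas density) with either standard masses
    or the diatomic mode-mass matrix."""

    def __init__(self, n_molecules: int = 64, phase: str = "liquid",
                 mtmd: bool = False, seed: int = 1):
        self.mtmd = mtmd
        self.model = (DiatomicMassModel(M_N, ROT_FACTOR * M_N,
                                        VIB_FACTOR * M_N)
                      if mtmd else None)
        builder = build_n2_liquid if phase == "liquid" else build_n2_gas
        self.state, self.topo = builder(n_molecules, seed=seed,
                                        mass_model=self.model)
        if self.model is None:
            self.model = ConstantMassModel.physical(self.topo)
        box = float(self.state.h[0, 0])
        self.ff = N2ForceField(self.topo, cutoff=_lj_cutoff(box))

    def config(self, dt_fs: float, seed: int = 0) -> IntegratorConfig:
        # cell mass = total system mass: keeps the breathing mode well
        # below the stability limit at the largest time steps scanned
        return IntegratorConfig(dt_fs=dt_fs,
                                W=float(self.topo.masses.sum()),
                                pressure_gpa=0.0001,
                                uniform_scaling=True, seed=seed)

    def run(self, dt_fs: float, n_steps: int, stride: int = 1,
            equilibration_steps: int = 0, abort_band: float | None = None,
            state: SystemState | None = None):
        return run_md(state or self.state, self.topo, self.ff, self.model,
                      self.config(dt_fs), n_steps, sample_stride=stride,
                      abort_band=abort_band,
                      equilibration_steps=equilibration_steps)


def vibrational_peaks(n_molecules: int = 64, mtmd: bool = False,
                      seed: int = 1, equil_ps: float = 2.0,
                      prod_ps: float = 8.0, dt_fs: float | None = None,
                      sample_fs: float = 2.0):
    """Mode-filtered spectrum peaks of the liquid N₂ fixture.

    Standard masses integrate at 1 fs; the accelerated run (100-fold
    vibrational, 4-fold rotational mass) at 4 fs.  Returns a dict with the
    per-class peak frequencies (ps⁻¹) and the mean production temperature.
    """
    study = N2Study(n_molecules, "liquid", mtmd, seed)
    if dt_fs is None:
        dt_fs = 4.0 if mtmd else 1.0
    stride = max(1, int(round(sample_fs / dt_fs)))
    equil_steps = int(round(equil_ps * 1e3 / dt_fs))
    prod_steps = int(round(prod_ps * 1e3 / dt_fs))
    _, traj = study.run(dt_fs, prod_steps, stride=stride,
                        equilibration_steps=equil_steps)
    out = {"temperature_K": float(np.mean(traj.temperature)),
           "c_max_dev": float(np.max(np.abs(traj.c_factor - 1.0)))}
    for mode in ("trans", "rot", "vib"):
        res = mode_filtered_spectrum(traj, study.topo, mode)
        out[f"{mode}_peak_per_ps"] = res.peak_frequency
    return out


def stability_scan(phase: str = "liquid", mtmd: bool = False,
                   dt_grid=(1.0, 4.0), horizon_steps: int = 5000,
                   n_molecules: int = 64, seed: int = 1,
                   equil_ps: float = 2.0,
                   tol_mev_per_atom: float = 1.0) -> ScanResult:
    """Maximum stable time step of the N₂ fixture under a bounded
    conserved-quantity criterion (see :mod:`mtmd.analysis.stability`).

    The fixture is pre-equilibrated once with a conservative time step so
    that every scanned step starts from the same thermalized state.
    """
    study = N2Study(n_molecules, phase, mtmd, seed)
    dt_equil = 2.0 if not mtmd else 5.0
    state, _ = study.run(dt_equil, int(equil_ps * 1e3 / dt_equil), stride=10**9)

    def run_fn(dt_fs, n_steps, abort_band):
        stride = max(1, n_steps // 2000)
        _, traj = study.run(dt_fs, n_steps, stride=stride,
                            abort_band=abort_band, state=state)
        return traj

    return max_stable_dt(run_fn, dt_grid, horizon_steps,
                         n_atoms=study.topo.n_atoms,
                         tol_mev_per_atom=tol_mev_per_atom)


def drift_comparison(n_steps: int = 20000, seed: int = 3,
                     temperature: float = 40.0, w: float = 0.5,
                     dt_scale: float = 0.5, short_horizon: int = 1000):
    """Symplectic vs explicit integration of the toy molecular crystal
    under the full internal-coordinate mass matrix.

    Both integrators run the same number of steps at half the
    one-tenth-period time step (the non-symplectic drift at the full rule
    step heats this small system out of its basin before the horizon
    ends).  Returns conserved-quantity series and summary bands/drifts
    (eV): the symplectic band is the peak-to-peak excursion after the
    short horizon; the explicit drift is the fitted secular change over
    the completed portion of the run.  The explicit run is
    failure-tolerant: if it leaves the stable regime early, the series up
    to that point is returned (early blow-up is itself drift data).
    """
    from .analysis.frequencies import mass_weighted_frequencies
    from .massmatrix import build_mass_matrix

    state, topo, ff, hess = build_toy_crystal(seed=seed)
    model = InternalHessianMassModel(topo, state.s @ state.h.T, hess, w=w,
                                     base="repartitioned")
    M = build_mass_matrix(state.s @ state.h.T, topo, model,
                          with_derivs=False).M
    rep = mass_weighted_frequencies(hess, M)
    dt_fs = rep.dt_rule * dt_scale

    rng = np.random.default_rng(seed)
    ps = boltzmann_momenta(topo, temperature, model, state.s, state.h, rng)
    st = SystemState(state.s.copy(), state.h.copy(), ps, np.zeros((3, 3)))
    # microcanonical (fixed cell): the cleanest setting for checking
    # long-horizon energy conservation of the two integrators
    cfg = IntegratorConfig(dt_fs=dt_fs, W=20.0, pressure_gpa=0.0,
                           fix_cell=True)
    stride = max(1, n_steps // 4000)
    _, traj_sym = run_md(st, topo, ff, model, cfg, n_steps,
                         sample_stride=stride)

    # explicit variant propagates velocities; convert the initial momenta
    from .integrator import ConvergenceError, StabilityError
    from .kinetics import Kinetics
    kin = Kinetics(topo, model).evaluate(state.s, state.h, with_derivs=False)
    st_e = SystemState(state.s.copy(), state.h.copy(), kin.velocity(ps),
                       np.zeros((3, 3)))
    E_e_parts, t_e_parts = [], []
    n_chunk = max(stride, n_steps // 20)
    done = 0
    completed = True
    while done < n_steps:
        try:
            st_e, tr = run_md(st_e, topo, ff, model, cfg,
                              min(n_chunk, n_steps - done),
                              sample_stride=stride, integrator="explicit")
        except (StabilityError, ConvergenceError, FloatingPointError):
            completed = False
            break
        skip = 1 if done else 0          # drop the duplicated start frame
        E_e_parts.append(tr.conserved[skip:])
        t_e_parts.append(tr.t_fs[skip:])  # state time accumulates over chunks
        done += min(n_chunk, n_steps - done)
    E_e = np.concatenate(E_e_parts)
    t_e = np.concatenate(t_e_parts)

    ks = max(1, short_horizon // stride)
    E_s = traj_sym.conserved
    return {
        "dt_fs": dt_fs,
        "symplectic": E_s,
        "explicit": E_e,
        "t_fs": traj_sym.t_fs,
        "t_fs_explicit": t_e,
        "explicit_completed": completed,
        "band_sym": float(E_s[ks:].max() - E_s[ks:].min()),
        "band_sym_short": float(E_s[:ks].max() - E_s[:ks].min()),
        "band_exp_short": float(E_e[:ks].max() - E_e[:ks].min()),
        "drift_exp": float(np.polyfit(t_e, E_e, 1)[0] * (t_e[-1] - t_e[0])),
        "n_atoms": topo.n_atoms,
    }
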