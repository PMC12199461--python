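"""Variable-cell mass-tensor molecular dynamics propagators.

The dynamical variables are the scaled coordinates ``s`` (fractional,
Cartesian positions ``R = h s``), the cell matrix ``h`` (columns = lattice
vectors), and their conjugate momenta ``p_s`` and ``p_h``.  The Hamiltonian

    H = ½ p_sᵀ G(s,h)⁻¹ p_s + (1/2W) Tr(p_hᵀ p_h) + U(s,h) + P det h

with mass-weighted metric tensor G = (I⊗h)ᵀ M(s,h) (I⊗h) generates NpH
(isobaric–isoenthalpic) dynamics; H itself — the enthalpy — is the
conserved quantity.

The symplectic propagator is the generalized Störmer–Verlet (leapfrog)
scheme: a half kick of the momenta with derivatives at the old positions
(implicit in ``p_s`` because the kinetic term is momentum-quadratic; solved
by fixed-point iteration), a full position/cell drift (implicit in ``s``
because G⁻¹ must be re-evaluated at the new positions; solved by one
fixed-point step followed by Newton–Raphson), and an explicit second half
kick at the advanced positions.  Exactly one force evaluation per step is
required; derivatives at the advanced positions are reused for the next
step's first half kick.  With a constant mass matrix both implicit
equations degenerate to explicit updates and the scheme reduces to
standard Störmer–Verlet.

A second-order explicit (but non-symplectic) variant is provided for
comparison: it integrates the velocities of the Lagrangian equations of
motion with a velocity-Verlet scheme whose velocity-dependent acceleration
is closed with fixed corrector passes.  Over long runs it exhibits a slow
energy drift that the symplectic scheme does not.

All internal arithmetic uses u/Å/eV units (time unit ≈ 10.1805 fs); the
configuration carries femtoseconds and GPa and converts at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import Kinetics, KineticEvaluation
from .units import GPA, KB, TIME_FS

__all__ = ["SystemState", "IntegratorConfig", "ConvergenceError",
           "StabilityError", "Stepper", "ExplicitStepper", "Trajectory",
           "project_uniform_scaling", "conserved_quantity",
           "boltzmann_momenta", "run_md"]


class ConvergenceError(RuntimeError):
    """An implicit solver failed to converge; carries the iterate history."""

    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


class StabilityError(RuntimeError):
    """The integration left the stable regime (non-finite state or
    conserved-quantity excursion beyond the configured band)."""


@dataclass
class SystemState:
    """Dynamical variables of the variable-cell system."""
    s: np.ndarray            # (N, 3) scaled coordinates, kept unwrapped
    h: np.ndarray            # (3, 3) cell matrix, Å
    ps: np.ndarray           # (N, 3) scaled momenta
    ph: np.ndarray           # (3, 3) cell momenta
    t_fs: float = 0.0

    def copy(self) -> "SystemState":
        return SystemState(self.s.copy(), self.h.copy(), self.ps.copy(),
                           self.ph.copy(), self.t_fs)

    def validate(self):
        if np.linalg.det(self.h) <= 0:
            raise ValueError("cell matrix must have positive determinant")
        for a in (self.s, self.h, self.ps, self.ph):
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite state")


@dataclass
class IntegratorConfig:
    dt_fs: float = 1.0
    W: float = 20.0                  # cell mass, u
    pressure_gpa: float = 0.0001
    uniform_scaling: bool = True
    fix_cell: bool = False
    fp_tol: float = 1e-12
    fp_max_iter: int = 30
    newton_tol: float = 1e-12
    newton_max_iter: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.dt_fs <= 0 or self.W <= 0:
            raise ValueError("dt and W must be positive")
        if self.fp_tol <= 0 or self.newton_tol <= 0:
            raise ValueError("tolerances must be positive")

    @property
    def dt(self) -> float:
        return self.dt_fs / TIME_FS

    @property
    def pressure(self) -> float:
        return self.pressure_gpa * GPA


def project_uniform_scaling(increment: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Orthogonal (Frobenius) projection of a cell-momentum increment onto
    the one-dimensional subspace of uniform cell scalings, span{h}."""
    coeff = np.sum(increment * h) / np.sum(h * h)
    return coeff * h


@dataclass
class StepStats:
    fp_iters: int = 0
    newton_iters: int = 0


def _cell_force(ef_dU_dh, f_h_kin, h, P):
    det = np.linalg.det(h)
    return f_h_kin - ef_dU_dh - P * det * np.linalg.inv(h).T


class Stepper:
    """Symplectic generalized-leapfrog propagator."""

    def __init__(self, topo, forcefield, mass_model, cfg: IntegratorConfig):
        self.topo = topo
        self.ff = forcefield
        self.cfg = cfg
        self.kinetics = Kinetics(topo, mass_model)
        self._kin = None     # KineticEvaluation at current positions
        self._ef = None      # forces at current positions
        self.stats_log: list[StepStats] = []

    # -- cached evaluations ------------------------------------------------
    def _ensure_cache(self, state: SystemState):
        if self._kin is None or not (np.array_equal(self._kin.s, state.s)
                                     and np.array_equal(self._kin.h, state.h)):
            self._kin = self.kinetics.evaluate(state.s, state.h)
            self._ef = self.ff.energy_forces(state.s, state.h)

    def momentum_half_step(self, state: SystemState, stats: StepStats):
        """First half kick (implicit in p_s; explicit cell part)."""
        cfg = self.cfg
        dt = cfg.dt
        self._ensure_cache(state)
        kin, ef = self._kin, self._ef
        f_pot = -ef.dU_ds
        ps = state.ps
        if self.kinetics.constant:
            ps_half = ps + 0.5 * dt * f_pot
            stats.fp_iters += 1
        else:
            scale = max(1.0, float(np.max(np.abs(ps))))
            tol = cfg.fp_tol * scale
            ps_half = ps.copy()
            history = []
            converged = False
            for it in range(cfg.fp_max_iter):
                v = kin.velocity(ps_half)
                f_s, _, _ = kin.kinetic_forces(v)
                ps_new = ps + 0.5 * dt * (f_s + f_pot)
                delta = float(np.max(np.abs(ps_new - ps_half)))
                history.append(delta)
                ps_half = ps_new
                stats.fp_iters += 1
                if delta < tol:
                    converged = True
                    break
                # divergence: hand over to Newton, which solves the same
                # implicit equation wherever a solution exists
                if it >= 2 and history[-1] > history[-2] > history[-3]:
                    break
            if not converged:
                # restart from p^(n): Newton must track the physical root,
                # not the runaway fixed-point iterate
                ps_half = ps.copy()
                for it in range(cfg.newton_max_iter):
                    v = kin.velocity(ps_half)
                    f_s, _, _ = kin.kinetic_forces(v)
                    r = ps_half - ps - 0.5 * dt * (f_s + f_pot)
                    if float(np.max(np.abs(r))) < tol:
                        converged = True
                        break
                    try:
                        delta = kin.solve_momentum_jacobian(-r, v, dt)
                    except np.linalg.LinAlgError:
                        break
                    ps_half = ps_half + delta
                    stats.fp_iters += 1
            if not converged:
                raise ConvergenceError(
                    f"momentum half-step solvers did not converge (dt = "
                    f"{cfg.dt_fs} fs)", history)
        # cell momentum half kick, explicit given ps_half
        if cfg.fix_cell:
            ph_half = np.zeros((3, 3))
        else:
            v = kin.velocity(ps_half)
            _, f_h, _ = kin.kinetic_forces(v)
            incr = 0.5 * dt * _cell_force(ef.dU_dh, f_h, state.h, cfg.pressure)
            if cfg.uniform_scaling:
                incr = project_uniform_scaling(incr, state.h)
            ph_half = state.ph + incr
        return ps_half, ph_half

    def position_full_step(self, state: SystemState, ps_half, ph_half,
                           stats: StepStats):
        """Full drift: h explicitly, s implicitly (fixed point + Newton)."""
        cfg = self.cfg
        dt = cfg.dt
        h1 = state.h if cfg.fix_cell else state.h + dt * ph_half / cfg.W
        kin0 = self._kin
        v0 = kin0.velocity(ps_half)
        s1 = state.s + dt * v0                       # explicit predictor
        if self.kinetics.constant and cfg.fix_cell:
            kin1 = kin0
            return state.s + dt * kin1.velocity(ps_half), h1, kin1
        # one fixed-point step, then Newton–Raphson on the residual
        kin1 = self.kinetics.evaluate(s1, h1)
        s1 = state.s + 0.5 * dt * (v0 + kin1.velocity(ps_half))
        stats.newton_iters += 1
        for it in range(cfg.newton_max_iter):
            kin1 = self.kinetics.evaluate(s1, h1)
            v1 = kin1.velocity(ps_half)
            r = s1 - state.s - 0.5 * dt * (v0 + v1)
            if float(np.max(np.abs(r))) < cfg.newton_tol:
                return s1, h1, kin1
            try:
                delta = kin1.solve_position_jacobian(-r, v1, dt)
            except np.linalg.LinAlgError:
                delta = -0.5 * r                      # damped fixed point
            s1 = s1 + delta
            stats.newton_iters += 1
        raise ConvergenceError(
            f"position update did not converge in {cfg.newton_max_iter} "
            f"Newton iterations (dt = {cfg.dt_fs} fs); try a smaller time step")

    def momentum_final_half_step(self, state_new_h, kin1: KineticEvaluation,
                                 ef1, ps_half, ph_half):
        """Second half kick, explicit at the advanced positions."""
        cfg = self.cfg
        dt = cfg.dt
        v1 = kin1.velocity(ps_half)
        f_s, f_h, _ = kin1.kinetic_forces(v1)
        ps1 = ps_half + 0.5 * dt * (f_s - ef1.dU_ds)
        if cfg.fix_cell:
            ph1 = np.zeros((3, 3))
        else:
            incr = 0.5 * dt * _cell_force(ef1.dU_dh, f_h, state_new_h,
                                          cfg.pressure)
            if cfg.uniform_scaling:
                incr = project_uniform_scaling(incr, state_new_h)
            ph1 = ph_half + incr
        return ps1, ph1

    def step(self, state: SystemState) -> SystemState:
        stats = StepStats()
        ps_half, ph_half = self.momentum_half_step(state, stats)
        s1, h1, kin1 = self.position_full_step(state, ps_half, ph_half, stats)
        ef1 = self.ff.energy_forces(s1, h1)
        ps1, ph1 = self.momentum_final_half_step(h1, kin1, ef1, ps_half,
                                                 ph_half)
        self._kin, self._ef = kin1, ef1              # reuse next step
        self.stats_log.append(stats)
        return SystemState(s1, h1, ps1, ph1, state.t_fs + self.cfg.dt_fs)

    def conserved(self, state: SystemState) -> float:
        self._ensure_cache(state)
        ke = self._kin.kinetic_energy(state.ps)
        cell_ke = float(np.sum(state.ph * state.ph)) / (2.0 * self.cfg.W)
        pv = self.cfg.pressure * np.linalg.det(state.h)
        return ke + cell_ke + self._ef.U + pv

    @property
    def c_factor(self) -> float:
        return self._kin.c if self._kin is not None else 1.0


def conserved_quantity(state: SystemState, topo, forcefield, mass_model,
                       cfg: IntegratorConfig) -> float:
    """Enthalpy-like conserved quantity of the NpH dynamics (eV)."""
    kin = Kinetics(topo, mass_model).evaluate(state.s, state.h,
                                              with_derivs=False)
    ke = kin.kinetic_energy(state.ps)
    cell_ke = float(np.sum(state.ph * state.ph)) / (2.0 * cfg.W)
    U = forcefield.energy_forces(state.s, state.h).U
    return ke + cell_ke + U + cfg.pressure * np.linalg.det(state.h)


def boltzmann_momenta(topo, temperature, mass_model, s, h, rng,
                      remove_net_momentum=True):
    """Scaled momenta p_s drawn from the Boltzmann distribution consistent
    with the (position-dependent) mass matrix: Cartesian velocities from
    N(0, k_B T M⁻¹), then p_s = hᵀ M v."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    kin = Kinetics(topo, mass_model).evaluate(s, h, with_derivs=False)
    v = kin.sample_cart_velocities(temperature, rng)
    if remove_net_momentum and temperature > 0:
        v = kin.remove_net_momentum(v)
    return kin.ps_from_cart_velocity(v)


class ExplicitStepper:
    """Second-order explicit, non-symplectic variant: velocity Verlet on
    the Lagrangian equations of motion, with the velocity-dependent part of
    the acceleration closed by a fixed corrector pass.  State momenta
    are interpreted as velocities (ṡ, ḣ)."""

    N_CORRECTOR = 1

    def __init__(self, topo, forcefield, mass_model, cfg: IntegratorConfig):
        self.topo = topo
        self.ff = forcefield
        self.cfg = cfg
        self.kinetics = Kinetics(topo, mass_model)
        self._accel = None
        self.stats_log: list[StepStats] = []

    def _acceleration(self, kin: KineticEvaluation, ef, v, vh):
        cfg = self.cfg
        f_s, f_h, _ = kin.kinetic_forces(v)
        rhs = f_s - ef.dU_ds - kin.G_dot_apply(v, v, vh)
        a_s = kin.velocity(rhs)                      # G⁻¹ · rhs
        if cfg.fix_cell:
            a_h = np.zeros((3, 3))
        else:
            a_h = _cell_force(ef.dU_dh, f_h, kin.h, cfg.pressure) / cfg.W
            if cfg.uniform_scaling:
                a_h = project_uniform_scaling(a_h, kin.h)
        return a_s, a_h

    def step(self, state: SystemState) -> SystemState:
        cfg = self.cfg
        dt = cfg.dt
        v, vh = state.ps, state.ph                  # velocities here
        if self._accel is None:
            kin = self.kinetics.evaluate(state.s, state.h)
            ef = self.ff.energy_forces(state.s, state.h)
            self._accel = self._acceleration(kin, ef, v, vh)
        a_s, a_h = self._accel
        v_half = v + 0.5 * dt * a_s
        vh_half = np.zeros((3, 3)) if cfg.fix_cell else vh + 0.5 * dt * a_h
        s1 = state.s + dt * v_half
        h1 = state.h if cfg.fix_cell else state.h + dt * vh_half
        kin1 = self.kinetics.evaluate(s1, h1)
        ef1 = self.ff.energy_forces(s1, h1)
        v1, vh1 = v_half, vh_half
        for _ in range(self.N_CORRECTOR):
            a1 = self._acceleration(kin1, ef1, v1, vh1)
            v1 = v_half + 0.5 * dt * a1[0]
            vh1 = np.zeros((3, 3)) if cfg.fix_cell else vh_half + 0.5 * dt * a1[1]
        self._accel = self._acceleration(kin1, ef1, v1, vh1)
        self.stats_log.append(StepStats())
        return SystemState(s1, h1, v1, vh1, state.t_fs + cfg.dt_fs)

    def conserved(self, state: SystemState) -> float:
        kin = self.kinetics.evaluate(state.s, state.h, with_derivs=False)
        y = kin.apply_M(state.ps @ state.h.T)
        ke = 0.5 * float(np.sum((state.ps @ state.h.T) * y))
        cell_ke = 0.5 * self.cfg.W * float(np.sum(state.ph * state.ph))
        U = self.ff.energy_forces(state.s, state.h).U
        return ke + cell_ke + U + self.cfg.pressure * np.linalg.det(state.h)

    @property
    def c_factor(self) -> float:
        return 1.0


@dataclass
class Trajectory:
    """Recorded frames of a run (scaled coordinates kept unwrapped)."""
    topo: object
    sample_dt_fs: float
    s: np.ndarray = None          # (F, N, 3)
    h: np.ndarray = None          # (F, 3, 3)
    ps: np.ndarray = None         # (F, N, 3)
    t_fs: np.ndarray = None       # (F,)
    conserved: np.ndarray = None  # (F,) eV
    c_factor: np.ndarray = None   # (F,)
    temperature: np.ndarray = None  # (F,) K
    stats: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.t_fs)

    def positions(self) -> np.ndarray:
        """Unwrapped Cartesian positions (F, N, 3)."""
        return np.einsum("fij,fnj->fni", self.h, self.s)


def run_md(state: SystemState, topo, forcefield, mass_model,
           cfg: IntegratorConfig, n_steps: int, sample_stride: int = 1,
           integrator: str = "symplectic", abort_band: float | None = None,
           equilibration_steps: int = 0) -> tuple[SystemState, Trajectory]:
    """Propagate ``n_steps`` and record every ``sample_stride``-th frame.

    ``abort_band``: optional conserved-quantity excursion (eV, relative to
    the value at the start of sampling) beyond which a
    :class:`StabilityError` is raised — the detector used by the
    maximum-stable-time-step scan.
    """
    state = state.copy()
    state.validate()
    cls = {"symplectic": Stepper, "explicit": ExplicitStepper}[integrator]
    stepper = cls(topo, forcefield, mass_model, cfg)
    for _ in range(equilibration_steps):
        state = stepper.step(state)
    frames = {k: [] for k in ("s", "h", "ps", "t", "E", "c", "T")}
    n_dof = 3 * topo.n_atoms
    E0 = None

    def record(st):
        E = stepper.conserved(st)
        kin = (stepper._kin if isinstance(stepper, Stepper)
               else stepper.kinetics.evaluate(st.s, st.h, with_derivs=False))
        ke = (kin.kinetic_energy(st.ps) if isinstance(stepper, Stepper)
              else 0.5 * float(np.sum((st.ps @ st.h.T)
                                      * kin.apply_M(st.ps @ st.h.T))))
        frames["s"].append(st.s.copy())
        frames["h"].append(st.h.copy())
        frames["ps"].append(st.ps.copy())
        frames["t"].append(st.t_fs)
        frames["E"].append(E)
        frames["c"].append(stepper.c_factor if isinstance(stepper, Stepper)
                           else kin.c)
        frames["T"].append(2.0 * ke / (n_dof * KB))
        return E

    E0 = record(state)
    for i in range(1, n_steps + 1):
        state = stepper.step(state)
        if not (np.all(np.isfinite(state.s)) and np.all(np.isfinite(state.ps))
                and np.all(np.isfinite(state.h))):
            raise StabilityError(f"non-finite state at step {i}")
        if i % sample_stride == 0:
            E = record(state)
            if abort_band is not None and abs(E - E0) > abort_band:
                raise StabilityError(
                    f"conserved quantity left the ±{abort_band:.3g} eV band "
                    f"at step {i}")
    traj = Trajectory(
        topo, sample_dt_fs=cfg.dt_fs * sample_stride,
        s=np.array(frames["s"]), h=np.array(frames["h"]),
        ps=np.array(frames["ps"]), t_fs=np.array(frames["t"]),
        conserved=np.array(frames["E"]), c_factor=np.array(frames["c"]),
        temperature=np.array(frames["T"]), stats=stepper.stats_log)
    return state, traj
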