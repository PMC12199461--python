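"""Synthetic system builders.

These generators define the study conditions of the validation suite:

* :func:`build_n2_liquid` — N₂ molecules in a periodic cubic box at the
  density of 512 molecules per (32 Å)³ (approximately the experimental
  density of liquid nitrogen); molecules on a jittered lattice with random
  orientations and Boltzmann velocities.
* :func:`build_n2_gas` — the same at gas density (512 molecules per
  (480 Å)³) and high temperature.
* :func:`build_toy_crystal` — a periodic "crystal" of small chain
  molecules (H–O–O–H-like: two heavy centers with light terminal atoms)
  with harmonic bonds/angles and intermolecular Lennard-Jones, relaxed to
  a local minimum and bundled with its finite-difference Hessian.  The
  molecules carry bonds, angles and one dihedral each, so the full
  redundant internal-coordinate machinery is exercised.

Builds are deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from .forcefield import (N2ForceField, N2Params, ToyPolyParams,
                         ToyPolyForceField, fd_hessian)
from .integrator import SystemState, boltzmann_momenta
from .massmatrix import ConstantMassModel
from .topology import build_topology

__all__ = ["build_n2_liquid", "build_n2_gas", "build_toy_crystal",
           "N2_LIQUID_BOX", "N2_GAS_BOX", "PackingError"]

#: reference geometry: 512 molecules per box of this side length (Å)
N2_LIQUID_BOX = 32.0
N2_GAS_BOX = 480.0

_N2_BOND = N2Params().r0


class PackingError(RuntimeError):
    pass


def _n2_box(n_molecules, box_len, temperature, seed, mass_model,
            reference_box, min_dist=2.0):
    rng = np.random.default_rng(seed)
    if box_len is None:
        # keep the reference number density
        box_len = reference_box * (n_molecules / 512.0) ** (1.0 / 3.0)
    g = int(np.ceil(n_molecules ** (1.0 / 3.0)))
    spacing = box_len / g
    sites = np.array([(i, j, k) for i in range(g) for j in range(g)
                      for k in range(g)][:n_molecules], float)
    centers = (sites + 0.5) * spacing
    centers += rng.uniform(-0.05, 0.05, centers.shape) * spacing
    # random orientations, uniform on the sphere
    u = rng.standard_normal((n_molecules, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pos = np.empty((2 * n_molecules, 3))
    pos[0::2] = centers - 0.5 * _N2_BOND * u
    pos[1::2] = centers + 0.5 * _N2_BOND * u
    h = box_len * np.eye(3)

    topo = build_topology(pos, ["N"] * (2 * n_molecules), cell=h,
                          include_angles=False, include_dihedrals=False)
    if len(topo.bonds) != n_molecules or topo.n_molecules != n_molecules:
        raise PackingError("bond detection did not yield isolated diatomics")
    # minimum intermolecular contact
    mid = topo.molecule_ids
    iu, ju = np.triu_indices(len(pos), k=1)
    mask = mid[iu] != mid[ju]
    d = pos[iu[mask]] - pos[ju[mask]]
    ds = d @ np.linalg.inv(h).T
    ds -= np.round(ds)
    dmin = float(np.linalg.norm(ds @ h.T, axis=1).min())
    if dmin < min_dist:
        raise PackingError(
            f"intermolecular contact {dmin:.2f} Å below {min_dist} Å")

    s = pos @ np.linalg.inv(h).T
    if mass_model is None:
        mass_model = ConstantMassModel.physical(topo)
    ps = boltzmann_momenta(topo, temperature, mass_model, s, h, rng)
    state = SystemState(s, h, ps, np.zeros((3, 3)))
    return state, topo


def build_n2_liquid(n_molecules: int = 512, box_len: float | None = None,
                    temperature: float = 180.0, seed: int = 0,
                    mass_model=None):
    """Liquid-density N₂ box.  With the default ``box_len=None`` the box is
    scaled to keep 512 molecules per (32 Å)³.  The default initial
    temperature of 180 K virializes to roughly 90 K (half of the kinetic
    energy is converted to potential energy as the lattice melts)."""
    return _n2_box(n_molecules, box_len, temperature, seed, mass_model,
                   N2_LIQUID_BOX)


def build_n2_gas(n_molecules: int = 512, box_len: float | None = None,
                 temperature: float = 1750.0, seed: int = 0,
                 mass_model=None):
    """Gas-density N₂ box (512 molecules per (480 Å)³), ~1500 K after
    equipartition with the vibrational potential."""
    return _n2_box(n_molecules, box_len, temperature, seed, mass_model,
                   N2_GAS_BOX)


#: template molecule: H-O-O-H-like chain with a gauche dihedral (Å)
_TOY_TEMPLATE = np.array([
    [-1.25, 0.85, 0.10],
    [-0.70, 0.00, 0.00],
    [0.70, 0.00, 0.00],
    [1.25, 0.60, -0.65],
])
_TOY_ELEMENTS = ["H", "O", "O", "H"]


def default_toy_params() -> ToyPolyParams:
    """Stiffnesses of the toy molecular crystal.

    The scales are chosen so the internal-coordinate frequency ladder is
    well separated — bond stretches fastest, then angle bends, then the
    torsion, then the intermolecular modes — which makes the frequency
    reduction of each successively larger internal-coordinate set of the
    mass model visible."""
    return ToyPolyParams(k_b=[45.0, 50.0, 45.0], b0=[1.0, 1.4, 1.0],
                         k_a=[14.0, 14.0], a0=[1.75, 1.75],
                         k_d=[6.0], d0=[1.4],
                         eps=0.06, rm=3.0, cutoff=3.2)


def build_toy_crystal(n_molecules: int = 2, params: ToyPolyParams | None = None,
                      seed: int = 0, box_len: float = 8.0,
                      gtol: float = 1e-6, hessian_step: float = 1e-3):
    """Periodic toy molecular crystal, relaxed to a local minimum at a
    fixed deterministic cell.

    Returns ``(state, topo, forcefield, hessian)`` where ``hessian`` is
    the finite-difference Cartesian Hessian at the minimum (needed by the
    internal-coordinate mass model; the relaxation makes the K-matrix
    neglect in the Hessian transform exact).  Momenta are zero; draw them
    with :func:`mtmd.integrator.boltzmann_momenta`.
    """
    if params is None:
        params = default_toy_params()
    # molecules stacked along z with alternating 180° orientation; the
    # stack spacing puts nearest intermolecular contacts near the
    # Lennard-Jones minimum, so the crystal is cohesive at unit cell scale
    spacing = 3.6
    h = np.diag([box_len, box_len, spacing * n_molecules])
    flip = np.diag([-1.0, -1.0, 1.0])
    pos = []
    elements = []
    for k in range(n_molecules):
        center = np.array([0.5 * box_len, 0.5 * box_len, (k + 0.5) * spacing])
        Rm = flip if k % 2 else np.eye(3)
        pos.append(_TOY_TEMPLATE @ Rm.T + center)
        elements += _TOY_ELEMENTS
    pos = np.concatenate(pos, axis=0)
    nb = len(params.k_b) if np.ndim(params.k_b) else None
    topo = build_topology(pos, elements, cell=h)
    params = ToyPolyParams(
        k_b=np.tile(np.atleast_1d(params.k_b), n_molecules)
        if nb else params.k_b,
        b0=np.tile(np.atleast_1d(params.b0), n_molecules)
        if np.ndim(params.b0) else params.b0,
        k_a=np.tile(np.atleast_1d(params.k_a), n_molecules)
        if np.ndim(params.k_a) else params.k_a,
        a0=np.tile(np.atleast_1d(params.a0), n_molecules)
        if np.ndim(params.a0) else params.a0,
        k_d=np.tile(np.atleast_1d(params.k_d), n_molecules)
        if np.ndim(params.k_d) else params.k_d,
        d0=np.tile(np.atleast_1d(params.d0), n_molecules)
        if np.ndim(params.d0) else params.d0,
        eps=params.eps, rm=params.rm, cutoff=params.cutoff)
    ff = ToyPolyForceField(topo, params)

    res = minimize(lambda x: ff.cart_energy_grad(x.reshape(-1, 3), h),
                   pos.reshape(-1), jac=True, method="L-BFGS-B",
                   options=dict(gtol=1e-12, ftol=1e-18, maxiter=5000))
    X0 = res.x.reshape(-1, 3)
    gnorm = float(np.max(np.abs(ff.cart_energy_grad(X0, h)[1])))
    if gnorm > gtol:
        raise RuntimeError(f"relaxation stalled at |g|={gnorm:.2e} eV/Å")
    hess = fd_hessian(X0, lambda X: ff.cart_energy(X, h), step=hessian_step)
    s = X0 @ np.linalg.inv(h).T
    state = SystemState(s, h, np.zeros_like(s), np.zeros((3, 3)))
    return state, topo, ff, hess
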