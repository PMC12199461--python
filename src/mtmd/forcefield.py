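"""Classical force fields with analytic derivatives w.r.t. scaled
coordinates and the cell matrix.

Provided force fields:

* :class:`N2ForceField` — rigid-cell-agnostic diatomic nitrogen model:
  harmonic bonds plus a 12-6 Lennard-Jones term over all intermolecular
  atom pairs, ``U = Σ ½K_r(r−r0)² + Σ ϵ[(r_m/r)¹² − 2(r_m/r)⁶]``.
* :class:`ToyPolyForceField` — harmonic bonds and angles (intramolecular)
  plus intermolecular Lennard-Jones; a desk-scale polyatomic surrogate.
* :class:`DoubleWellBondForceField` — bonds with a symmetric quartic
  double well, used for ensemble-consistency validation.

All positions are handled as scaled (fractional) coordinates ``s`` with
Cartesian positions ``R = h s``; the Lennard-Jones terms use the minimum
image convention in fractional space (valid for near-orthorhombic cells)
and are shifted to zero at the cutoff.  Bonded terms use direct (unwrapped)
differences — molecules are assumed whole in ``s`` space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .topology import Topology

__all__ = ["N2Params", "ToyPolyParams", "EnergyForces", "N2ForceField",
           "ToyPolyForceField", "DoubleWellBondForceField", "fd_hessian",
           "cell_gradient", "MinimumImageError"]


class MinimumImageError(ValueError):
    """Cutoff exceeds half the smallest cell width."""


@dataclass
class N2Params:
    """The four-parameter N₂ force field (Wang et al. parametrization)."""
    r0: float = 1.0977        # equilibrium bond length, Å
    Kr: float = 138.331       # bond spring constant, eV/Å²
    eps: float = 0.003456     # Lennard-Jones well depth, eV
    rm: float = 3.614         # Lennard-Jones minimum distance, Å

    def __post_init__(self):
        if min(self.r0, self.Kr, self.eps, self.rm) <= 0:
            raise ValueError("N2 parameters must be strictly positive")


@dataclass
class ToyPolyParams:
    """Harmonic bonds/angles, optional cosine torsions, and intermolecular
    Lennard-Jones."""
    k_b: object = 20.0        # eV/Å², scalar or per-bond array
    b0: object = 1.0          # Å
    k_a: object = 3.0         # eV/rad², scalar or per-angle array
    a0: object = 1.9          # rad
    k_d: object = 0.0         # eV, scalar or per-dihedral; U = k_d(1−cos Δφ)
    d0: object = 0.0          # rad
    eps: float = 0.005        # eV
    rm: float = 3.2           # Å
    cutoff: float = 5.5       # Å


@dataclass
class EnergyForces:
    U: float
    dU_ds: np.ndarray   # (N, 3)
    dU_dh: np.ndarray   # (3, 3)


def _cell_widths(h: np.ndarray) -> np.ndarray:
    """Distances between opposite cell faces."""
    a = h.T  # rows = lattice vectors
    vol = abs(np.linalg.det(h))
    cross = np.array([np.cross(a[1], a[2]), np.cross(a[2], a[0]),
                      np.cross(a[0], a[1])])
    return vol / np.linalg.norm(cross, axis=1)


def _check_cutoff(cutoff, h):
    if cutoff >= 0.5 * _cell_widths(h).min():
        raise MinimumImageError(
            f"cutoff {cutoff} Å violates the minimum-image convention for "
            f"cell widths {_cell_widths(h)}")


class _PairLJ:
    """Shifted 12-6 Lennard-Jones over a fixed intermolecular pair list."""

    def __init__(self, topo: Topology, eps, rm, cutoff):
        n = topo.n_atoms
        iu, ju = np.triu_indices(n, k=1)
        inter = topo.molecule_ids[iu] != topo.molecule_ids[ju]
        self.iu, self.ju = iu[inter], ju[inter]
        self.eps, self.rm, self.cutoff = eps, rm, cutoff
        self.u_shift = eps * ((rm / cutoff) ** 12 - 2 * (rm / cutoff) ** 6)

    def accumulate(self, s, h, dU_ds, dU_dh):
        if len(self.iu) == 0:
            return 0.0
        _check_cutoff(self.cutoff, h)
        ds = s[self.iu] - s[self.ju]
        ds -= np.round(ds)
        dR = ds @ h.T
        r2 = np.einsum("pa,pa->p", dR, dR)
        mask = r2 < self.cutoff ** 2
        if not np.any(mask):
            return 0.0
        ds, dR, r2 = ds[mask], dR[mask], r2[mask]
        iu, ju = self.iu[mask], self.ju[mask]
        inv2 = (self.rm ** 2) / r2
        a6 = inv2 ** 3
        U = float(np.sum(self.eps * (a6 * a6 - 2 * a6) - self.u_shift))
        # dU/dr² = eps*(12 a¹²/r² *(-1) ... ) derivative wrt r2:
        dU_dr2 = self.eps * (-6.0 * a6 * a6 + 6.0 * a6) / r2
        gR = (2.0 * dU_dr2)[:, None] * dR        # ∂U/∂(ΔR)
        gs = gR @ h                              # ∂U/∂(Δs)
        np.add.at(dU_ds, iu, gs)
        np.add.at(dU_ds, ju, -gs)
        dU_dh += np.einsum("pa,pb->ab", gR, ds)
        return U


class _BondTerm:
    """Harmonic (or user-supplied scalar) bond energies over direct
    differences."""

    def __init__(self, bonds, k, r0):
        self.bonds = np.asarray(bonds, int).reshape(-1, 2)
        nb = len(self.bonds)
        self.k = np.broadcast_to(np.asarray(k, float), (nb,)).copy()
        self.r0 = np.broadcast_to(np.asarray(r0, float), (nb,)).copy()

    def accumulate(self, s, h, dU_ds, dU_dh):
        if len(self.bonds) == 0:
            return 0.0
        i, j = self.bonds[:, 0], self.bonds[:, 1]
        ds = s[i] - s[j]
        dR = ds @ h.T
        r = np.linalg.norm(dR, axis=1)
        dr = r - self.r0
        U = float(np.sum(0.5 * self.k * dr ** 2))
        gR = (self.k * dr / r)[:, None] * dR
        gs = gR @ h
        np.add.at(dU_ds, i, gs)
        np.add.at(dU_ds, j, -gs)
        dU_dh += np.einsum("pa,pb->ab", gR, ds)
        return U


class _AngleTerm:
    def __init__(self, angles, k, a0):
        self.angles = [tuple(a) for a in angles]
        na = len(self.angles)
        self.k = np.broadcast_to(np.asarray(k, float), (na,)).copy()
        self.a0 = np.broadcast_to(np.asarray(a0, float), (na,)).copy()

    def accumulate(self, s, h, dU_ds, dU_dh):
        U = 0.0
        X = s @ h.T
        for (i, j, k_), ka, a0 in zip(self.angles, self.k, self.a0):
            idx = [i, j, k_]
            th, g, _ = geometry.angle(X[idx], with_hess=False)
            d = th - a0
            U += 0.5 * ka * d * d
            gX = (ka * d) * g.reshape(3, 3)
            dU_ds[idx] += gX @ h
            dU_dh += np.einsum("ia,ib->ab", gX, s[idx])
        return float(U)


class _TorsionTerm:
    """U = k_d (1 − cos(φ − φ0)): smooth in φ, curvature k_d at φ0."""

    def __init__(self, dihedrals, k, d0):
        self.dihedrals = [tuple(d) for d in dihedrals]
        nd = len(self.dihedrals)
        self.k = np.broadcast_to(np.asarray(k, float), (nd,)).copy()
        self.d0 = np.broadcast_to(np.asarray(d0, float), (nd,)).copy()

    def accumulate(self, s, h, dU_ds, dU_dh):
        U = 0.0
        X = s @ h.T
        for idx, kd, d0 in zip(self.dihedrals, self.k, self.d0):
            if kd == 0.0:
                continue
            idx = list(idx)
            phi, g, _ = geometry.dihedral(X[idx], with_hess=False)
            U += kd * (1.0 - np.cos(phi - d0))
            gX = (kd * np.sin(phi - d0)) * g.reshape(4, 3)
            dU_ds[idx] += gX @ h
            dU_dh += np.einsum("ia,ib->ab", gX, s[idx])
        return float(U)


class _ForceFieldBase:
    terms: list

    def energy_forces(self, s: np.ndarray, h: np.ndarray) -> EnergyForces:
        s = np.asarray(s, float).reshape(-1, 3)
        h = np.asarray(h, float)
        if abs(np.linalg.det(h)) < 1e-12:
            raise ValueError("singular cell matrix")
        dU_ds = np.zeros_like(s)
        dU_dh = np.zeros((3, 3))
        U = sum(t.accumulate(s, h, dU_ds, dU_dh) for t in self.terms)
        if not (np.isfinite(U) and np.all(np.isfinite(dU_ds))
                and np.all(np.isfinite(dU_dh))):
            raise FloatingPointError("non-finite energy or gradient")
        return EnergyForces(U, dU_ds, dU_dh)

    # Cartesian interface (fixed cell) for Hessians and relaxation
    def cart_energy_grad(self, X: np.ndarray, h: np.ndarray):
        hinv = np.linalg.inv(h)
        s = np.asarray(X, float).reshape(-1, 3) @ hinv.T
        ef = self.energy_forces(s, h)
        return ef.U, ef.dU_ds @ hinv

    def cart_energy(self, X: np.ndarray, h: np.ndarray) -> float:
        return self.cart_energy_grad(X, h)[0]


class N2ForceField(_ForceFieldBase):
    def __init__(self, topo: Topology, params: N2Params | None = None,
                 cutoff: float = 10.0):
        params = params or N2Params()
        for mol in topo.molecules():
            if len(mol) != 2:
                raise ValueError("N2 force field requires diatomic molecules")
        self.params = params
        self.cutoff = cutoff
        self.terms = [_BondTerm(topo.bonds, params.Kr, params.r0),
                      _PairLJ(topo, params.eps, params.rm, cutoff)]


class ToyPolyForceField(_ForceFieldBase):
    def __init__(self, topo: Topology, params: ToyPolyParams | None = None):
        params = params or ToyPolyParams()
        self.params = params
        self.terms = [_BondTerm(topo.bonds, params.k_b, params.b0),
                      _AngleTerm(topo.angles, params.k_a, params.a0),
                      _TorsionTerm(topo.dihedrals, params.k_d, params.d0),
                      _PairLJ(topo, params.eps, params.rm, params.cutoff)]


class _DoubleWellBondTerm:
    """U(r) = A ((r − r0)² − d²)² per bond: two minima at r0 ± d."""

    def __init__(self, bonds, A, r0, d):
        self.bonds = np.asarray(bonds, int).reshape(-1, 2)
        self.A, self.r0, self.d = A, r0, d

    def accumulate(self, s, h, dU_ds, dU_dh):
        if len(self.bonds) == 0:
            return 0.0
        i, j = self.bonds[:, 0], self.bonds[:, 1]
        ds = s[i] - s[j]
        dR = ds @ h.T
        r = np.linalg.norm(dR, axis=1)
        x = r - self.r0
        w = x * x - self.d ** 2
        U = float(np.sum(self.A * w * w))
        dU_dr = 4.0 * self.A * w * x
        gR = (dU_dr / r)[:, None] * dR
        gs = gR @ h
        np.add.at(dU_ds, i, gs)
        np.add.at(dU_ds, j, -gs)
        dU_dh += np.einsum("pa,pb->ab", gR, ds)
        return U


class DoubleWellBondForceField(_ForceFieldBase):
    """Isolated molecules whose bonds see a symmetric double well; barrier
    height A·d⁴ at r = r0."""

    def __init__(self, topo: Topology, A: float = 2.0, r0: float = 1.2,
                 d: float = 0.12):
        self.terms = [_DoubleWellBondTerm(topo.bonds, A, r0, d)]
        self.barrier = A * d ** 4


def cell_gradient(forcefield, s: np.ndarray, h: np.ndarray) -> np.ndarray:
    """∂U/∂h at fixed scaled coordinates (3×3)."""
    return forcefield.energy_forces(s, h).dU_dh


def fd_hessian(positions: np.ndarray, energy_fn, step: float = 1e-3) -> np.ndarray:
    """Symmetric central-difference Hessian of ``energy_fn`` (a function of
    the flattened Cartesian coordinates or an (N, 3) array)."""
    if step <= 0:
        raise ValueError("step must be positive")
    x0 = np.asarray(positions, float).reshape(-1)
    n = x0.size

    def e(x):
        val = energy_fn(x.reshape(-1, 3))
        if not np.isfinite(val):
            raise FloatingPointError("non-finite energy during displacement")
        return val

    H = np.empty((n, n))
    e0 = e(x0)
    for j in range(n):
        for k in range(j, n):
            if j == k:
                xp = x0.copy(); xp[j] += step
                xm = x0.copy(); xm[j] -= step
                H[j, j] = (e(xp) - 2.0 * e0 + e(xm)) / step ** 2
            else:
                xpp = x0.copy(); xpp[j] += step; xpp[k] += step
                xmm = x0.copy(); xmm[j] -= step; xmm[k] -= step
                xpm = x0.copy(); xpm[j] += step; xpm[k] -= step
                xmp = x0.copy(); xmp[j] -= step; xmp[k] += step
                H[j, k] = H[k, j] = (e(xpp) - e(xpm) - e(xmp) + e(xmm)) / (4 * step ** 2)
    return 0.5 * (H + H.T)
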