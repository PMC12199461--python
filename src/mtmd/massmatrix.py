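"""Position-dependent, determinant-constrained mass matrices.

A mass model assigns every molecule a symmetric positive-definite
``3n × 3n`` Cartesian mass block ``A_mol(X)``; the full mass matrix is the
block-diagonal assembly rescaled by a global factor,

    M(q) = c(q) · A(q),      c(q) = (D0 / det A(q))^(1/3N),

so that ``det M`` is held exactly at its reference value ``D0`` — the
condition under which the configurational canonical distribution remains
proportional to ``exp(−βU)``.  ``c`` is normalized to 1 at the reference
geometry by setting ``D0 = det A(q0)``.

Implemented models:

* :class:`ConstantMassModel` — per-atom (physical or repartitioned) masses;
  ``c ≡ 1``.
* :class:`DiatomicMassModel` — per-molecule decomposition into three
  translational, two rotational and one vibrational mode with independent
  masses; its determinant ``m_trans³ m_rot² m_vib`` is constant by
  construction, so ``c ≡ 1``.
* :class:`InternalHessianMassModel` — ``A = w·Bᵀ(q) H_{q,0} B(q) + M_p``
  with the reference Hessian in redundant internal coordinates ``H_{q,0}``
  and the Wilson B matrix of the current geometry; here ``c(q)`` fluctuates
  and the determinant constraint is enforced through the closed form above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .internals import MoleculeInternals, thresholded_pinv, PINV_RTOL
from .topology import Topology

__all__ = ["ConstantMassModel", "DiatomicMassModel", "InternalHessianMassModel",
           "MassEvaluation", "diatomic_block", "mass_repartitioned",
           "reference_hessian_internal", "build_mass_matrix", "build_G",
           "dGinv_derivatives"]


# --------------------------------------------------------------------------
# mode projectors of the diatomic decomposition
_P_PLUS = 0.5 * np.array([[1.0, 1.0], [1.0, 1.0]])    # in-phase (translation)
_P_MINUS = 0.5 * np.array([[1.0, -1.0], [-1.0, 1.0]])  # out-of-phase


def _kron22(Q, B):
    """np.kron(Q, B) batched over leading axes of B (..., 3, 3) -> (..., 6, 6)."""
    B = np.asarray(B)
    out = np.empty(B.shape[:-2] + (6, 6))
    for i in range(2):
        for j in range(2):
            out[..., 3 * i:3 * i + 3, 3 * j:3 * j + 3] = Q[i, j] * B
    return out


@dataclass
class DiatomicMassModel:
    """Per-mode masses for diatomic molecules (u)."""
    m_trans: float
    m_rot: float
    m_vib: float

    def __post_init__(self):
        if min(self.m_trans, self.m_rot, self.m_vib) <= 0:
            raise ValueError("mode masses must be strictly positive")

    @property
    def is_constant(self) -> bool:
        return self.m_rot == self.m_vib  # direction dependence then cancels

    def bind(self, topo: Topology):
        return _BoundDiatomic(self, topo)


def diatomic_block(d_hat: np.ndarray, model: DiatomicMassModel) -> np.ndarray:
    """6×6 molecular mass block for bond direction ``d_hat`` (unit vector):
    three translational, two rotational and one vibrational mode."""
    d_hat = np.asarray(d_hat, float)
    if abs(np.linalg.norm(d_hat) - 1.0) > 1e-8:
        raise ValueError("d_hat must be a unit vector")
    D = np.outer(d_hat, d_hat)
    I3 = np.eye(3)
    return (model.m_trans * _kron22(_P_PLUS, I3)
            + model.m_rot * _kron22(_P_MINUS, I3 - D)
            + model.m_vib * _kron22(_P_MINUS, D))


class _BoundDiatomic:
    """Vectorized diatomic blocks + Cartesian derivatives for all molecules."""

    def __init__(self, model: DiatomicMassModel, topo: Topology):
        mols = topo.molecules()
        if any(len(m) != 2 for m in mols):
            raise ValueError("diatomic mass model requires diatomic molecules")
        self.model = model
        self.atoms = np.array([m for m in mols])      # (M, 2)
        self.is_constant = model.is_constant
        self.rescale = False                           # det is constant
        self.logdet_ref = None
        M = len(mols)
        self.n_dof = 6 * M

    def groups(self):
        return [self]

    def evaluate(self, Xg: np.ndarray, with_derivs: bool):
        """Xg (M, 2, 3) -> A (M, 6, 6), dA (M, 6, 6, 6) over atom coords."""
        m = self.model
        d = Xg[:, 1] - Xg[:, 0]
        r = np.linalg.norm(d, axis=1)
        if np.any(r < 1e-10):
            raise FloatingPointError("zero-length bond in mass model")
        u = d / r[:, None]
        D = np.einsum("ma,mb->mab", u, u)
        I3 = np.eye(3)
        A = (m.m_trans * _kron22(_P_PLUS, np.broadcast_to(I3, D.shape))
             + m.m_rot * _kron22(_P_MINUS, I3 - D)
             + m.m_vib * _kron22(_P_MINUS, D))
        if not with_derivs:
            return A, None
        # ∂u/∂d = (I − uuᵀ)/r ; ∂(uuᵀ)_ab/∂d_c = P_ac u_b + u_a P_bc
        P = (I3 - D) / r[:, None, None]
        dD = (np.einsum("mac,mb->mcab", P, u)
              + np.einsum("ma,mbc->mcab", u, P))      # (M, 3, 3, 3): [c, a, b]
        dM6 = (m.m_vib - m.m_rot) * _kron22(_P_MINUS, dD)  # (M, 3, 6, 6)
        dA = np.empty((len(A), 6, 6, 6))
        dA[:, 0:3] = -dM6     # derivative w.r.t. atom 0 coords
        dA[:, 3:6] = dM6      # atom 1
        return A, dA


class ConstantMassModel:
    """Constant (position-independent) diagonal mass matrix."""

    def __init__(self, masses):
        self.masses = np.asarray(masses, float)
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")
        self.is_constant = True

    @classmethod
    def physical(cls, topo: Topology):
        return cls(topo.masses)

    @classmethod
    def repartitioned(cls, topo: Topology):
        return cls(np.full(topo.n_atoms, topo.masses.mean()))

    def bind(self, topo: Topology):
        if len(self.masses) != topo.n_atoms:
            raise ValueError("mass array does not match topology")
        return _BoundConstant(self, topo)


class _BoundConstant:
    def __init__(self, model: ConstantMassModel, topo: Topology):
        self.masses = model.masses
        self.is_constant = True
        self.rescale = False
        self.logdet_ref = None
        self.atoms = np.array([m for m in topo.molecules()], dtype=object)
        self._topo = topo

    def groups(self):
        return []   # the constant fast path never touches groups


def mass_repartitioned(topo: Topology) -> np.ndarray:
    """Constant mass matrix ``(1/N)(Σ m_i) I_{3N}``: mean mass on every
    Cartesian degree of freedom, conserving the total mass."""
    return topo.masses.mean() * np.eye(3 * topo.n_atoms)


def reference_hessian_internal(Hx0_mol: np.ndarray, B0: np.ndarray,
                               zero_offdiag: bool = False,
                               grad: np.ndarray | None = None,
                               grad_tol: float = 1e-5,
                               pinv_rtol: float = PINV_RTOL) -> np.ndarray:
    """Forward transform of a Cartesian Hessian to redundant internal
    coordinates, ``H_{q,0} = B₀^{T+} H_{x,0} B₀^{+}``.

    Valid at a local minimum, where the gradient-weighted second-derivative
    (K-matrix) term vanishes; a warning is emitted if a nonzero reference
    gradient is supplied.  The result is symmetrized and its (numerically)
    negative eigenvalues are clipped at zero.
    """
    if grad is not None and np.max(np.abs(grad)) > grad_tol:
        warnings.warn("reference gradient is not zero: the K-matrix term is "
                      "neglected only approximately", RuntimeWarning)
    Bp = thresholded_pinv(B0, pinv_rtol)
    Hq = Bp.T @ Hx0_mol @ Bp
    Hq = 0.5 * (Hq + Hq.T)
    if zero_offdiag:
        Hq = np.diag(np.diag(Hq))
    w, V = np.linalg.eigh(Hq)
    if w.min() < 0:
        Hq = (V * np.clip(w, 0.0, None)) @ V.T
        Hq = 0.5 * (Hq + Hq.T)
    return Hq


class InternalHessianMassModel:
    """Mass matrix from a reference Hessian in redundant internal
    coordinates: ``A = w·Bᵀ(q) H_{q,0} B(q) + M_p`` per molecule.

    Parameters
    ----------
    w : weight in u·Å²/eV.  0.5 is the molecular-crystal recipe, 0.2 the
        liquid-water recipe.
    base : 'physical', 'repartitioned', or an (N,) mass array for ``M_p``.
    zero_offdiag : null the off-diagonal internal-coordinate couplings of
        ``H_{q,0}`` (the diagonal variant).
    """

    def __init__(self, topo: Topology, X0: np.ndarray, Hx0: np.ndarray,
                 w: float = 0.5, base: object = "repartitioned",
                 zero_offdiag: bool = False, grad0: np.ndarray | None = None,
                 pinv_rtol: float = PINV_RTOL):
        if w < 0:
            raise ValueError("w must be non-negative")
        self.w = float(w)
        self.topo = topo
        self.zero_offdiag = zero_offdiag
        X0 = np.asarray(X0, float).reshape(-1, 3)
        if isinstance(base, str):
            if base == "physical":
                base_masses = topo.masses
            elif base == "repartitioned":
                base_masses = np.full(topo.n_atoms, topo.masses.mean())
            else:
                raise ValueError(f"unknown base mass choice {base!r}")
        else:
            base_masses = np.asarray(base, float)
        self.base_masses = base_masses

        Hx0 = np.asarray(Hx0, float)
        self.evaluators = MoleculeInternals.from_topology(topo)
        self.Hq0 = []
        self.Mp = []
        for ev in self.evaluators:
            idx = ev.atom_idx
            cols = np.concatenate([np.arange(3 * i, 3 * i + 3) for i in idx])
            Hx_mol = Hx0[np.ix_(cols, cols)]
            _, B0, _ = ev.evaluate(X0[idx], with_hess=False)
            g_mol = None if grad0 is None else np.asarray(grad0).reshape(-1)[cols]
            self.Hq0.append(reference_hessian_internal(
                Hx_mol, B0, zero_offdiag, g_mol, pinv_rtol=pinv_rtol))
            self.Mp.append(np.diag(np.repeat(base_masses[idx], 3)))
        self.is_constant = self.w == 0.0
        self._X0 = X0

    def bind(self, topo: Topology):
        if (topo.n_atoms != self.topo.n_atoms
                or not np.array_equal(topo.molecule_ids,
                                      self.topo.molecule_ids)):
            raise ValueError("model was constructed for a different system")
        if self.is_constant:
            return _BoundConstant(ConstantMassModel(self.base_masses), topo)
        return _BoundInternal(self)


class _BoundInternal:
    def __init__(self, model: InternalHessianMassModel):
        self.model = model
        self.is_constant = False
        self.rescale = True
        self._groups = [_InternalGroup(model, k)
                        for k in range(len(model.evaluators))]
        # reference determinant D0 fixes c(q0) = 1
        self.logdet_ref = sum(
            np.linalg.slogdet(g.evaluate(model._X0[g.atoms[0]][None],
                                         with_derivs=False)[0][0])[1]
            for g in self._groups)

    def groups(self):
        return self._groups


class _InternalGroup:
    """A single molecule of the internal-coordinate model (batch size 1)."""

    def __init__(self, model: InternalHessianMassModel, k: int):
        ev = model.evaluators[k]
        self.ev = ev
        self.atoms = ev.atom_idx[None, :]     # (1, n)
        self.Hq0 = model.Hq0[k]
        self.Mp = model.Mp[k]
        self.w = model.w

    def evaluate(self, Xg: np.ndarray, with_derivs: bool):
        X_mol = Xg[0]
        _, B, D2 = self.ev.evaluate(X_mol, with_hess=with_derivs)
        P = self.Hq0 @ B                       # (m, 3n)
        A = self.w * (B.T @ P) + self.Mp
        A = 0.5 * (A + A.T)
        if not with_derivs:
            return A[None], None
        dA = np.einsum("ipk,iq->kpq", D2, P)
        dA = self.w * (dA + dA.transpose(0, 2, 1))
        return A[None], dA[None]


# --------------------------------------------------------------------------
# dense user-facing assembly (reference implementation; used by tests and
# small-system utilities — the integrator uses the blockwise fast path)

@dataclass
class MassEvaluation:
    """Dense mass matrix with the determinant constraint applied."""
    M: np.ndarray          # (3N, 3N)
    c: float               # determinant-restoring rescale factor
    dM_dx: np.ndarray | None   # (3N, 3N, 3N): ∂M/∂x_k (Cartesian), or None
    logdet: float          # log det M


def _dense_A(bound, X, with_derivs):
    if bound.is_constant:
        masses = (bound.masses if hasattr(bound, "masses")
                  else bound.model.base_masses)
        n3 = 3 * len(masses)
        A = np.diag(np.repeat(masses, 3))
        return A, (np.zeros((n3, n3, n3)) if with_derivs else None)
    n3 = 3 * X.shape[0]
    A = np.zeros((n3, n3))
    dA = np.zeros((n3, n3, n3)) if with_derivs else None
    for g in bound.groups():
        for b in range(len(g.atoms)):
            idx = g.atoms[b]
            cols = np.concatenate([np.arange(3 * i, 3 * i + 3) for i in idx])
            Ab, dAb = g.evaluate(X[idx][None], with_derivs)
            A[np.ix_(cols, cols)] += Ab[0]
            if with_derivs:
                for kk, col in enumerate(cols):
                    dA[col][np.ix_(cols, cols)] += dAb[0][kk]
    return A, dA


def build_mass_matrix(X: np.ndarray, topo: Topology, model,
                      with_derivs: bool = True) -> MassEvaluation:
    """Dense ``M(q) = c(q)·A(q)`` at Cartesian coordinates ``X`` with
    molecules whole.  ``dM_dx[k]`` is the derivative w.r.t. Cartesian
    coordinate ``x_k`` including the chain through ``c``."""
    X = np.asarray(X, float).reshape(-1, 3)
    bound = model.bind(topo)
    A, dA = _dense_A(bound, X, with_derivs)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        raise ValueError("mass matrix block is not positive definite")
    n3 = A.shape[0]
    if bound.rescale:
        logc = (bound.logdet_ref - logdetA) / n3
    else:
        logc = 0.0
    c = float(np.exp(logc))
    M = c * A
    dM = None
    if with_derivs:
        Ainv = np.linalg.inv(A)
        # ∂c/∂x_k = −(c/3N)·tr(A⁻¹ ∂A/∂x_k)
        if bound.rescale:
            tr = np.einsum("pq,kqp->k", Ainv, dA)
            dlogc = -tr / n3
        else:
            dlogc = np.zeros(n3)
        dM = c * dA + np.einsum("k,pq->kpq", dlogc, M)
    return MassEvaluation(M, c, dM, logdetA + n3 * logc)


def build_G(h: np.ndarray, M: np.ndarray):
    """Mass-weighted metric tensor ``G = (I⊗h)ᵀ M (I⊗h)`` and its inverse."""
    n = M.shape[0] // 3
    H = np.kron(np.eye(n), h)
    G = H.T @ M @ H
    G = 0.5 * (G + G.T)
    return G, np.linalg.inv(G)


def dGinv_derivatives(s: np.ndarray, h: np.ndarray, topo: Topology, model):
    """Analytic derivatives of G⁻¹ w.r.t. scaled coordinates and the cell.

    Returns ``(dGinv_ds, dGinv_dh)`` with shapes (3N, 3N, 3N) (leading index
    = flattened scaled coordinate) and (3, 3, 3N, 3N).  Dense reference
    implementation intended for small systems and verification.
    """
    s = np.asarray(s, float).reshape(-1, 3)
    h = np.asarray(h, float)
    N = s.shape[0]
    n3 = 3 * N
    X = s @ h.T
    me = build_mass_matrix(X, topo, model, with_derivs=True)
    H = np.kron(np.eye(N), h)
    G = H.T @ me.M @ H
    Ginv = np.linalg.inv(G)

    dM = me.dM_dx                    # (3N, 3N, 3N) Cartesian
    dGinv_ds = np.empty((n3, n3, n3))
    for i in range(N):
        for a in range(3):
            # ∂M/∂s_{ia} = Σ_c ∂M/∂X_{ic} h_{ca}
            dM_s = np.einsum("c,cpq->pq", h[:, a], dM[3 * i:3 * i + 3])
            dG = H.T @ dM_s @ H
            dGinv_ds[3 * i + a] = -Ginv @ dG @ Ginv
    dGinv_dh = np.empty((3, 3, n3, n3))
    for a in range(3):
        for b in range(3):
            E = np.zeros((3, 3))
            E[a, b] = 1.0
            dH = np.kron(np.eye(N), E)
            dM_h = np.einsum("i,ipq->pq", s[:, b],
                             dM.reshape(N, 3, n3, n3)[:, a])
            dG = dH.T @ me.M @ H + H.T @ me.M @ dH + H.T @ dM_h @ H
            dGinv_dh[a, b] = -Ginv @ dG @ Ginv
    return dGinv_ds, dGinv_dh
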