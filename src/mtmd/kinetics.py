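"""Blockwise kinetic-energy machinery for the variable-cell equations of
motion.

The scaled-coordinate kinetic energy is ½ p_sᵀ G⁻¹ p_s with the
mass-weighted metric tensor G = (I⊗h)ᵀ M (I⊗h).  Because M is block
diagonal (one block per molecule), G never has to be formed: all
applications of G⁻¹ reduce to per-molecule solves conjugated with h, and
all kinetic force terms (−½ pᵀ (∂G⁻¹/∂·) p) reduce to contractions of the
per-molecule block derivatives ∂A/∂x with the Cartesian velocity — the
relation ∂G⁻¹ = −G⁻¹(∂G)G⁻¹ is used throughout.

A :class:`KineticEvaluation` is built once per geometry (s, h) and reused
by every solver iteration at that geometry; only the cheap contractions are
repeated when the momenta change.
"""

from __future__ import annotations

import numpy as np

from .topology import Topology

__all__ = ["Kinetics", "KineticEvaluation"]


class Kinetics:
    """Binds a mass model to a topology and evaluates kinetic quantities."""

    def __init__(self, topo: Topology, mass_model):
        self.topo = topo
        self.bound = mass_model.bind(topo)
        self.n_atoms = topo.n_atoms
        self.n3 = 3 * topo.n_atoms
        self.constant = self.bound.is_constant

    def evaluate(self, s: np.ndarray, h: np.ndarray,
                 with_derivs: bool | None = None) -> "KineticEvaluation":
        if with_derivs is None:
            with_derivs = not self.constant
        return KineticEvaluation(self, s, h, with_derivs)


class _GroupEval:
    __slots__ = ("atoms", "A", "dA", "Ainv", "trace", "logdet")


class KineticEvaluation:
    def __init__(self, kin: Kinetics, s, h, with_derivs):
        self.kin = kin
        self.s = np.asarray(s, float).reshape(-1, 3)
        self.h = np.asarray(h, float)
        self.hinv = np.linalg.inv(self.h)
        self.X = self.s @ self.h.T
        self.with_derivs = with_derivs
        bound = kin.bound
        self.rescale = bound.rescale

        if kin.constant:
            self.masses = bound.masses if hasattr(bound, "masses") else None
            self.logc = 0.0
            self.c = 1.0
            self.groups = []
            self.glnc_x = None
            return

        self.groups = []
        logdet = 0.0
        for g in bound.groups():
            ge = _GroupEval()
            ge.atoms = g.atoms                       # (M, n)
            Xg = self.X[g.atoms]                     # (M, n, 3)
            A, dA = g.evaluate(Xg, with_derivs)      # A (M, 3n, 3n)
            ge.A, ge.dA = A, dA
            ge.Ainv = np.linalg.inv(A)
            sign, ld = np.linalg.slogdet(A)
            if np.any(sign <= 0):
                raise FloatingPointError("mass block lost positive definiteness")
            ge.logdet = float(np.sum(ld))
            logdet += ge.logdet
            if with_derivs:
                ge.trace = np.einsum("mqp,mkpq->mk", ge.Ainv, dA)  # (M, 3n)
            self.groups.append(ge)
        self.logdetA = logdet
        if self.rescale:
            self.logc = (bound.logdet_ref - logdet) / kin.n3
        else:
            self.logc = 0.0
        self.c = float(np.exp(self.logc))
        if self.rescale and with_derivs:
            gx = np.zeros((kin.n_atoms, 3))
            for ge in self.groups:
                M_, n = ge.atoms.shape
                np.add.at(gx, ge.atoms.reshape(-1),
                          (-ge.trace / kin.n3).reshape(M_, n, 3).reshape(-1, 3))
            self.glnc_x = gx                 # ∂ln c / ∂X  (N, 3)
        else:
            self.glnc_x = None

    # -- gather/scatter helpers over molecule blocks -----------------------
    def _gather(self, y, ge):
        M_, n = ge.atoms.shape
        return y[ge.atoms].reshape(M_, 3 * n)

    def _scatter(self, out, vals, ge):
        M_, n = ge.atoms.shape
        np.add.at(out, ge.atoms.reshape(-1), vals.reshape(M_ * n, 3))

    # -- core applications -------------------------------------------------
    def apply_M(self, y: np.ndarray) -> np.ndarray:
        """u = M y for a Cartesian-indexed field y (N, 3)."""
        if self.kin.constant:
            return self.masses[:, None] * y
        u = np.zeros_like(y)
        for ge in self.groups:
            Y = self._gather(y, ge)
            self._scatter(u, np.einsum("mpq,mq->mp", ge.A, Y), ge)
        return self.c * u

    def apply_Minv(self, u: np.ndarray) -> np.ndarray:
        if self.kin.constant:
            return u / self.masses[:, None]
        y = np.zeros_like(u)
        for ge in self.groups:
            U = self._gather(u, ge)
            self._scatter(y, np.einsum("mpq,mq->mp", ge.Ainv, U), ge)
        return y / self.c

    def velocity(self, ps: np.ndarray) -> np.ndarray:
        """ṡ = G⁻¹ p_s."""
        return self.apply_Minv(ps @ self.hinv) @ self.hinv.T

    def cart_velocity(self, ps: np.ndarray) -> np.ndarray:
        """Ṙ = h ṡ (the Cartesian velocity field)."""
        return self.apply_Minv(ps @ self.hinv)

    def ps_from_cart_velocity(self, v_cart: np.ndarray) -> np.ndarray:
        """p_s = hᵀ (M v_cart) per atom."""
        return self.apply_M(v_cart) @ self.h

    def kinetic_energy(self, ps: np.ndarray) -> float:
        return 0.5 * float(np.sum(ps * self.velocity(ps)))

    # -- kinetic force terms ----------------------------------------------
    def kinetic_forces(self, v: np.ndarray):
        """(f_s, f_h) with f_s,i = ½ vᵀ(∂G/∂s_i)v and
        f_h,ab = ½ vᵀ(∂G/∂h_ab)v, for a scaled velocity field v = G⁻¹p.

        These equal the −½ pᵀ(∂G⁻¹/∂·)p terms of the equations of motion.
        """
        y = v @ self.h.T                      # Cartesian velocity
        u = self.apply_M(y)
        ke = 0.5 * float(np.sum(y * u))
        f_h = np.einsum("ia,ib->ab", u, v)    # explicit congruence part
        f_s = np.zeros_like(v)
        if self.kin.constant or not self.with_derivs:
            return f_s, f_h, ke
        T = np.zeros_like(v)                  # ½ yᵀ(∂A/∂X_{i,c})y per (i,c)
        for ge in self.groups:
            if ge.dA is None:
                continue
            Y = self._gather(y, ge)
            Tg = 0.5 * np.einsum("mkpq,mp,mq->mk", ge.dA, Y, Y)
            self._scatter(T, Tg, ge)
        f_s += self.c * (T @ self.h)
        f_h += self.c * np.einsum("ia,ib->ab", T, self.s)
        if self.rescale:
            f_s += (2.0 * ke) * 0.5 * (self.glnc_x @ self.h)
            f_h += ke * np.einsum("ia,ib->ab", self.glnc_x, self.s)
        return f_s, f_h, ke

    # -- Newton solve for the implicit position update ---------------------
    def solve_position_jacobian(self, rhs: np.ndarray, v: np.ndarray,
                                dt: float) -> np.ndarray:
        """Solve (I − (Δt/2)·∂(G⁻¹p)/∂s) Δ = rhs  at fixed p (with v = G⁻¹p).

        The Jacobian is block diagonal over molecules plus a rank-one term
        from the determinant-constraint factor c(q); the rank-one part is
        folded in with the Sherman–Morrison identity.
        """
        if self.kin.constant:
            return rhs.copy()
        blocks = self._position_jacobian_blocks(v)

        def block_solve(r):
            out = np.zeros_like(r)
            for W_mat, ge in zip(blocks, self.groups):
                M_, nat = ge.atoms.shape
                n3 = 3 * nat
                J = np.broadcast_to(np.eye(n3), (M_, n3, n3)).copy()
                J += 0.5 * dt * W_mat
                R = self._gather(r, ge)
                sol = np.linalg.solve(J, R[..., None])[..., 0]
                out[ge.atoms.reshape(-1)] = sol.reshape(M_ * nat, 3)
            return out

        x = block_solve(rhs)
        if self.rescale:
            glnc_s = self.glnc_x @ self.h
            w_ = block_solve(v)
            denom = 1.0 + 0.5 * dt * float(np.sum(glnc_s * w_))
            x -= w_ * (0.5 * dt * float(np.sum(glnc_s * x)) / denom)
        return x

    def _position_jacobian_blocks(self, v):
        """Per-group blocks Zb with Zb[:, k] = (I⊗h⁻¹) A⁻¹ (∂A/∂s_k) (h v),
        the molecule-local part of ∂(G⁻¹p)/∂s (up to sign)."""
        y = v @ self.h.T
        out = []
        for ge in self.groups:
            M_, nat = ge.atoms.shape
            n3 = 3 * nat
            Y = self._gather(y, ge)
            W = np.einsum("mkpq,mq->mkp", ge.dA, Y)
            Ws = np.einsum("micp,ca->miap",
                           W.reshape(M_, nat, 3, n3), self.h).reshape(M_, n3, n3)
            Z = np.einsum("mpq,mkq->mkp", ge.Ainv, Ws)
            Zb = np.einsum("bc,mkjc->mkjb",
                           self.hinv, Z.reshape(M_, n3, nat, 3)).reshape(M_, n3, n3)
            out.append(Zb.transpose(0, 2, 1))     # [row = output, col = k]
        return out

    def solve_momentum_jacobian(self, rhs: np.ndarray, v: np.ndarray,
                                dt: float) -> np.ndarray:
        """Solve (I − (Δt/2)·∂f_s/∂p) Δ = rhs for the implicit momentum half
        kick, where f_s,i = ½ vᵀ(∂G/∂s_i)v and ∂f_s/∂p is the transpose of
        the position-update sensitivity (same blocks, transposed), plus the
        rank-one determinant-constraint term."""
        if self.kin.constant:
            return rhs.copy()
        blocks = self._position_jacobian_blocks(v)

        def block_solve(r):
            out = np.zeros_like(r)
            for Zb, ge in zip(blocks, self.groups):
                M_, nat = ge.atoms.shape
                n3 = 3 * nat
                J = np.broadcast_to(np.eye(n3), (M_, n3, n3)).copy()
                J -= 0.5 * dt * Zb.transpose(0, 2, 1)
                R = self._gather(r, ge)
                sol = np.linalg.solve(J, R[..., None])[..., 0]
                out[ge.atoms.reshape(-1)] = sol.reshape(M_ * nat, 3)
            return out

        x = block_solve(rhs)
        if self.rescale:
            # rank-one term −(dt/2)·glnc_s ⊗ v  (transpose of the position one)
            glnc_s = self.glnc_x @ self.h
            w_ = block_solve(glnc_s)
            denom = 1.0 - 0.5 * dt * float(np.sum(v * w_))
            x += w_ * (0.5 * dt * float(np.sum(v * x)) / denom)
        return x

    # -- directional derivative of G (explicit Lagrangian integrator) ------
    def G_dot_apply(self, w: np.ndarray, s_dot: np.ndarray,
                    h_dot: np.ndarray) -> np.ndarray:
        """(dG/dt) w along the phase-space direction (ṡ, ḣ), as (N, 3)."""
        y = w @ self.h.T
        u = self.apply_M(y)
        ydot = w @ h_dot.T
        out = u @ h_dot + self.apply_M(ydot) @ self.h
        if self.kin.constant or not self.with_derivs:
            return out
        Xdot = self.s @ h_dot.T + s_dot @ self.h.T
        Mydot = np.zeros_like(w)
        dlnc = 0.0
        for ge in self.groups:
            M_, nat = ge.atoms.shape
            Y = self._gather(y, ge)
            Xd = self._gather(Xdot, ge)
            Adot = np.einsum("mkpq,mk->mpq", ge.dA, Xd)
            self._scatter(Mydot, np.einsum("mpq,mq->mp", Adot, Y), ge)
            if self.rescale:
                dlnc += -float(np.einsum("mk,mk->", ge.trace, Xd)) / self.kin.n3
        out += (self.c * Mydot + dlnc * u) @ self.h
        return out

    # -- Boltzmann sampling -------------------------------------------------
    def sample_cart_velocities(self, temperature: float, rng) -> np.ndarray:
        """Draw Cartesian velocities from N(0, k_B T M⁻¹)."""
        from .units import KB
        kT = KB * temperature
        z = rng.standard_normal((self.kin.n_atoms, 3))
        if temperature == 0.0:
            return np.zeros((self.kin.n_atoms, 3))
        if self.kin.constant:
            return np.sqrt(kT / self.masses)[:, None] * z
        v = np.zeros((self.kin.n_atoms, 3))
        for ge in self.groups:
            M_, nat = ge.atoms.shape
            L = np.linalg.cholesky(self.c * ge.A)
            Z = self._gather(z, ge)
            # v = L^{-T} z  gives covariance (L Lᵀ)⁻¹ = M⁻¹
            sol = np.linalg.solve(np.transpose(L, (0, 2, 1)), Z[..., None])[..., 0]
            v[ge.atoms.reshape(-1)] = sol.reshape(M_ * nat, 3)
        return np.sqrt(kT) * v

    def remove_net_momentum(self, v_cart: np.ndarray) -> np.ndarray:
        """Subtract the uniform velocity that zeroes the total Cartesian
        momentum Σ (M v)_i."""
        p = self.apply_M(v_cart)
        P_tot = p.sum(axis=0)
        ones = np.ones((self.kin.n_atoms, 3))
        S = np.zeros((3, 3))
        for a in range(3):
            e = np.zeros((self.kin.n_atoms, 3))
            e[:, a] = 1.0
            S[:, a] = self.apply_M(e).sum(axis=0)
        u0 = np.linalg.solve(S, P_tot)
        return v_cart - u0
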