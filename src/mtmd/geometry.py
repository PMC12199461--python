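"""Analytic values, gradients and Hessians of internal coordinates.

Bond lengths, bond angles and dihedral (torsion) angles as functions of the
Cartesian coordinates of the participating atoms.  Each function returns

* the coordinate value (Å for bonds, radians for angles/dihedrals),
* the gradient with respect to the stacked atom coordinates (3n,),
* optionally the dense Hessian (3n, 3n).

Angles are computed through ``arccos`` of a clamped cosine; dihedrals through
``atan2`` for full-range sign stability.  Dihedral derivatives use the
decomposition φ = atan2(|b2|·(b1·(b2×b3)), (b1×b2)·(b2×b3)) whose numerator
and denominator are built from dot products and the triple product, giving
closed-form first and second derivatives without special cases away from the
collinear degeneracy.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "bond",
    "angle",
    "dihedral",
]


class DegenerateGeometryError(ValueError):
    """Raised when an internal coordinate is evaluated at a singular geometry
    (zero-length bond, collinear dihedral axis, angle at 0 or π)."""


def _outer(a, b):
    return np.outer(a, b)


def bond(x: np.ndarray, with_hess: bool = True):
    """Bond length between ``x[0]`` and ``x[1]`` (shape (2, 3))."""
    u = x[1] - x[0]
    r = float(np.linalg.norm(u))
    if r < 1e-10:
        raise DegenerateGeometryError("zero-length bond")
    uh = u / r
    g = np.concatenate([-uh, uh])
    if not with_hess:
        return r, g, None
    P = (np.eye(3) - _outer(uh, uh)) / r
    H = np.empty((6, 6))
    H[:3, :3] = P
    H[3:, 3:] = P
    H[:3, 3:] = -P
    H[3:, :3] = -P
    return r, g, H


# Maps from (u, v) = (x0 - x1, x2 - x1) to atom coordinates, constant.
_L_ANGLE = np.zeros((6, 9))
_L_ANGLE[0:3, 0:3] = np.eye(3)
_L_ANGLE[0:3, 3:6] = -np.eye(3)
_L_ANGLE[3:6, 3:6] = -np.eye(3)
_L_ANGLE[3:6, 6:9] = np.eye(3)


def angle(x: np.ndarray, with_hess: bool = True):
    """Bond angle at the central atom ``x[1]`` (shape (3, 3)), in (0, π)."""
    u = x[0] - x[1]
    v = x[2] - x[1]
    a = float(np.linalg.norm(u))
    b = float(np.linalg.norm(v))
    if a < 1e-10 or b < 1e-10:
        raise DegenerateGeometryError("angle with zero-length arm")
    c = float(u @ v) / (a * b)
    c = max(-1.0, min(1.0, c))
    s2 = 1.0 - c * c
    if s2 < 1e-12:
        raise DegenerateGeometryError("angle at 0 or π")
    s = np.sqrt(s2)
    theta = float(np.arccos(c))

    # gradient of cosine w.r.t. (u, v)
    gu = v / (a * b) - c * u / (a * a)
    gv = u / (a * b) - c * v / (b * b)
    gc = np.concatenate([gu, gv])
    g = _L_ANGLE.T @ (-gc / s)
    if not with_hess:
        return theta, g, None

    I3 = np.eye(3)
    uu = _outer(u, u)
    vv = _outer(v, v)
    uv = _outer(u, v)
    a2, b2_ = a * a, b * b
    Huu = (-(uv + uv.T) / (a2 * a * b) - c * I3 / a2 + 3.0 * c * uu / (a2 * a2))
    Hvv = (-(uv + uv.T).T / (a * b2_ * b) - c * I3 / b2_ + 3.0 * c * vv / (b2_ * b2_))
    Huv = (I3 / (a * b) - vv / (a * b2_ * b) - uu / (a2 * a * b)
           + c * uv / (a2 * b2_))
    Hc = np.empty((6, 6))
    Hc[:3, :3] = Huu
    Hc[3:, 3:] = Hvv
    Hc[:3, 3:] = Huv
    Hc[3:, :3] = Huv.T
    Htheta = -Hc / s - (c / (s * s2)) * _outer(gc, gc)
    H = _L_ANGLE.T @ Htheta @ _L_ANGLE
    return theta, g, H


# Maps from (b1, b2, b3) = (x1-x0, x2-x1, x3-x2) to atom coordinates.
_L_DIH = np.zeros((9, 12))
for _k, (_i, _j) in enumerate([(1, 0), (2, 1), (3, 2)]):
    _L_DIH[3 * _k:3 * _k + 3, 3 * _i:3 * _i + 3] = np.eye(3)
    _L_DIH[3 * _k:3 * _k + 3, 3 * _j:3 * _j + 3] = -np.eye(3)


def _cross_mat(a):
    return np.array([[0.0, -a[2], a[1]],
                     [a[2], 0.0, -a[0]],
                     [-a[1], a[0], 0.0]])


def dihedral(x: np.ndarray, with_hess: bool = True):
    """Dihedral angle over the four atoms ``x`` (shape (4, 3)), in (−π, π]."""
    b1 = x[1] - x[0]
    b2 = x[2] - x[1]
    b3 = x[3] - x[2]
    p = float(b1 @ b2)
    q = float(b2 @ b3)
    r_ = float(b1 @ b3)
    s2 = float(b2 @ b2)
    if s2 < 1e-20:
        raise DegenerateGeometryError("dihedral with zero-length axis")
    beta = np.sqrt(s2)

    X = p * q - r_ * s2
    D = float(b1 @ np.cross(b2, b3))
    Y = beta * D
    rho2 = X * X + Y * Y
    if rho2 < 1e-20:
        raise DegenerateGeometryError("dihedral with collinear axis")
    phi = float(np.arctan2(Y, X))

    z = np.zeros(3)
    gp = np.concatenate([b2, b1, z])
    gq = np.concatenate([z, b3, b2])
    gr = np.concatenate([b3, z, b1])
    gs2 = np.concatenate([z, 2.0 * b2, z])
    gbeta = np.concatenate([z, b2 / beta, z])
    gX = q * gp + p * gq - s2 * gr - r_ * gs2
    gD = np.concatenate([np.cross(b2, b3), np.cross(b3, b1), np.cross(b1, b2)])
    gY = beta * gD + D * gbeta

    phi_X = -Y / rho2
    phi_Y = X / rho2
    g9 = phi_X * gX + phi_Y * gY
    g = _L_DIH.T @ g9
    if not with_hess:
        return phi, g, None

    def blockmat(blocks):
        H = np.zeros((9, 9))
        for (i, j), m in blocks.items():
            H[3 * i:3 * i + 3, 3 * j:3 * j + 3] += m
            if i != j:
                H[3 * j:3 * j + 3, 3 * i:3 * i + 3] += m.T
        return H

    I3 = np.eye(3)
    Hp = blockmat({(0, 1): I3})
    Hq = blockmat({(1, 2): I3})
    Hr = blockmat({(0, 2): I3})
    Hs2 = blockmat({(1, 1): 2.0 * I3})
    b2h = b2 / beta
    Hbeta = blockmat({(1, 1): (I3 - _outer(b2h, b2h)) / beta})
    HD = blockmat({(0, 1): -_cross_mat(b3), (0, 2): _cross_mat(b2),
                   (1, 2): -_cross_mat(b1)})

    HX = (q * Hp + p * Hq - s2 * Hr - r_ * Hs2
          + _outer(gp, gq) + _outer(gq, gp)
          - _outer(gr, gs2) - _outer(gs2, gr))
    HY = (beta * HD + D * Hbeta + _outer(gbeta, gD) + _outer(gD, gbeta))

    phi_XX = 2.0 * X * Y / (rho2 * rho2)
    phi_YY = -phi_XX
    phi_XY = (Y * Y - X * X) / (rho2 * rho2)
    H9 = (phi_X * HX + phi_Y * HY
          + phi_XX * _outer(gX, gX) + phi_YY * _outer(gY, gY)
          + phi_XY * (_outer(gX, gY) + _outer(gY, gX)))
    H = _L_DIH.T @ H9 @ _L_DIH
    return phi, g, H
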