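"""Evaluation of redundant internal coordinates: values, Wilson B matrix,
second derivatives, and the thresholded pseudoinverse.

The Wilson B matrix holds the first derivatives ``B[i, j] = ∂q_i/∂x_j`` of
the internal coordinates with respect to the 3N Cartesian coordinates; the
second derivatives ``∂²q_i/∂x∂x`` are kept per coordinate as small dense
blocks over the participating atoms.  All evaluations assume molecules that
have been made whole (unwrapped) so that q_i(x) is smooth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry
from .geometry import DegenerateGeometryError
from .topology import Topology

__all__ = ["InternalEvaluation", "MoleculeInternals", "evaluate_internals",
           "thresholded_pinv", "prune_degenerate_internals",
           "internal_report"]

#: relative singular-value cutoff for the pseudoinverse of B
PINV_RTOL = 1e-2


@dataclass
class InternalEvaluation:
    """Values and derivatives of a set of internal coordinates."""
    values: np.ndarray        # (n_q,)
    B: np.ndarray             # (n_q, 3N)
    B_pinv: np.ndarray        # (3N, n_q)
    d2q: list                 # per coordinate: (atom_idx, H) with H (3n, 3n)
    kinds: list               # 'bond' | 'angle' | 'dihedral'


def thresholded_pinv(B: np.ndarray, rtol: float = PINV_RTOL) -> np.ndarray:
    """Moore–Penrose pseudoinverse with singular values below
    ``rtol * σ_max`` treated as exactly zero."""
    B = np.asarray(B, float)
    if B.size == 0 or not np.any(B):
        raise ValueError("cannot pseudo-invert an all-zero matrix")
    U, s, Vt = np.linalg.svd(B, full_matrices=False)
    keep = s > rtol * s[0]
    return (Vt[keep].T / s[keep]) @ U[:, keep].T


def _internal_list(topo: Topology):
    items = [("bond", b) for b in topo.bonds]
    items += [("angle", a) for a in topo.angles]
    items += [("dihedral", d) for d in topo.dihedrals]
    return items


_EVAL = {"bond": geometry.bond, "angle": geometry.angle,
         "dihedral": geometry.dihedral}


def evaluate_internals(topo: Topology, positions: np.ndarray,
                       with_hess: bool = True,
                       pinv_rtol: float = PINV_RTOL) -> InternalEvaluation:
    """Evaluate all internal coordinates of ``topo`` at Cartesian
    ``positions`` (N, 3).  Raises :class:`DegenerateGeometryError` at
    singular geometries."""
    X = np.asarray(positions, float).reshape(-1, 3)
    items = _internal_list(topo)
    nq = len(items)
    n3 = 3 * topo.n_atoms
    values = np.empty(nq)
    B = np.zeros((nq, n3))
    d2q = []
    kinds = []
    for row, (kind, idx) in enumerate(items):
        idx = list(idx)
        v, g, H = _EVAL[kind](X[idx], with_hess=with_hess)
        values[row] = v
        cols = np.concatenate([np.arange(3 * i, 3 * i + 3) for i in idx])
        B[row, cols] = g
        kinds.append(kind)
        d2q.append((np.array(idx), H))
    return InternalEvaluation(values, B, thresholded_pinv(B, pinv_rtol),
                              d2q, kinds)


def prune_degenerate_internals(topo: Topology, positions: np.ndarray,
                               tol: float = 1e-3) -> Topology:
    """Drop angles within ``tol`` radians of π (and dihedrals whose axis
    angles are that close to π) at the reference geometry, where the B matrix
    rows become singular.  Returns a new pruned :class:`Topology`."""
    X = np.asarray(positions, float).reshape(-1, 3)

    def angle_ok(i, j, k):
        try:
            th = geometry.angle(X[[i, j, k]], with_hess=False)[0]
        except DegenerateGeometryError:
            return False
        return th < np.pi - tol and th > tol

    angles = [a for a in topo.angles if angle_ok(*a)]
    dihedrals = [d for d in topo.dihedrals
                 if angle_ok(d[0], d[1], d[2]) and angle_ok(d[1], d[2], d[3])]
    return Topology(topo.elements, topo.masses, topo.molecule_ids,
                    list(topo.bonds), angles, dihedrals)


class MoleculeInternals:
    """Per-molecule internal-coordinate evaluator.

    Holds the molecule's atom indices and its internal coordinates with
    atom indices relative to the molecule, and evaluates values, the local
    Wilson B matrix (m, 3n) and the stacked second-derivative tensor
    (m, 3n, 3n) from the molecule's Cartesian coordinates.
    """

    def __init__(self, atom_idx: np.ndarray, internals):
        self.atom_idx = np.asarray(atom_idx, int)
        pos = {int(a): k for k, a in enumerate(self.atom_idx)}
        self.internals = [(kind, [pos[int(a)] for a in idx])
                          for kind, idx in internals]
        self.n = len(self.atom_idx)
        self.m = len(self.internals)

    @classmethod
    def from_topology(cls, topo: Topology):
        """One evaluator per molecule, in molecule-id order."""
        groups = {m: [] for m in range(topo.n_molecules)}
        for kind, idx in _internal_list(topo):
            groups[int(topo.molecule_ids[idx[0]])].append((kind, idx))
        return [cls(atoms, groups[m])
                for m, atoms in enumerate(topo.molecules())]

    def evaluate(self, X_mol: np.ndarray, with_hess: bool = True):
        """values (m,), B (m, 3n), D2 (m, 3n, 3n) at molecule coordinates."""
        n3 = 3 * self.n
        values = np.empty(self.m)
        B = np.zeros((self.m, n3))
        D2 = np.zeros((self.m, n3, n3)) if with_hess else None
        for row, (kind, loc) in enumerate(self.internals):
            v, g, H = _EVAL[kind](X_mol[loc], with_hess=with_hess)
            values[row] = v
            cols = np.concatenate([np.arange(3 * i, 3 * i + 3) for i in loc])
            B[row, cols] = g
            if with_hess:
                D2[row][np.ix_(cols, cols)] = H
        return values, B, D2


def internal_report(topo: Topology, positions: np.ndarray) -> str:
    """Plain-text report of the internal-coordinate list with values."""
    ev = evaluate_internals(topo, positions, with_hess=False)
    lines = ["# kind    atoms               value"]
    for kind, (idx, _), v in zip(ev.kinds, ev.d2q, ev.values):
        unit = "Å" if kind == "bond" else "rad"
        lines.append(f"{kind:<9}{' '.join(f'{i:>4d}' for i in idx):<20}"
                     f"{v: .6f} {unit}")
    return "\n".join(lines) + "\n"
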