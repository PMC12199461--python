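"""Molecular topology: bond detection and redundant internal coordinates.

Bonds are detected from interatomic distances against scaled covalent radii;
connected components of the bond graph define molecules.  From the bond
graph, all bond angles (paths of length two) and proper dihedrals (paths of
length three over distinct atoms) are enumerated, giving the redundant
internal-coordinate set used by the internal-coordinate mass matrix.

The bonding pattern is fixed at setup: no bond breaking or re-detection
along trajectories is supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Topology", "detect_bonds", "enumerate_internals", "COVALENT_RADII",
           "ATOMIC_MASSES", "UnknownElementError"]

# Single-bond covalent radii in Å (Cordero et al., Dalton Trans. 2008).
COVALENT_RADII = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Br": 1.20, "I": 1.39,
}

# Standard atomic weights in u.
ATOMIC_MASSES = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098, "Ca": 40.078,
    "Br": 79.904, "I": 126.90,
}


class UnknownElementError(KeyError):
    """Raised when an element symbol has no entry in the bundled tables."""


@dataclass
class Topology:
    """Atoms, molecules and the redundant internal-coordinate list.

    Every bond/angle/dihedral references atoms within a single molecule so
    that the mass matrix retains its block-diagonal structure (one block per
    molecule)."""

    elements: list
    masses: np.ndarray                 # (N,) physical masses in u
    molecule_ids: np.ndarray           # (N,) int
    bonds: list = field(default_factory=list)       # [(i, j)], i < j
    angles: list = field(default_factory=list)      # [(i, j, k)], vertex j
    dihedrals: list = field(default_factory=list)   # [(i, j, k, l)]

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_molecules(self) -> int:
        return int(self.molecule_ids.max()) + 1 if self.n_atoms else 0

    def molecules(self):
        """Atom index arrays, one per molecule, in molecule-id order."""
        return [np.flatnonzero(self.molecule_ids == m)
                for m in range(self.n_molecules)]

    def validate(self) -> None:
        mid = self.molecule_ids
        for group in (self.bonds, self.angles, self.dihedrals):
            for tup in group:
                if len(set(tup)) != len(tup):
                    raise ValueError(f"repeated atom in internal {tup}")
                if len(set(mid[list(tup)])) != 1:
                    raise ValueError(
                        f"internal coordinate {tup} crosses molecules")
        canon = {tuple(sorted(b)) for b in self.bonds}
        if len(canon) != len(self.bonds):
            raise ValueError("duplicate bonds")


def _min_image_dists(positions: np.ndarray, cell: np.ndarray):
    """All-pairs minimum-image distances. Returns (iu, ju, d)."""
    n = len(positions)
    iu, ju = np.triu_indices(n, k=1)
    d = positions[iu] - positions[ju]
    if cell is not None:
        hinv = np.linalg.inv(cell)
        ds = d @ hinv.T
        ds -= np.round(ds)
        d = ds @ cell.T
    return iu, ju, np.linalg.norm(d, axis=1)


def detect_bonds(positions: np.ndarray, elements, cell: np.ndarray | None = None,
                 scale: float = 1.2):
    """Detect covalent bonds from minimum-image interatomic distances.

    A bond is assigned whenever the distance is below
    ``scale * (r_cov(a) + r_cov(b))``.  Returns ``(bonds, molecule_ids)``
    where molecules are the connected components of the bond graph.
    """
    positions = np.asarray(positions, float).reshape(-1, 3)
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite positions")
    if scale <= 0:
        raise ValueError("scale must be positive")
    try:
        radii = np.array([COVALENT_RADII[e] for e in elements])
    except KeyError as exc:
        raise UnknownElementError(
            f"no covalent radius for element {exc.args[0]!r}") from exc
    iu, ju, d = _min_image_dists(positions, cell)
    cutoff = scale * (radii[iu] + radii[ju])
    bonds = [(int(i), int(j)) for i, j in zip(iu[d < cutoff], ju[d < cutoff])]

    # connected components
    n = len(positions)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in bonds:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = {}
    mol_ids = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        mol_ids[i] = roots.setdefault(r, len(roots))
    return bonds, mol_ids


def enumerate_internals(bonds, n_atoms: int | None = None,
                        include_angles: bool = True,
                        include_dihedrals: bool = True):
    """Enumerate angles and dihedrals from a bond list.

    Angles are all length-2 paths i-j-k (vertex j); dihedrals all length-3
    paths i-j-k-l with four distinct atoms.  Both are deduplicated up to
    reversal.  Returns ``(angles, dihedrals)``.
    """
    adj: dict[int, set] = {}
    for i, j in bonds:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)

    angles = []
    if include_angles:
        for j in sorted(adj):
            nb = sorted(adj[j])
            for a in range(len(nb)):
                for b in range(a + 1, len(nb)):
                    angles.append((nb[a], j, nb[b]))

    dihedrals = []
    if include_dihedrals:
        seen = set()
        for j, k in list(bonds) + [(k, j) for j, k in bonds]:
            for i in adj.get(j, ()):
                if i == k:
                    continue
                for l in adj.get(k, ()):
                    if l == j or l == i:
                        continue
                    key = (i, j, k, l) if (j, k, i, l) <= (k, j, l, i) else (l, k, j, i)
                    if key not in seen:
                        seen.add(key)
                        dihedrals.append(key)
    return angles, dihedrals


def build_topology(positions, elements, cell=None, scale: float = 1.2,
                   include_angles: bool = True, include_dihedrals: bool = True,
                   masses=None) -> Topology:
    """Detect bonds and enumerate all internal coordinates in one call."""
    bonds, mol_ids = detect_bonds(positions, elements, cell, scale)
    angles, dihedrals = enumerate_internals(
        bonds, len(elements), include_angles, include_dihedrals)
    if masses is None:
        try:
            masses = np.array([ATOMIC_MASSES[e] for e in elements])
        except KeyError as exc:
            raise UnknownElementError(
                f"no atomic mass for element {exc.args[0]!r}") from exc
    else:
        masses = np.asarray(masses, float)
    topo = Topology(list(elements), masses, mol_ids, bonds, angles, dihedrals)
    topo.validate()
    return topo
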