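"""Molecular topology, internal-coordinate geometry and torsion CV selection.

A :class:`Molecule` is an ordered list of element symbols plus a bond graph
with single/multiple-order flags; a :class:`Conformation` attaches Cartesian
coordinates (A).  Internal coordinates (bonds, angles, proper dihedrals) are
enumerated from the bond graph and measured with the IUPAC sign convention
for dihedrals, range (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .constants import ATOMIC_MASSES, ELEMENTS


class TopologyError(ValueError):
    """Invalid molecule specification (unknown element, bad bond index...)."""


class DegenerateGeometryError(ValueError):
    """Raised when a dihedral is undefined because three atoms are collinear."""


@dataclass(frozen=True)
class Molecule:
    """Elements + bond graph.  Atom order is the order of ``elements``."""

    name: str
    elements: tuple[str, ...]
    #: canonical bond set: sorted (i, j) -> integer bond order (1 = single)
    bonds: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[e] for e in self.elements])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        for (i, j), order in self.bonds.items():
            g.add_edge(i, j, order=order)
        return g

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def heavy_atom_count(self) -> int:
        return sum(1 for e in self.elements if e != "H")


@dataclass
class Conformation:
    """Cartesian coordinates of one molecule, with a provenance tag."""

    molecule: Molecule
    coordinates: np.ndarray  # (N, 3), Angstrom
    provenance: str = "fixture"  # relaxation-path | md | biased-md | scan | fixture

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (self.molecule.n_atoms, 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{self.molecule.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")

    def copy(self, provenance: str | None = None) -> "Conformation":
        return Conformation(
            self.molecule,
            self.coordinates.copy(),
            provenance or self.provenance,
        )


@dataclass(frozen=True)
class InternalCoords:
    """Enumerated internal-coordinate terms of a molecule."""

    bonds: tuple[tuple[int, int], ...]
    angles: tuple[tuple[int, int, int], ...]
    dihedrals: tuple[tuple[int, int, int, int], ...]


def build_molecule(
    elements: Sequence[str],
    bonds: Iterable[tuple[int, int] | tuple[int, int, int]],
    name: str = "mol",
) -> Molecule:
    """Construct a Molecule, canonicalizing the bond set.

    ``bonds`` entries are ``(i, j)`` or ``(i, j, order)``; duplicates under
    index reversal collapse to one canonical bond.  Elements outside the
    supported 8-element alphabet are rejected by name.
    """
    elements = tuple(elements)
    for e in elements:
        if e not in ELEMENTS:
            raise TopologyError(f"unsupported element symbol: {e!r}")
    n = len(elements)
    canon: dict[tuple[int, int], int] = {}
    for entry in bonds:
        if len(entry) == 2:
            i, j = entry  # type: ignore[misc]
            order = 1
        else:
            i, j, order = entry  # type: ignore[misc]
        if not (0 <= i < n and 0 <= j < n):
            raise TopologyError(f"bond index out of range: ({i}, {j}) with {n} atoms")
        if i == j:
            raise TopologyError(f"self-loop bond on atom {i}")
        key = (min(i, j), max(i, j))
        canon[key] = int(order)
    return Molecule(name=name, elements=elements, bonds=dict(sorted(canon.items())))


def enumerate_internal_coords(mol: Molecule) -> InternalCoords:
    """All bonds, angle triples and proper dihedrals, lexicographically ordered.

    Angles are (i, j, k) with j the central atom and i < k; dihedrals run
    around each bond (j, k) with outer atoms i, l; each term appears once
    (the orientation with the lexicographically smaller index tuple wins).
    """
    bonds = tuple(sorted(mol.bonds))
    nbrs = {i: mol.neighbors(i) for i in range(mol.n_atoms)}

    angles = []
    for j in range(mol.n_atoms):
        nb = nbrs[j]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                angles.append((nb[a], j, nb[b]))
    angles.sort()

    dihedrals = set()
    for (j, k) in bonds:
        for i in nbrs[j]:
            if i == k:
                continue
            for l in nbrs[k]:
                if l == j or l == i:
                    continue
                term = (i, j, k, l)
                rev = (l, k, j, i)
                dihedrals.add(min(term, rev))
    return InternalCoords(bonds=bonds, angles=tuple(angles), dihedrals=tuple(sorted(dihedrals)))


# ---------------------------------------------------------------------------
# geometry: values and analytic gradients
# ---------------------------------------------------------------------------

_DEGENERATE_TOL = 1e-10


def wrap_angle(deg: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle in degrees to the interval (-180, 180]."""
    wrapped = -np.mod(-np.asarray(deg) + 180.0, 360.0) + 180.0
    return float(wrapped) if np.isscalar(deg) else wrapped


def bond_length(coords: np.ndarray, i: int, j: int) -> float:
    return float(np.linalg.norm(coords[j] - coords[i]))


def bond_angle(coords: np.ndarray, i: int, j: int, k: int) -> float:
    """Angle i-j-k in degrees, in [0, 180]."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _DEGENERATE_TOL or nv < _DEGENERATE_TOL:
        raise DegenerateGeometryError(f"coincident atoms in angle ({i},{j},{k})")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def dihedral_angle(
    coords: np.ndarray, i: int, j: int, k: int, l: int, strict: bool = True
) -> float | None:
    """Proper dihedral i-j-k-l in degrees, IUPAC convention, (-180, 180].

    Collinear j-k with either outer bond makes the torsion undefined; with
    ``strict`` a :class:`DegenerateGeometryError` is raised, otherwise None
    is returned (never a silent NaN).
    """
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _DEGENERATE_TOL or np.linalg.norm(n2) < _DEGENERATE_TOL:
        if strict:
            raise DegenerateGeometryError(
                f"collinear atoms make dihedral ({i},{j},{k},{l}) undefined"
            )
        return None
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    phi = np.degrees(np.arctan2(y, x))
    return float(wrap_angle(phi))


def dihedral_gradient(
    coords: np.ndarray, i: int, j: int, k: int, l: int
) -> tuple[float, np.ndarray]:
    """Dihedral value (radians) and its gradient w.r.t. all coordinates.

    Returns ``(phi_rad, grad)`` where ``grad`` has shape (N, 3) and is zero
    off the four participating atoms.  Standard analytic formulas in terms
    of the two plane normals.
    """
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1sq = float(np.dot(n1, n1))
    n2sq = float(np.dot(n2, n2))
    nb2 = float(np.linalg.norm(b2))
    if n1sq < _DEGENERATE_TOL**2 or n2sq < _DEGENERATE_TOL**2 or nb2 < _DEGENERATE_TOL:
        raise DegenerateGeometryError(
            f"collinear atoms make dihedral ({i},{j},{k},{l}) undefined"
        )
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / nb2))
    phi = float(np.arctan2(y, x))

    dphi_di = -nb2 / n1sq * n1
    dphi_dl = nb2 / n2sq * n2
    s12 = float(np.dot(b1, b2)) / (nb2 * nb2)
    s32 = float(np.dot(b3, b2)) / (nb2 * nb2)
    dphi_dj = -(1.0 + s12) * dphi_di + s32 * dphi_dl
    dphi_dk = s12 * dphi_di - (1.0 + s32) * dphi_dl

    grad = np.zeros_like(coords)
    grad[i] = dphi_di
    grad[j] = dphi_dj
    grad[k] = dphi_dk
    grad[l] = dphi_dl
    return phi, grad


def angle_gradient(
    coords: np.ndarray, i: int, j: int, k: int
) -> tuple[float, np.ndarray]:
    """Angle value (radians) and gradient (N, 3) for term i-j-k."""
    u = coords[i] - coords[j]
    v = coords[k] - coords[j]
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu < _DEGENERATE_TOL or nv < _DEGENERATE_TOL:
        raise DegenerateGeometryError(f"coincident atoms in angle ({i},{j},{k})")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    theta = float(np.arccos(c))
    s = np.sqrt(max(1.0 - c * c, 1e-14))
    dtheta_du = (c * u / nu - v / nv) / (nu * s)
    dtheta_dv = (c * v / nv - u / nu) / (nv * s)
    grad = np.zeros_like(coords)
    grad[i] = dtheta_du
    grad[k] = dtheta_dv
    grad[j] = -(dtheta_du + dtheta_dv)
    return theta, grad


def measure(conf: Conformation, term: Sequence[int]) -> float:
    """Measure a bond (A), angle or dihedral (degrees) on a conformation."""
    coords = conf.coordinates
    term = tuple(term)
    if len(term) == 2:
        return bond_length(coords, *term)
    if len(term) == 3:
        return bond_angle(coords, *term)
    if len(term) == 4:
        return dihedral_angle(coords, *term, strict=True)  # type: ignore[return-value]
    raise ValueError(f"internal-coordinate term must have 2-4 indices, got {term}")


# ---------------------------------------------------------------------------
# torsion CV selection
# ---------------------------------------------------------------------------


def select_torsion_cvs(mol: Molecule) -> list[tuple[int, int, int, int]]:
    """One representative dihedral per rotatable bond.

    A bond is eligible as a torsion collective variable when it is a single
    bond, both endpoints have at least one further neighbor, and the bond is
    not part of any cycle (ring torsions cannot be scanned rigidly).  The
    representative outer atoms are the lowest-index neighbors on each side.
    """
    g = mol.graph()
    bridges = set(frozenset(e) for e in nx.bridges(g)) if g.number_of_edges() else set()
    cvs = []
    for (j, k), order in sorted(mol.bonds.items()):
        if order != 1:
            continue
        if g.degree[j] < 2 or g.degree[k] < 2:
            continue
        if frozenset((j, k)) not in bridges:
            continue  # bond lies on a cycle
        i = min(a for a in mol.neighbors(j) if a != k)
        l = min(a for a in mol.neighbors(k) if a != j)
        cvs.append((i, j, k, l))
    return cvs


def torsion_grid(
    increment: float, span: float = 360.0, origin: float = 0.0
) -> np.ndarray:
    """Equally spaced dihedral targets: span/increment angles from ``origin``.

    The increment must divide the span exactly.  Angles are wrapped to
    (-180, 180].
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    ratio = span / increment
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"increment {increment} does not divide span {span}")
    n = int(round(ratio))
    return wrap_angle(origin + increment * np.arange(n))
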