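"""Synthetic fixture generator: parameterized toy molecules with declared
torsional barriers.

Fixture molecules are toys, not real chemistry — element labels matter only
for masses and descriptor channels.  Four families emulate the structural
motifs of drug-like sets: plain heavy-atom chains, six-rings with a tail,
biaryl-like ring pairs joined by one rotatable bond, and multi-torsion
chains.  Each rotatable bond (torsion CV) carries a two-fold Fourier term
with V2 = barrier/2, so a constrained scan of the oracle reproduces the
declared barrier height; the ideal geometry itself defines the bond and
angle reference values, so every enumerated bonded term is parameterized.
Nonbonded interactions are off by default to keep declared barriers exact;
they can be enabled for richer demos.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .active_learning import FixtureSystem
from .moltopo import (
    Conformation,
    Molecule,
    bond_angle,
    bond_length,
    build_molecule,
    enumerate_internal_coords,
    select_torsion_cvs,
)
from .oracle import ForceFieldParams

FAMILIES = ("chain", "ring-with-tail", "biaryl-like", "multi-torsion")

_BOND_K = 300.0  # kcal/mol/A^2
_ANGLE_K = 60.0  # kcal/mol/rad^2


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one toy molecule.

    ``size`` is the heavy-atom count (chain families) and is ignored for
    the ring families, whose size is fixed by the motif.  ``barriers``
    gives the torsional barrier height (kcal/mol) for each rotatable bond
    in CV order; a single value is broadcast.
    """

    family: str = "chain"
    size: int = 4
    barriers: tuple[float, ...] = (3.0,)
    seed: int = 0
    name: str = ""
    jitter: float = 0.03  # A, seeded displacement of the start conformation
    nonbonded: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown fixture family {self.family!r}")


def _chain_coords(n: int, d: float = 1.53, theta: float = 111.0) -> np.ndarray:
    """Zigzag chain in the xy plane with small z offsets to break planarity."""
    half = np.radians(theta) / 2.0
    coords = np.zeros((n, 3))
    for i in range(n):
        coords[i] = (i * d * np.sin(half), (i % 2) * d * np.cos(half), 0.12 * (i % 3))
    return coords


def _hexagon(center: np.ndarray, radius: float = 1.4, phase: float = 0.0,
             twist: float = 0.0) -> np.ndarray:
    """Planar six-ring, optionally twisted out of the xy plane about x."""
    pts = []
    for k in range(6):
        a = np.radians(phase + 60.0 * k)
        local = np.array([np.cos(a), np.sin(a) * np.cos(twist), np.sin(a) * np.sin(twist)])
        pts.append(center + radius * local)
    return np.array(pts)


def _topology_and_ideal(spec: FixtureSpec) -> tuple[Molecule, np.ndarray]:
    if spec.family in ("chain", "multi-torsion"):
        n = spec.size
        # chains of 2-3 atoms are valid torsion-free toys; multi-torsion
        # needs at least two rotatable bonds
        minimum = 2 if spec.family == "chain" else 5
        if n < minimum:
            raise ValueError(f"{spec.family} fixture needs at least {minimum} atoms")
        elements = ["C"] * n
        bonds = [(i, i + 1) for i in range(n - 1)]
        coords = _chain_coords(n)
    elif spec.family == "ring-with-tail":
        elements = ["C"] * 8
        bonds = [(i, (i + 1) % 6) for i in range(6)] + [(0, 6), (6, 7)]
        ring = _hexagon(np.zeros(3))
        tail = np.array([[2.9, 0.0, 0.35], [3.9, 0.9, 0.7]])
        coords = np.vstack([ring, tail])
    else:  # biaryl-like
        elements = ["C"] * 12
        ring_a = _hexagon(np.zeros(3))
        center_b = np.array([1.4 + 1.5 + 1.4, 0.0, 0.0])
        ring_b = _hexagon(center_b, phase=180.0, twist=np.radians(40.0))
        bonds = (
            [(i, (i + 1) % 6) for i in range(6)]
            + [(6 + i, 6 + (i + 1) % 6) for i in range(6)]
            + [(0, 6)]
        )
        coords = np.vstack([ring_a, ring_b])
    mol = build_molecule(elements, bonds, name=spec.name or f"{spec.family}-{spec.seed}")
    return mol, coords


def make_fixture(spec: FixtureSpec) -> FixtureSystem:
    """Build a toy molecule, its oracle parameters and a start conformation.

    Deterministic for a fixed seed.  Rejects specs whose declared barriers
    have no rotatable bond to live on.
    """
    mol, ideal = _topology_and_ideal(spec)
    ic = enumerate_internal_coords(mol)
    cvs = select_torsion_cvs(mol)
    if spec.barriers and not cvs:
        raise ValueError(
            f"fixture spec declares torsion barriers but the "
            f"{spec.family!r} topology has no rotatable bond"
        )

    barriers = spec.barriers
    if len(barriers) == 1 and len(cvs) > 1:
        barriers = barriers * len(cvs)
    if len(barriers) != len(cvs):
        raise ValueError(
            f"{len(barriers)} barriers declared for {len(cvs)} rotatable bonds"
        )

    bond_params = {
        (i, j): (_BOND_K, bond_length(ideal, i, j)) for i, j in ic.bonds
    }
    angle_params = {
        t: (_ANGLE_K, np.radians(bond_angle(ideal, *t))) for t in ic.angles
    }
    dihedral_params = {
        cv: ((barrier / 2.0, 2, np.pi),) for cv, barrier in zip(cvs, barriers)
    }
    n = mol.n_atoms
    params = ForceFieldParams(
        bond=bond_params,
        angle=angle_params,
        dihedral=dihedral_params,
        epsilon=(0.05,) * n if spec.nonbonded else (),
        sigma=(3.2,) * n if spec.nonbonded else (),
        charges=(0.0,) * n if spec.nonbonded else (),
    )

    rng = np.random.default_rng(spec.seed)
    start = ideal + spec.jitter * rng.standard_normal(ideal.shape)
    return FixtureSystem(
        molecule=mol,
        params=params,
        start=Conformation(mol, start, provenance="fixture"),
    )


def default_fixture_suite(seed: int = 0) -> list[FixtureSystem]:
    """The fixture molecules the loop demos and tests run on."""
    return [
        make_fixture(FixtureSpec("chain", size=4, barriers=(3.0,), seed=seed, name="chain4")),
        make_fixture(FixtureSpec("chain", size=5, barriers=(4.0,), seed=seed + 1, name="chain5")),
        make_fixture(
            FixtureSpec("biaryl-like", barriers=(6.0,), seed=seed + 2, name="biaryl")
        ),
    ]
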