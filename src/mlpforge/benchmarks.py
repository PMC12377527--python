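"""Evaluation suite: torsion-profile metrics, geometry comparison, MD errors.

Implements the standard accuracy metrics used to compare a surrogate
potential against a reference method:

* torsion-profile MAE / RMSE over relative energies on a shared dihedral
  grid (per-profile bin average first, then average over molecules — the
  RMSE takes the root per molecule before averaging);
* MAEB, the mean absolute error of torsional barrier heights (barrier =
  max - min of each profile), and NABH, the number of profiles whose
  barrier error exceeds a chemical-accuracy threshold (strictly more than
  1 kcal/mol by default);
* Kabsch-superposition RMSD and internal-coordinate MAEs for relaxed
  structures (dihedral differences use the circular metric);
* MD trajectory error statistics: relative-energy and force-component
  MAE/RMSE plus the per-frame aggregate force-error magnitude
  ||dF|| = sqrt(1/N sum_i |dF_i|^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .moltopo import (
    DegenerateGeometryError,
    Molecule,
    bond_angle,
    bond_length,
    dihedral_angle,
    enumerate_internal_coords,
)
from .oracle import LabeledFrame


@dataclass
class TorsionProfile:
    """Energy versus dihedral angle for one molecule, possibly per method."""

    molecule_id: str
    dihedral: tuple[int, int, int, int]
    angles: np.ndarray  # degrees, one period
    energies: dict[str, np.ndarray] = field(default_factory=dict)  # kcal/mol
    converged: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        for label, e in self.energies.items():
            e = np.asarray(e, dtype=float)
            if e.shape != self.angles.shape:
                raise ValueError(f"energies[{label!r}] not aligned with angles")
            self.energies[label] = e

    @property
    def n_bins(self) -> int:
        return len(self.angles)


@dataclass
class TorsionProfile2D:
    """Energy on the outer grid of two dihedrals."""

    molecule_id: str
    dihedral_a: tuple[int, int, int, int]
    dihedral_b: tuple[int, int, int, int]
    angles_a: np.ndarray
    angles_b: np.ndarray
    energies: np.ndarray  # (n_a, n_b)
    converged: np.ndarray

    @property
    def n_structures(self) -> int:
        return int(self.energies.size)


# ---------------------------------------------------------------------------
# relative energies and profile metrics
# ---------------------------------------------------------------------------

RELATIVE_CONVENTIONS = ("first_point", "minimum", "first_frame")


def relative_energies(energies: Sequence[float], convention: str) -> np.ndarray:
    """Shift an energy array to the convention's reference point.

    ``first_point``/``first_frame`` subtract element 0 (the two names exist
    because torsion work and MD work phrase the same operation differently);
    ``minimum`` subtracts the array minimum.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy array")
    if convention in ("first_point", "first_frame"):
        return e - e[0]
    if convention == "minimum":
        return e - e.min()
    raise ValueError(f"unknown relative-energy convention {convention!r}")


def _matched_pairs(
    profiles_ml: Sequence[TorsionProfile],
    profiles_ref: Sequence[TorsionProfile],
    label_ml: str,
    label_ref: str,
) -> list[tuple[np.ndarray, np.ndarray]]:
    if len(profiles_ml) != len(profiles_ref):
        raise ValueError("profile sets differ in length")
    pairs = []
    for pm, pr in zip(profiles_ml, profiles_ref):
        if pm.n_bins != pr.n_bins or not np.allclose(pm.angles, pr.angles):
            raise ValueError(f"angle grids differ for molecule {pm.molecule_id!r}")
        pairs.append((pm.energies[label_ml], pr.energies[label_ref]))
    return pairs


def profile_metrics(
    profiles_ml: Sequence[TorsionProfile],
    profiles_ref: Sequence[TorsionProfile],
    convention: str = "first_point",
    label_ml: str = "ml",
    label_ref: str = "ref",
) -> tuple[float, float]:
    """Torsion-profile (MAE, RMSE) in kcal/mol over matched profile sets.

    Both metrics average per-molecule bin statistics over molecules; the
    RMSE takes the square root of the per-molecule bin-mean square before
    the molecule average (not a pooled RMSE).
    """
    pairs = _matched_pairs(profiles_ml, profiles_ref, label_ml, label_ref)
    maes, rmses = [], []
    for e_ml, e_ref in pairs:
        d = relative_energies(e_ref, convention) - relative_energies(e_ml, convention)
        maes.append(np.mean(np.abs(d)))
        rmses.append(np.sqrt(np.mean(d**2)))
    return float(np.mean(maes)), float(np.mean(rmses))


@dataclass
class BarrierReport:
    barriers_ml: np.ndarray
    barriers_ref: np.ndarray
    errors: np.ndarray  # ref - ml, per molecule
    maeb: float
    nabh: int
    threshold: float


def barrier_metrics(
    profiles_ml: Sequence[TorsionProfile],
    profiles_ref: Sequence[TorsionProfile],
    threshold: float = 1.0,
    label_ml: str = "ml",
    label_ref: str = "ref",
) -> BarrierReport:
    """Barrier-height comparison: MAEB and the NABH count.

    The barrier of a profile is max - min of its energies; NABH counts
    molecules whose absolute barrier error is strictly greater than
    ``threshold`` (default 1 kcal/mol, chemical accuracy).
    """
    pairs = _matched_pairs(profiles_ml, profiles_ref, label_ml, label_ref)
    b_ml = np.array([float(e.max() - e.min()) for e, _ in pairs])
    b_ref = np.array([float(e.max() - e.min()) for _, e in pairs])
    errors = b_ref - b_ml
    return BarrierReport(
        barriers_ml=b_ml,
        barriers_ref=b_ref,
        errors=errors,
        maeb=float(np.mean(np.abs(errors))),
        nabh=int(np.sum(np.abs(errors) > threshold)),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# geometry comparison
# ---------------------------------------------------------------------------


def kabsch_rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Minimum RMSD (A) over rigid superpositions (proper rotations only)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape[0] != a.shape[0] or mask.shape[0] != b.shape[0]:
            raise ValueError("mask length does not match coordinates")
        a, b = a[mask], b[mask]
    if a.shape != b.shape:
        raise ValueError("coordinate arrays differ in shape")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot, _ = Rotation.align_vectors(a, b)
    resid = a - rot.apply(b)  # recompute residual: scipy's rssd loses
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))  # precision near 0


def circular_difference(deg_a: float, deg_b: float) -> float:
    """Smallest absolute angular difference, in [0, 180]."""
    d = abs(deg_a - deg_b) % 360.0
    return min(d, 360.0 - d)


@dataclass
class GeometryDiffReport:
    rmsd: float
    bond_mae: float  # A
    angle_mae: float  # degrees, compared on [0, 180] without wrapping
    torsion_mae: float  # degrees, circular metric
    n_bonds: int
    n_angles: int
    n_torsions: int
    n_skipped_torsions: int  # degenerate (collinear) in either structure


def internal_coord_maes(
    mol: Molecule, coords_a: np.ndarray, coords_b: np.ndarray
) -> GeometryDiffReport:
    """Bond/angle/torsion MAEs between two conformations of one molecule."""
    ic = enumerate_internal_coords(mol)
    bond_d = [
        abs(bond_length(coords_a, i, j) - bond_length(coords_b, i, j))
        for i, j in ic.bonds
    ]
    angle_d = [
        abs(bond_angle(coords_a, *t) - bond_angle(coords_b, *t)) for t in ic.angles
    ]
    tors_d = []
    skipped = 0
    for t in ic.dihedrals:
        da = dihedral_angle(coords_a, *t, strict=False)
        db = dihedral_angle(coords_b, *t, strict=False)
        if da is None or db is None:
            skipped += 1
            continue
        tors_d.append(circular_difference(da, db))
    return GeometryDiffReport(
        rmsd=kabsch_rmsd(coords_a, coords_b),
        bond_mae=float(np.mean(bond_d)) if bond_d else 0.0,
        angle_mae=float(np.mean(angle_d)) if angle_d else 0.0,
        torsion_mae=float(np.mean(tors_d)) if tors_d else 0.0,
        n_bonds=len(bond_d),
        n_angles=len(angle_d),
        n_torsions=len(tors_d),
        n_skipped_torsions=skipped,
    )


# ---------------------------------------------------------------------------
# MD trajectory error statistics
# ---------------------------------------------------------------------------


@dataclass
class TrajErrorReport:
    energy_mae: float  # relative energies, kcal/mol
    energy_rmse: float
    force_component_mae: float  # all 3N components pooled, kcal/mol/A
    force_component_rmse: float
    force_magnitude_series: np.ndarray  # per-frame ||dF||
    force_magnitude_mae: float
    force_magnitude_rmse: float


def frame_force_magnitude(delta_forces: np.ndarray) -> float:
    """Aggregate force-error magnitude of one frame.

    ||dF|| = sqrt( (1/N) sum_i (dF_ix^2 + dF_iy^2 + dF_iz^2) ).
    """
    d = np.asarray(delta_forces, dtype=float)
    return float(np.sqrt(np.sum(d**2) / d.shape[0]))


def traj_error_stats(
    frames_ref: Sequence[LabeledFrame], frames_ml: Sequence[LabeledFrame]
) -> TrajErrorReport:
    """Error statistics between two labelings of the same trajectory.

    Relative energies are taken against each method's own first frame
    before differencing, so constant per-method energy offsets cancel.
    """
    if len(frames_ref) != len(frames_ml) or len(frames_ref) == 0:
        raise ValueError("frame lists must be non-empty and aligned")
    n_atoms = frames_ref[0].forces.shape[0]
    for fr, fm in zip(frames_ref, frames_ml):
        if fr.forces.shape != (n_atoms, 3) or fm.forces.shape != (n_atoms, 3):
            raise ValueError("frame lists are not aligned on one molecule")

    e_ref = relative_energies([f.energy for f in frames_ref], "first_frame")
    e_ml = relative_energies([f.energy for f in frames_ml], "first_frame")
    de = e_ref - e_ml

    df = np.stack([fr.forces - fm.forces for fr, fm in zip(frames_ref, frames_ml)])
    comps = df.reshape(-1)
    mags = np.array([frame_force_magnitude(d) for d in df])
    return TrajErrorReport(
        energy_mae=float(np.mean(np.abs(de))),
        energy_rmse=float(np.sqrt(np.mean(de**2))),
        force_component_mae=float(np.mean(np.abs(comps))),
        force_component_rmse=float(np.sqrt(np.mean(comps**2))),
        force_magnitude_series=mags,
        force_magnitude_mae=float(np.mean(np.abs(mags))),
        force_magnitude_rmse=float(np.sqrt(np.mean(mags**2))),
    )
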