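"""Analytic reference force field used as the labeling oracle.

The workflow needs a ground-truth source of energies and forces to play the
role that an ab initio labeler plays in production pipelines.  Here that
role is filled by a classical force field with harmonic bonds and angles,
Fourier torsions, Lennard-Jones and Coulomb nonbonded terms — smooth
everywhere, with exact analytic gradients, and cheap enough to label
thousands of frames per second.  "Degraded" copies of the oracle
(:func:`perturb_params`) serve as lower-accuracy comparator methods in the
benchmark demos.

Functional forms (all energies kcal/mol, lengths A, angles internally rad):

* bond      ``E = k_b (r - r0)^2``
* angle     ``E = k_a (theta - theta0)^2``
* torsion   ``E = sum_n V_n (1 + cos(n phi - gamma_n))``
* LJ        ``E = 4 eps [(sigma/r)^12 - (sigma/r)^6]``, Lorentz-Berthelot
* Coulomb   ``E = 332.0637 q_i q_j / r``

Nonbonded pairs separated by one or two bonds are excluded; 1-4 pairs are
scaled.  Torsion entries may be omitted for individual dihedrals (they then
contribute zero, the usual force-field convention); bond and angle terms
must be parameterized for every enumerated term.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .moltopo import Conformation, Molecule, enumerate_internal_coords

COULOMB_K = 332.0637  # kcal mol^-1 A e^-2


class MissingParameterError(KeyError):
    """A bonded term of the molecule has no force-field parameters."""


@dataclass(frozen=True)
class ForceFieldParams:
    """Per-term force-field parameters for one molecule.

    Bond and angle keys are canonical index tuples (sorted endpoints for
    bonds; angle (i, j, k) with i < k); dihedral keys follow the canonical
    orientation of :func:`mlpforge.moltopo.enumerate_internal_coords`.
    """

    bond: Mapping[tuple[int, int], tuple[float, float]]  # (k_b, r0)
    angle: Mapping[tuple[int, int, int], tuple[float, float]]  # (k_a, theta0 rad)
    dihedral: Mapping[tuple[int, int, int, int], tuple[tuple[float, int, float], ...]] = field(
        default_factory=dict
    )  # ((V_n, n, gamma rad), ...)
    epsilon: tuple[float, ...] = ()  # per-atom LJ well depth
    sigma: tuple[float, ...] = ()  # per-atom LJ diameter
    charges: tuple[float, ...] = ()  # per-atom partial charge, e
    scale14_lj: float = 0.5
    scale14_coul: float = 1.0 / 1.2

    def validate(self) -> None:
        for key, (kb, r0) in self.bond.items():
            if kb < 0 or r0 < 0:
                raise ValueError(f"negative bond parameter for {key}")
        for key, (ka, _) in self.angle.items():
            if ka < 0:
                raise ValueError(f"negative angle constant for {key}")
        for key, terms in self.dihedral.items():
            for (_, n, _) in terms:
                if int(n) < 1:
                    raise ValueError(f"non-positive periodicity in dihedral {key}")
        if any(e < 0 for e in self.epsilon) or any(s < 0 for s in self.sigma):
            raise ValueError("negative Lennard-Jones parameter")


def _canonical_angle(t: tuple[int, int, int]) -> tuple[int, int, int]:
    i, j, k = t
    return (i, j, k) if i < k else (k, j, i)


def _canonical_dihedral(t: tuple[int, int, int, int]) -> tuple[int, int, int, int]:
    return min(t, tuple(reversed(t)))  # type: ignore[return-value]


class ForceFieldEvaluator:
    """Precompiled evaluator for one (molecule, params) pair.

    Builds flat index/parameter arrays once so that repeated
    ``energy_forces`` calls during dynamics are vectorized numpy work.
    """

    def __init__(self, mol: Molecule, params: ForceFieldParams):
        params.validate()
        self.mol = mol
        self.params = params
        ic = enumerate_internal_coords(mol)

        try:
            bond_terms = [(i, j, *params.bond[(i, j)]) for i, j in ic.bonds]
        except KeyError as exc:
            raise MissingParameterError(f"no bond parameters for term {exc.args[0]}") from exc
        self._b_i = np.array([t[0] for t in bond_terms], dtype=int)
        self._b_j = np.array([t[1] for t in bond_terms], dtype=int)
        self._b_k = np.array([t[2] for t in bond_terms])
        self._b_r0 = np.array([t[3] for t in bond_terms])

        angle_params = {_canonical_angle(k): v for k, v in params.angle.items()}
        try:
            ang = [(i, j, k, *angle_params[(i, j, k)]) for i, j, k in ic.angles]
        except KeyError as exc:
            raise MissingParameterError(f"no angle parameters for term {exc.args[0]}") from exc
        self._a_idx = np.array([t[:3] for t in ang], dtype=int).reshape(-1, 3)
        self._a_k = np.array([t[3] for t in ang])
        self._a_t0 = np.array([t[4] for t in ang])

        dih_params = {_canonical_dihedral(k): v for k, v in params.dihedral.items()}
        unknown = set(dih_params) - set(ic.dihedrals)
        if unknown:
            raise MissingParameterError(f"dihedral parameters for non-existent term {sorted(unknown)[0]}")
        d_idx, d_v, d_n, d_g = [], [], [], []
        for term in ic.dihedrals:
            for (vn, n, gamma) in dih_params.get(term, ()):
                d_idx.append(term)
                d_v.append(vn)
                d_n.append(int(n))
                d_g.append(gamma)
        self._d_idx = np.array(d_idx, dtype=int).reshape(-1, 4)
        self._d_v = np.array(d_v)
        self._d_n = np.array(d_n)
        self._d_g = np.array(d_g)

        self._build_nonbonded()

    def _build_nonbonded(self) -> None:
        mol, params = self.mol, self.params
        n = mol.n_atoms
        has_nb = len(params.epsilon) == n and len(params.sigma) == n
        self._nb_i = np.zeros(0, dtype=int)
        self._nb_j = np.zeros(0, dtype=int)
        if not has_nb or n < 2:
            self._nb_eps = np.zeros(0)
            self._nb_sig = np.zeros(0)
            self._nb_qq = np.zeros(0)
            return
        g = mol.graph()
        dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=3))
        eps = np.asarray(params.epsilon)
        sig = np.asarray(params.sigma)
        q = np.asarray(params.charges) if len(params.charges) == n else np.zeros(n)
        ii, jj, ee, ss, qq = [], [], [], [], []
        for i in range(n):
            for j in range(i + 1, n):
                d = dist.get(i, {}).get(j, 99)
                if d <= 2:
                    continue  # 1-2 / 1-3 exclusion
                w_lj = params.scale14_lj if d == 3 else 1.0
                w_c = params.scale14_coul if d == 3 else 1.0
                ii.append(i)
                jj.append(j)
                ee.append(w_lj * np.sqrt(eps[i] * eps[j]))
                ss.append(0.5 * (sig[i] + sig[j]))
                qq.append(w_c * COULOMB_K * q[i] * q[j])
        self._nb_i = np.array(ii, dtype=int)
        self._nb_j = np.array(jj, dtype=int)
        self._nb_eps = np.array(ee)
        self._nb_sig = np.array(ss)
        self._nb_qq = np.array(qq)

    # -- evaluation -------------------------------------------------------

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Total energy (kcal/mol) and forces (kcal/mol/A) at ``coords``."""
        coords = np.asarray(coords, dtype=float)
        energy = 0.0
        forces = np.zeros_like(coords)

        if self._b_i.size:
            dv = coords[self._b_j] - coords[self._b_i]
            r = np.linalg.norm(dv, axis=1)
            dr = r - self._b_r0
            energy += float(np.sum(self._b_k * dr**2))
            dEdr = 2.0 * self._b_k * dr
            fvec = (dEdr / r)[:, None] * dv
            np.add.at(forces, self._b_i, fvec)
            np.add.at(forces, self._b_j, -fvec)

        if self._a_idx.size:
            i, j, k = self._a_idx[:, 0], self._a_idx[:, 1], self._a_idx[:, 2]
            u = coords[i] - coords[j]
            v = coords[k] - coords[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            c = np.clip(np.einsum("md,md->m", u, v) / (nu * nv), -1.0, 1.0)
            theta = np.arccos(c)
            s = np.sqrt(np.maximum(1.0 - c * c, 1e-14))
            dt = theta - self._a_t0
            energy += float(np.sum(self._a_k * dt**2))
            dEdt = 2.0 * self._a_k * dt
            du = (c[:, None] * u / nu[:, None] - v / nv[:, None]) / (nu * s)[:, None]
            dv_ = (c[:, None] * v / nv[:, None] - u / nu[:, None]) / (nv * s)[:, None]
            np.add.at(forces, i, -dEdt[:, None] * du)
            np.add.at(forces, k, -dEdt[:, None] * dv_)
            np.add.at(forces, j, dEdt[:, None] * (du + dv_))

        if self._d_idx.size:
            i, j, k, l = (self._d_idx[:, m] for m in range(4))
            b1 = coords[j] - coords[i]
            b2 = coords[k] - coords[j]
            b3 = coords[l] - coords[k]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            n1sq = np.einsum("md,md->m", n1, n1)
            n2sq = np.einsum("md,md->m", n2, n2)
            nb2 = np.linalg.norm(b2, axis=1)
            x = np.einsum("md,md->m", n1, n2)
            y = np.einsum("md,md->m", np.cross(n1, n2), b2 / nb2[:, None])
            phi = np.arctan2(y, x)
            energy += float(np.sum(self._d_v * (1.0 + np.cos(self._d_n * phi - self._d_g))))
            dEdphi = -self._d_v * self._d_n * np.sin(self._d_n * phi - self._d_g)
            dpi = -(nb2 / n1sq)[:, None] * n1
            dpl = (nb2 / n2sq)[:, None] * n2
            s12 = (np.einsum("md,md->m", b1, b2) / nb2**2)[:, None]
            s32 = (np.einsum("md,md->m", b3, b2) / nb2**2)[:, None]
            dpj = -(1.0 + s12) * dpi + s32 * dpl
            dpk = s12 * dpi - (1.0 + s32) * dpl
            np.add.at(forces, i, -dEdphi[:, None] * dpi)
            np.add.at(forces, j, -dEdphi[:, None] * dpj)
            np.add.at(forces, k, -dEdphi[:, None] * dpk)
            np.add.at(forces, l, -dEdphi[:, None] * dpl)

        if self._nb_i.size:
            dv = coords[self._nb_j] - coords[self._nb_i]
            r = np.linalg.norm(dv, axis=1)
            sr6 = (self._nb_sig / r) ** 6
            energy += float(np.sum(4.0 * self._nb_eps * (sr6**2 - sr6)))
            energy += float(np.sum(self._nb_qq / r))
            dEdr = 4.0 * self._nb_eps * (-12.0 * sr6**2 + 6.0 * sr6) / r - self._nb_qq / r**2
            fvec = (dEdr / r)[:, None] * dv
            np.add.at(forces, self._nb_i, fvec)
            np.add.at(forces, self._nb_j, -fvec)

        return energy, forces


@dataclass
class LabeledFrame:
    """A conformation together with its reference energy and forces."""

    conformation: Conformation
    energy: float  # kcal/mol
    forces: np.ndarray  # (N, 3), kcal/mol/A
    source: str = "oracle"  # oracle | ensemble-member | degraded-oracle

    def __post_init__(self) -> None:
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.shape != (self.conformation.molecule.n_atoms, 3):
            raise ValueError("forces shape does not match atom count")
        if not np.isfinite(self.energy) or not np.all(np.isfinite(self.forces)):
            raise ValueError("non-finite label")


def ff_energy_forces(
    mol: Molecule, params: ForceFieldParams, conf: Conformation, source: str = "oracle"
) -> LabeledFrame:
    """Label one conformation with the analytic oracle."""
    ev = ForceFieldEvaluator(mol, params)
    e, f = ev.energy_forces(conf.coordinates)
    return LabeledFrame(conformation=conf, energy=e, forces=f, source=source)


def perturb_params(
    params: ForceFieldParams, scale: float, seed: int
) -> ForceFieldParams:
    """Deterministically jitter every continuous parameter by ``scale``.

    Each constant c becomes ``c * (1 + scale * g)`` with g ~ N(0, 1) drawn
    in a fixed key order from ``seed``; non-negative constants are clipped
    at zero so the perturbed field stays valid.  ``scale=0`` is the
    identity.  Used to fabricate lower-accuracy comparator methods.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    rng = np.random.default_rng(seed)

    def jit(x: float, nonneg: bool = True) -> float:
        y = x * (1.0 + scale * rng.standard_normal())
        return max(0.0, y) if nonneg else y

    bond = {k: (jit(v[0]), jit(v[1])) for k, v in sorted(params.bond.items())}
    angle = {k: (jit(v[0]), jit(v[1])) for k, v in sorted(params.angle.items())}
    dihedral = {
        k: tuple((jit(vn), n, g) for (vn, n, g) in terms)
        for k, terms in sorted(params.dihedral.items())
    }
    epsilon = tuple(jit(e) for e in params.epsilon)
    sigma = tuple(jit(s) for s in params.sigma)
    charges = tuple(jit(q, nonneg=False) for q in params.charges)
    return replace(
        params,
        bond=bond,
        angle=angle,
        dihedral=dihedral,
        epsilon=epsilon,
        sigma=sigma,
        charges=charges,
    )
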