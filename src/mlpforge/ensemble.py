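"""Committee of seeded surrogate potentials for query-by-committee selection.

Each committee member is an atomic-environment regressor: smooth radial
descriptors with per-element channels (plus a rotation-invariant vector
moment that carries angular information) are passed through a fixed,
seed-drawn tanh random-feature layer, and the output weights are solved in
closed form by ridge least squares on energies and forces jointly.  The
total energy is a sum of per-atom contributions, so the model is extensive
and its forces are the exact analytic negative gradient.

Committee diversity comes from seed-dependent initialization of the random
feature layer — the mechanism the concurrent-learning loop needs for a
meaningful force model deviation — not from bagging.  Training is
deterministic: same seeds + same data (in the same order) give bitwise
identical members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import ELEMENTS
from .moltopo import Conformation, Molecule
from .oracle import LabeledFrame


@dataclass(frozen=True)
class DescriptorConfig:
    """Smooth radial descriptor with per-element neighbor channels.

    ``cutoff`` (A) bounds the atomic environment; descriptor values and
    their coordinate gradients go smoothly to zero there via the cosine
    cutoff function fc(r) = 0.5 (cos(pi r / rc) + 1).
    """

    cutoff: float = 6.0
    n_centers: int = 10
    center_min: float = 0.8
    center_max: float | None = None  # default: cutoff - 0.8
    width_factor: float = 0.6
    elements: tuple[str, ...] = ELEMENTS
    include_vector_moment: bool = True  # angular channel: |sum_j g(r) u_ij|^2

    @property
    def centers(self) -> np.ndarray:
        hi = self.center_max if self.center_max is not None else self.cutoff - 0.8
        return np.linspace(self.center_min, hi, self.n_centers)

    @property
    def width(self) -> float:
        c = self.centers
        spacing = c[1] - c[0] if len(c) > 1 else self.cutoff / 2
        return self.width_factor * spacing

    @property
    def n_features(self) -> int:
        per_channel = self.n_centers * (2 if self.include_vector_moment else 1)
        return len(self.elements) * per_channel


def featurize(
    mol: Molecule, conf: Conformation, cfg: DescriptorConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom features and their coordinate gradients.

    Returns ``(features, grads)`` with shapes (N, D) and (N, D, N, 3);
    ``grads[i, d, a]`` is the derivative of feature d of atom i with
    respect to the position of atom a.  Features are invariant under rigid
    motion and under permutation of identical atoms; an isolated atom has
    an all-zero feature vector.
    """
    coords = np.asarray(conf.coordinates, dtype=float)
    n = mol.n_atoms
    mu = cfg.centers
    w = cfg.width
    rc = cfg.cutoff
    n_ch = len(cfg.elements)
    sel = np.zeros((n_ch, n))
    for c_idx, e in enumerate(cfg.elements):
        sel[c_idx] = [1.0 if el == e else 0.0 for el in mol.elements]

    diff = coords[None, :, :] - coords[:, None, :]  # j - i
    r = np.linalg.norm(diff, axis=-1)
    np.fill_diagonal(r, np.inf)
    inside = r < rc
    rs = np.where(inside, r, rc)  # safe radius for the smooth window
    u = np.where(inside[:, :, None], diff / rs[:, :, None], 0.0)

    fc = np.where(inside, 0.5 * (np.cos(np.pi * rs / rc) + 1.0), 0.0)
    dfc = np.where(inside, -0.5 * np.pi / rc * np.sin(np.pi * rs / rc), 0.0)
    gauss = np.exp(-((rs[:, :, None] - mu) ** 2) / (2.0 * w * w))
    g = gauss * fc[:, :, None] * inside[:, :, None]
    gp = (
        gauss * (dfc[:, :, None] - fc[:, :, None] * (rs[:, :, None] - mu) / (w * w))
    ) * inside[:, :, None]

    # radial channel
    F = np.einsum("ijm,cj->icm", g, sel)
    GF = np.einsum("ijm,ijd,cj->icmjd", gp, u, sel)
    idx = np.arange(n)
    GF[idx, :, :, idx, :] = -GF.sum(axis=3)[idx]

    feats = [F.reshape(n, -1)]
    grads = [GF.reshape(n, -1, n, 3)]

    if cfg.include_vector_moment:
        V = np.einsum("ijm,ijd,cj->icmd", g, u, sel)
        A = np.einsum("icmd,icmd->icm", V, V)
        eye = np.eye(3)
        rinv = np.where(inside, 1.0 / rs, 0.0)
        # T[i,j,m,d,e] = d(g_ijm * u_ijd)/d r_je
        T = (
            gp[:, :, :, None, None] * u[:, :, None, :, None] * u[:, :, None, None, :]
            + g[:, :, :, None, None]
            * (eye[None, None, None] - u[:, :, None, :, None] * u[:, :, None, None, :])
            * rinv[:, :, None, None, None]
        )
        GA = 2.0 * np.einsum("icmd,ijmde,cj->icmje", V, T, sel)
        GA[idx, :, :, idx, :] = -GA.sum(axis=3)[idx]
        feats.append(A.reshape(n, -1))
        grads.append(GA.reshape(n, -1, n, 3))

    return np.concatenate(feats, axis=1), np.concatenate(grads, axis=1)


# ---------------------------------------------------------------------------


@dataclass
class MemberModel:
    """One committee member: fixed random feature layer + linear readout."""

    seed: int
    W: np.ndarray  # (n_hidden, D)
    b: np.ndarray  # (n_hidden,)
    theta: np.ndarray  # per-element (bias, readout weights), flattened
    loss_history: list[float] = field(default_factory=list)


@dataclass
class EnsembleModel:
    """N_m seeded surrogate potentials sharing one descriptor config."""

    cfg: DescriptorConfig
    members: list[MemberModel]
    feat_mean: np.ndarray
    feat_scale: np.ndarray
    n_hidden: int
    trained: bool = False

    @property
    def n_members(self) -> int:
        return len(self.members)

    # -- internals --------------------------------------------------------

    def _element_index(self, mol: Molecule) -> np.ndarray:
        emap = {e: i for i, e in enumerate(self.cfg.elements)}
        return np.array([emap[e] for e in mol.elements], dtype=int)

    def _design_blocks(
        self, member: MemberModel, mol: Molecule, feats: np.ndarray, grads: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Energy row (P,) and force rows (N, 3, P) for one frame, linear in theta.

        The per-atom energy is bias + linear readout of the normalized
        descriptors + tanh random-feature readout, all element-resolved.
        The linear channel keeps force predictions (and hence committee
        disagreement) alive outside the training distribution, where the
        tanh units saturate.
        """
        n = mol.n_atoms
        z = (feats - self.feat_mean) / self.feat_scale
        h = np.tanh(z @ member.W.T + member.b)  # (N, nh)
        dz = grads / self.feat_scale[None, :, None, None]
        # dh[i, q, a, e] = (1 - h^2) * W @ dz
        dh = (1.0 - h**2)[:, :, None, None] * np.einsum("qd,idae->iqae", member.W, dz)

        nh = self.n_hidden
        D = feats.shape[1]
        p_per = 1 + D + nh
        P = len(self.cfg.elements) * p_per
        eidx = self._element_index(mol)

        erow = np.zeros(P)
        for i in range(n):
            off = eidx[i] * p_per
            erow[off] += 1.0
            erow[off + 1 : off + 1 + D] += z[i]
            erow[off + 1 + D : off + p_per] += h[i]

        frows = np.zeros((n, 3, P))
        for i in range(n):
            off = eidx[i] * p_per
            # force on atom a gets -d e_i / d r_a
            frows[:, :, off + 1 : off + 1 + D] += -np.transpose(dz[i], (1, 2, 0))
            frows[:, :, off + 1 + D : off + p_per] += -np.transpose(dh[i], (1, 2, 0))
        return erow, frows

    def member_energy_forces(
        self, member: MemberModel, mol: Molecule, conf: Conformation
    ) -> tuple[float, np.ndarray]:
        feats, grads = featurize(mol, conf, self.cfg)
        erow, frows = self._design_blocks(member, mol, feats, grads)
        e = float(erow @ member.theta)
        f = frows @ member.theta
        return e, f

    # -- public API -------------------------------------------------------

    def predict(
        self, mol: Molecule, conf: Conformation
    ) -> tuple[list[tuple[float, np.ndarray]], tuple[float, np.ndarray]]:
        """Per-member (energy, forces) and the ensemble mean."""
        if not self.trained:
            raise RuntimeError("ensemble has not been trained")
        feats, grads = featurize(mol, conf, self.cfg)
        per_member = []
        for member in self.members:
            erow, frows = self._design_blocks(member, mol, feats, grads)
            per_member.append((float(erow @ member.theta), frows @ member.theta))
        e_mean = float(np.mean([e for e, _ in per_member]))
        f_mean = np.mean([f for _, f in per_member], axis=0)
        return per_member, (e_mean, f_mean)

    def member_forces(self, mol: Molecule, conf: Conformation) -> np.ndarray:
        """Stacked per-member forces, shape (N_m, N, 3)."""
        per_member, _ = self.predict(mol, conf)
        return np.stack([f for _, f in per_member])

    def evaluator(self, mol: Molecule, member: int = 0) -> "MemberEvaluator":
        if not self.trained:
            raise RuntimeError("ensemble has not been trained")
        return MemberEvaluator(self, mol, member)


class MemberEvaluator:
    """Potential-protocol adapter: one member driving dynamics on one molecule."""

    def __init__(self, model: EnsembleModel, mol: Molecule, member: int = 0):
        self.model = model
        self.mol = mol
        self.member = model.members[member]

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        conf = Conformation(self.mol, np.asarray(coords, dtype=float), provenance="md")
        return self.model.member_energy_forces(self.member, self.mol, conf)


def _init_member(seed: int, n_hidden: int, n_features: int) -> MemberModel:
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n_hidden, n_features)) / np.sqrt(n_features)
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    n_elem = len(ELEMENTS)
    theta = np.zeros(n_elem * (1 + n_features + n_hidden))
    return MemberModel(seed=seed, W=W, b=b, theta=theta)


def train_ensemble(
    dataset: Sequence[LabeledFrame],
    cfg: DescriptorConfig,
    seeds: Sequence[int],
    warm_start: EnsembleModel | None = None,
    n_hidden: int = 64,
    ridge: float = 1.0,
    energy_weight: float = 1.0,
    force_weight: float = 1.0,
) -> EnsembleModel:
    """Fit the committee to labeled frames by joint energy+force ridge regression.

    With a warm start, each member keeps its random feature layer and its
    previous readout weights are the origin of the recorded loss history;
    normalization statistics are inherited (frozen after the first fit) so
    features remain comparable across iterations.  The recorded training
    loss (regularized energy+force objective) is non-increasing.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    if len(seeds) < 2:
        raise ValueError("committee needs at least 2 members")

    if warm_start is not None:
        if list(s.seed for s in warm_start.members) != list(seeds):
            raise ValueError("warm start member seeds do not match")
        model = EnsembleModel(
            cfg=warm_start.cfg,
            members=[
                MemberModel(m.seed, m.W, m.b, m.theta.copy(), list(m.loss_history))
                for m in warm_start.members
            ],
            feat_mean=warm_start.feat_mean,
            feat_scale=warm_start.feat_scale,
            n_hidden=warm_start.n_hidden,
        )
        cfg = warm_start.cfg
        n_hidden = warm_start.n_hidden
    else:
        members = [_init_member(s, n_hidden, cfg.n_features) for s in seeds]
        model = EnsembleModel(
            cfg=cfg,
            members=members,
            feat_mean=np.zeros(cfg.n_features),
            feat_scale=np.ones(cfg.n_features),
            n_hidden=n_hidden,
        )
        # normalization from the first training set, frozen thereafter
        all_feats = np.concatenate(
            [featurize(f.conformation.molecule, f.conformation, cfg)[0] for f in dataset]
        )
        model.feat_mean = all_feats.mean(axis=0)
        scale = all_feats.std(axis=0)
        model.feat_scale = np.where(scale > 1e-10, scale, 1.0)

    # assemble per-frame descriptor data once (shared across members)
    frame_data = []
    for frame in dataset:
        mol = frame.conformation.molecule
        feats, grads = featurize(mol, frame.conformation, cfg)
        frame_data.append((mol, feats, grads, frame.energy, frame.forces))

    we = np.sqrt(energy_weight)
    wf = np.sqrt(force_weight)
    for member in model.members:
        rows, targets = [], []
        for mol, feats, grads, energy, forces in frame_data:
            erow, frows = model._design_blocks(member, mol, feats, grads)
            rows.append(we * erow[None, :])
            targets.append([we * energy])
            rows.append(wf * frows.reshape(-1, erow.size))
            targets.append(wf * np.asarray(forces).ravel())
        A = np.concatenate(rows, axis=0)
        y = np.concatenate([np.atleast_1d(t) for t in targets])

        def objective(theta: np.ndarray) -> float:
            resid = A @ theta - y
            return float(resid @ resid + ridge * (theta @ theta))

        loss0 = objective(member.theta)
        P = A.shape[1]
        # columns of absent elements are identically zero; solve the
        # reduced system and scatter back
        nz = np.flatnonzero(np.any(A != 0.0, axis=0))
        A_nz = A[:, nz]
        A_reg = np.concatenate([A_nz, np.sqrt(ridge) * np.eye(len(nz))], axis=0)
        y_reg = np.concatenate([y, np.zeros(len(nz))])
        theta_nz, *_ = np.linalg.lstsq(A_reg, y_reg, rcond=None)
        theta = np.zeros(P)
        theta[nz] = theta_nz
        loss1 = objective(theta)
        if loss1 <= loss0:
            member.theta = theta
            member.loss_history.extend([loss0, loss1])
        else:  # keep the warm-start solution if it is already better
            member.loss_history.extend([loss0, loss0])

    model.trained = True
    return model
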