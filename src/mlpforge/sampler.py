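"""Exploration engines: Langevin NVT dynamics, biased dihedral sampling,
structure relaxation and constrained torsion scans.

The integrator is the BAOAB splitting of Langevin dynamics, which reduces
exactly to velocity Verlet when the friction is zero (NVE mode) and gives
accurate configurational sampling at large timesteps.  Dihedral biasing is
an adaptive kernel bias on a periodic collective variable whose total
magnitude saturates smoothly at a configurable cap (default 70 kJ/mol
converted to kcal/mol) — enough to push a trajectory over torsional
barriers without any free-energy machinery.  Constrained torsion scans
hold the scanned dihedral with a stiff harmonic restraint in the wrapped
angle and report energies without the restraint term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy.optimize import minimize

from .benchmarks import TorsionProfile, TorsionProfile2D
from .constants import DEFAULT_BIAS_CAP_KCAL, KB, KCAL_MOL_TO_AMU_A2_PER_FS2
from .moltopo import Conformation, Molecule, dihedral_angle, dihedral_gradient


class Potential(Protocol):
    """Anything that maps coordinates to (energy, forces)."""

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]: ...


class IntegrationError(RuntimeError):
    """Non-finite energy encountered during dynamics; carries the step index."""

    def __init__(self, step: int, message: str = "non-finite energy"):
        super().__init__(f"{message} at step {step}")
        self.step = step


@dataclass(frozen=True)
class SamplerConfig:
    """Langevin NVT run parameters."""

    temperature: float = 300.0  # K
    timestep: float = 0.5  # fs
    friction: float = 0.02  # 1/fs; 0 disables the thermostat (NVE)
    steps: int = 1000
    seed: int = 0
    record_stride: int = 10

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.friction > 0 and self.temperature <= 0:
            raise ValueError("thermostatted runs need temperature > 0")
        if self.record_stride < 1 or self.steps < 1:
            raise ValueError("steps and record_stride must be >= 1")


@dataclass
class BiasConfig:
    """Adaptive dihedral bias: capped kernels on one torsion CV."""

    cv: tuple[int, int, int, int]
    cap: float = DEFAULT_BIAS_CAP_KCAL  # kcal/mol; bias is everywhere <= cap
    kernel_width: float = 25.0  # degrees
    kernel_height: float = 1.5  # kcal/mol per deposition
    deposition_stride: int = 25  # steps between kernel depositions
    bias_factor: float = 10.0  # well-tempered attenuation of kernel height
    fill_fraction: float = 0.95  # deposition stops where bias reaches this x cap

    def __post_init__(self) -> None:
        if self.cap <= 0 or self.kernel_width <= 0:
            raise ValueError("bias cap and kernel width must be positive")


class DihedralBias:
    """Well-tempered kernel bias, smoothly clamped below the cap.

    S(phi) is a sum of periodic Gaussian kernels deposited along the
    trajectory (heights attenuated well-tempered style); the applied bias
    is the soft minimum V = -a ln(exp(-S/a) + exp(-cap/a)), which equals S
    until near the cap and is strictly below the cap everywhere.  Keeping
    the transform at identity below the cap matters: a transform that
    flattens the interior of a filled basin parks the walker at the basin
    edges, where continued deposition builds walls on the slopes instead
    of carrying the walker over the barrier.
    """

    _SOFTMIN_SHARPNESS = 1.0  # kcal/mol

    def __init__(self, config: BiasConfig, temperature: float):
        self.config = config
        self.temperature = temperature
        self.centers: list[float] = []  # radians
        self.heights: list[float] = []

    def _sum_kernels(self, phi: float) -> tuple[float, float]:
        if not self.centers:
            return 0.0, 0.0
        w = np.radians(self.config.kernel_width)
        c = np.asarray(self.centers)
        h = np.asarray(self.heights)
        d = np.arctan2(np.sin(phi - c), np.cos(phi - c))  # wrapped difference
        k = h * np.exp(-(d**2) / (2.0 * w * w))
        return float(np.sum(k)), float(np.sum(-k * d / (w * w)))

    def value_and_cv_gradient(self, phi: float) -> tuple[float, float]:
        s, ds = self._sum_kernels(phi)
        cap = self.config.cap
        a = self._SOFTMIN_SHARPNESS
        v = -a * float(np.logaddexp(-s / a, -cap / a))
        dv = ds / (1.0 + np.exp(-(cap - s) / a))
        return max(v, 0.0), float(dv)

    def deposit(self, phi: float) -> None:
        v, _ = self.value_and_cv_gradient(phi)
        # stop filling where the bias has reached its working level:
        # unbounded accumulation would saturate the transform everywhere
        # (including the barrier top) and cancel the bias differential
        if v >= self.config.fill_fraction * self.config.cap:
            return
        dT = (self.config.bias_factor - 1.0) * KB * max(self.temperature, 1.0)
        height = self.config.kernel_height * float(np.exp(-v / dT))
        self.centers.append(phi)
        self.heights.append(height)

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        phi, grad = dihedral_gradient(coords, *self.config.cv)
        v, dv = self.value_and_cv_gradient(phi)
        return v, -dv * grad


@dataclass
class Frame:
    coordinates: np.ndarray
    velocities: np.ndarray | None
    potential_energy: float
    kinetic_energy: float
    bias_energy: float = 0.0

    @property
    def total_energy(self) -> float:
        return self.potential_energy + self.kinetic_energy


@dataclass
class Trajectory:
    molecule: Molecule
    frames: list[Frame] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)

    def conformations(self, provenance: str = "md") -> list[Conformation]:
        return [
            Conformation(self.molecule, f.coordinates.copy(), provenance)
            for f in self.frames
        ]

    def kinetic_temperatures(self) -> np.ndarray:
        ndof = 3 * self.molecule.n_atoms
        return np.array([2.0 * f.kinetic_energy / (ndof * KB) for f in self.frames])


def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Velocity draw (A/fs) at the target temperature."""
    kt = KB * max(temperature, 0.0) * KCAL_MOL_TO_AMU_A2_PER_FS2
    sig = np.sqrt(kt / masses)
    return sig[:, None] * rng.standard_normal((len(masses), 3))


def _kinetic_energy(masses: np.ndarray, velocities: np.ndarray) -> float:
    ke = 0.5 * float(np.sum(masses[:, None] * velocities**2))
    return ke / KCAL_MOL_TO_AMU_A2_PER_FS2  # back to kcal/mol


def run_md(
    potential: Potential,
    mol: Molecule,
    conf0: Conformation,
    cfg: SamplerConfig,
    bias: BiasConfig | None = None,
    on_blowup: str = "raise",
) -> Trajectory:
    """NVT (or NVE when friction is 0) Langevin dynamics, BAOAB splitting.

    Velocities are initialized from the Maxwell-Boltzmann distribution at
    the run temperature with the run seed; the physical and bias energies
    are recorded separately on every stored frame.  Frame count is
    1 + floor(steps / record_stride).  A non-finite energy aborts with the
    step index (``on_blowup="raise"``) or returns the frames recorded so
    far (``"truncate"``, used when an immature surrogate drives
    exploration).
    """
    if on_blowup not in ("raise", "truncate"):
        raise ValueError(f"unknown on_blowup policy {on_blowup!r}")
    rng = np.random.default_rng(cfg.seed)
    masses = mol.masses
    x = conf0.coordinates.copy()
    v = maxwell_boltzmann_velocities(masses, cfg.temperature, rng)
    dt = cfg.timestep
    unit = KCAL_MOL_TO_AMU_A2_PER_FS2

    bias_pot = DihedralBias(bias, cfg.temperature) if bias is not None else None

    def eval_all(coords: np.ndarray) -> tuple[float, float, np.ndarray]:
        e, f = potential.energy_forces(coords)
        if bias_pot is not None:
            be, bf = bias_pot.energy_forces(coords)
            return e, be, f + bf
        return e, 0.0, f

    c1 = np.exp(-cfg.friction * dt) if cfg.friction > 0 else 1.0
    kt = KB * max(cfg.temperature, 0.0) * unit
    c2 = np.sqrt((1.0 - c1 * c1) * kt / masses)[:, None] if cfg.friction > 0 else None

    e_pot, e_bias, forces = eval_all(x)
    traj = Trajectory(
        mol,
        metadata={
            "config": cfg,
            "bias": bias,
            "potential": type(potential).__name__,
        },
    )
    traj.frames.append(
        Frame(x.copy(), v.copy(), e_pot, _kinetic_energy(masses, v), e_bias)
    )

    for step in range(1, cfg.steps + 1):
        v = v + 0.5 * dt * forces / masses[:, None] * unit  # B
        x = x + 0.5 * dt * v  # A
        if c2 is not None:  # O
            v = c1 * v + c2 * rng.standard_normal(v.shape)
        x = x + 0.5 * dt * v  # A
        e_pot, e_bias, forces = eval_all(x)
        if not np.isfinite(e_pot) or not np.all(np.isfinite(forces)):
            if on_blowup == "truncate":
                traj.metadata["truncated_at_step"] = step
                return traj
            raise IntegrationError(step)
        v = v + 0.5 * dt * forces / masses[:, None] * unit  # B

        if bias_pot is not None and step % bias.deposition_stride == 0:
            phi = dihedral_angle(x, *bias.cv, strict=False)
            if phi is not None:
                bias_pot.deposit(np.radians(phi))
                e_pot, e_bias, forces = eval_all(x)

        if step % cfg.record_stride == 0:
            traj.frames.append(
                Frame(x.copy(), v.copy(), e_pot, _kinetic_energy(masses, v), e_bias)
            )
    return traj


# ---------------------------------------------------------------------------
# relaxation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DihedralRestraint:
    """Stiff harmonic restraint on the wrapped dihedral angle."""

    term: tuple[int, int, int, int]
    target: float  # degrees
    k: float = 1000.0  # kcal/mol/rad^2

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        phi, grad = dihedral_gradient(coords, *self.term)
        d = phi - np.radians(self.target)
        d = float(np.arctan2(np.sin(d), np.cos(d)))
        return 0.5 * self.k * d * d, -self.k * d * grad


class RestrainedPotential:
    """Base potential plus a list of restraint terms."""

    def __init__(self, base: Potential, restraints: Sequence[DihedralRestraint]):
        self.base = base
        self.restraints = list(restraints)

    def energy_forces(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        e, f = self.base.energy_forces(coords)
        for r in self.restraints:
            re, rf = r.energy_forces(coords)
            e += re
            f = f + rf
        return e, f


@dataclass
class RelaxationResult:
    trajectory: Trajectory  # monotone-energy path; last frame = optimized
    converged: bool
    fmax: float
    n_steps: int

    @property
    def final(self) -> Conformation:
        return Conformation(
            self.trajectory.molecule,
            self.trajectory.frames[-1].coordinates.copy(),
            "relaxation-path",
        )


def _fmax(forces: np.ndarray) -> float:
    return float(np.max(np.linalg.norm(forces, axis=1)))


def relax(
    potential: Potential,
    mol: Molecule,
    conf0: Conformation,
    fmax_tol: float = 0.05,
    restraints: Sequence[DihedralRestraint] | None = None,
    max_steps: int = 500,
) -> RelaxationResult:
    """Local geometry optimization (L-BFGS) with the full path retained.

    Terminates when the maximum per-atom force norm drops below
    ``fmax_tol`` (kcal/mol/A) or the step budget is exhausted (the result
    is then flagged unconverged).  The recorded path is the monotone
    non-increasing-energy sequence of accepted steps, usable for
    harvesting nonequilibrium frames.
    """
    if fmax_tol <= 0:
        raise ValueError("fmax_tol must be positive")
    pot: Potential = (
        RestrainedPotential(potential, restraints) if restraints else potential
    )
    n = mol.n_atoms
    x0 = conf0.coordinates.copy()

    e0, f0 = pot.energy_forces(x0)
    if not np.isfinite(e0):
        raise IntegrationError(0, "non-finite energy at the starting geometry")
    traj = Trajectory(mol, metadata={"kind": "relaxation"})
    traj.frames.append(Frame(x0.copy(), None, e0, 0.0))
    if _fmax(f0) < fmax_tol:
        return RelaxationResult(traj, True, _fmax(f0), 0)

    path: list[np.ndarray] = []

    def fun(flat: np.ndarray) -> tuple[float, np.ndarray]:
        e, f = pot.energy_forces(flat.reshape(n, 3))
        if not np.isfinite(e):
            raise IntegrationError(len(path), "non-finite energy during relaxation")
        return e, -f.ravel()

    # L-BFGS can terminate on its own ftol before the force criterion is
    # met; restart from the current point until converged or out of budget
    x_run = x0.ravel()
    remaining = max_steps
    stalls = 0
    while remaining > 0:
        res = minimize(
            fun,
            x_run,
            jac=True,
            method="L-BFGS-B",
            callback=lambda xk: path.append(xk.copy()),
            options={"maxiter": remaining, "ftol": 1e-14, "gtol": 1e-12},
        )
        remaining -= max(res.nit, 1)
        x_run = res.x
        if _fmax(-res.jac.reshape(n, 3)) < fmax_tol:
            break
        stalls = stalls + 1 if res.nit == 0 else 0
        if stalls >= 3:  # repeated line-search failure: give up, flag unconverged
            break
    # keep only accepted (energy-decreasing) iterates
    last_e = e0
    for xk in path:
        e, _ = pot.energy_forces(xk.reshape(n, 3))
        if e <= last_e:
            traj.frames.append(Frame(xk.reshape(n, 3).copy(), None, e, 0.0))
            last_e = e
    xf = res.x.reshape(n, 3)
    ef, ff = pot.energy_forces(xf)
    if ef <= last_e and not np.allclose(xf, traj.frames[-1].coordinates):
        traj.frames.append(Frame(xf.copy(), None, ef, 0.0))
    fmax = _fmax(pot.energy_forces(traj.frames[-1].coordinates)[1])
    return RelaxationResult(traj, fmax < fmax_tol, fmax, len(traj.frames) - 1)


def harvest_relaxation(
    traj: Trajectory, stride: int = 1, include_endpoint: bool = False
) -> list[Conformation]:
    """Nonequilibrium frames from a relaxation path, every ``stride`` steps.

    The endpoint (the optimized structure) is excluded by default; with
    ``include_endpoint`` it is appended once.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(traj.frames)
    idx = list(range(0, n - 1, stride))
    if include_endpoint:
        idx.append(n - 1)
    return [
        Conformation(traj.molecule, traj.frames[i].coordinates.copy(), "relaxation-path")
        for i in idx
    ]


# ---------------------------------------------------------------------------
# constrained torsion scans
# ---------------------------------------------------------------------------


def torsion_scan(
    potential: Potential,
    mol: Molecule,
    dihedral: tuple[int, int, int, int],
    increment: float,
    conf0: Conformation | None = None,
    starts: Sequence[Conformation] | None = None,
    protocol: str = "successive",
    restraint_k: float = 1000.0,
    fmax_tol: float = 0.1,
    max_steps: int = 300,
    method_label: str = "scan",
    molecule_id: str | None = None,
) -> tuple[TorsionProfile, list[Conformation]]:
    """Constrained torsion scan: relax everything but the scanned dihedral.

    At each grid angle the dihedral is held at the target by a stiff
    harmonic restraint while all other degrees of freedom relax; reported
    energies are evaluated without the restraint term.  The ``successive``
    protocol seeds each optimization from the previous angle's optimum
    (ascending from the starting conformation's measured dihedral);
    ``per-angle-seeded`` uses the supplied ``starts``.  Non-converged
    points are flagged in the profile, never dropped.
    """
    from .moltopo import torsion_grid  # local import to keep module load light

    if protocol not in ("successive", "per-angle-seeded"):
        raise ValueError(f"unknown scan protocol {protocol!r}")
    if protocol == "successive":
        if conf0 is None:
            raise ValueError("successive protocol needs a starting conformation")
        origin = dihedral_angle(conf0.coordinates, *dihedral)
        angles = torsion_grid(increment, origin=origin)
        seeds: list[Conformation | None] = [None] * len(angles)
        seeds[0] = conf0
    else:
        if starts is None:
            raise ValueError("per-angle-seeded protocol needs per-angle starts")
        angles = np.array(
            [dihedral_angle(s.coordinates, *dihedral) for s in starts], dtype=float
        )
        seeds = list(starts)

    energies = np.empty(len(angles))
    converged = np.zeros(len(angles), dtype=bool)
    optimized: list[Conformation] = []
    prev: Conformation | None = None
    for idx, target in enumerate(angles):
        start = seeds[idx] if seeds[idx] is not None else prev
        assert start is not None
        restraint = DihedralRestraint(dihedral, float(target), restraint_k)
        result = relax(
            potential, mol, start, fmax_tol=fmax_tol, restraints=[restraint],
            max_steps=max_steps,
        )
        opt = result.final
        opt.provenance = "scan"
        e_plain, _ = potential.energy_forces(opt.coordinates)
        energies[idx] = e_plain
        converged[idx] = result.converged
        optimized.append(opt)
        prev = opt

    profile = TorsionProfile(
        molecule_id=molecule_id or mol.name,
        dihedral=dihedral,
        angles=angles,
        energies={method_label: energies},
        converged={method_label: converged},
    )
    return profile, optimized


def torsion_scan_2d(
    potential: Potential,
    mol: Molecule,
    dihedral_a: tuple[int, int, int, int],
    dihedral_b: tuple[int, int, int, int],
    increment: float,
    conf0: Conformation,
    restraint_k: float = 1000.0,
    fmax_tol: float = 0.1,
    max_steps: int = 300,
) -> TorsionProfile2D:
    """Full outer grid over two dihedrals with both restraints applied.

    Grid size is (360/increment)^2; each row is scanned successively along
    dihedral B, rows are seeded from the previous row's first point.
    """
    from .moltopo import torsion_grid

    origin_a = dihedral_angle(conf0.coordinates, *dihedral_a)
    origin_b = dihedral_angle(conf0.coordinates, *dihedral_b)
    angles_a = torsion_grid(increment, origin=origin_a)
    angles_b = torsion_grid(increment, origin=origin_b)
    na, nb = len(angles_a), len(angles_b)
    energies = np.empty((na, nb))
    converged = np.zeros((na, nb), dtype=bool)

    row_seed = conf0
    for ia, ta in enumerate(angles_a):
        prev = row_seed
        first_of_row: Conformation | None = None
        for ib, tb in enumerate(angles_b):
            restraints = [
                DihedralRestraint(dihedral_a, float(ta), restraint_k),
                DihedralRestraint(dihedral_b, float(tb), restraint_k),
            ]
            result = relax(
                potential, mol, prev, fmax_tol=fmax_tol, restraints=restraints,
                max_steps=max_steps,
            )
            opt = result.final
            e_plain, _ = potential.energy_forces(opt.coordinates)
            energies[ia, ib] = e_plain
            converged[ia, ib] = result.converged
            prev = opt
            if first_of_row is None:
                first_of_row = opt
        row_seed = first_of_row if first_of_row is not None else row_seed

    return TorsionProfile2D(
        molecule_id=mol.name,
        dihedral_a=dihedral_a,
        dihedral_b=dihedral_b,
        angles_a=angles_a,
        angles_b=angles_b,
        energies=energies,
        converged=converged,
    )


def subsample_equal_intervals(traj: Trajectory, n: int) -> list[Conformation]:
    """n frames at equal index intervals, always including the final frame."""
    total = len(traj.frames)
    if not (1 <= n <= total):
        raise ValueError(f"cannot take {n} frames from a {total}-frame trajectory")
    idx = [int(np.floor((k + 1) * total / n)) - 1 for k in range(n)]
    return [
        Conformation(traj.molecule, traj.frames[i].coordinates.copy(), "md")
        for i in idx
    ]
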