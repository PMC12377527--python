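"""The concurrent-learning loop: force model deviation, adaptive candidate
selection, labeling, curriculum over molecule size, stopping rule, and
dataset manifest accounting.

The loop grows a training set by query-by-committee: an ensemble of seeded
surrogate potentials is retrained each iteration (warm-started from the
previous one), new configurations are explored by molecular dynamics, and
frames where the committee disagrees most — measured by the maximal
per-atom standard deviation of predicted forces — are labeled by the
oracle and appended.  Iterations stop when the lower selection bound
sigma_l stops moving (max - min below a tolerance over a trailing window).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .ensemble import DescriptorConfig, EnsembleModel, train_ensemble
from .moltopo import Conformation, Molecule, select_torsion_cvs
from .oracle import ForceFieldEvaluator, ForceFieldParams, LabeledFrame
from .sampler import (
    BiasConfig,
    SamplerConfig,
    harvest_relaxation,
    relax,
    run_md,
)

# ---------------------------------------------------------------------------
# model deviation (the committee disagreement signal)
# ---------------------------------------------------------------------------


def model_deviation(member_forces: np.ndarray) -> float:
    """Maximal per-atom force standard deviation across the committee.

    ``member_forces`` has shape (N_m, N, 3).  The deviation is

        sigma = max_i sqrt( (1/N_m) sum_alpha || F_i^alpha - F_i^mean ||^2 )

    with population (1/N_m) normalization.
    """
    f = np.asarray(member_forces, dtype=float)
    if f.ndim != 3 or f.shape[2] != 3:
        raise ValueError(f"member forces must have shape (N_m, N, 3), got {f.shape}")
    if f.shape[0] < 2:
        raise ValueError("model deviation needs at least 2 committee members")
    mean = f.mean(axis=0)
    dev = f - mean[None]
    per_atom = np.sqrt(np.mean(np.sum(dev**2, axis=2), axis=0))
    return float(per_atom.max())


@dataclass
class DeviationRecord:
    conformation: Conformation
    sigma: float
    member_forces: np.ndarray | None = None


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionPolicy:
    """Thresholds governing which explored configurations become candidates.

    ``sigma_u`` discards likely-nonphysical frames; in top-fraction mode
    the ``r_candi`` share of the remaining frames with the largest
    deviation becomes the candidate set, and sigma_l is the lowest
    deviation in that set.  Band mode instead takes frames with
    band_lower < sigma <= band_upper.  From the candidates,
    ``subsample_max`` frames at most are drawn uniformly without
    replacement for labeling.
    """

    sigma_u: float = 0.5  # kcal/mol/A
    r_candi: float = 0.12  # within the customary [0.10, 0.15] range
    band_lower: float = 0.15
    band_upper: float = 0.45
    subsample_min: int = 50
    subsample_max: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_candi <= 1):
            raise ValueError("r_candi must lie in (0, 1]")
        if self.band_lower >= self.band_upper:
            raise ValueError("band lower bound must be below the upper bound")
        if self.subsample_min > self.subsample_max:
            raise ValueError("subsample_min must be <= subsample_max")


@dataclass
class SelectionResult:
    discarded: list[int]  # record indices with sigma > sigma_u
    kept: list[int]
    candidates: list[int]
    sigma_l: float | None  # undefined (None) when the kept set is empty
    subsample: list[int]  # labeled subset of the candidates


def select_candidates(
    records: Sequence[DeviationRecord],
    policy: SelectionPolicy,
    mode: str = "top-fraction",
) -> SelectionResult:
    """Partition deviation records into discarded / kept / candidates.

    Top-fraction mode: frames above sigma_u are discarded; of the kept
    frames, ceil(r_candi * |kept|) with the largest sigma are candidates
    (ties broken by input index, stable) and sigma_l is the smallest
    candidate sigma.  Band mode: candidates are kept frames with
    band_lower < sigma <= band_upper.  The subsample is drawn uniformly
    without replacement with the policy seed.
    """
    if len(records) == 0:
        raise ValueError("no deviation records to select from")
    if mode not in ("top-fraction", "band"):
        raise ValueError(f"unknown selection mode {mode!r}")

    sigmas = np.array([r.sigma for r in records])
    discarded = [i for i in range(len(records)) if sigmas[i] > policy.sigma_u]
    kept = [i for i in range(len(records)) if sigmas[i] <= policy.sigma_u]

    if not kept:
        return SelectionResult(discarded, [], [], None, [])

    if mode == "top-fraction":
        n_cand = math.ceil(policy.r_candi * len(kept))
        order = sorted(kept, key=lambda i: (-sigmas[i], i))
        candidates = sorted(order[:n_cand])
        sigma_l = float(min(sigmas[i] for i in candidates))
    else:
        candidates = [
            i for i in kept if policy.band_lower < sigmas[i] <= policy.band_upper
        ]
        sigma_l = float(min((sigmas[i] for i in candidates), default=np.nan))
        if not candidates:
            sigma_l = None

    rng = np.random.default_rng(policy.seed)
    n_sub = min(policy.subsample_max, len(candidates))
    if n_sub and n_sub < len(candidates):
        subsample = sorted(rng.choice(len(candidates), size=n_sub, replace=False))
        subsample = [candidates[i] for i in subsample]
    else:
        subsample = list(candidates)
    return SelectionResult(discarded, kept, candidates, sigma_l, subsample)


# ---------------------------------------------------------------------------
# labeling
# ---------------------------------------------------------------------------


class FFLabeler:
    """Labeling oracle over a set of molecules, each with its own parameters."""

    def __init__(self, systems: dict[str, tuple[Molecule, ForceFieldParams]]):
        self._evaluators = {
            name: ForceFieldEvaluator(mol, params)
            for name, (mol, params) in systems.items()
        }

    def evaluator(self, name: str) -> ForceFieldEvaluator:
        return self._evaluators[name]

    def label(self, conf: Conformation, source: str = "oracle") -> LabeledFrame:
        ev = self._evaluators[conf.molecule.name]
        e, f = ev.energy_forces(conf.coordinates)
        return LabeledFrame(conformation=conf, energy=e, forces=f, source=source)


def label_batch(
    labeler: FFLabeler | Callable[[Conformation], LabeledFrame],
    configs: Sequence[Conformation],
) -> tuple[list[LabeledFrame], list[tuple[int, str]]]:
    """Label configurations in order; failures are recorded, not fatal."""
    fn = labeler.label if isinstance(labeler, FFLabeler) else labeler
    frames: list[LabeledFrame] = []
    failures: list[tuple[int, str]] = []
    for idx, conf in enumerate(configs):
        try:
            frames.append(fn(conf))
        except Exception as exc:  # noqa: BLE001 - batch must continue
            failures.append((idx, str(exc)))
    return frames, failures


# ---------------------------------------------------------------------------
# stopping rule and molecule screening
# ---------------------------------------------------------------------------


def check_converged(
    sigma_l_trace: Sequence[float], window: int = 8, tol: float = 0.01
) -> bool:
    """True iff the trailing ``window`` of the sigma_l trace has max - min < tol."""
    if len(sigma_l_trace) == 0:
        raise ValueError("empty sigma_l trace")
    if len(sigma_l_trace) < window:
        return False
    tail = np.asarray(sigma_l_trace[-window:], dtype=float)
    return bool(tail.max() - tail.min() < tol)


def screen_molecules(
    ensemble: EnsembleModel,
    systems: Sequence[tuple[Molecule, Conformation]],
    threshold: float = 0.45,
) -> tuple[list[Molecule], np.ndarray]:
    """Molecules whose starting conformation the committee disagrees on.

    Returns the molecules with sigma > threshold and the full sigma array
    (one value per input system, in order).
    """
    sigmas = np.array(
        [model_deviation(ensemble.member_forces(mol, conf)) for mol, conf in systems]
    )
    selected = [systems[i][0] for i in range(len(systems)) if sigmas[i] > threshold]
    return selected, sigmas


# ---------------------------------------------------------------------------
# manifest accounting
# ---------------------------------------------------------------------------

MANIFEST_SOURCES = ("relaxation_path", "md", "scan")


@dataclass
class ManifestRow:
    label: str
    molecules: int = 0
    relaxation_path: int = 0
    md: int = 0
    scan: int = 0

    @property
    def total(self) -> int:
        return self.relaxation_path + self.md + self.scan


@dataclass
class Manifest:
    rows: list[ManifestRow] = field(default_factory=list)

    def row(self, label: str) -> ManifestRow:
        for r in self.rows:
            if r.label == label:
                return r
        r = ManifestRow(label)
        self.rows.append(r)
        return r

    def add(self, label: str, source: str, count: int, molecules: int = 0) -> None:
        r = self.row(label)
        key = source.replace("-", "_")
        if key not in MANIFEST_SOURCES:
            raise ValueError(f"unknown configuration source {source!r}")
        setattr(r, key, getattr(r, key) + count)
        r.molecules += molecules


@dataclass
class ManifestTotals:
    molecules: int
    relaxation_path: int
    md: int
    scan: int
    configurations: int


def manifest_totals(manifest: Manifest) -> ManifestTotals:
    """Column sums and the grand configuration total, exact integer arithmetic."""
    for r in manifest.rows:
        for key in ("molecules", *MANIFEST_SOURCES):
            if getattr(r, key) < 0:
                raise ValueError(f"negative count in manifest row {r.label!r}")
    return ManifestTotals(
        molecules=sum(r.molecules for r in manifest.rows),
        relaxation_path=sum(r.relaxation_path for r in manifest.rows),
        md=sum(r.md for r in manifest.rows),
        scan=sum(r.scan for r in manifest.rows),
        configurations=sum(r.total for r in manifest.rows),
    )


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurriculumStage:
    """One rung of the size/temperature curriculum.

    Within a stage, exploration temperature and run length ramp linearly
    from ``temperature``/``steps`` to ``temperature_end``/``steps_end``
    across its iterations — early iterations probe gently near the data
    the committee already trusts, later ones push further out.
    """

    label: str
    max_heavy_atoms: int
    temperature: float  # K, at the first iteration
    steps: int  # MD steps per exploration run, at the first iteration
    max_iterations: int = 5
    bias: bool = False  # bias the first torsion CV of each molecule
    temperature_end: float | None = None  # default: no ramp
    steps_end: int | None = None

    def schedule(self, iteration: int) -> tuple[float, int]:
        """(temperature, steps) for a 0-based iteration within the stage."""
        frac = iteration / max(self.max_iterations - 1, 1)
        t_end = self.temperature_end if self.temperature_end is not None else self.temperature
        s_end = self.steps_end if self.steps_end is not None else self.steps
        return (
            self.temperature + frac * (t_end - self.temperature),
            int(round(self.steps + frac * (s_end - self.steps))),
        )


@dataclass
class FixtureSystem:
    """A molecule with its oracle parameters and a starting conformation."""

    molecule: Molecule
    params: ForceFieldParams
    start: Conformation

    def is_physical(self, conf: Conformation, stretch: float = 1.8, compress: float = 0.5) -> bool:
        """Reject exploded/collapsed geometries by bonded-distance sanity.

        A frame whose bond lengths leave [compress, stretch] x r0 is
        nonphysical in the same sense as the deviation upper bound's
        purpose: it should never be labeled or trained on.
        """
        coords = conf.coordinates
        for (i, j), (_, r0) in self.params.bond.items():
            r = float(np.linalg.norm(coords[j] - coords[i]))
            if not (compress * r0 <= r <= stretch * r0):
                return False
        return True


@dataclass
class LoopState:
    iteration: int = 0
    dataset: list[LabeledFrame] = field(default_factory=list)
    sigma_l_trace: list[float] = field(default_factory=list)
    ensemble: EnsembleModel | None = None
    manifest: Manifest = field(default_factory=Manifest)
    stage_index: int = 0


def _stage_seed(base: int, *parts: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(parts))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def run_loop(
    stages: Sequence[CurriculumStage],
    policy: SelectionPolicy,
    systems: Sequence[FixtureSystem],
    descriptor: DescriptorConfig | None = None,
    ensemble_seeds: Sequence[int] = (11, 22, 33, 44),
    seed: int = 0,
    timestep: float = 0.5,
    friction: float = 0.05,
    record_stride: int = 10,
    convergence_window: int = 8,
    convergence_tol: float = 0.01,
    n_hidden: int = 64,
    heldout_frames_per_system: int = 20,
    n_init_perturbations: int = 15,
    init_jitter: float = 0.05,
    warnings_out: list[str] | None = None,
) -> tuple[LoopState, dict]:
    """Run the concurrent-learning loop over a curriculum of stages.

    Each iteration trains the committee (warm-started), explores with the
    stage's temperature and run length, computes deviations, selects and
    labels candidates, and appends them to the dataset.  A stage ends when
    its sigma_l trace converges or its iteration budget is spent.  Fully
    reproducible from ``seed`` and the ensemble seeds.

    Returns the final state and a JSON-able report with per-iteration
    statistics and a held-out force-RMSE trace.
    """
    if len(stages) == 0:
        raise ValueError("stage list is empty")
    descriptor = descriptor or DescriptorConfig()
    labeler = FFLabeler({s.molecule.name: (s.molecule, s.params) for s in systems})
    state = LoopState()
    report: dict = {"iterations": [], "warnings": []}
    if warnings_out is None:
        warnings_out = report["warnings"]

    def _initial_frames(system: FixtureSystem, traj, rng_key: int) -> list[LabeledFrame]:
        """Relaxation-path frames plus labeled jitters of the endpoint.

        The perturbed-endpoint frames give the very first committee local
        curvature information around each minimum, which one descent path
        alone does not provide.
        """
        confs = harvest_relaxation(traj, stride=1, include_endpoint=True)
        end = confs[-1]
        rng = np.random.default_rng(_stage_seed(seed, 777, rng_key))
        for _ in range(n_init_perturbations):
            confs.append(
                Conformation(
                    system.molecule,
                    end.coordinates + init_jitter * rng.standard_normal(end.coordinates.shape),
                    provenance="relaxation-path",
                )
            )
        frames, _ = label_batch(labeler, confs)
        return frames

    # --- initial dataset: optimized endpoints + harvested relaxation paths
    stage0_bound = stages[0].max_heavy_atoms
    relaxed_starts: dict[str, Conformation] = {}
    for s_idx, system in enumerate(systems):
        ev = labeler.evaluator(system.molecule.name)
        res = relax(ev, system.molecule, system.start, fmax_tol=1e-3, max_steps=300)
        relaxed_starts[system.molecule.name] = res.final
        if system.molecule.heavy_atom_count() <= stage0_bound:
            frames = _initial_frames(system, res.trajectory, s_idx)
            state.dataset.extend(frames)
            state.manifest.add(
                stages[0].label, "relaxation_path", len(frames), molecules=1
            )

    # --- held-out frames for the learning-property audit (oracle MD, own seeds)
    heldout: list[LabeledFrame] = []
    for s_idx, system in enumerate(systems):
        ev = labeler.evaluator(system.molecule.name)
        cfg = SamplerConfig(
            temperature=300.0,
            timestep=timestep,
            friction=friction,
            steps=heldout_frames_per_system * record_stride,
            seed=_stage_seed(seed, 999, s_idx),
            record_stride=record_stride,
        )
        traj = run_md(ev, system.molecule, relaxed_starts[system.molecule.name], cfg)
        frames, _ = label_batch(labeler, traj.conformations())
        heldout.extend(frames[1:])

    def heldout_rmse(model: EnsembleModel) -> float:
        errs = []
        for frame in heldout:
            _, (_, f_mean) = model.predict(frame.conformation.molecule, frame.conformation)
            errs.append(np.mean((f_mean - frame.forces) ** 2))
        return float(np.sqrt(np.mean(errs)))

    # --- iterate stages
    prev_bound = stage0_bound
    for stage_idx, stage in enumerate(stages):
        state.stage_index = stage_idx
        stage_systems = [
            s for s in systems if s.molecule.heavy_atom_count() <= stage.max_heavy_atoms
        ]
        # molecules entering the curriculum at this rung contribute their
        # relaxation paths before exploration starts, as the workflow's
        # per-stage initial data
        if stage_idx > 0:
            for system in systems:
                nh = system.molecule.heavy_atom_count()
                if prev_bound < nh <= stage.max_heavy_atoms:
                    ev = labeler.evaluator(system.molecule.name)
                    res = relax(
                        ev, system.molecule, system.start, fmax_tol=1e-3, max_steps=300
                    )
                    relaxed_starts[system.molecule.name] = res.final
                    frames = _initial_frames(system, res.trajectory, 1000 + stage_idx)
                    state.dataset.extend(frames)
                    state.manifest.add(
                        stage.label, "relaxation_path", len(frames), molecules=1
                    )
        prev_bound = max(prev_bound, stage.max_heavy_atoms)
        if not stage_systems:
            msg = f"stage {stage.label!r}: no explorable molecules, skipped"
            warnings_out.append(msg)
            continue
        stage_trace: list[float] = []

        for it in range(stage.max_iterations):
            state.iteration += 1
            state.ensemble = train_ensemble(
                state.dataset,
                descriptor,
                seeds=list(ensemble_seeds),
                warm_start=state.ensemble,
                n_hidden=n_hidden,
            )

            records: list[DeviationRecord] = []
            n_nonphysical = 0
            stage_temp, stage_steps = stage.schedule(it)
            for m_idx, system in enumerate(stage_systems):
                run_seed = _stage_seed(seed, stage_idx, it, m_idx)
                cfg = SamplerConfig(
                    temperature=stage_temp,
                    timestep=timestep,
                    friction=friction,
                    steps=stage_steps,
                    seed=run_seed,
                    record_stride=record_stride,
                )
                bias_cfg = None
                provenance = "md"
                if stage.bias:
                    cvs = select_torsion_cvs(system.molecule)
                    if cvs:
                        bias_cfg = BiasConfig(cv=cvs[0])
                        provenance = "biased-md"
                # exploration is driven by one committee member, as in
                # query-by-committee practice
                pot = state.ensemble.evaluator(system.molecule, member=0)
                traj = run_md(
                    pot, system.molecule,
                    relaxed_starts[system.molecule.name], cfg, bias=bias_cfg,
                    on_blowup="truncate",
                )
                if "truncated_at_step" in traj.metadata:
                    warnings_out.append(
                        f"stage {stage.label!r} it {state.iteration}: exploration of "
                        f"{system.molecule.name!r} diverged at step "
                        f"{traj.metadata['truncated_at_step']}"
                    )
                for conf in traj.conformations(provenance)[1:]:
                    if not system.is_physical(conf):
                        n_nonphysical += 1
                        continue
                    forces = state.ensemble.member_forces(system.molecule, conf)
                    records.append(DeviationRecord(conf, model_deviation(forces)))

            if not records:
                warnings_out.append(
                    f"stage {stage.label!r} it {state.iteration}: no frames explored"
                )
                state.sigma_l_trace.append(0.0)
                stage_trace.append(0.0)
                continue
            iter_policy = SelectionPolicy(
                sigma_u=policy.sigma_u,
                r_candi=policy.r_candi,
                band_lower=policy.band_lower,
                band_upper=policy.band_upper,
                subsample_min=policy.subsample_min,
                subsample_max=policy.subsample_max,
                seed=_stage_seed(policy.seed, stage_idx, it),
            )
            sel = select_candidates(records, iter_policy, mode="top-fraction")
            to_label = [records[i].conformation for i in sel.subsample]
            frames, failures = label_batch(labeler, to_label)
            state.dataset.extend(frames)
            for frame in frames:
                src = (
                    "md"
                    if frame.conformation.provenance in ("md", "biased-md")
                    else "scan"
                )
                state.manifest.add(stage.label, src, 1)

            sigma_l = sel.sigma_l if sel.sigma_l is not None else 0.0
            state.sigma_l_trace.append(sigma_l)
            stage_trace.append(sigma_l)
            report["iterations"].append(
                {
                    "stage": stage.label,
                    "iteration": state.iteration,
                    "n_explored": len(records) + n_nonphysical,
                    "n_nonphysical": n_nonphysical,
                    "n_discarded": len(sel.discarded),
                    "n_candidates": len(sel.candidates),
                    "n_labeled": len(frames),
                    "n_label_failures": len(failures),
                    "sigma_l": sigma_l,
                    "dataset_size": len(state.dataset),
                    "heldout_force_rmse": heldout_rmse(state.ensemble),
                }
            )
            if check_converged(stage_trace, window=convergence_window, tol=convergence_tol):
                break

    # final retrain on the complete dataset
    state.ensemble = train_ensemble(
        state.dataset,
        descriptor,
        seeds=list(ensemble_seeds),
        warm_start=state.ensemble,
        n_hidden=n_hidden,
    )
    report["final_heldout_force_rmse"] = heldout_rmse(state.ensemble)
    report["sigma_l_trace"] = list(state.sigma_l_trace)
    report["manifest"] = {
        r.label: {
            "molecules": r.molecules,
            "relaxation_path": r.relaxation_path,
            "md": r.md,
            "scan": r.scan,
            "total": r.total,
        }
        for r in state.manifest.rows
    }
    totals = manifest_totals(state.manifest)
    report["manifest_totals"] = {
        "molecules": totals.molecules,
        "configurations": totals.configurations,
    }
    return state, report
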