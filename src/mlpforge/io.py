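"""File formats: extended-XYZ frames, molecule/parameter JSON, profile and
manifest CSV.  All writers are atomic (temp file + rename) so interrupted
runs never leave truncated artifacts.

Extended-XYZ dialect: the comment line carries ``key=value`` pairs
including a ``Properties=`` descriptor (``species:S:1:pos:R:3`` plus
``:forces:R:3`` when forces are present) and optional ``energy=``,
``bias=``, ``temperature=`` scalars.  Frames without forces read back with
forces None, not zero.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd

from .active_learning import Manifest, ManifestRow, manifest_totals
from .benchmarks import TorsionProfile
from .moltopo import Conformation, Molecule, build_molecule
from .oracle import ForceFieldParams, LabeledFrame


# ---------------------------------------------------------------------------
# atomic writes
# ---------------------------------------------------------------------------


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` via a temporary file in the same directory."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path: str | Path, obj: object) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------


@dataclass
class XYZFrame:
    """One extended-XYZ frame."""

    elements: tuple[str, ...]
    coordinates: np.ndarray  # (N, 3)
    energy: float | None = None
    forces: np.ndarray | None = None  # (N, 3) or None (absent, not zero)
    extra: dict[str, float] = field(default_factory=dict)  # bias, temperature...


def frame_from_labeled(frame: LabeledFrame) -> XYZFrame:
    return XYZFrame(
        elements=frame.conformation.molecule.elements,
        coordinates=frame.conformation.coordinates,
        energy=frame.energy,
        forces=frame.forces,
    )


def _format_frame(frame: XYZFrame) -> str:
    n = len(frame.elements)
    props = "species:S:1:pos:R:3" + (":forces:R:3" if frame.forces is not None else "")
    fields = [f"Properties={props}"]
    if frame.energy is not None:
        fields.append(f"energy={frame.energy:.10f}")
    for key, value in frame.extra.items():
        fields.append(f"{key}={value:.10f}")
    lines = [str(n), " ".join(fields)]
    for i in range(n):
        row = f"{frame.elements[i]:2s} " + " ".join(
            f"{x:.10f}" for x in frame.coordinates[i]
        )
        if frame.forces is not None:
            row += " " + " ".join(f"{x:.10f}" for x in frame.forces[i])
        lines.append(row)
    return "\n".join(lines)


def write_extxyz(path: str | Path, frames: Iterable[XYZFrame]) -> None:
    atomic_write_text(path, "\n".join(_format_frame(f) for f in frames) + "\n")


class ExtXYZError(ValueError):
    """Malformed extended-XYZ input; message carries the offending line."""


def _parse_comment(comment: str) -> dict[str, str]:
    out = {}
    for token in comment.split():
        if "=" in token:
            key, value = token.split("=", 1)
            out[key] = value.strip('"')
    return out


def read_extxyz(source: str | Path | IO[str]) -> list[XYZFrame]:
    """Parse all frames; truncated frames raise with the line number."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()  # type: ignore[union-attr]
    else:
        lines = Path(source).read_text().splitlines()
    frames: list[XYZFrame] = []
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError as exc:
            raise ExtXYZError(f"line {pos + 1}: expected atom count") from exc
        if pos + 1 >= len(lines):
            raise ExtXYZError(f"frame {len(frames)}: missing comment line")
        if pos + 2 + n > len(lines):
            raise ExtXYZError(
                f"frame {len(frames)} starting at line {pos + 1} is truncated "
                f"({len(lines) - pos - 2} of {n} atom lines present)"
            )
        meta = _parse_comment(lines[pos + 1])
        has_forces = "forces" in meta.get("Properties", "")
        elements, coords, forces = [], [], []
        for k in range(n):
            lineno = pos + 2 + k
            parts = lines[lineno].split()
            want = 7 if has_forces else 4
            if len(parts) < want:
                raise ExtXYZError(f"line {lineno + 1}: expected {want} columns")
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
            if has_forces:
                forces.append([float(x) for x in parts[4:7]])
        extra = {
            k: float(v)
            for k, v in meta.items()
            if k not in ("Properties", "energy")
            and v.replace(".", "").replace("-", "").replace("e", "").isdigit()
        }
        frames.append(
            XYZFrame(
                elements=tuple(elements),
                coordinates=np.array(coords),
                energy=float(meta["energy"]) if "energy" in meta else None,
                forces=np.array(forces) if has_forces else None,
                extra=extra,
            )
        )
        pos += 2 + n
    return frames


# ---------------------------------------------------------------------------
# molecule and parameter JSON
# ---------------------------------------------------------------------------


def molecule_to_json(mol: Molecule) -> dict:
    return {
        "name": mol.name,
        "elements": list(mol.elements),
        "bonds": [[i, j, order] for (i, j), order in sorted(mol.bonds.items())],
    }


def molecule_from_json(obj: dict) -> Molecule:
    return build_molecule(
        obj["elements"],
        [tuple(b) for b in obj["bonds"]],
        name=obj.get("name", "mol"),
    )


def params_to_json(params: ForceFieldParams) -> dict:
    return {
        "bond": {f"{i}-{j}": list(v) for (i, j), v in sorted(params.bond.items())},
        "angle": {
            f"{i}-{j}-{k}": list(v) for (i, j, k), v in sorted(params.angle.items())
        },
        "dihedral": {
            "-".join(map(str, key)): [list(t) for t in terms]
            for key, terms in sorted(params.dihedral.items())
        },
        "epsilon": list(params.epsilon),
        "sigma": list(params.sigma),
        "charges": list(params.charges),
        "scale14_lj": params.scale14_lj,
        "scale14_coul": params.scale14_coul,
    }


def params_from_json(obj: dict) -> ForceFieldParams:
    def key(s: str) -> tuple[int, ...]:
        return tuple(int(x) for x in s.split("-"))

    return ForceFieldParams(
        bond={key(k): tuple(v) for k, v in obj.get("bond", {}).items()},  # type: ignore[misc]
        angle={key(k): tuple(v) for k, v in obj.get("angle", {}).items()},  # type: ignore[misc]
        dihedral={
            key(k): tuple((float(a), int(b), float(c)) for a, b, c in v)
            for k, v in obj.get("dihedral", {}).items()
        },  # type: ignore[arg-type]
        epsilon=tuple(obj.get("epsilon", ())),
        sigma=tuple(obj.get("sigma", ())),
        charges=tuple(obj.get("charges", ())),
        scale14_lj=obj.get("scale14_lj", 0.5),
        scale14_coul=obj.get("scale14_coul", 1.0 / 1.2),
    )


# ---------------------------------------------------------------------------
# profile CSV
# ---------------------------------------------------------------------------


def write_profile_csv(path: str | Path, profile: TorsionProfile) -> None:
    df = pd.DataFrame({"angle": profile.angles})
    for label, energies in profile.energies.items():
        df[label] = energies
    atomic_write_text(path, df.to_csv(index=False))


def read_profile_csv(
    path: str | Path,
    molecule_id: str = "",
    dihedral: tuple[int, int, int, int] = (0, 1, 2, 3),
) -> TorsionProfile:
    df = pd.read_csv(path)
    if "angle" not in df.columns:
        raise ValueError(f"{path}: profile CSV needs an 'angle' column")
    energies = {
        c: df[c].to_numpy(dtype=float) for c in df.columns if c != "angle"
    }
    return TorsionProfile(
        molecule_id=molecule_id or Path(path).stem,
        dihedral=dihedral,
        angles=df["angle"].to_numpy(dtype=float),
        energies=energies,
    )


# ---------------------------------------------------------------------------
# manifest CSV
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["category", "molecules", "relaxation_path", "md", "scan", "total"]


def write_manifest_csv(
    path: str | Path, manifest: Manifest, include_totals: bool = True
) -> None:
    rows = [
        [r.label, r.molecules, r.relaxation_path, r.md, r.scan, r.total]
        for r in manifest.rows
    ]
    if include_totals:
        t = manifest_totals(manifest)
        rows.append(
            ["Total", t.molecules, t.relaxation_path, t.md, t.scan, t.configurations]
        )
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    atomic_write_text(path, df.to_csv(index=False))


def read_manifest_csv(path: str | Path) -> tuple[Manifest, ManifestRow | None]:
    """Read a manifest CSV; a trailing 'Total' row is split off if present."""
    df = pd.read_csv(path)
    manifest = Manifest()
    stated_total: ManifestRow | None = None
    for _, row in df.iterrows():
        mrow = ManifestRow(
            label=str(row["category"]),
            molecules=int(row["molecules"]),
            relaxation_path=int(row["relaxation_path"]),
            md=int(row["md"]),
            scan=int(row["scan"]),
        )
        if mrow.label.lower() == "total":
            stated_total = mrow
            stated_total_cfg = int(row["total"])
            stated_total.__dict__["stated_configurations"] = stated_total_cfg
        else:
            manifest.rows.append(mrow)
    return manifest, stated_total


def check_manifest_csv(path: str | Path) -> tuple[bool, str]:
    """Verify that the stated totals row matches the recomputed column sums."""
    manifest, stated = read_manifest_csv(path)
    totals = manifest_totals(manifest)
    if stated is None:
        return True, "no totals row to check; column sums are internally consistent"
    problems = []
    for key, have in (
        ("molecules", totals.molecules),
        ("relaxation_path", totals.relaxation_path),
        ("md", totals.md),
        ("scan", totals.scan),
    ):
        want = getattr(stated, key)
        if have != want:
            problems.append(f"{key}: stated {want}, recomputed {have}")
    stated_cfg = stated.__dict__.get("stated_configurations")
    if stated_cfg is not None and stated_cfg != totals.configurations:
        problems.append(
            f"configurations: stated {stated_cfg}, recomputed {totals.configurations}"
        )
    if problems:
        return False, "; ".join(problems)
    return True, "totals row matches recomputed sums"


def published_manifest() -> Manifest:
    """The published training-set manifest shipped with the package."""
    from importlib.resources import files

    path = files("mlpforge.data").joinpath("published_manifest.csv")
    with path.open("r") as fh:  # type: ignore[union-attr]
        df = pd.read_csv(fh)
    manifest = Manifest()
    for _, row in df.iterrows():
        manifest.rows.append(
            ManifestRow(
                label=str(row["category"]),
                molecules=int(row["molecules"]),
                relaxation_path=int(row["relaxation_path"]),
                md=int(row["md"]),
                scan=int(row["scan"]),
            )
        )
    return manifest


def trajectory_frames(traj, include_velocity_energies: bool = True) -> list[XYZFrame]:
    """Convert a sampler Trajectory to extended-XYZ frames."""
    frames = []
    for f in traj.frames:
        extra = {"bias": f.bias_energy}
        if include_velocity_energies:
            extra["kinetic"] = f.kinetic_energy
        frames.append(
            XYZFrame(
                elements=traj.molecule.elements,
                coordinates=f.coordinates,
                energy=f.potential_energy,
                forces=None,
                extra=extra,
            )
        )
    return frames


def conformation_from_frame(frame: XYZFrame, mol: Molecule, provenance: str = "fixture") -> Conformation:
    if tuple(frame.elements) != mol.elements:
        raise ValueError("frame elements do not match molecule")
    return Conformation(mol, frame.coordinates.copy(), provenance)
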