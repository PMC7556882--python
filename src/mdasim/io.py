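"""Trajectory and log I/O.

Snapshots are written as extended-XYZ text frames: a particle count line, a
key=value comment line (box, periodicity, dimensionality, cumulative
force-evaluation stamp), then one line per particle with the bead label,
coordinates, molecule id and charge.  Coordinates are written with
shortest-round-trip ``repr`` so a write/read cycle reproduces every float
bit-exactly.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import ParticleSystem, SimulationBox

__all__ = ["Frame", "FrameParseError", "write_frames", "read_frames"]


class FrameParseError(ValueError):
    """Malformed trajectory file; message carries the offending line number."""


@dataclass
class Frame:
    """A stamped configuration snapshot (what the analysis pipeline consumes)."""

    positions: np.ndarray
    labels: np.ndarray  # per-particle bead label, e.g. "HB"
    molecule_id: np.ndarray
    charge: np.ndarray
    box_lengths: np.ndarray
    periodic: np.ndarray
    force_evals: int = 0

    @property
    def n(self) -> int:
        return int(self.positions.shape[0])

    @property
    def dim(self) -> int:
        return int(self.box_lengths.size)

    @property
    def box(self) -> SimulationBox:
        return SimulationBox(self.box_lengths.copy(), self.periodic.copy())

    @classmethod
    def from_system(cls, system: ParticleSystem, force_evals: int = 0) -> "Frame":
        labels = (
            np.asarray(system.type_labels, dtype="U8")[system.bead_type]
            if system.type_labels
            else system.bead_type.astype("U8")
        )
        return cls(
            system.positions.copy(),
            labels,
            system.molecule_id.copy(),
            system.charge.copy(),
            system.box.lengths.copy(),
            system.box.periodic.copy(),
            int(force_evals),
        )


def _fmt(x: float) -> str:
    return repr(float(x))


def write_frames(path, frames: list[Frame]) -> None:
    """Write frames as extended-XYZ text (full float precision)."""
    path = Path(path)
    with path.open("w") as fh:
        for fr in frames:
            fh.write(f"{fr.n}\n")
            box = " ".join(_fmt(x) for x in fr.box_lengths)
            per = " ".join("T" if p else "F" for p in fr.periodic)
            fh.write(
                f'box="{box}" periodic="{per}" dim={fr.dim} '
                f"force_evals={fr.force_evals} "
                f"Properties=species:S:1:pos:R:{fr.dim}:molecule_id:I:1:charge:R:1\n"
            )
            for i in range(fr.n):
                coords = " ".join(_fmt(x) for x in fr.positions[i])
                fh.write(
                    f"{fr.labels[i]} {coords} {int(fr.molecule_id[i])} "
                    f"{_fmt(fr.charge[i])}\n"
                )


def read_frames(path) -> list[Frame]:
    """Parse an extended-XYZ trajectory written by :func:`write_frames`."""
    path = Path(path)
    frames: list[Frame] = []
    with path.open() as fh:
        lines = fh.readlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError as exc:
            raise FrameParseError(
                f"{path}:{ln + 1}: expected particle count, got {lines[ln]!r}"
            ) from exc
        if ln + 1 >= len(lines):
            raise FrameParseError(f"{path}:{ln + 1}: missing comment line")
        meta = _parse_comment(lines[ln + 1], path, ln + 2)
        dim = meta["dim"]
        pos = np.empty((n, dim))
        labels = np.empty(n, dtype="U8")
        mol = np.empty(n, dtype=np.int64)
        charge = np.empty(n)
        for i in range(n):
            lno = ln + 2 + i
            if lno >= len(lines):
                raise FrameParseError(f"{path}:{lno + 1}: truncated frame")
            parts = lines[lno].split()
            if len(parts) != 1 + dim + 2:
                raise FrameParseError(
                    f"{path}:{lno + 1}: expected {1 + dim + 2} columns, "
                    f"got {len(parts)}"
                )
            try:
                labels[i] = parts[0]
                pos[i] = [float(x) for x in parts[1 : 1 + dim]]
                mol[i] = int(parts[1 + dim])
                charge[i] = float(parts[2 + dim])
            except ValueError as exc:
                raise FrameParseError(f"{path}:{lno + 1}: {exc}") from exc
        frames.append(
            Frame(pos, labels, mol, charge, meta["box"], meta["periodic"],
                  meta["force_evals"])
        )
        ln += 2 + n
    return frames


def _parse_comment(line: str, path, lineno: int) -> dict:
    try:
        tokens = shlex.split(line)
        kv = dict(tok.split("=", 1) for tok in tokens if "=" in tok)
        box = np.array([float(x) for x in kv["box"].split()])
        per_raw = kv.get("periodic", " ".join("T" * box.size))
        periodic = np.array([tok == "T" for tok in per_raw.split()])
        dim = int(kv.get("dim", box.size))
        force_evals = int(kv.get("force_evals", 0))
    except (KeyError, ValueError) as exc:
        raise FrameParseError(f"{path}:{lineno}: bad comment line: {exc}") from exc
    if box.size != dim or periodic.size != dim:
        raise FrameParseError(f"{path}:{lineno}: box/dim mismatch")
    return dict(box=box, periodic=periodic, dim=dim, force_evals=force_evals)
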