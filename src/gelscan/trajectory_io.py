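"""Trajectory containers and text I/O (multi-model PDB, extended XYZ).

The PDB dialect written here is standard MODEL/ENDMDL multi-model PDB
with two package conventions documented for round-tripping:

* each MODEL record is followed by ``REMARK 250  TIME_NS=<t>`` carrying
  the snapshot time (plain PDB has no per-frame clock);
* the segment-id column (73–76) carries the atom's moiety tag,
  truncated to four characters, so annotated templates survive export.

Boxes are written as CRYST1 records (orthorhombic, 90° angles).  The
extended-XYZ dialect stores ``time_ns`` and ``box`` in the comment line.
Coordinates are Ångström throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_model import MonomerTemplate, SystemFrame

__all__ = ["Trajectory", "frame_schedule", "read_trajectory", "write_trajectory"]

_SEG = {
    "FMOC": "FMC",
    "PHE_SIDECHAIN": "PHE",
    "FLUORINE": "FLR",
    "CARBOXYL": "COO",
    "BACKBONE": "BCK",
    "LINKER": "LNK",
}


@dataclass
class Trajectory:
    """Ordered snapshots of one replicate of an N-monomer system."""

    replicate_id: int
    template: MonomerTemplate
    frames: list[SystemFrame] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        times = [f.time_ns for f in self.frames]
        if any(b >= a for a, b in zip(times[1:], times[:-1])):
            raise ValueError("frame times must be strictly increasing")
        if self.frames:
            n0 = self.frames[0].n_monomers
            box0 = self.frames[0].box
            for f in self.frames:
                if f.n_monomers != n0 or not np.allclose(f.box, box0):
                    raise ValueError("all frames must share box and monomer count")
                if f.coords.shape[1] != self.template.n_atoms:
                    raise ValueError(
                        f"frame {f.frame_index}: atom count {f.coords.shape[1]} "
                        f"!= template atom count {self.template.n_atoms}"
                    )

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def frame_schedule(
    production_ns: float, interval_ns: float, n_replicates: int
) -> tuple[int, list[float]]:
    """Snapshot schedule: frames at t = k·interval for k = 1..prod/interval.

    The t = 0 configuration is not analyzed, so 80 ns sampled every
    0.2 ns gives 400 snapshots per replicate and 2000 over 5 replicates.
    Returns ``(total_count, per_replicate_times)``.
    """
    if production_ns <= 0 or interval_ns <= 0:
        raise ValueError("production_ns and interval_ns must be positive")
    ratio = production_ns / interval_ns
    k = round(ratio)
    if abs(ratio - k) > 1e-9 * max(1.0, ratio) or k == 0:
        raise ValueError(
            f"interval {interval_ns} ns does not divide production {production_ns} ns"
        )
    times = [i * interval_ns for i in range(1, k + 1)]
    return n_replicates * k, times


# ---------------------------------------------------------------------------
# multi-model PDB


def write_trajectory(traj: Trajectory, path, fmt: str = "pdb") -> None:
    """Write a trajectory as multi-model PDB (``fmt='pdb'``) or extended
    XYZ (``fmt='xyz'``).  Output is deterministic for fixed input."""
    path = Path(path)
    fmt = fmt.lower()
    if fmt in ("pdb", "pdb_multimodel"):
        path.write_text(_to_pdb(traj))
    elif fmt == "xyz":
        path.write_text(_to_xyz(traj))
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


def _to_pdb(traj: Trajectory) -> str:
    t = traj.template
    lines = [f"REMARK 200 GELSCAN TRAJECTORY REPLICATE={traj.replicate_id}"]
    for frame in traj.frames:
        a_, b_, c_ = frame.box
        lines.append(f"MODEL     {frame.frame_index + 1:4d}")
        lines.append(f"REMARK 250  TIME_NS={frame.time_ns:.6f}")
        lines.append(
            f"CRYST1{a_:9.3f}{b_:9.3f}{c_:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
        serial = 1
        for m in range(frame.n_monomers):
            resid = (m % 9999) + 1
            for k, atom in enumerate(t.atoms):
                x, y, zz = frame.coords[m, k]
                seg = _SEG[atom.moiety.value]
                lines.append(
                    f"HETATM{serial % 100000:5d} {atom.name:<4.4s}"
                    f"{'FMP':>3s} A{resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{zz:8.3f}{1.00:6.2f}{0.00:6.2f}      "
                    f"{seg:<4.4s}{atom.element:>2.2s}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _to_xyz(traj: Trajectory) -> str:
    t = traj.template
    out = []
    for frame in traj.frames:
        n_total = frame.n_monomers * t.n_atoms
        out.append(str(n_total))
        bx = " ".join(f"{v:.6f}" for v in frame.box)
        out.append(
            f'time_ns={frame.time_ns:.6f} box="{bx}" n_monomers={frame.n_monomers} '
            f"replicate={traj.replicate_id}"
        )
        for m in range(frame.n_monomers):
            for k, atom in enumerate(t.atoms):
                x, y, zz = frame.coords[m, k]
                out.append(f"{atom.element:<2s} {x:15.6f} {y:15.6f} {zz:15.6f}")
    return "\n".join(out) + "\n"


def read_trajectory(path, fmt: str, template: MonomerTemplate) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    The template supplies the per-monomer atom layout; a file whose atom
    count is not a multiple of the template's raises with the offending
    frame named.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty trajectory file")
    fmt = fmt.lower()
    if fmt in ("pdb", "pdb_multimodel"):
        return _from_pdb(text, template, path)
    if fmt == "xyz":
        return _from_xyz(text, template, path)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def _from_pdb(text: str, template: MonomerTemplate, path) -> Trajectory:
    replicate = 0
    frames: list[SystemFrame] = []
    cur: list[list[float]] | None = None
    time_ns = 0.0
    box = np.array([90.0, 90.0, 90.0])
    model_no = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "REMARK" and "REPLICATE=" in line:
            replicate = int(line.split("REPLICATE=")[1].split()[0])
        elif rec == "MODEL":
            cur = []
            model_no = int(line.split()[1])
        elif rec == "REMARK" and "TIME_NS=" in line:
            time_ns = float(line.split("TIME_NS=")[1].split()[0])
        elif rec == "CRYST1":
            box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
        elif rec in ("ATOM", "HETATM"):
            if cur is None:
                cur = []
            try:
                cur.append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinate record") from exc
        elif rec == "ENDMDL":
            frames.append(
                _make_frame(cur, model_no - 1, time_ns, box, template, model_no)
            )
            cur = None
    if cur:  # single model without MODEL/ENDMDL bracketing
        frames.append(_make_frame(cur, len(frames), time_ns, box, template, 1))
    if not frames:
        raise ValueError(f"{path}: no coordinate frames found")
    return Trajectory(replicate_id=replicate, template=template, frames=frames)


def _make_frame(flat, frame_index, time_ns, box, template, model_no) -> SystemFrame:
    arr = np.array(flat, dtype=float)
    na = template.n_atoms
    if arr.size == 0 or len(arr) % na:
        raise ValueError(
            f"frame {model_no}: {len(arr)} atoms is not a multiple of the "
            f"template atom count {na}"
        )
    return SystemFrame(
        frame_index=frame_index,
        time_ns=time_ns,
        box=box,
        coords=arr.reshape(len(arr) // na, na, 3),
    )


def _from_xyz(text: str, template: MonomerTemplate, path) -> Trajectory:
    lines = text.splitlines()
    frames: list[SystemFrame] = []
    replicate = 0
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: expected atom count") from exc
        comment = lines[i + 1]
        fields = dict(
            kv.split("=", 1) for kv in _split_comment(comment) if "=" in kv
        )
        time_ns = float(fields.get("time_ns", len(frames)))
        box = np.array([float(v) for v in fields["box"].strip('"').split()])
        replicate = int(fields.get("replicate", replicate))
        rows = []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{i + 3 + j}: malformed XYZ atom line")
            rows.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(
            _make_frame(rows, len(frames), time_ns, box, template, len(frames) + 1)
        )
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no coordinate frames found")
    return Trajectory(replicate_id=replicate, template=template, frames=frames)


def _split_comment(comment: str) -> list[str]:
    """Split key=value tokens, keeping quoted values whole."""
    out, cur, inq = [], "", False
    for ch in comment:
        if ch == '"':
            inq = not inq
            cur += ch
        elif ch == " " and not inq:
            if cur:
                out.append(cur)
            cur = ""
        else:
            cur += ch
    if cur:
        out.append(cur)
    return out
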