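"""Trajectory and result serialization.

Two plain-text frame formats are supported:

* extended XYZ with a Lattice/Properties comment line and per-bead columns
  ``species x y z vx vy vz mol``;
* a LAMMPS-dump-compatible dialect with ``id type mol x y z vx vy vz``
  columns (type indices 1..4 map to H, C, W, S).

Frames written by either writer read back with identical type and molecule
columns and positions at the stored precision.  Bond/angle topology is not
stored in frames; :func:`rebuild_topology` reconstructs it from molecule
ids for states whose lipids follow the standard bead order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .engine import SystemState
from .forcefield import BEAD_TYPES, DEFAULT_LIPID, LipidTopology


class ParseError(ValueError):
    """Malformed trajectory file; message carries the 1-based line number."""


def write_frame(state: SystemState, path, fmt: str | None = None, precision: int = 8) -> None:
    """Write one frame as extended XYZ (.xyz) or LAMMPS dump (.dump/.lammpstrj)."""
    path = Path(path)
    if fmt is None:
        fmt = "dump" if path.suffix in (".dump", ".lammpstrj") else "xyz"
    if fmt == "xyz":
        _write_xyz(state, path, precision)
    elif fmt == "dump":
        _write_dump(state, path, precision)
    else:
        raise ValueError(f"unsupported format {fmt!r}; use 'xyz' or 'dump'")


def read_frame(path) -> SystemState:
    """Read one frame; the dialect is inferred from the file contents."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("ITEM:"):
        return _read_dump(path)
    return _read_xyz(path)


def _write_xyz(state: SystemState, path: Path, prec: int) -> None:
    b = state.box
    fmtf = f"%.{prec}g"
    with open(path, "w") as fh:
        fh.write(f"{state.n_beads}\n")
        fh.write(
            f'Lattice="{b[0]:g} 0 0 0 {b[1]:g} 0 0 0 {b[2]:g}" '
            f"Properties=species:S:1:pos:R:3:velo:R:3:mol:I:1 Step={state.step}\n"
        )
        for i in range(state.n_beads):
            p, v = state.pos[i], state.vel[i]
            fh.write(
                f"{BEAD_TYPES[state.types[i]]} "
                + " ".join(fmtf % x for x in (p[0], p[1], p[2], v[0], v[1], v[2]))
                + f" {state.mol[i]}\n"
            )


def _read_xyz(path: Path) -> SystemState:
    with open(path) as fh:
        lines = fh.readlines()
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise ParseError(f"{path}:1: expected bead count") from None
    if len(lines) < n + 2:
        raise ParseError(f"{path}:{len(lines)}: truncated file; expected {n + 2} lines")
    header = lines[1]
    step = 0
    box = None
    if 'Lattice="' in header:
        lat = header.split('Lattice="')[1].split('"')[0].split()
        box = np.array([float(lat[0]), float(lat[4]), float(lat[8])])
    if "Step=" in header:
        step = int(float(header.split("Step=")[1].split()[0]))
    if box is None:
        raise ParseError(f"{path}:2: missing Lattice specification")
    pos = np.empty((n, 3))
    vel = np.zeros((n, 3))
    types = np.empty(n, dtype=np.int8)
    mol = np.zeros(n, dtype=np.int32)
    for i in range(n):
        ln = lines[i + 2].split()
        try:
            types[i] = BEAD_TYPES.index(ln[0])
            pos[i] = [float(x) for x in ln[1:4]]
            if len(ln) >= 7:
                vel[i] = [float(x) for x in ln[4:7]]
            if len(ln) >= 8:
                mol[i] = int(ln[7])
        except (IndexError, ValueError):
            raise ParseError(f"{path}:{i + 3}: malformed bead line") from None
    return SystemState(box=box, pos=pos, vel=vel, types=types, mol=mol, step=step)


def _write_dump(state: SystemState, path: Path, prec: int) -> None:
    b = state.box
    fmtf = f"%.{prec}g"
    with open(path, "w") as fh:
        fh.write(f"ITEM: TIMESTEP\n{state.step}\n")
        fh.write(f"ITEM: NUMBER OF ATOMS\n{state.n_beads}\n")
        fh.write("ITEM: BOX BOUNDS pp pp pp\n")
        for a in range(3):
            fh.write(f"0 {b[a]:g}\n")
        fh.write("ITEM: ATOMS id type mol x y z vx vy vz\n")
        for i in range(state.n_beads):
            p, v = state.pos[i], state.vel[i]
            fh.write(
                f"{i + 1} {state.types[i] + 1} {state.mol[i]} "
                + " ".join(fmtf % x for x in (p[0], p[1], p[2], v[0], v[1], v[2]))
                + "\n"
            )


def _read_dump(path: Path) -> SystemState:
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    step = 0
    n = None
    box = np.empty(3)
    cols = None
    try:
        while i < len(lines):
            ln = lines[i].strip()
            if ln.startswith("ITEM: TIMESTEP"):
                step = int(lines[i + 1])
                i += 2
            elif ln.startswith("ITEM: NUMBER OF ATOMS"):
                n = int(lines[i + 1])
                i += 2
            elif ln.startswith("ITEM: BOX BOUNDS"):
                for a in range(3):
                    lo, hi = (float(x) for x in lines[i + 1 + a].split()[:2])
                    box[a] = hi - lo
                i += 4
            elif ln.startswith("ITEM: ATOMS"):
                cols = ln.split()[2:]
                i += 1
                break
            else:
                i += 1
    except (IndexError, ValueError):
        raise ParseError(f"{path}:{i + 1}: malformed header") from None
    if n is None or cols is None:
        raise ParseError(f"{path}:{i + 1}: missing NUMBER OF ATOMS or ATOMS section")
    need = {"id", "type", "x", "y", "z"}
    if not need.issubset(cols):
        raise ParseError(f"{path}:{i}: ATOMS columns {cols} lack {sorted(need - set(cols))}")
    if len(lines) < i + n:
        raise ParseError(f"{path}:{len(lines)}: truncated file; expected {n} atom lines")
    ix = {c: k for k, c in enumerate(cols)}
    pos = np.empty((n, 3))
    vel = np.zeros((n, 3))
    types = np.empty(n, dtype=np.int8)
    mol = np.zeros(n, dtype=np.int32)
    for k in range(n):
        ln = lines[i + k].split()
        try:
            ai = int(ln[ix["id"]]) - 1
            types[ai] = int(ln[ix["type"]]) - 1
            pos[ai] = [float(ln[ix["x"]]), float(ln[ix["y"]]), float(ln[ix["z"]])]
            if "vx" in ix:
                vel[ai] = [float(ln[ix["vx"]]), float(ln[ix["vy"]]), float(ln[ix["vz"]])]
            if "mol" in ix:
                mol[ai] = int(ln[ix["mol"]])
        except (IndexError, ValueError):
            raise ParseError(f"{path}:{i + k + 1}: malformed atom line") from None
    return SystemState(box=box, pos=pos, vel=vel, types=types, mol=mol, step=step)


def rebuild_topology(state: SystemState, topology: LipidTopology | None = None) -> SystemState:
    """Reconstruct bond/angle arrays from molecule ids (mol > 0 = lipids,
    beads per lipid contiguous and in standard order)."""
    topo = topology or DEFAULT_LIPID
    npl = topo.beads_per_lipid
    bonds, angles = [], []
    for m in np.unique(state.mol):
        if m <= 0:
            continue
        idx = np.flatnonzero(state.mol == m)
        if len(idx) != npl:
            raise ValueError(f"molecule {m} has {len(idx)} beads; expected {npl}")
        bonds.append(topo.bonds + idx[0])
        angles.append(topo.angles + idx[0])
    out = state.copy()
    out.bonds = (np.concatenate(bonds) if bonds else np.empty((0, 2))).astype(np.int32)
    out.angles = (np.concatenate(angles) if angles else np.empty((0, 3))).astype(np.int32)
    out.topology = topo
    return out


def write_state_sidecar(state: SystemState, path) -> None:
    """JSON sidecar with the builder spec and partition bookkeeping."""
    counts = {BEAD_TYPES[t]: int(np.sum(state.types == t)) for t in range(4)}
    payload = {"n_beads": state.n_beads, "box": state.box.tolist(), "seed": state.seed,
               "step": state.step, "counts_by_type": counts, "meta": _jsonable(state.meta)}
    Path(path).write_text(json.dumps(payload, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def write_profile_csv(profile, path, extra_header: dict | None = None) -> None:
    """CSV (r, value) with a JSON header comment (bins, frames, selection)."""
    hdr = {"bin_width": profile.bin_width, "n_frames": profile.n_frames,
           "types": [int(t) for t in profile.types]}
    if extra_header:
        hdr.update(extra_header)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(hdr) + "\n")
        fh.write("r,value\n")
        for r, v in zip(profile.r, profile.values):
            fh.write(f"{r:.6g},{v:.8g}\n")


def write_stress_csv(sp, path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + json.dumps({"bin_width": sp.bin_width, "n_frames": sp.n_frames}) + "\n")
        fh.write("r,P_N,P_T,s\n")
        for r, pn, pt, s in zip(sp.r, sp.P_N, sp.P_T, sp.s):
            fh.write(f"{r:.6g},{pn:.8g},{pt:.8g},{s:.8g}\n")
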