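"""Plain-text readers and writers.

Delimited time-series tables with ``# key = value`` headers, per-frame
XYZ-like coordinate blocks (nm), a minimal fixed-column PDB ATOM subset
(Angstrom, converted to nm on read) and flat key:value config files.
"""
from __future__ import annotations

import ast
from pathlib import Path

import numpy as np

from .structure import Atom, FrameSeries, HBStateMatrix

__all__ = [
    "write_hb_matrix",
    "read_hb_matrix",
    "write_series",
    "read_series",
    "write_xyz",
    "read_xyz",
    "frames_to_xyz",
    "xyz_to_frames",
    "read_pdb_frames",
    "write_flat_config",
    "read_flat_config",
    "read_points",
]

ANGSTROM_TO_NM = 0.1


def _parse_headers(lines):
    meta = {}
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        if "=" in line:
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
    else:
        body_start = len(lines)
    return meta, body_start


def write_hb_matrix(path, states: HBStateMatrix) -> None:
    """HB-state matrix as tab-delimited text: time column plus one 0/1
    column per bond, with dt and bond labels in the header."""
    path = Path(path)
    n = states.n_frames
    times = np.arange(n) * states.dt
    labels = ";".join(f"{i},{j}" for i, j in states.bond_labels)
    with open(path, "w") as fh:
        fh.write(f"# dt_ps = {states.dt!r}\n")
        fh.write(f"# h_max = {states.h_max}\n")
        fh.write(f"# bond_labels = {labels}\n")
        fh.write("time_ps\t" + "\t".join(f"b{k}" for k in range(states.n_bonds)) + "\n")
        for t in range(n):
            row = "\t".join("1" if v else "0" for v in states.states[t])
            fh.write(f"{times[t]:.6g}\t{row}\n")


def read_hb_matrix(path) -> HBStateMatrix:
    lines = Path(path).read_text().splitlines()
    meta, start = _parse_headers(lines)
    dt = float(meta.get("dt_ps", 1.0))
    labels = []
    if meta.get("bond_labels"):
        for tok in meta["bond_labels"].split(";"):
            i, j = tok.split(",")
            labels.append((int(i), int(j)))
    data = np.loadtxt(lines[start + 1 :], dtype=float, ndmin=2)
    states = data[:, 1:].astype(bool)
    if not labels:
        labels = [(k, k + 4) for k in range(states.shape[1])]
    h_max = int(meta.get("h_max", states.shape[1]))
    return HBStateMatrix(dt=dt, states=states, bond_labels=labels, h_max=h_max)


def write_series(path, values, dt: float, name: str = "value", units: str = "") -> None:
    """Scalar time series as two-column delimited text."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        fh.write(f"# dt_ps = {dt!r}\n")
        if units:
            fh.write(f"# units = {units}\n")
        fh.write(f"time_ps\t{name}\n")
        for k, v in enumerate(values):
            fh.write(f"{k * dt:.6g}\t{float(v)!r}\n")


def read_series(path):
    """Returns (dt_ps, values)."""
    lines = Path(path).read_text().splitlines()
    meta, start = _parse_headers(lines)
    data = np.loadtxt(lines[start + 1 :], dtype=float, ndmin=2)
    return float(meta.get("dt_ps", 1.0)), data[:, 1]


def write_xyz(path, positions: np.ndarray, dt: float, labels=None) -> None:
    """Per-frame XYZ blocks: atom count, a ``t= <ps>`` comment line, then
    ``label x y z`` rows in nm."""
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 3 or pos.shape[2] != 3:
        raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
    n_frames, n_atoms, _ = pos.shape
    if labels is None:
        labels = [f"P{i}" for i in range(n_atoms)]
    with open(path, "w") as fh:
        for t in range(n_frames):
            fh.write(f"{n_atoms}\n")
            fh.write(f"t= {t * dt:.6g}\n")
            for a in range(n_atoms):
                x, y, z = (float(c) for c in pos[t, a])
                fh.write(f"{labels[a]} {x!r} {y!r} {z!r}\n")


def read_xyz(path):
    """Returns (dt_ps, labels, positions) from per-frame XYZ blocks."""
    lines = Path(path).read_text().splitlines()
    frames, times = [], []
    labels = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n_atoms = int(lines[i].strip())
        comment = lines[i + 1]
        t = 0.0
        if "t=" in comment:
            t = float(comment.split("t=")[1].split()[0])
        block_labels, coords = [], []
        for row in lines[i + 2 : i + 2 + n_atoms]:
            parts = row.split()
            block_labels.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if labels is None:
            labels = block_labels
        frames.append(coords)
        times.append(t)
        i += 2 + n_atoms
    pos = np.asarray(frames)
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    return dt, labels, pos


def frames_to_xyz(path, frames: FrameSeries) -> None:
    """FrameSeries to XYZ blocks; labels encode role:residue."""
    labels = [f"{a.role}:{a.residue}" for a in frames.atoms]
    dt = frames.dt if frames.n_frames > 1 else 1.0
    write_xyz(path, frames.coords, dt, labels=labels)


def xyz_to_frames(path) -> FrameSeries:
    dt, labels, pos = read_xyz(path)
    atoms = []
    for lab in labels:
        role, _, res = lab.partition(":")
        atoms.append(Atom(int(res) if res else 0, role))
    times = np.arange(pos.shape[0]) * dt
    return FrameSeries(times=times, atoms=tuple(atoms), coords=pos)


def read_pdb_frames(path) -> FrameSeries:
    """Minimal fixed-column PDB reader (ATOM records, MODEL = frame).

    Uses atom name, resSeq and x/y/z only; coordinates are converted from
    Angstrom to nm.  Atom names CA/O/N map onto the matching roles; other
    names are skipped.
    """
    frames = []
    current = []
    atoms = None

    def flush():
        nonlocal atoms, current
        if not current:
            return
        if atoms is None:
            atoms = [a for a, _ in current]
        frames.append([c for _, c in current])
        current = []

    for line in Path(path).read_text().splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            flush()
        elif rec == "ENDMDL":
            flush()
        elif rec == "ATOM":
            name = line[12:16].strip()
            if name not in ("CA", "O", "N"):
                continue
            res = int(line[22:26])
            x = float(line[30:38]) * ANGSTROM_TO_NM
            y = float(line[38:46]) * ANGSTROM_TO_NM
            z = float(line[46:54]) * ANGSTROM_TO_NM
            current.append((Atom(res, name), [x, y, z]))
    flush()
    if not frames:
        raise ValueError("no ATOM records found")
    coords = np.asarray(frames)
    times = np.arange(coords.shape[0], dtype=float)
    return FrameSeries(times=times, atoms=tuple(atoms), coords=coords)


def write_flat_config(path, config: dict) -> None:
    """Flat ``key: value`` file (scalars only)."""
    with open(path, "w") as fh:
        for key, val in config.items():
            fh.write(f"{key}: {val!r}\n")


def read_flat_config(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        out[key.strip()] = ast.literal_eval(val.strip())
    return out


def read_points(path) -> np.ndarray:
    """(eta, gamma) pairs from two-column delimited text (``#`` comments
    allowed)."""
    pts = np.loadtxt(path, ndmin=2)
    if pts.shape[1] < 2:
        raise ValueError("points file needs two columns: eta gamma")
    return pts[:, :2]
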