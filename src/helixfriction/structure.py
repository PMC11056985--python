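"""Structural observables from coordinate frames.

Turns time series of atomic coordinates into the quantities the rest of the
stack consumes: per-frame helical (i, i+4) hydrogen-bond states, the total
bond count ``h``, end-to-end distances, and the RMSD from an ideal-helix
reference after optimal rigid-body superposition.

Coordinates are in nanometres throughout; times in picoseconds.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Atom",
    "FrameSeries",
    "HBStateMatrix",
    "Histogram1D",
    "HB_CUTOFF_NM",
    "detect_hbonds",
    "helix_fraction",
    "end_to_end",
    "rmsdh",
    "rmsdh_histogram",
]

#: Default donor-acceptor distance cutoff (nm) for a formed helical HB.
#: A bond is formed when |O_i - N_{i+4}| is strictly below this value.
HB_CUTOFF_NM = 0.36

ATOM_ROLES = ("CA", "O", "N", "terminal")


class Atom(NamedTuple):
    """A labelled atom: residue index plus its role in the analysis."""

    residue: int
    role: str


@dataclass
class FrameSeries:
    """Time-stamped coordinate snapshots of selected atoms.

    Parameters
    ----------
    times : ndarray, shape (n_frames,)
        Frame timestamps in ps, strictly increasing.
    atoms : sequence of Atom
        Atom labels; ordering is identical in every frame.
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Positions in nm.
    """

    times: np.ndarray
    atoms: tuple
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.atoms = tuple(Atom(int(a[0]), str(a[1])) for a in self.atoms)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] != self.times.size:
            raise ValueError("times and coords disagree on the frame count")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atoms and coords disagree on the atom count")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def dt(self) -> float:
        """Median frame interval in ps (0.0 for a single frame)."""
        if self.times.size < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    def indices(self, roles: Iterable[str]) -> np.ndarray:
        roles = set(roles)
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.role in roles], dtype=int
        )


@dataclass
class HBStateMatrix:
    """Per-frame, per-bond boolean hydrogen-bond formation states.

    ``h_series`` (the per-frame count of formed bonds) is derived from the
    boolean matrix and always equals its row sums.
    """

    dt: float
    states: np.ndarray
    bond_labels: list
    h_max: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.ndim != 2:
            raise ValueError("states must be a 2-D (frames x bonds) matrix")
        if self.h_max < self.states.shape[1]:
            raise ValueError("h_max smaller than the number of bond columns")

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.states.shape[1]

    @property
    def h_series(self) -> np.ndarray:
        """Number of formed bonds per frame (row sums of ``states``)."""
        return self.states.sum(axis=1).astype(np.int64)


@dataclass
class Histogram1D:
    """Simple binned state-density table: ``counts[i]`` covers
    ``edges[i] <= x < edges[i+1]`` (last bin right-closed)."""

    edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def detect_hbonds(frames: FrameSeries, cutoff: float = HB_CUTOFF_NM) -> HBStateMatrix:
    """Detect helical (i, i+4) hydrogen bonds by the distance criterion.

    Bond (i, i+4) is formed at frame t iff ``|O_i - N_{i+4}| < cutoff``
    (strict inequality).  The topology is every residue pair (i, i+4) with
    both residues present in the frame series; each such pair must carry a
    carbonyl O on residue i and an amide N on residue i+4.

    Returns
    -------
    HBStateMatrix
        With one column per (i, i+4) pair and ``h_max`` equal to the number
        of pairs.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    by_key = {}
    for idx, a in enumerate(frames.atoms):
        by_key.setdefault((a.residue, a.role), idx)
    residues = sorted({a.residue for a in frames.atoms})
    resset = set(residues)
    pairs = [(i, i + 4) for i in residues if i + 4 in resset]
    if not pairs:
        raise ValueError("topology has no (i, i+4) residue pairs")
    o_idx, n_idx = [], []
    for i, j in pairs:
        if (i, "O") not in by_key:
            raise ValueError(f"residue {i} is missing required atom role O")
        if (j, "N") not in by_key:
            raise ValueError(f"residue {j} is missing required atom role N")
        o_idx.append(by_key[(i, "O")])
        n_idx.append(by_key[(j, "N")])
    diff = frames.coords[:, o_idx, :] - frames.coords[:, n_idx, :]
    dist = np.linalg.norm(diff, axis=2)
    states = dist < cutoff
    return HBStateMatrix(
        dt=frames.dt,
        states=states,
        bond_labels=pairs,
        h_max=len(pairs),
        meta={"cutoff_nm": cutoff},
    )


def helix_fraction(states: HBStateMatrix) -> float:
    """Mean fraction of formed helical bonds, f = <h_i> / h_max."""
    if states.h_max <= 0:
        raise ValueError("h_max must be positive to define a helix fraction")
    return float(states.h_series.mean() / states.h_max)


def end_to_end(frames: FrameSeries) -> np.ndarray:
    """Per-frame Euclidean distance between the two terminal atoms.

    Atoms with role ``terminal`` are used when exactly two are present;
    otherwise the first and last CA atoms serve as termini.
    """
    term = frames.indices(["terminal"])
    if term.size == 2:
        i, j = term
    elif term.size > 0:
        raise ValueError(f"expected exactly 2 terminal atoms, found {term.size}")
    else:
        ca = frames.indices(["CA"])
        if ca.size < 2:
            raise ValueError("no terminal atoms and fewer than 2 CA atoms")
        i, j = ca[0], ca[-1]
    return np.linalg.norm(frames.coords[:, i, :] - frames.coords[:, j, :], axis=1)


def _kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Least-squares RMSD of p onto q after optimal rotation+translation.

    Proper rotations only: a reflection is corrected by flipping the sign
    of the smallest singular value.
    """
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    # apply the optimal rotation and measure residuals directly: the
    # closed-form sum-of-squares expression cancels catastrophically for
    # near-congruent frames
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    resid = pc @ rot - qc
    return float(np.sqrt((resid**2).sum() / len(p)))


def rmsdh(
    frames: FrameSeries,
    reference: FrameSeries,
    selection: Sequence[str] = ("CA",),
) -> np.ndarray:
    """RMSD from the reference (ideal helix) after rigid realignment.

    Each frame is superposed onto the first frame of ``reference`` using the
    closed-form least-squares rotation (Kabsch), restricted to atoms whose
    role is in ``selection`` (default CA).
    """
    sel_f = frames.indices(selection)
    sel_r = reference.indices(selection)
    if sel_f.size != sel_r.size:
        raise ValueError(
            f"selection atom counts differ: {sel_f.size} vs {sel_r.size}"
        )
    if sel_f.size == 0:
        raise ValueError("selection matches no atoms")
    q = reference.coords[0, sel_r, :]
    out = np.empty(frames.n_frames)
    for t in range(frames.n_frames):
        out[t] = _kabsch_rmsd(frames.coords[t, sel_f, :], q)
    return out


def rmsdh_histogram(series: np.ndarray, bin_width: float) -> Histogram1D:
    """Bin an RMSDH series into a state-density table.

    Counts sum to the number of frames; bin edges are multiples of
    ``bin_width`` spanning the data.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    lo = np.floor(series.min() / bin_width) * bin_width
    hi = np.ceil(series.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(series, bins=edges)
    return Histogram1D(edges=edges, counts=counts)
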