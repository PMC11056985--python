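"""Synthetic trajectory generators.

Discrete-time samples of continuous-time two-state hydrogen-bond kinetics,
helix-geometry end-to-end distances, 3-D Brownian particle paths and
ideal-helix coordinate frames.  These stand in for MD output so that every
downstream estimator can be validated against known ground truth; they make
no claim to reproduce MD ensembles.

Units: rates in 1/us, frame intervals in ps, lengths in nm, diffusion
constants in cm^2/s.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .structure import Atom, FrameSeries, HBStateMatrix

__all__ = [
    "SpecValidationError",
    "KineticsSpec",
    "GeometrySpec",
    "BrownianSpec",
    "BrownianPaths",
    "simulate_hb_states",
    "hb_to_end_to_end",
    "simulate_brownian",
    "ideal_helix_coordinates",
]

PS_PER_US = 1.0e6
#: 1 cm^2/s expressed in nm^2/ps.
CM2_PER_S_TO_NM2_PER_PS = 100.0


class SpecValidationError(ValueError):
    """Raised when a generator spec violates one of its invariants."""


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise SpecValidationError(f"{name}: {msg}")


@dataclass(frozen=True)
class KineticsSpec:
    """Two-state per-bond hydrogen-bond kinetics.

    Each bond switches between broken and formed with rates ``k_form`` and
    ``k_break`` (1/us).  ``cooperativity`` multiplies ``k_form`` whenever at
    least one neighbouring bond is currently formed (1.0 = independent
    bonds).  The chain is sampled every ``dt`` ps using the exact per-step
    transition probabilities ``1 - exp(-k*dt)``.
    """

    n_bonds: int
    k_form: float
    k_break: float
    cooperativity: float = 1.0
    dt: float = 2.0
    n_frames: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        _require(int(self.n_bonds) >= 1, "n_bonds", "must be >= 1")
        _require(self.k_form > 0, "k_form", "must be > 0")
        # k_break == 0 is admitted: the formed state becomes absorbing.
        _require(self.k_break >= 0, "k_break", "must be >= 0")
        _require(self.cooperativity > 0, "cooperativity", "must be > 0")
        _require(self.dt > 0, "dt", "must be > 0")
        _require(int(self.n_frames) >= 2, "n_frames", "must be >= 2")


@dataclass(frozen=True)
class GeometrySpec:
    """Helix geometry plus the coil (fully broken) end-to-end statistics."""

    rise_per_residue: float = 0.15
    twist_per_residue: float = 100.0
    helix_radius: float = 0.23
    coil_length_mean: float = 1.0
    coil_length_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.rise_per_residue > 0, "rise_per_residue", "must be > 0")
        _require(self.helix_radius > 0, "helix_radius", "must be > 0")
        _require(self.coil_length_sd >= 0, "coil_length_sd", "must be >= 0")


@dataclass(frozen=True)
class BrownianSpec:
    """Ensemble of independent 3-D Brownian particles."""

    n_particles: int
    d_true: float
    dt: float = 2.0
    n_frames: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        _require(int(self.n_particles) >= 1, "n_particles", "must be >= 1")
        _require(self.d_true > 0, "d_true", "must be > 0")
        _require(self.dt > 0, "dt", "must be > 0")
        _require(int(self.n_frames) >= 2, "n_frames", "must be >= 2")


@dataclass
class BrownianPaths:
    """Particle position series: ``positions`` has shape
    (n_frames, n_particles, 3), in nm."""

    dt: float
    positions: np.ndarray
    meta: dict = field(default_factory=dict)


def _telegraph(rng: np.random.Generator, n: int, p_form: float, p_break: float) -> np.ndarray:
    """Sample one bond's boolean state chain of length ``n``.

    Uses alternating geometric run lengths, which is exactly equivalent to
    stepping the two-state chain frame by frame (forward run lengths from
    any fixed time are geometric by memorylessness) but costs O(#runs).
    The initial state is drawn from the stationary distribution.
    """
    if p_break <= 0.0:
        # Formed state is absorbing.
        out = np.ones(n, dtype=bool)
        state = True  # stationary distribution puts all mass on formed
        if not state:  # pragma: no cover - kept for clarity
            first = min(int(rng.geometric(p_form)), n)
            out[:first] = False
        return out
    pi1 = p_form / (p_form + p_break)
    first_state = bool(rng.random() < pi1)
    pair_mean = 1.0 / p_form + 1.0 / p_break
    chunks = []
    total = 0
    cur = first_state
    while total < n:
        m = max(8, int(1.5 * (n - total) / pair_mean) + 1)
        inter = np.empty(2 * m, dtype=np.int64)
        inter[0::2] = rng.geometric(p_break if cur else p_form, size=m)
        inter[1::2] = rng.geometric(p_form if cur else p_break, size=m)
        chunks.append(inter)
        total += int(inter.sum())
    lens = np.concatenate(chunks) if len(chunks) > 1 else chunks[0]
    vals = np.empty(lens.size, dtype=bool)
    vals[0::2] = first_state
    vals[1::2] = not first_state
    # Trim to the needed number of runs before expanding.
    cum = np.cumsum(lens)
    last = int(np.searchsorted(cum, n))
    return np.repeat(vals[: last + 1], lens[: last + 1])[:n]


def _coupled_chain(
    rng: np.random.Generator, spec: KineticsSpec, p_break: float
) -> np.ndarray:
    """Frame-by-frame chain with nearest-neighbour cooperativity."""
    dt_us = spec.dt / PS_PER_US
    p_form = -np.expm1(-spec.k_form * dt_us)
    p_form_coop = -np.expm1(-spec.k_form * spec.cooperativity * dt_us)
    n, nb = spec.n_frames, spec.n_bonds
    states = np.empty((n, nb), dtype=bool)
    pi1 = p_form / (p_form + p_break) if p_break > 0 else 1.0
    s = rng.random(nb) < pi1
    for t in range(n):
        states[t] = s
        neigh = np.zeros(nb, dtype=bool)
        neigh[1:] |= s[:-1]
        neigh[:-1] |= s[1:]
        pf = np.where(neigh, p_form_coop, p_form)
        u = rng.random(nb)
        s = np.where(s, u >= p_break, u < pf)
    return states


def simulate_hb_states(spec: KineticsSpec) -> HBStateMatrix:
    """Simulate per-bond boolean formation states.

    For independent bonds (``cooperativity == 1``) the stationary occupancy
    of each bond is ``k_form / (k_form + k_break)`` up to O(k*dt) sampling
    corrections, and formed/broken run lengths are geometric with parameter
    ``1 - exp(-k*dt)``.
    """
    rng = np.random.default_rng(spec.seed)
    dt_us = spec.dt / PS_PER_US
    p_form = -np.expm1(-spec.k_form * dt_us)
    p_break = -np.expm1(-spec.k_break * dt_us)
    if spec.cooperativity == 1.0 or spec.n_bonds == 1:
        cols = [
            _telegraph(rng, spec.n_frames, p_form, p_break)
            for _ in range(spec.n_bonds)
        ]
        states = np.column_stack(cols)
    else:
        states = _coupled_chain(rng, spec, p_break)
    return HBStateMatrix(
        dt=spec.dt,
        states=states,
        bond_labels=[(i, i + 4) for i in range(spec.n_bonds)],
        h_max=spec.n_bonds,
        meta={
            "generator": "simulate_hb_states",
            "seed": spec.seed,
            "k_form_per_us": spec.k_form,
            "k_break_per_us": spec.k_break,
            "cooperativity": spec.cooperativity,
        },
    )


def hb_to_end_to_end(states: HBStateMatrix, geom: GeometrySpec) -> np.ndarray:
    """Map HB counts to an end-to-end distance series (nm).

    distance(t) = coil baseline sample + h(t) * rise_per_residue, so the
    conditional mean given h formed bonds increases by exactly one helix
    rise per extra bond.  The coil baseline is Gaussian truncated at zero
    (distances are nonnegative).
    """
    rng = np.random.default_rng(geom.seed)
    h = states.h_series
    if geom.coil_length_sd == 0.0:
        coil = np.full(h.size, geom.coil_length_mean)
    else:
        a = (0.0 - geom.coil_length_mean) / geom.coil_length_sd
        coil = stats.truncnorm.rvs(
            a,
            np.inf,
            loc=geom.coil_length_mean,
            scale=geom.coil_length_sd,
            size=h.size,
            random_state=rng,
        )
    return coil + h * geom.rise_per_residue


def simulate_brownian(spec: BrownianSpec) -> BrownianPaths:
    """Independent 3-D Brownian paths with per-axis step variance
    ``2 * d_true * dt`` (all particles start at the origin)."""
    rng = np.random.default_rng(spec.seed)
    d_nm2ps = spec.d_true * CM2_PER_S_TO_NM2_PER_PS
    sigma = np.sqrt(2.0 * d_nm2ps * spec.dt)
    steps = rng.normal(0.0, sigma, size=(spec.n_frames - 1, spec.n_particles, 3))
    pos = np.empty((spec.n_frames, spec.n_particles, 3))
    pos[0] = 0.0
    np.cumsum(steps, axis=0, out=pos[1:])
    return BrownianPaths(
        dt=spec.dt,
        positions=pos,
        meta={"generator": "simulate_brownian", "seed": spec.seed,
              "d_true_cm2_s": spec.d_true},
    )


def ideal_helix_coordinates(
    n_residues: int,
    geom: Optional[GeometrySpec] = None,
    o_axial_offset: float = 0.23,
    n_axial_offset: float = 0.10,
) -> FrameSeries:
    """Single-frame ideal helix with CA, O and N atoms per residue.

    CA atoms sit on a regular helix with the spec's rise, twist and radius.
    The carbonyl O of residue i is offset along the helix axis toward the
    C-terminus and the amide N slightly the other way, so that for the
    default alpha-helix geometry every (i, i+4) O...N distance is ~0.31 nm,
    comfortably below the 0.36 nm bond criterion.
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    geom = geom or GeometrySpec()
    i = np.arange(n_residues)
    theta = np.deg2rad(geom.twist_per_residue) * i
    ca = np.column_stack(
        (
            geom.helix_radius * np.cos(theta),
            geom.helix_radius * np.sin(theta),
            geom.rise_per_residue * i,
        )
    )
    axis = np.array([0.0, 0.0, 1.0])
    o = ca + o_axial_offset * axis
    n_at = ca - n_axial_offset * axis
    atoms = []
    coords = []
    for k in range(n_residues):
        atoms += [Atom(k, "CA"), Atom(k, "O"), Atom(k, "N")]
        coords += [ca[k], o[k], n_at[k]]
    return FrameSeries(
        times=np.array([0.0]),
        atoms=tuple(atoms),
        coords=np.asarray(coords)[None, :, :],
    )
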