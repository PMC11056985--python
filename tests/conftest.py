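"""Shared fixtures and independent reference implementations (oracles)."""
from __future__ import annotations

import numpy as np
import pytest

from helixfriction.structure import Atom, FrameSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def telegraph_acf_mean():
    """Replicate-averaged single-bond ACF for k_form=5/us, k_break=15/us.

    A single series' normalized-ACF error depends only on T/tau_c, so
    precision comes from averaging ACF curves over independent replicas
    (16 x 80 us here), not from longer series or more bonds.
    Returns (acf, dt_ps); the true relaxation time is 50_000 ps.
    """
    from helixfriction.kinetics import autocorrelation
    from helixfriction.synthgen import KineticsSpec, simulate_hb_states

    acfs = []
    for rep in range(16):
        spec = KineticsSpec(n_bonds=1, k_form=5.0, k_break=15.0, dt=20.0,
                            n_frames=4_000_000, seed=9000 + rep)
        m = simulate_hb_states(spec)
        acfs.append(autocorrelation(m.h_series.astype(float), max_lag=20_000))
    return np.mean(acfs, axis=0), 20.0


def make_frames(coords, atoms, dt=2.0):
    """FrameSeries from raw coordinates (n_frames, n_atoms, 3)."""
    coords = np.asarray(coords, dtype=float)
    times = np.arange(coords.shape[0]) * dt
    return FrameSeries(times=times, atoms=tuple(atoms), coords=coords)


def single_pair_frames(o_pos, n_pos):
    """One frame containing the O of residue 0 and the N of residue 4."""
    atoms = [Atom(0, "O"), Atom(4, "N")]
    coords = np.asarray([[o_pos, n_pos]], dtype=float)
    return make_frames(coords, atoms)


def random_rigid_transform(rng):
    """A uniformly random proper rotation plus a random translation."""
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    trans = rng.normal(0, 2.0, size=3)
    return rot.as_matrix(), trans


# ---------------------------------------------------------------- oracles

def acf_direct(x, max_lag):
    """Direct-sum unbiased autocorrelation (O(N * max_lag) oracle)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    dx = x - x.mean()
    denom = (dx**2).sum() / n
    out = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        out[lag] = (dx[: n - lag] * dx[lag:]).sum() / (n - lag) / denom
    return out


def msd_double_loop(pos):
    """Naive all-origins MSD oracle: mean over t of |r(t+m)-r(t)|^2,
    averaged over particles.  O(N^2) - tiny inputs only."""
    pos = np.asarray(pos, dtype=float)
    n = pos.shape[0]
    out = np.zeros(n)
    for m in range(n):
        disp = pos[m:] - pos[: n - m]
        out[m] = (disp**2).sum(axis=2).mean()
    return out


def dwell_scan(signal, target=None):
    """Naive per-frame dwell scan.

    Returns (completed_run_lengths, censored_count) where censored counts
    boundary runs matching ``target`` (or all boundary runs when target is
    None, i.e. value-agnostic segmentation).
    """
    signal = list(signal)
    runs = []  # (value, length)
    for v in signal:
        if runs and runs[-1][0] == v:
            runs[-1][1] += 1
        else:
            runs.append([v, 1])
    if len(runs) <= 2:
        keep = [r for r in runs if target is None or bool(r[0]) == target]
        return [], len(keep)
    interior = runs[1:-1]
    boundary = [runs[0], runs[-1]]
    completed = [
        length for v, length in interior if target is None or bool(v) == target
    ]
    censored = sum(
        1 for v, _ in boundary if target is None or bool(v) == target
    )
    return completed, censored


def rmsd_bruteforce(p, q):
    """RMSD after superposition, by rotation grid search plus local
    refinement - independent of the closed-form solution."""
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)

    def cost(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((pc @ r.T - qc) ** 2).sum() / len(p))

    best = []
    grid = np.linspace(-np.pi, np.pi, 7)
    for a in grid:
        for b in grid:
            for c in grid:
                v = np.array([a, b, c])
                best.append((cost(v), v))
    best.sort(key=lambda t: t[0])
    out = np.inf
    for _, v0 in best[:5]:
        res = minimize(cost, v0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        out = min(out, res.fun)
    return out
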