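"""Water diffusion, relative viscosity and zero-viscosity extrapolation.

Ensemble- and time-origin-averaged mean-square displacement gives the
water diffusion constant (slope/6); the relative viscosity is the inverse
ratio of diffusion constants; friction-vs-viscosity series are fit with a
straight line (whose intercept is the internal friction) or a power law
gamma = gamma_w * (eta/eta0)^beta.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "D_W0_REF_CM2_S",
    "MSDResult",
    "ViscosityFit",
    "ensemble_msd",
    "msd_diffusion",
    "relative_viscosity",
    "fit_friction_vs_viscosity",
    "normalize_series",
]

#: Reference self-diffusion constant of the pure-water model (cm^2/s).
D_W0_REF_CM2_S = 5.6635e-5

#: 1 nm^2/ps expressed in cm^2/s.
NM2_PER_PS_TO_CM2_PER_S = 1.0e-2


@dataclass
class MSDResult:
    lag_times_ps: np.ndarray
    msd_nm2: np.ndarray
    d_cm2_s: float
    slope_nm2_ps: float
    intercept_nm2: float
    r_value: float
    window: tuple
    flags: list = field(default_factory=list)


@dataclass
class ViscosityFit:
    """Linear or power-law fit of friction against relative viscosity."""

    model: str  # "linear" | "power"
    a: float | None = None  # linear slope
    gamma0: float | None = None  # linear intercept = internal friction
    gamma_w: float | None = None  # power-law prefactor (friction at eta/eta0=1)
    beta: float | None = None  # power-law exponent
    residuals: np.ndarray | None = None

    @property
    def rss(self) -> float:
        return float((self.residuals**2).sum()) if self.residuals is not None else np.nan


def _msd_all_origins(pos: np.ndarray) -> np.ndarray:
    """MSD over all time origins for every particle, FFT-accelerated.

    pos has shape (n_frames, n_particles, 3); returns (n_frames,
    n_particles).  Equivalent to the naive double loop
    mean_t |r(t+m) - r(t)|^2 for each lag m.
    """
    n, n_part, _ = pos.shape
    m = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(pos, m, axis=0)
    s2 = np.fft.irfft((f * np.conj(f)).real + 1j * 0, m, axis=0)[:n].sum(axis=2)
    sq = (pos**2).sum(axis=2)  # (n, n_part)
    d_ext = np.vstack([sq, np.zeros((1, n_part))])
    # sub[m] = D[m-1] + D[n-m]; sub[0] = 0 by the zero padding row
    idx_prev = np.arange(-1, n - 1)
    idx_tail = n - np.arange(n)
    sub = d_ext[idx_prev] + d_ext[idx_tail]
    q = 2.0 * sq.sum(axis=0) - np.cumsum(sub, axis=0)
    denom = (n - np.arange(n))[:, None]
    s1 = q / denom
    return s1 - 2.0 * s2 / denom


def ensemble_msd(
    positions: np.ndarray, dt: float, chunk_frames: int | None = None
):
    """Particle-averaged MSD curve; optionally averaged over consecutive
    trajectory chunks of ``chunk_frames`` frames each.

    Returns (lag_times_ps, msd_nm2).
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 3 or pos.shape[2] != 3:
        raise ValueError("positions must have shape (n_frames, n_particles, 3)")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = pos.shape[0]
    if chunk_frames is None or chunk_frames >= n:
        msd = _msd_all_origins(pos).mean(axis=1)
        return np.arange(n) * dt, msd
    if chunk_frames < 2:
        raise ValueError("chunk_frames must be >= 2")
    n_chunks = n // chunk_frames
    if n_chunks == 0:
        raise ValueError("trajectory shorter than one chunk")
    acc = np.zeros(chunk_frames)
    for c in range(n_chunks):
        seg = pos[c * chunk_frames : (c + 1) * chunk_frames]
        # re-reference each chunk to its own first frame
        acc += _msd_all_origins(seg - seg[0]).mean(axis=1)
    return np.arange(chunk_frames) * dt, acc / n_chunks


def msd_diffusion(
    positions: np.ndarray,
    dt: float,
    fit_window: tuple = (0.1, 0.5),
    chunk_frames: int | None = None,
) -> MSDResult:
    """Diffusion constant from the MSD slope: D = slope / 6.

    The linear fit runs over ``fit_window`` (fractions of the maximum lag),
    excluding the short-time nonlinear domain.  Diagnostics flag a
    zero MSD and curvature within the fit window (slope differing by more
    than 10% between the two window halves).
    """
    lags, msd = ensemble_msd(positions, dt, chunk_frames=chunk_frames)
    n = lags.size
    i0 = max(1, int(fit_window[0] * n))
    i1 = min(n, int(fit_window[1] * n))
    if i1 - i0 < 3:
        raise ValueError("fit window too short: fewer than 3 points")
    flags = []
    if msd.max() < 1e-12:
        return MSDResult(
            lag_times_ps=lags,
            msd_nm2=msd,
            d_cm2_s=0.0,
            slope_nm2_ps=0.0,
            intercept_nm2=0.0,
            r_value=0.0,
            window=(i0, i1),
            flags=["zero_msd"],
        )
    res = stats.linregress(lags[i0:i1], msd[i0:i1])
    mid = (i0 + i1) // 2
    s_a = stats.linregress(lags[i0:mid], msd[i0:mid]).slope
    s_b = stats.linregress(lags[mid:i1], msd[mid:i1]).slope
    denom = 0.5 * abs(s_a + s_b)
    if denom > 0 and abs(s_b - s_a) / denom > 0.10:
        flags.append("nonlinear")
    d_nm2ps = res.slope / 6.0
    return MSDResult(
        lag_times_ps=lags,
        msd_nm2=msd,
        d_cm2_s=d_nm2ps * NM2_PER_PS_TO_CM2_PER_S,
        slope_nm2_ps=float(res.slope),
        intercept_nm2=float(res.intercept),
        r_value=float(res.rvalue),
        window=(i0, i1),
        flags=flags,
    )


def relative_viscosity(d_w: float, d_w0_ref: float = D_W0_REF_CM2_S) -> float:
    """Relative viscosity eta/eta0 = D_w0 / D_w (Stokes ratio)."""
    if d_w <= 0:
        raise ValueError("d_w must be positive")
    if d_w0_ref <= 0:
        raise ValueError("d_w0_ref must be positive")
    return d_w0_ref / d_w


def fit_friction_vs_viscosity(
    points, model: str = "linear", refine: bool = False
) -> ViscosityFit:
    """Fit (eta/eta0, gamma) pairs.

    ``linear``: gamma = a * eta + gamma0 (gamma0 = internal friction).
    ``power``: gamma = gamma_w * eta^beta, fit in log-log space by linear
    least squares (stable with as few as 3 points); ``refine=True`` polishes
    with a nonlinear fit in the original space.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (eta, gamma)")
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    eta, gamma = pts[:, 0], pts[:, 1]
    if model == "linear":
        slope, intercept = np.polyfit(eta, gamma, 1)
        resid = gamma - (slope * eta + intercept)
        return ViscosityFit(model="linear", a=float(slope), gamma0=float(intercept),
                            residuals=resid)
    if model == "power":
        if np.any(eta <= 0) or np.any(gamma <= 0):
            raise ValueError("power-law fit requires positive eta and gamma")
        beta, logg = np.polyfit(np.log(eta), np.log(gamma), 1)
        gamma_w = float(np.exp(logg))
        beta = float(beta)
        if refine:
            try:
                popt, _ = optimize.curve_fit(
                    lambda e, gw, b: gw * e**b, eta, gamma, p0=[gamma_w, beta],
                    maxfev=20000,
                )
                gamma_w, beta = float(popt[0]), float(popt[1])
            except RuntimeError:
                pass  # keep the log-log solution
        if gamma_w <= 0:
            raise ValueError("power-law prefactor must be positive")
        resid = gamma - gamma_w * eta**beta
        return ViscosityFit(model="power", gamma_w=gamma_w, beta=beta,
                            residuals=resid)
    raise ValueError(f"unknown model {model!r}")


def normalize_series(points, tol: float = 1e-6) -> np.ndarray:
    """Divide all friction values by the value at eta/eta0 = 1.

    Uses the point at relative viscosity one when present (within ``tol``),
    otherwise interpolates; raises when no reference value is obtainable.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (eta, gamma)")
    eta, gamma = pts[:, 0], pts[:, 1]
    at_one = np.nonzero(np.abs(eta - 1.0) <= tol)[0]
    if at_one.size:
        ref = gamma[at_one[0]]
    elif eta.min() < 1.0 < eta.max():
        order = np.argsort(eta)
        ref = float(np.interp(1.0, eta[order], gamma[order]))
    else:
        raise ValueError("no reference point at relative viscosity 1")
    if ref == 0:
        raise ValueError("reference friction at eta/eta0 = 1 is zero")
    out = pts.copy()
    out[:, 1] = gamma / ref
    return out
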