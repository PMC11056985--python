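"""Two-state folding kinetics from the hydrogen-bond count series.

Autocorrelation of h(t), mono-exponential relaxation-time fits, and the
two-state closure that turns (tau_f, f) into folding/unfolding rate
constants and the equilibrium constant K, including the complete-differential
error rule used for K.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FitError",
    "RelaxationFit",
    "RateEstimate",
    "autocorrelation",
    "fit_relaxation",
    "rates_from_relaxation",
    "propagate_K_error",
]


class FitError(RuntimeError):
    """Non-convergent or degenerate fit; carries diagnostics in ``info``."""

    def __init__(self, message: str, info: dict | None = None):
        super().__init__(message)
        self.info = info or {}


@dataclass
class RelaxationFit:
    """Result of fitting C(t) = A exp(-t/tau) (+ c)."""

    tau: float
    amplitude: float
    constant: float
    used_constant: bool
    rss: float
    n_points: int
    aicc: float


@dataclass
class RateEstimate:
    """Two-state rates and equilibrium constant.

    Rates are in inverse units of ``tau_f`` (1/us when tau_f is in us).
    ``K == k_fold / k_unfold == f / (1 - f)`` by construction.
    """

    tau_f: float
    f: float
    k_fold: float
    k_unfold: float
    K: float
    errors: dict = field(default_factory=dict)


def autocorrelation(
    series: np.ndarray, max_lag: int, normalization: str = "unbiased"
) -> np.ndarray:
    """Normalized autocorrelation C(lag) of a scalar series.

    C(0) = 1 and C(lag) = <dh(t) dh(t+lag)> / <dh^2> with dh = h - mean(h),
    the angle brackets averaging over all available pairs (``unbiased``).
    ``normalization="biased"`` divides every lag by N instead; the two agree
    for max_lag << N.  Computed via FFT (zero-padded, no wraparound).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if max_lag < 0 or max_lag >= n:
        raise ValueError("series length must exceed max_lag")
    if np.ptp(x) == 0:
        raise ValueError("degenerate series: zero variance")
    dx = x - x.mean()
    m = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(dx, m)
    acov = np.fft.irfft(f * np.conj(f), m)[: max_lag + 1]
    if normalization == "unbiased":
        acov = acov / (n - np.arange(max_lag + 1))
    elif normalization == "biased":
        acov = acov / n
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return acov / acov[0]


def _aicc(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    penalty = 2 * k * (k + 1) / (n - k - 1) if n - k - 1 > 0 else np.inf
    return n * np.log(rss / n) + 2 * k + penalty


def fit_relaxation(
    acf: np.ndarray,
    dt: float,
    with_constant: str | bool = "auto",
    cutoff: float = 0.05,
) -> RelaxationFit:
    """Fit the relaxation time tau_f to an autocorrelation function.

    Least-squares fit of ``C(t) = A exp(-t/tau) + c`` against lag times
    ``t = lag * dt``.  Only lags up to the first crossing of
    ``C < cutoff`` enter the fit (long-lag noise dominates otherwise).
    ``with_constant`` may be True, False, or "auto", in which case the
    constant is kept only when it improves the corrected AIC.
    """
    acf = np.asarray(acf, dtype=float)
    if acf.size < 3:
        raise ValueError("need at least 3 lag points")
    if dt <= 0:
        raise ValueError("dt must be positive")
    below = np.nonzero(acf < cutoff)[0]
    end = int(below[0]) if below.size else acf.size
    end = int(np.clip(end, 4, acf.size))
    t = np.arange(end) * dt
    y = acf[:end]

    near = np.nonzero(y < np.exp(-1.0))[0]
    tau0 = t[near[0]] if near.size and near[0] > 0 else max(t[-1] / 2.0, dt)

    def m_simple(tt, a, tau):
        return a * np.exp(-tt / tau)

    def m_const(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    def _fit(model, p0):
        popt, _ = curve_fit(model, t, y, p0=p0, maxfev=20000)
        rss = float(((model(t, *popt) - y) ** 2).sum())
        return popt, rss

    results = {}
    try:
        if with_constant in (False, "auto"):
            popt, rss = _fit(m_simple, [1.0, tau0])
            results["simple"] = (popt, rss, _aicc(rss, end, 2))
        if with_constant in (True, "auto"):
            popt, rss = _fit(m_const, [1.0, tau0, 0.0])
            results["const"] = (popt, rss, _aicc(rss, end, 3))
    except RuntimeError as exc:
        if not results:
            raise FitError(
                "relaxation fit did not converge",
                info={"n_points": end, "tau0": tau0, "cause": str(exc)},
            ) from exc
    if not results:
        raise FitError("relaxation fit did not converge", info={"n_points": end})
    key = min(results, key=lambda k: results[k][2])
    popt, rss, aicc = results[key]
    used_constant = key == "const"
    tau = float(abs(popt[1]))
    if tau <= 0 or not np.isfinite(tau):
        raise FitError("fitted tau is not positive", info={"popt": list(popt)})
    return RelaxationFit(
        tau=tau,
        amplitude=float(popt[0]),
        constant=float(popt[2]) if used_constant else 0.0,
        used_constant=used_constant,
        rss=rss,
        n_points=end,
        aicc=aicc,
    )


def rates_from_relaxation(tau_f: float, f: float) -> RateEstimate:
    """Two-state closure: k_fold + k_unfold = 1/tau_f with K = f/(1-f).

    Hence k_fold = f/tau_f and k_unfold = (1-f)/tau_f.  Requires
    0 < f < 1 (a trajectory pinned at either end has no transitions).
    """
    if tau_f <= 0:
        raise ValueError("tau_f must be positive")
    if not 0.0 < f < 1.0:
        raise ValueError("no transitions: f must lie strictly between 0 and 1")
    k_fold = f / tau_f
    k_unfold = (1.0 - f) / tau_f
    return RateEstimate(
        tau_f=tau_f,
        f=f,
        k_fold=k_fold,
        k_unfold=k_unfold,
        K=k_fold / k_unfold,
    )


def propagate_K_error(
    K: float, k_fold: float, dk_fold: float, k_unfold: float, dk_unfold: float
) -> float:
    """Maximum error of K = k_fold/k_unfold via the complete differential:
    dK = K * (dk_fold/k_fold + dk_unfold/k_unfold)."""
    if k_fold <= 0 or k_unfold <= 0:
        raise ValueError("rates must be positive")
    if dk_fold < 0 or dk_unfold < 0:
        raise ValueError("rate errors must be nonnegative")
    return K * (dk_fold / k_fold + dk_unfold / k_unfold)
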