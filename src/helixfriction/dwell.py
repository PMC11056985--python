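"""Dwell-time extraction and exponential-mixture fitting.

Maximal constant runs of a binary bond signal (or of the total HB count)
give dwell durations; these are binned on a logarithmic time axis and the
log-domain generating function is fit with a one- or two-component
exponential mixture.  The amplitude-weighted mean of the component time
constants is the single ensemble dwell time feeding the local friction
estimate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, minimize

from .structure import HBStateMatrix

__all__ = [
    "DwellSet",
    "LogHistogram",
    "ExpMixFit",
    "MODES",
    "extract_dwells",
    "log_histogram",
    "fit_exponential_mixture",
    "ensemble_dwell_time",
]

MODES = ("per_bond_formed", "per_bond_broken", "total_h_constant")


@dataclass
class DwellSet:
    """Censoring-aware collection of dwell durations (ps).

    The first and last runs of every scanned signal are boundary-truncated:
    their true durations are only bounded from below, so they are excluded
    from ``durations`` and tallied in ``censored_count`` (only runs matching
    the selected mode are counted).
    """

    durations: np.ndarray
    mode: str
    censored_count: int
    dt: float

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)

    @property
    def n(self) -> int:
        return self.durations.size


@dataclass
class LogHistogram:
    """Counts over bins uniform in log10(duration)."""

    edges: np.ndarray  # log10(ps)
    counts: np.ndarray
    bins_per_decade: int
    n_total: int

    @property
    def centers_log10(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def centers(self) -> np.ndarray:
        """Bin centers on the time axis (ps)."""
        return 10.0 ** self.centers_log10


@dataclass
class ExpMixFit:
    """Exponential-mixture fit of a log-binned dwell histogram."""

    components: list  # [(weight, tau_ps)], weights sum to 1, sorted by tau
    mean_tau: float  # amplitude-weighted mean of component taus (ps)
    n_components: int
    goodness: dict = field(default_factory=dict)
    fallback: bool = False


def _runs(sig: np.ndarray):
    """Starts, lengths and values of maximal constant runs of ``sig``."""
    sig = np.asarray(sig)
    change = np.flatnonzero(sig[1:] != sig[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [sig.size - 1]))
    return starts, ends - starts + 1, sig[starts]


def extract_dwells(states: HBStateMatrix, mode: str = "per_bond_formed") -> DwellSet:
    """Pool completed dwell durations over all bonds.

    ``per_bond_formed`` / ``per_bond_broken`` segment each bond's boolean
    state and keep runs of the corresponding value; ``total_h_constant``
    segments the total-HB series into runs of constant h (any value).
    Durations are run length x dt; boundary runs are censored.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if states.n_frames < 2:
        raise ValueError("need at least 2 frames")
    durations = []
    censored = 0
    if mode == "total_h_constant":
        signals = [(states.h_series, None)]
    else:
        target = mode == "per_bond_formed"
        signals = [(states.states[:, b], target) for b in range(states.n_bonds)]
    for sig, target in signals:
        _, lengths, values = _runs(sig)
        keep = np.ones(values.size, dtype=bool) if target is None else values == bool(target)
        if values.size <= 2:
            censored += int(keep.sum())
            continue
        censored += int(keep[0]) + int(keep[-1])
        interior = keep.copy()
        interior[0] = interior[-1] = False
        durations.append(lengths[interior] * states.dt)
    if not durations or sum(d.size for d in durations) == 0:
        raise ValueError("insufficient transitions: no completed dwells")
    return DwellSet(
        durations=np.concatenate(durations),
        mode=mode,
        censored_count=censored,
        dt=states.dt,
    )


def log_histogram(dwells: DwellSet, bins_per_decade: int = 10) -> LogHistogram:
    """Histogram of dwell durations with bins uniform in log10(t)."""
    if bins_per_decade <= 0:
        raise ValueError("bins_per_decade must be positive")
    d = dwells.durations
    if d.size == 0:
        raise ValueError("no durations to bin")
    logd = np.log10(d)
    lo = np.floor(logd.min() * bins_per_decade) / bins_per_decade
    hi = np.ceil(logd.max() * bins_per_decade) / bins_per_decade
    if hi <= lo:
        hi = lo + 1.0 / bins_per_decade
    n_bins = int(round((hi - lo) * bins_per_decade))
    edges = lo + np.arange(n_bins + 1) / bins_per_decade
    counts, _ = np.histogram(logd, bins=edges)
    return LogHistogram(
        edges=edges,
        counts=counts,
        bins_per_decade=bins_per_decade,
        n_total=d.size,
    )


def _mix_counts(t, amps, taus, bpd):
    """Expected counts in log-uniform bins at centers t for an exponential
    mixture: n = ln(10)/bpd * sum_j A_j (t/tau_j) exp(-t/tau_j)."""
    w = np.log(10.0) / bpd
    out = np.zeros_like(t, dtype=float)
    for a, tau in zip(amps, taus):
        out += a * (t / tau) * np.exp(-t / tau)
    return w * out


def fit_exponential_mixture(
    hist: LogHistogram,
    n_components: int = 2,
    method: str = "leastsq",
    degeneracy_ratio: float = 1.5,
) -> ExpMixFit:
    """Fit the log-domain generating function of the dwell histogram.

    Least squares on bin counts by default (zero-count bins included with
    unit weight); ``method="poisson"`` refines by Poisson likelihood.
    Components come back sorted by tau, amplitudes normalized to weights.
    A two-component fit that fails or collapses (tau ratio below
    ``degeneracy_ratio`` or a vanishing weight) falls back to one component
    with ``fallback=True``.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    t = hist.centers
    y = hist.counts.astype(float)
    n_free = 2 * n_components
    if np.count_nonzero(y) < max(2, n_free) and n_components == 2:
        return _fallback_to_single(hist, method, "too few occupied bins")
    if np.count_nonzero(y) < 2:
        raise ValueError("too few occupied bins to fit")

    n_tot = float(y.sum())
    tau_bar = float((y * t).sum() / n_tot)

    def model(tt, *logp):
        amps = np.exp(logp[:n_components])
        taus = np.exp(logp[n_components:])
        return _mix_counts(tt, amps, taus, hist.bins_per_decade)

    if n_components == 1:
        p0 = np.log([n_tot, tau_bar])
    else:
        cum = np.cumsum(y) / n_tot
        t_lo = t[np.searchsorted(cum, 0.3)]
        t_hi = t[min(np.searchsorted(cum, 0.9), t.size - 1)]
        if t_hi <= t_lo:
            t_lo, t_hi = tau_bar / 3.0, tau_bar * 2.0
        p0 = np.log([0.6 * n_tot, 0.4 * n_tot, t_lo, t_hi])

    try:
        popt, _ = curve_fit(model, t, y, p0=p0, maxfev=50000)
    except RuntimeError as exc:
        if n_components == 2:
            return _fallback_to_single(hist, method, f"no convergence: {exc}")
        raise

    amps = np.exp(popt[:n_components])
    taus = np.exp(popt[n_components:])

    if method == "poisson":
        def nll(logp):
            mu = np.clip(model(t, *logp), 1e-12, None)
            return float((mu - y * np.log(mu)).sum())

        res = minimize(nll, popt, method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-10})
        if res.success:
            amps = np.exp(res.x[:n_components])
            taus = np.exp(res.x[n_components:])

    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    weights = amps / amps.sum()

    if n_components == 2 and (
        taus[1] / taus[0] < degeneracy_ratio or weights.min() < 0.01
    ):
        return _fallback_to_single(hist, method, "degenerate two-component fit")

    resid = _mix_counts(t, amps, taus, hist.bins_per_decade) - y
    fit = ExpMixFit(
        components=[(float(w), float(tau)) for w, tau in zip(weights, taus)],
        mean_tau=float((weights * taus).sum()),
        n_components=n_components,
        goodness={
            "rss": float((resid**2).sum()),
            "n_bins": int(t.size),
            "n_events": int(hist.n_total),
        },
    )
    return fit


def _fallback_to_single(hist: LogHistogram, method: str, reason: str) -> ExpMixFit:
    fit = fit_exponential_mixture(hist, n_components=1, method=method)
    fit.fallback = True
    fit.goodness["fallback_reason"] = reason
    return fit


def ensemble_dwell_time(fit: ExpMixFit, rule: str = "amplitude_weighted") -> float:
    """Collapse a mixture fit to one ensemble dwell time tau (ps).

    Rules: ``amplitude_weighted`` (default; sum of weight*tau), ``slow``
    (largest tau), ``fast`` (smallest tau).
    """
    taus = [tau for _, tau in fit.components]
    if rule == "amplitude_weighted":
        return fit.mean_tau
    if rule == "slow":
        return max(taus)
    if rule == "fast":
        return min(taus)
    raise ValueError(f"unknown rule {rule!r}")
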