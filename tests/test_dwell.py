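"""Dwell extraction, log histograms and exponential-mixture fits."""
from __future__ import annotations

import numpy as np
import pytest

from conftest import dwell_scan
from helixfriction.dwell import (
    DwellSet,
    ensemble_dwell_time,
    extract_dwells,
    fit_exponential_mixture,
    log_histogram,
)
from helixfriction.structure import HBStateMatrix
from helixfriction.synthgen import KineticsSpec, simulate_hb_states

PS_PER_US = 1.0e6


def matrix_from(cols, dt=2.0):
    states = np.asarray(cols, dtype=bool).T if np.ndim(cols) == 2 else np.asarray(cols, dtype=bool)[:, None]
    return HBStateMatrix(dt=dt, states=states,
                         bond_labels=[(i, i + 4) for i in range(states.shape[1])],
                         h_max=states.shape[1])


def exp_mix_histogram(taus, weights, n_total, bins_per_decade=10, span=(0.5, 4.0)):
    """Noiseless log-binned histogram: expected counts of an exponential
    mixture evaluated at bin centers (exact model class for the fitter)."""
    from helixfriction.dwell import LogHistogram, _mix_counts

    edges = np.arange(span[0], span[1] + 1e-9, 1.0 / bins_per_decade)
    centers = 10 ** (0.5 * (edges[:-1] + edges[1:]))
    amps = np.asarray(weights) * n_total
    counts = _mix_counts(centers, amps, np.asarray(taus), bins_per_decade)
    return LogHistogram(edges=edges, counts=counts, bins_per_decade=bins_per_decade,
                        n_total=n_total)


def sampled_histogram(durations, bins_per_decade=10):
    ds = DwellSet(durations=np.asarray(durations, float), mode="per_bond_formed",
                  censored_count=0, dt=1e-6)
    return log_histogram(ds, bins_per_decade=bins_per_decade)


class TestExtractDwells:
    def test_hand_traced_convention(self):
        # leading formed run and trailing broken run are censored; the only
        # completed formed run is the two-frame one -> 4 ps at dt = 2 ps
        m = matrix_from([1, 1, 1, 0, 0, 1, 1, 0])
        d = extract_dwells(m, mode="per_bond_formed")
        np.testing.assert_array_equal(np.sort(d.durations), [4.0])
        assert d.censored_count == 1

    def test_hand_traced_broken(self):
        m = matrix_from([1, 1, 1, 0, 0, 1, 1, 0])
        d = extract_dwells(m, mode="per_bond_broken")
        np.testing.assert_array_equal(np.sort(d.durations), [4.0])
        assert d.censored_count == 1

    def test_alternating_all_dt(self):
        m = matrix_from([1, 0] * 50)
        d = extract_dwells(m, mode="per_bond_formed")
        assert (d.durations == 2.0).all()

    def test_total_h_constant_mode(self):
        states = np.array(
            [[1, 0], [1, 0], [1, 1], [1, 1], [1, 1], [0, 1], [1, 1]], dtype=bool
        )
        m = matrix_from(states.T)
        d = extract_dwells(m, mode="total_h_constant")
        # h = [1,1,2,2,2,1,2]; completed runs: the 3-frame h=2 and 1-frame h=1
        np.testing.assert_array_equal(np.sort(d.durations), [2.0, 6.0])
        assert d.censored_count == 2

    @pytest.mark.parametrize("mode, target", [
        ("per_bond_formed", True),
        ("per_bond_broken", False),
        ("total_h_constant", None),
    ])
    def test_matches_naive_scan_oracle(self, rng, mode, target):
        for _ in range(10):
            n_bonds = int(rng.integers(1, 4))
            p = rng.uniform(0.05, 0.6)
            states = rng.random((1000, n_bonds)) < p
            m = matrix_from(states.T if n_bonds > 1 else states[:, 0])
            expected, censored = [], 0
            if mode == "total_h_constant":
                runs, cens = dwell_scan(m.h_series, target=None)
                expected, censored = runs, cens
            else:
                for b in range(m.n_bonds):
                    runs, cens = dwell_scan(m.states[:, b], target=target)
                    expected += runs
                    censored += cens
            if not expected:
                with pytest.raises(ValueError):
                    extract_dwells(m, mode=mode)
                continue
            d = extract_dwells(m, mode=mode)
            np.testing.assert_array_equal(
                np.sort(d.durations), np.sort(np.asarray(expected) * 2.0)
            )
            assert d.censored_count == censored

    def test_no_transitions_raises(self):
        m = matrix_from([1] * 50)
        with pytest.raises(ValueError, match="insufficient transitions"):
            extract_dwells(m)

    def test_mean_formed_dwell_matches_rate(self):
        # k_break = 0.1/ps at dt = 0.2 ps keeps discretization bias ~1%
        k = 0.1 * PS_PER_US  # 1/ps in 1/us
        spec = KineticsSpec(n_bonds=1, k_form=k, k_break=k, dt=0.2,
                            n_frames=1_500_000, seed=23)
        m = simulate_hb_states(spec)
        d = extract_dwells(m, mode="per_bond_formed")
        assert d.n > 10_000
        assert d.durations.mean() == pytest.approx(10.0, rel=0.03)


class TestLogHistogram:
    def test_single_value_single_bin(self):
        h = sampled_histogram(np.full(50, 12.0))
        assert h.counts.sum() == 50
        assert (h.counts > 0).sum() == 1

    def test_counts_conserved(self, rng):
        d = rng.exponential(30.0, size=5000) + 0.1
        h = sampled_histogram(d)
        assert h.counts.sum() == 5000

    def test_mode_near_tau_for_exponential(self, rng):
        tau = 50.0
        d = rng.exponential(tau, size=100_000) + 1e-9
        h = sampled_histogram(d)
        peak = h.centers[np.argmax(h.counts)]
        assert tau / 1.6 < peak < tau * 1.6  # log-domain density peaks at t = tau

    def test_bad_bins_per_decade(self):
        with pytest.raises(ValueError):
            sampled_histogram([1.0, 2.0], bins_per_decade=0)


class TestFitExponentialMixture:
    def test_noiseless_single_exponential(self):
        h = exp_mix_histogram([20.0], [1.0], n_total=10_000)
        fit = fit_exponential_mixture(h, n_components=1)
        assert fit.components[0][1] == pytest.approx(20.0, rel=1e-4)

    def test_noiseless_biexponential(self):
        h = exp_mix_histogram([10.0, 100.0], [0.7, 0.3], n_total=10_000,
                              span=(0.0, 3.5))
        fit = fit_exponential_mixture(h, n_components=2)
        (w1, t1), (w2, t2) = fit.components
        assert t1 == pytest.approx(10.0, rel=1e-3)
        assert t2 == pytest.approx(100.0, rel=1e-3)
        assert w1 == pytest.approx(0.7, abs=1e-3)

    def test_stochastic_biexponential_recovery(self, rng):
        n = 50_000
        comp = rng.random(n) < 0.7
        d = np.where(comp, rng.exponential(10.0, n), rng.exponential(100.0, n))
        fit = fit_exponential_mixture(sampled_histogram(d), n_components=2)
        (w1, t1), (w2, t2) = fit.components
        assert t1 == pytest.approx(10.0, rel=0.10)
        assert t2 == pytest.approx(100.0, rel=0.10)
        assert w1 == pytest.approx(0.7, abs=0.05)

    def test_two_component_on_single_exponential_falls_back(self, rng):
        d = rng.exponential(25.0, size=20_000)
        fit = fit_exponential_mixture(sampled_histogram(d), n_components=2)
        assert fit.fallback or fit.n_components == 1

    def test_fitted_tau_consistent_with_sample_mean(self, rng):
        tau = 40.0
        d = rng.exponential(tau, size=30_000)
        fit = fit_exponential_mixture(sampled_histogram(d), n_components=1)
        se = d.std() / np.sqrt(d.size)
        assert abs(fit.mean_tau - d.mean()) < 3 * se + 0.02 * tau

    def test_poisson_refinement_close_to_leastsq(self, rng):
        d = rng.exponential(15.0, size=20_000)
        h = sampled_histogram(d)
        a = fit_exponential_mixture(h, n_components=1)
        b = fit_exponential_mixture(h, n_components=1, method="poisson")
        assert b.mean_tau == pytest.approx(a.mean_tau, rel=0.1)

    def test_dt_halving_robustness(self):
        k = 0.05 * PS_PER_US  # 1/us; mean dwell 20 ps
        taus = []
        for dt, frames in ((0.5, 2_000_000), (0.25, 4_000_000)):
            spec = KineticsSpec(n_bonds=1, k_form=k, k_break=k, dt=dt,
                                n_frames=frames, seed=31)
            m = simulate_hb_states(spec)
            d = extract_dwells(m, mode="per_bond_formed")
            fit = fit_exponential_mixture(log_histogram(d), n_components=1)
            taus.append(fit.mean_tau)
        assert taus[1] == pytest.approx(taus[0], rel=0.05)


class TestEnsembleDwellTime:
    def test_single_component_passthrough(self):
        h = exp_mix_histogram([36.6], [1.0], n_total=5_000)
        fit = fit_exponential_mixture(h, n_components=1)
        assert ensemble_dwell_time(fit) == pytest.approx(36.6, rel=1e-4)

    def test_amplitude_weighting_arithmetic(self):
        from helixfriction.dwell import ExpMixFit

        fit = ExpMixFit(components=[(0.5, 10.0), (0.5, 30.0)], mean_tau=20.0,
                        n_components=2)
        assert ensemble_dwell_time(fit) == 20.0
        assert ensemble_dwell_time(fit, rule="slow") == 30.0
        assert ensemble_dwell_time(fit, rule="fast") == 10.0

    def test_end_to_end_recovers_break_rate(self):
        k_break_per_ps = 0.02
        spec = KineticsSpec(n_bonds=2, k_form=0.02 * PS_PER_US,
                            k_break=k_break_per_ps * PS_PER_US, dt=0.5,
                            n_frames=2_000_000, seed=37)
        m = simulate_hb_states(spec)
        d = extract_dwells(m, mode="per_bond_formed")
        fit = fit_exponential_mixture(log_histogram(d), n_components=1)
        assert ensemble_dwell_time(fit) == pytest.approx(1.0 / k_break_per_ps,
                                                         rel=0.05)
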