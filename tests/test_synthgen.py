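"""Generator statistics against their analytic laws."""
from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from helixfriction.dwell import extract_dwells
from helixfriction.kinetics import autocorrelation, fit_relaxation
from helixfriction.structure import HBStateMatrix
from helixfriction.synthgen import (
    BrownianSpec,
    GeometrySpec,
    KineticsSpec,
    SpecValidationError,
    hb_to_end_to_end,
    ideal_helix_coordinates,
    simulate_brownian,
    simulate_hb_states,
)

PS_PER_US = 1.0e6


def occupancy_se(k_form, k_break, total_time_us):
    """Standard error of the time-averaged occupancy of a telegraph
    process observed for total_time_us: var = 2*tau_c/T * pi*(1-pi)."""
    pi = k_form / (k_form + k_break)
    tau_c = 1.0 / (k_form + k_break)
    return np.sqrt(2.0 * tau_c / total_time_us * pi * (1.0 - pi))


class TestKineticsSpecValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            (dict(n_bonds=0), "n_bonds"),
            (dict(k_form=0.0), "k_form"),
            (dict(k_break=-1.0), "k_break"),
            (dict(cooperativity=0.0), "cooperativity"),
            (dict(dt=0.0), "dt"),
            (dict(n_frames=1), "n_frames"),
        ],
    )
    def test_invalid_field_named(self, kwargs, field):
        base = dict(n_bonds=1, k_form=5.0, k_break=15.0, dt=2.0, n_frames=10)
        base.update(kwargs)
        with pytest.raises(SpecValidationError, match=field):
            KineticsSpec(**base)


class TestSimulateHBStates:
    def test_stationary_occupancy_within_3se(self):
        # 8 independent bonds observed for 4 us each: pooled SE shrinks by sqrt(8)
        spec = KineticsSpec(n_bonds=8, k_form=5.0, k_break=15.0, dt=2.0,
                            n_frames=2_000_000, seed=7)
        m = simulate_hb_states(spec)
        occ = m.states.mean()
        se = occupancy_se(5.0, 15.0, 4.0) / np.sqrt(8)
        assert abs(occ - 0.25) < 3 * se

    def test_absorbing_when_k_break_zero(self):
        spec = KineticsSpec(n_bonds=3, k_form=5.0, k_break=0.0, dt=2.0,
                            n_frames=1000, seed=0)
        m = simulate_hb_states(spec)
        for b in range(3):
            col = m.states[:, b]
            first = np.argmax(col) if col.any() else col.size
            assert col[first:].all()

    def test_deterministic_under_fixed_seed(self):
        spec = KineticsSpec(n_bonds=4, k_form=100.0, k_break=300.0, dt=2.0,
                            n_frames=50_000, seed=42)
        a = simulate_hb_states(spec)
        b = simulate_hb_states(spec)
        np.testing.assert_array_equal(a.states, b.states)

    def test_different_seeds_differ(self):
        kw = dict(n_bonds=1, k_form=1e4, k_break=1e4, dt=2.0, n_frames=10_000)
        a = simulate_hb_states(KineticsSpec(seed=0, **kw))
        b = simulate_hb_states(KineticsSpec(seed=1, **kw))
        assert not np.array_equal(a.states, b.states)

    def test_h_series_is_row_sum(self):
        spec = KineticsSpec(n_bonds=5, k_form=1e4, k_break=1e4, dt=2.0,
                            n_frames=5_000, seed=3)
        m = simulate_hb_states(spec)
        np.testing.assert_array_equal(m.h_series, m.states.sum(axis=1))
        assert m.h_series.max() <= m.h_max

    def test_cooperativity_raises_occupancy(self):
        kw = dict(n_bonds=6, k_form=2e3, k_break=6e3, dt=2.0, n_frames=200_000)
        indep = simulate_hb_states(KineticsSpec(cooperativity=1.0, seed=5, **kw))
        coop = simulate_hb_states(KineticsSpec(cooperativity=5.0, seed=5, **kw))
        assert coop.states.mean() > indep.states.mean() + 0.02

    def test_formed_dwells_exponential_ks(self):
        # mean run ~500 frames so discreteness stays below the KS resolution
        k = 1e3  # 1/us -> k*dt = 2e-3
        spec = KineticsSpec(n_bonds=1, k_form=k, k_break=k, dt=2.0,
                            n_frames=10_500_000, seed=11)
        m = simulate_hb_states(spec)
        dwells = extract_dwells(m, mode="per_bond_formed")
        assert dwells.n >= 10_000
        mean_true_ps = 1.0 / k * PS_PER_US
        res = stats.kstest(dwells.durations, "expon",
                           args=(0.0, mean_true_ps))
        assert res.pvalue > 0.01

    def test_acf_decay_rate_matches_sum_of_rates(self, telegraph_acf_mean):
        acf, dt = telegraph_acf_mean
        fit = fit_relaxation(acf, dt=dt, with_constant=False)
        tau_true_ps = 1.0 / (5.0 + 15.0) * PS_PER_US
        assert fit.tau == pytest.approx(tau_true_ps, rel=0.05)


class TestHBToEndToEnd:
    def test_zero_sd_arithmetic(self):
        states = HBStateMatrix(
            dt=2.0,
            states=np.array([[1, 1, 1, 1, 0]], dtype=bool),
            bond_labels=[(i, i + 4) for i in range(5)],
            h_max=5,
        )
        geom = GeometrySpec(rise_per_residue=0.15, coil_length_mean=1.0,
                            coil_length_sd=0.0)
        d = hb_to_end_to_end(states, geom)
        assert d[0] == pytest.approx(1.60)

    def test_conditional_means_step_by_rise(self):
        h_rows = np.zeros((6, 5), dtype=bool)
        for k in range(6):
            h_rows[k, :k] = True
        states = HBStateMatrix(dt=2.0, states=h_rows,
                               bond_labels=[(i, i + 4) for i in range(5)], h_max=5)
        geom = GeometrySpec(rise_per_residue=0.12, coil_length_mean=0.8,
                            coil_length_sd=0.0)
        d = hb_to_end_to_end(states, geom)
        np.testing.assert_allclose(np.diff(d), 0.12)

    def test_distances_nonnegative_under_heavy_noise(self):
        spec = KineticsSpec(n_bonds=3, k_form=1e4, k_break=1e4, dt=2.0,
                            n_frames=50_000, seed=2)
        states = simulate_hb_states(spec)
        geom = GeometrySpec(coil_length_mean=0.1, coil_length_sd=0.5, seed=9)
        d = hb_to_end_to_end(states, geom)
        assert (d >= 0).all()

    def test_deterministic(self):
        spec = KineticsSpec(n_bonds=2, k_form=1e4, k_break=1e4, dt=2.0,
                            n_frames=1_000, seed=4)
        states = simulate_hb_states(spec)
        geom = GeometrySpec(coil_length_sd=0.1, seed=21)
        np.testing.assert_array_equal(
            hb_to_end_to_end(states, geom), hb_to_end_to_end(states, geom)
        )


class TestSimulateBrownian:
    def test_step_variance(self):
        spec = BrownianSpec(n_particles=200, d_true=5.6635e-5, dt=2.0,
                            n_frames=2_000, seed=8)
        paths = simulate_brownian(spec)
        steps = np.diff(paths.positions, axis=0)
        var = steps.var()
        expected = 2.0 * spec.d_true * 100.0 * spec.dt  # nm^2 per axis
        assert var == pytest.approx(expected, rel=0.01)

    def test_rejects_zero_diffusion(self):
        with pytest.raises(SpecValidationError, match="d_true"):
            BrownianSpec(n_particles=1, d_true=0.0, dt=2.0, n_frames=10)

    def test_same_seed_same_paths(self):
        spec = BrownianSpec(n_particles=5, d_true=1e-5, dt=2.0,
                            n_frames=500, seed=77)
        a = simulate_brownian(spec)
        b = simulate_brownian(spec)
        np.testing.assert_array_equal(a.positions, b.positions)


class TestIdealHelix:
    def test_consecutive_ca_chord(self):
        geom = GeometrySpec(rise_per_residue=0.15, twist_per_residue=100.0,
                            helix_radius=0.23)
        frames = ideal_helix_coordinates(8, geom)
        ca = frames.coords[0, frames.indices(["CA"])]
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        chord = np.sqrt(0.15**2 + (2 * 0.23 * np.sin(np.deg2rad(50.0))) ** 2)
        assert chord == pytest.approx(0.383, abs=5e-4)
        np.testing.assert_allclose(d, chord, rtol=1e-12)

    def test_two_residues(self):
        frames = ideal_helix_coordinates(2)
        ca = frames.coords[0, frames.indices(["CA"])]
        chord = np.sqrt(0.15**2 + (2 * 0.23 * np.sin(np.deg2rad(50.0))) ** 2)
        assert np.linalg.norm(ca[1] - ca[0]) == pytest.approx(chord, rel=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            ideal_helix_coordinates(1)

    def test_all_i_ip4_pairs_below_cutoff(self):
        from helixfriction.structure import detect_hbonds

        frames = ideal_helix_coordinates(12)
        m = detect_hbonds(frames)
        assert m.h_max == 8
        assert (m.h_series == m.h_max).all()
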