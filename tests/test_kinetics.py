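"""Exact dwell densities, classification and thermodynamics of clock models."""

import json

import numpy as np
import pytest
from scipy import stats

from burstcycle.kinetics import (
    AbsorbingMesostateError,
    ClockModel,
    ConnectivityError,
    RateGraph,
    alpha_eq,
    classify_density,
    cycle_current,
    density_eval,
    entropy_per_cycle,
    entropy_rate,
    graph_from_json,
    graph_to_json,
    is_detailed_balanced,
    mesostate_dwell_density,
    sample_mesostate_dwells,
    stationary_distribution,
    thermo_summary,
)

from conftest import random_clock


def cycle_graph(w21=1.0, w32=1.0, w13=1.0):
    w = np.zeros((3, 3))
    w[1, 0], w[2, 1], w[0, 2] = w21, w32, w13
    return RateGraph(w, ("ON", "ON", "OFF"))


class TestStationaryDistribution:
    @pytest.mark.parametrize(
        "rates, labels, expected",
        [
            ([[0, 1], [1, 0]], ("A", "B"), (0.5, 0.5)),
            # uniform unidirectional cycle
            ([[0, 0, 1], [1, 0, 0], [0, 1, 0]], ("ON", "ON", "OFF"),
             (1 / 3, 1 / 3, 1 / 3)),
            # p1 w21 = p2 w32 = p3 w13 solved by hand for w21=2, w32=w13=1
            ([[0, 0, 1], [2, 0, 0], [0, 1, 0]], ("ON", "ON", "OFF"),
             (0.2, 0.4, 0.4)),
        ],
    )
    def test_known_solutions(self, rates, labels, expected):
        p = stationary_distribution(RateGraph(rates, labels))
        assert p == pytest.approx(expected, abs=1e-10)

    def test_generator_balance_random(self, rng):
        for _ in range(20):
            g = random_clock(rng).to_rate_graph()
            p = stationary_distribution(g)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(p >= 0)
            assert np.abs(g.generator() @ p).max() < 1e-10

    def test_disconnected_graph_rejected(self):
        w = np.zeros((3, 3))
        w[1, 0] = 1.0  # 1 -> 2 only; no way back
        g = RateGraph(w, ("A", "B", "C"))
        with pytest.raises(ConnectivityError):
            stationary_distribution(g)

    def test_matches_gillespie_occupancy(self, rng):
        from burstcycle.simulate import simulate_ctmc

        g = cycle_graph(w21=2.0)
        p = stationary_distribution(g)
        tr = simulate_ctmc(g, 20000.0, 77)
        ends = np.concatenate([tr.times[1:], [tr.t_max]])
        occ = np.zeros(3)
        for s, a, b in zip(tr.states, tr.times, ends):
            occ[s] += b - a
        occ /= occ.sum()
        assert occ == pytest.approx(p, abs=0.02)


class TestDwellDensity:
    def test_single_state_mesostate_is_exponential(self):
        w = np.zeros((2, 2))
        w[1, 0] = 0.7  # exit rate from the 1-state mesostate
        w[0, 1] = 0.3
        g = RateGraph(w, ("ON", "OFF"))
        d = mesostate_dwell_density(g, "ON")
        assert d.exponents == pytest.approx([-0.7])
        t = np.linspace(0, 5, 50)
        assert density_eval(d, t) == pytest.approx(0.7 * np.exp(-0.7 * t))
        assert classify_density(d).label == "monotone"

    def test_erlang_clock_density(self):
        # alpha=0, w12=0, w21=w32=1: convolution of two unit exponentials
        d = mesostate_dwell_density(cycle_graph(), "ON")
        assert d.degenerate
        t = np.array([0.0, 0.5, 1.0, 2.0])
        assert d.density(t) == pytest.approx(t * np.exp(-t), abs=1e-12)
        assert d.density(1.0) == pytest.approx(np.exp(-1.0))
        assert d.mean() == pytest.approx(2.0)
        assert d.normalization() == pytest.approx(1.0)

    def test_alpha_zero_density_vanishes_at_origin(self, rng):
        for _ in range(20):
            m = random_clock(rng, alpha_mode="zero")
            d = mesostate_dwell_density(m.to_rate_graph(), "ON")
            assert abs(float(d.density(0.0))) < 1e-12
            assert classify_density(d).label == "maximally_peaked"

    def test_density_invariants_random(self, rng):
        for _ in range(30):
            m = random_clock(rng)
            d = mesostate_dwell_density(m.to_rate_graph(), "ON")
            assert d.normalization() == pytest.approx(1.0, abs=1e-9)
            t = np.linspace(0, d.time_horizon(), 500)
            assert np.all(d.density(t) >= -1e-9)
            assert np.all(np.diff(np.abs(d.exponents)) <= 1e-12)

    def test_survival_matches_density_integral(self, clock):
        d = mesostate_dwell_density(clock.to_rate_graph(), "ON")
        from scipy.integrate import quad

        for t0 in (0.0, 0.5, 2.0):
            tail, _ = quad(lambda u: float(d.density(u)), t0, 200.0)
            assert float(d.survival(t0)) == pytest.approx(tail, abs=1e-8)

    def test_negative_time_rejected(self, clock):
        d = mesostate_dwell_density(clock.to_rate_graph(), "ON")
        with pytest.raises(ValueError):
            density_eval(d, [-1.0])

    def test_inescapable_mesostate_rejected(self):
        w = np.zeros((3, 3))
        w[1, 0], w[0, 1] = 1.0, 1.0  # states 1,2 talk only to each other
        w[0, 2] = 1.0  # state 3 feeds in but is never entered
        g = RateGraph(w, ("ON", "ON", "OFF"))
        with pytest.raises((AbsorbingMesostateError, ConnectivityError)):
            mesostate_dwell_density(g, "ON")

    def test_agrees_with_gillespie_sample(self, clock, rng):
        d = mesostate_dwell_density(clock.to_rate_graph(), "ON")
        samp = sample_mesostate_dwells(clock.to_rate_graph(), "ON", 20000, rng)
        res = stats.kstest(samp, lambda t: 1.0 - d.survival(t))
        assert res.pvalue > 0.01
        assert samp.mean() == pytest.approx(d.mean(), rel=0.05)

    def test_full_trajectory_dwells_match_density(self, rng):
        """Dwells harvested from one long Gillespie trajectory follow the
        same law as the spectral density (flux-weighted entry)."""
        from burstcycle.simulate import mesostate_dwells, simulate_ctmc

        m = ClockModel(w21=1.0, w32=0.8, w13=1.2, w12=0.5, alpha=0.3)
        g = m.to_rate_graph()
        d = mesostate_dwell_density(g, "ON")
        tr = simulate_ctmc(g, 30000.0, 99)
        tab = mesostate_dwells(tr, g.mesostates)
        on = tab[(tab.label == "ON") & ~tab.censored_left & ~tab.censored_right]
        res = stats.kstest(on.duration_s.to_numpy(),
                           lambda t: 1.0 - d.survival(t))
        assert res.pvalue > 0.01


class TestClassification:
    def test_path_topology_is_monotone(self, rng):
        """3-state chains whose undirected skeleton is a path (no cycle)
        always give monotone 2-state mesostate densities."""
        for _ in range(50):
            r = 10 ** rng.uniform(-1, 1, size=4)
            w = np.zeros((3, 3))
            w[1, 0], w[0, 1] = r[0], r[1]  # edge 1-2
            w[2, 1], w[1, 2] = r[2], r[3]  # edge 2-3
            g = RateGraph(w, ("ON", "ON", "OFF"))
            d = mesostate_dwell_density(g, "ON")
            assert classify_density(d).label == "monotone"

    def test_detailed_balance_is_monotone(self, rng):
        for _ in range(50):
            m = random_clock(rng, alpha_mode="eq")
            d = mesostate_dwell_density(m.to_rate_graph(), "ON")
            assert classify_density(d).label == "monotone"

    def test_peaked_between_zero_and_equilibrium(self):
        m0 = ClockModel(w21=1.0, w32=1.0, w13=1.0, w12=0.25, alpha=0.0)
        m = ClockModel(w21=1.0, w32=1.0, w13=1.0, w12=0.25,
                       alpha=0.3 * alpha_eq(m0))
        d = mesostate_dwell_density(m.to_rate_graph(), "ON")
        c = classify_density(d)
        assert c.label == "peaked"
        assert c.f0 > 0


class TestThermodynamics:
    def test_alpha_eq_formula(self):
        m = ClockModel(w21=3.0, w32=2.0, w13=6.0, w12=1.0)
        assert alpha_eq(m) == pytest.approx(6.0)
        assert alpha_eq(ClockModel(w21=1, w32=1, w13=1, w12=1)) == 1.0

    def test_entropy_per_cycle(self):
        m = ClockModel(w21=3.0, w32=2.0, w13=6.0, w12=1.0, alpha=6.0)
        assert entropy_per_cycle(m) == pytest.approx(0.0, abs=1e-12)
        m = ClockModel(w21=3.0, w32=2.0, w13=6.0, w12=1.0, alpha=6.0 / np.e)
        assert entropy_per_cycle(m) == pytest.approx(2.0)

    def test_alpha_zero_diverges_with_warning(self):
        m = ClockModel(w21=1, w32=1, w13=1, w12=1, alpha=0.0)
        with pytest.warns(RuntimeWarning):
            assert entropy_per_cycle(m) == np.inf
        with pytest.warns(RuntimeWarning):
            assert entropy_rate(m) == np.inf

    def test_cycle_current(self):
        m = ClockModel(w21=1.0, w32=1.0, w13=1.0, w12=1e-9, alpha=0.0)
        # w12 ~ 0: uniform unidirectional cycle, J+ = w13 p3 = 1/3
        assert cycle_current(m) == pytest.approx(1 / 3, rel=1e-6)
        meq = ClockModel(w21=3, w32=2, w13=6, w12=1, alpha=6.0)
        assert cycle_current(meq) == pytest.approx(0.0, abs=1e-10)

    def test_current_changes_sign_past_equilibrium(self):
        m0 = ClockModel(w21=1.5, w32=0.8, w13=1.1, w12=0.6)
        ae = alpha_eq(m0)
        above = ClockModel(w21=1.5, w32=0.8, w13=1.1, w12=0.6, alpha=1.05 * ae)
        below = ClockModel(w21=1.5, w32=0.8, w13=1.1, w12=0.6, alpha=0.95 * ae)
        assert cycle_current(above) < 0 < cycle_current(below)

    def test_sigma_nonnegative_and_consistent(self, rng):
        for _ in range(100):
            m = random_clock(rng)
            if m.alpha == 0:
                continue
            ts = thermo_summary(m)
            assert ts.sigma >= -1e-12
            assert ts.sigma == pytest.approx(
                ts.current_plus * ts.delta_s_cycle, abs=1e-9
            )

    def test_detailed_balance_iff_everything_vanishes(self, rng):
        for _ in range(30):
            m = random_clock(rng, alpha_mode="eq")
            assert is_detailed_balanced(m)
            ts = thermo_summary(m)
            assert abs(ts.delta_s_cycle) < 1e-9
            assert abs(ts.current_plus) < 1e-12
            assert abs(ts.sigma) < 1e-12
        m = ClockModel(w21=1, w32=1, w13=1, w12=1, alpha=0.0)
        assert not is_detailed_balanced(m)

    def test_sigma_nonincreasing_in_alpha(self):
        m0 = ClockModel(w21=1.2, w32=0.9, w13=1.4, w12=0.7)
        ae = alpha_eq(m0)
        alphas = np.linspace(0.02 * ae, ae, 40)
        sigmas = [
            entropy_rate(ClockModel(w21=1.2, w32=0.9, w13=1.4, w12=0.7, alpha=a))
            for a in alphas
        ]
        assert np.all(np.diff(sigmas) <= 1e-12)


class TestSerialization:
    def test_graph_round_trip(self, clock):
        g = clock.to_rate_graph()
        g2 = graph_from_json(graph_to_json(g))
        assert np.allclose(g.rates, g2.rates)
        assert g.mesostates == g2.mesostates

    def test_clock_shorthand(self):
        doc = json.dumps(
            {"clock": {"w21": 1.0, "w32": 2.0, "w13": 3.0, "w12": 0.5,
                       "alpha": 0.1}}
        )
        g = graph_from_json(doc)
        assert g.rate(1, 0) == 1.0
        assert g.rate(2, 1) == 2.0
        assert g.rate(0, 2) == 3.0
        assert g.rate(0, 1) == 0.5
        assert g.rate(2, 0) == g.rate(1, 2) == 0.1
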