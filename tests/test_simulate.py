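"""Gillespie simulation, trace synthesis and scenario presets."""

import numpy as np
import pandas as pd
import pytest

from burstcycle.kinetics import (
    classify_density,
    mesostate_dwell_density,
    stationary_distribution,
)
from burstcycle.simulate import (
    SCENARIO_PRESETS,
    FourStateScenario,
    ObservationParams,
    chd1_like,
    isw2_like,
    mesostate_dwells,
    pho4_like,
    simulate_ctmc,
    synthesize_cohort,
    synthesize_image_stack,
    synthesize_trace,
    truth_period_table,
    wildtype_like,
)
from burstcycle.kinetics import RateGraph


def two_state(on_exit=0.1, off_exit=0.05):
    w = np.zeros((2, 2))
    w[1, 0], w[0, 1] = on_exit, off_exit
    return RateGraph(w, ("ON", "OFF"))


class TestSimulateCtmc:
    def test_exponential_sojourns(self):
        g = two_state(on_exit=0.1, off_exit=0.1)
        tr = simulate_ctmc(g, 2.0e5, 42)
        soj = np.diff(tr.times)
        se = 10.0 / np.sqrt(soj.size)
        assert soj.mean() == pytest.approx(10.0, abs=3 * se)

    def test_seed_determinism(self):
        g = two_state()
        a = simulate_ctmc(g, 5000.0, 7)
        b = simulate_ctmc(g, 5000.0, 7)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.states, b.states)

    def test_occupancy_matches_stationary(self):
        g = wildtype_like().to_rate_graph()
        p = stationary_distribution(g)
        occ = np.zeros(4)
        for seed in range(30):
            tr = simulate_ctmc(g, 20000.0, seed)
            ends = np.concatenate([tr.times[1:], [tr.t_max]])
            for s, a, b in zip(tr.states, tr.times, ends):
                occ[s] += b - a
        occ /= occ.sum()
        assert np.abs(occ - p).max() < 0.01

    def test_invalid_t_max(self):
        with pytest.raises(ValueError):
            simulate_ctmc(two_state(), 0.0, 1)


class TestMesostateDwells:
    def test_single_dwell_censored_both(self):
        g = two_state(on_exit=1e-9, off_exit=1e-9)
        tr = simulate_ctmc(g, 1250.0, 3, start_state=1)
        tab = mesostate_dwells(tr, g.mesostates)
        assert len(tab) == 1
        row = tab.iloc[0]
        assert row.censored_left and row.censored_right
        assert row.duration_s == 1250.0

    def test_durations_tile_the_window(self):
        g = wildtype_like().to_rate_graph()
        tr = simulate_ctmc(g, 1250.0, 11)
        tab = mesostate_dwells(tr, g.mesostates)
        assert tab.duration_s.sum() == pytest.approx(1250.0)
        assert (tab.label.values[1:] != tab.label.values[:-1]).all()

    def test_internal_dwell_mean_matches_phase_type(self):
        g = wildtype_like().to_rate_graph()
        d = mesostate_dwell_density(g, "ON")
        durs = []
        for seed in range(60):
            tab = mesostate_dwells(simulate_ctmc(g, 30000.0, seed), g.mesostates)
            sel = tab[(tab.label == "ON") & ~tab.censored_left & ~tab.censored_right]
            durs.append(sel.duration_s.to_numpy())
        durs = np.concatenate(durs)
        assert durs.mean() == pytest.approx(d.mean(), rel=0.03)

    def test_truth_period_table_classes(self):
        truth = pd.DataFrame(
            {
                "label": ["OFF", "ON", "OFF"],
                "censored_left": [True, False, False],
                "censored_right": [False, False, True],
            }
        )
        cls = truth_period_table(truth)["class"].tolist()
        assert cls == ["external_left", "internal", "external_right"]


class TestSynthesizeTrace:
    def test_no_signal_mode_is_background(self):
        p = ObservationParams(init_rate=0.0, background=100.0,
                              background_spread=0.0)
        g = two_state()
        tr = simulate_ctmc(g, p.window, 5)
        trc = synthesize_trace(tr, p, 6, partition=g.mesostates)
        assert np.median(trc.intensity) == pytest.approx(100.0, abs=1.0)
        assert (trc.truth_count == 0).all()

    def test_steady_state_transcript_count(self):
        # always ON: mean nascent count = initiation rate x residence time
        g = two_state(on_exit=1e-12, off_exit=1.0)
        p = ObservationParams(init_rate=0.2, residence_time=60.0, window=5000.0)
        tr = simulate_ctmc(g, p.window, 8, start_state=0)
        trc = synthesize_trace(tr, p, 9, partition=g.mesostates)
        counts = trc.truth_count[trc.time_s > 120]  # past the fill-in transient
        assert counts.mean() == pytest.approx(12.0, rel=0.1)

    def test_on_noise_exceeds_off_noise(self, small_cohort):
        resid_on, resid_off = [], []
        for trc in small_cohort.traces:
            sig = trc.truth_count * 1.0  # brightness 1
            resid = trc.intensity - sig
            resid_on.extend(resid[trc.truth_label == "ON"])
            resid_off.extend(resid[trc.truth_label == "OFF"])
        assert np.std(resid_on) > 1.3 * np.std(resid_off)

    def test_truth_aligns_with_period_table(self, small_cohort):
        p = small_cohort.params
        for trc in small_cohort.traces[:5]:
            tab = small_cohort.truth_periods[
                small_cohort.truth_periods.cell == trc.cell_id
            ]
            for _, row in tab.iterrows():
                sel = (trc.time_s >= row.start_s) & (trc.time_s < row.end_s)
                assert (trc.truth_label[sel] == row.label).all()


class TestCohort:
    def test_shapes_and_determinism(self, small_cohort):
        assert len(small_cohort.traces) == 40
        assert all(t.n_frames == 500 for t in small_cohort.traces)
        again = synthesize_cohort(wildtype_like(), ObservationParams(), 40, seed=123)
        for a, b in zip(small_cohort.traces, again.traces):
            assert np.array_equal(a.intensity, b.intensity)

    def test_cells_differ(self, small_cohort):
        a, b = small_cohort.traces[0], small_cohort.traces[1]
        assert not np.array_equal(a.intensity, b.intensity)

    def test_external_off_fraction_grows_with_slower_exit(self):
        base = wildtype_like()
        slow = FourStateScenario(**{**base.__dict__, "w14": base.w14 / 8,
                                    "strain": "slow"})
        p = ObservationParams()

        def ext_frac(s):
            co = synthesize_cohort(s, p, 40, seed=5)
            t = truth_period_table(co.truth_periods)
            off = t[t.label == "OFF"]
            return (off["class"] != "internal").mean()

        assert ext_frac(slow) > ext_frac(base)


class TestPresets:
    def test_wildtype_is_maximally_peaked(self):
        d = mesostate_dwell_density(wildtype_like().to_rate_graph(), "ON")
        assert classify_density(d).label == "maximally_peaked"

    def test_remodeler_mutants_are_peaked_not_maximal(self):
        for preset in (chd1_like, isw2_like):
            d = mesostate_dwell_density(preset().to_rate_graph(), "ON")
            c = classify_density(d)
            assert c.label == "peaked"
            assert c.f0 > 0

    def test_pho4_is_monotone_with_higher_branching(self):
        d = mesostate_dwell_density(pho4_like().to_rate_graph(), "ON")
        assert classify_density(d).label == "monotone"
        assert pho4_like().branching_prob == pytest.approx(0.65, abs=0.01)
        assert wildtype_like().branching_prob == pytest.approx(0.39, abs=0.01)

    def test_external_off_ordering(self):
        means = [1.0 / SCENARIO_PRESETS[k]().w14
                 for k in ("wildtype_like", "chd1_like", "isw2_like", "pho4_like")]
        assert means == sorted(means)

    def test_internal_means_within_20pct_of_wildtype(self):
        wt = wildtype_like()
        d_wt = mesostate_dwell_density(wt.to_rate_graph(), "ON")
        off_wt = mesostate_dwell_density(wt.on_rate_graph(), "OFF_short")
        for key in ("chd1_like", "isw2_like", "pho4_like"):
            s = SCENARIO_PRESETS[key]()
            d = mesostate_dwell_density(s.to_rate_graph(), "ON")
            off = mesostate_dwell_density(s.on_rate_graph(), "OFF_short")
            assert abs(d.mean() / d_wt.mean() - 1) < 0.20
            assert abs(off.mean() / off_wt.mean() - 1) < 0.20

    def test_long_off_validation(self):
        with pytest.raises(ValueError):
            FourStateScenario(w13=0.04, w21=0.04, w32=0.01, w12=0.01,
                              w42=0.006, w14=0.2)


class TestImageStack:
    def test_zero_intensity_no_spot(self):
        trc = _flat_trace(0.0, 20)
        stack, truth = synthesize_image_stack(trc, seed=1, noise=False)
        # nothing above the nuclear background level anywhere
        assert stack.max() <= 25.0 + 1e-6

    def test_noiseless_integral_matches_trace(self):
        trc = _flat_trace(5.0, 3)
        stack, truth = synthesize_image_stack(trc, seed=2, noise=False, gain=300.0)
        proj = stack[0].max(axis=0)
        cx, cy = int(round(truth.x[0])), int(round(truth.y[0]))
        patch = proj[cy - 8:cy + 9, cx - 8:cx + 9] - 25.0  # nuclear level
        assert patch.sum() == pytest.approx(5.0 * 300.0, rel=0.01)

    def test_seeded_reproducibility(self):
        trc = _flat_trace(5.0, 5)
        a, _ = synthesize_image_stack(trc, seed=3)
        b, _ = synthesize_image_stack(trc, seed=3)
        assert np.array_equal(a, b)


def _flat_trace(level, n_frames):
    from burstcycle.simulate import FluorescenceTrace

    return FluorescenceTrace(
        cell_id=0,
        time_s=np.arange(n_frames) * 2.5,
        intensity=np.full(n_frames, float(level)),
    )
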