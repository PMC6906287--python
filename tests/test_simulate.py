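"""Synthetic experiment generator: determinism, distributions, rendering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from poretrace.simulate import (AcquisitionSchedule, NoiseParams,
                                ScenarioParams, acquisition_schedule,
                                default_scenarios, events_to_frame,
                                render_movie, sample_event_stream,
                                sample_vesicle_population, synthesize_traces)
from poretrace.transport import DEFAULT_PORE, CargoSpecies


class TestSchedule:
    def test_canonical_two_color_cycle(self):
        s = acquisition_schedule(4, 2, 0.1, 0.5)
        assert s.cycle_period == pytest.approx(2.8)

    def test_single_position_single_channel(self):
        assert acquisition_schedule(1, 1, 0.1, 0.0).cycle_period == \
            pytest.approx(0.1)

    def test_three_color_six_position_cycle(self):
        # stated scheduler arithmetic: 6 * (3*0.1 + 0.5) s
        assert acquisition_schedule(6, 3, 0.1, 0.5).cycle_period == \
            pytest.approx(4.8)

    def test_timestamps_strictly_increasing_per_series(self):
        s = acquisition_schedule(4, 2, 0.1, 0.5, n_cycles=5)
        for fov in range(4):
            for ch in range(2):
                t = s.times_for(fov, ch)
                assert np.all(np.diff(t) > 0)
                assert np.allclose(np.diff(t), s.cycle_period)

    def test_frame_info_roundtrip(self):
        s = acquisition_schedule(2, 3, 0.1, 0.2, n_cycles=4)
        assert s.n_frames == 24
        times = [s.frame_info(f)[3] for f in range(s.n_frames)]
        assert all(a < b for a, b in zip(times, times[1:]))

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            acquisition_schedule(0, 2, 0.1, 0.5)


class TestPopulation:
    def test_degenerate_sigma_limit(self):
        ves = sample_vesicle_population(50, math.log(120.0), 1e-9, seed=1)
        assert np.allclose([v.diameter for v in ves], 120.0, rtol=1e-6)

    def test_fixed_seed_is_bitwise_deterministic(self):
        a = sample_vesicle_population(100, seed=7)
        b = sample_vesicle_population(100, seed=7)
        assert all(va.diameter == vb.diameter and va.position == vb.position
                   and va.content == vb.content for va, vb in zip(a, b))

    def test_lognormal_tail_against_closed_form(self):
        mu, sigma, n = math.log(120.0), 0.35, 10000
        ves = sample_vesicle_population(n, mu, sigma, positions_extent=4000.0,
                                        seed=11, min_separation=1.0)
        frac = np.mean([v.diameter > 70.0 for v in ves])
        expected = 1.0 - norm.cdf((math.log(70.0) - mu) / sigma)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_content_scales_with_volume(self):
        ves = sample_vesicle_population(200, seed=3)
        n0 = np.array([v.content["ATTO655"] for v in ves])
        vol = np.array([v.volume for v in ves])
        ratio = n0 / vol
        assert ratio.std() / ratio.mean() < 0.05  # rounding only

    def test_min_separation_respected_and_infeasible_packing_errors(self):
        ves = sample_vesicle_population(50, positions_extent=100.0, seed=5,
                                        min_separation=8.0)
        pos = np.array([v.position for v in ves])
        d = np.hypot(*(pos[:, None, :] - pos[None, :, :]).T)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 8.0
        with pytest.raises(RuntimeError):
            sample_vesicle_population(500, positions_extent=50.0, seed=5,
                                      min_separation=30.0)


class TestEventStream:
    def test_no_docking_without_lipidation_or_key(self):
        ves = sample_vesicle_population(100, seed=2)
        events = sample_event_stream(ves, default_scenarios()["NL-"], seed=3)
        assert all(e.outcome == "undocked" for e in events)

    def test_rate_independent_of_size_when_beta_zero(self):
        """With mechano_beta = 0 (and no pore-to-pore spread) the intensity
        flow rate k * N0 is identical across vesicle sizes: the volume factor
        of the rate constant cancels the volume-encapsulated dye count."""
        ves = sample_vesicle_population(80, seed=4)
        scen = ScenarioParams("L+", docking_rate=1e-3, insertion_prob_max=1.0,
                              insertion_d50=0.0, mechano_beta=0.0,
                              rate_cv=0.0)
        events = sample_event_stream(ves, scen, t_max=1e6, seed=5)
        by_id = {v.id: v for v in ves}
        kf = [e.k_per_species["ATTO655"] * by_id[e.vesicle_id].content["ATTO655"]
              for e in events if e.outcome == "docked_perforated"]
        assert len(kf) > 50
        assert np.std(kf) / np.mean(kf) < 0.02  # count rounding only

    def test_censored_docking_mle_recovers_mean(self):
        """Censored-exponential MLE oracle: total observed time / #events."""
        ves = sample_vesicle_population(5000, positions_extent=3000.0,
                                        seed=6, min_separation=1.0)
        scen = ScenarioParams("L+", docking_rate=1 / 1450.0)
        t_max = 28800.0
        events = sample_event_stream(ves, scen, t_max=t_max, seed=7)
        docks = np.array([e.dock_time for e in events
                          if e.dock_time is not None])
        n_cens = sum(e.dock_time is None for e in events)
        mle = (docks.sum() + n_cens * t_max) / docks.size
        assert mle == pytest.approx(1450.0, rel=0.05)

    def test_insertion_times_ordered_and_censored(self):
        ves = sample_vesicle_population(300, seed=8)
        events = sample_event_stream(ves, default_scenarios()["L+"],
                                     t_max=28800.0, seed=9)
        for e in events:
            if e.insert_time is not None:
                assert e.insert_time >= e.dock_time
                assert e.insert_time <= 28800.0

    def test_unknown_scenario_rejected(self):
        with pytest.raises(KeyError):
            default_scenarios()["unknown"]


@pytest.fixture
def tiny_setup():
    ves = sample_vesicle_population(6, positions_extent=64.0, seed=10,
                                    min_separation=12.0, margin=10.0)
    schedule = acquisition_schedule(1, 2, 0.1, 0.5, n_cycles=60,
                                    channel_labels=("pore", "ATTO655"))
    scen = ScenarioParams("L+", docking_rate=1 / 8.0, insertion_prob_max=1.0,
                          insertion_d50=0.0, reorientation_shape=2.0,
                          reorientation_scale=2.0,
                          empirical_hindrance=0.5, rate_cv=0.0)
    events = sample_event_stream(ves, scen, t_max=60 * 0.7, seed=11)
    return ves, schedule, events


class TestTraces:
    def test_undocked_trace_constant_without_noise(self, tiny_setup):
        ves, schedule, _ = tiny_setup
        from poretrace.simulate import EventTruth
        events = [EventTruth(vesicle_id=v.id) for v in ves]
        traces = synthesize_traces(ves, events, schedule,
                                   noise=NoiseParams.off(), seed=0)
        for _, grp in traces.groupby(["vesicle_id", "channel"]):
            assert grp["intensity"].nunique() == 1

    def test_perforated_trace_matches_model(self, tiny_setup):
        """Noise off: the dye trace equals the closed-form count time course
        times the per-molecule brightness at every frame time."""
        ves, schedule, events = tiny_setup
        from poretrace.simulate import DEFAULT_SPECIES
        from poretrace.transport import dye_count_timecourse
        traces = synthesize_traces(ves, events, schedule,
                                   noise=NoiseParams.off(), seed=0)
        checked = 0
        for ev in events:
            if ev.outcome != "docked_perforated":
                continue
            v = next(x for x in ves if x.id == ev.vesicle_id)
            grp = traces[(traces.vesicle_id == ev.vesicle_id)
                         & (traces.channel == "ATTO655")]
            t = grp["time_s"].to_numpy()
            counts = dye_count_timecourse(v, ev.k_per_species["ATTO655"],
                                          ev.insert_time, t, species="ATTO655")
            expected = counts * DEFAULT_SPECIES["ATTO655"].brightness
            assert np.allclose(grp["intensity"].to_numpy(), expected,
                               rtol=1e-9)
            checked += 1
        assert checked >= 1

    def test_pore_channel_steps_at_dock_time(self, tiny_setup):
        ves, schedule, events = tiny_setup
        traces = synthesize_traces(ves, events, schedule,
                                   noise=NoiseParams.off(), seed=0)
        for ev in events:
            grp = traces[(traces.vesicle_id == ev.vesicle_id)
                         & (traces.channel == "pore")]
            t = grp["time_s"].to_numpy()
            i = grp["intensity"].to_numpy()
            if ev.dock_time is None:
                assert np.all(i == 0)
            else:
                assert np.all(i[t < ev.dock_time] == 0)
                assert np.all(i[t >= ev.dock_time] > 0)

    def test_two_dye_dequenching(self):
        """After insertion the acceptor channel decays while the FRET-donor
        channel rises (dye de-quenching)."""
        from poretrace.simulate import DEFAULT_SPECIES, EventTruth
        from poretrace.transport import Vesicle
        v = Vesicle(id=0, diameter=200.0,
                    content={"ATTO655": 2000.0, "dTMR-40k": 500.0},
                    position=(10.0, 10.0))
        schedule = acquisition_schedule(
            1, 3, 0.1, 0.5, n_cycles=80,
            channel_labels=("pore", "ATTO655", "dTMR-40k"))
        ev = EventTruth(vesicle_id=0, dock_time=5.0, insert_time=10.0,
                        k_per_species={"ATTO655": 0.15, "dTMR-40k": 0.0},
                        outcome="docked_perforated")
        traces = synthesize_traces([v], [ev], schedule,
                                   noise=NoiseParams.off(), seed=0)
        acc = traces[traces.channel == "ATTO655"]
        don = traces[traces.channel == "dTMR-40k"]
        acc_after = acc[acc.time_s >= 10.0]["intensity"].to_numpy()
        don_after = don[don.time_s >= 10.0]["intensity"].to_numpy()
        assert np.all(np.diff(acc_after) <= 1e-9)
        assert acc_after[-1] < 0.1 * acc_after[0]
        assert np.all(np.diff(don_after) >= -1e-9)
        assert don_after[-1] > don_after[0]


class TestRenderMovie:
    def test_empty_scene_uniform_background(self):
        schedule = acquisition_schedule(1, 1, 0.1, 0.0, n_cycles=3,
                                        channel_labels=("ATTO655",))
        traces = pd.DataFrame({"vesicle_id": [], "frame": [],
                               "clean_intensity": []})
        movie, _ = render_movie([], traces, schedule,
                                noise=NoiseParams(enabled=False,
                                                  background=50.0),
                                canvas=32)
        assert movie.frames.shape == (3, 32, 32)
        assert np.all(movie.frames == 50)

    def test_single_spot_flux_conserved(self):
        """Analytic pixel-integrated Gaussian: rendered flux within 0.5% of
        the trace value."""
        from poretrace.transport import Vesicle
        v = Vesicle(id=0, diameter=200.0, content={}, position=(15.3, 16.7))
        schedule = acquisition_schedule(1, 1, 0.1, 0.0, n_cycles=2,
                                        channel_labels=("ATTO655",))
        traces = pd.DataFrame({"vesicle_id": [0, 0], "frame": [0, 1],
                               "clean_intensity": [5000.0, 2500.0]})
        movie, truth = render_movie([v], traces, schedule, psf_sigma=1.2,
                                    noise=NoiseParams.off(), canvas=32)
        for f, flux in [(0, 5000.0), (1, 2500.0)]:
            assert movie.frames[f].sum() == pytest.approx(flux, rel=0.005)
        assert movie.frames[0].argmax() == round(16.7) * 32 + round(15.3)

    def test_linear_drift_moves_truth_positions(self):
        from poretrace.transport import Vesicle
        v = Vesicle(id=0, diameter=200.0, content={}, position=(10.0, 20.0))
        n_cyc = 5
        schedule = acquisition_schedule(1, 1, 0.1, 0.0, n_cycles=n_cyc,
                                        channel_labels=("ATTO655",))
        traces = pd.DataFrame({"vesicle_id": [0] * n_cyc,
                               "frame": np.arange(n_cyc),
                               "clean_intensity": [100.0] * n_cyc})
        drift = np.tile([0.05, -0.02], (n_cyc, 1))
        _, truth = render_movie([v], traces, schedule, drift=drift,
                                noise=NoiseParams.off(), canvas=64)
        cum = np.cumsum(drift, axis=0) - drift[0]
        assert np.allclose(truth["x_px"], 10.0 + cum[:, 0])
        assert np.allclose(truth["y_px"], 20.0 + cum[:, 1])

    def test_determinism_under_seed(self):
        from poretrace.transport import Vesicle
        v = Vesicle(id=0, diameter=200.0, content={}, position=(8.0, 8.0))
        schedule = acquisition_schedule(1, 1, 0.1, 0.0, n_cycles=2,
                                        channel_labels=("ATTO655",))
        traces = pd.DataFrame({"vesicle_id": [0, 0], "frame": [0, 1],
                               "clean_intensity": [500.0, 500.0]})
        m1, _ = render_movie([v], traces, schedule, seed=9, canvas=24)
        m2, _ = render_movie([v], traces, schedule, seed=9, canvas=24)
        assert np.array_equal(m1.frames, m2.frames)


def test_scenario_defaults_fold_change_configured():
    scen = default_scenarios()
    assert scen["L+"].insertion_prob_max / scen["L-"].insertion_prob_max == \
        pytest.approx(2.2)
    assert scen["NL-"].docking_rate == 0.0
    assert scen["NL+"].docking_rate > 0
    assert scen["alpha_hemolysin"].mechano_beta > 0
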