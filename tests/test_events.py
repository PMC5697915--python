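"""Multi-unit burst detection and corner-stop segmentation."""

import numpy as np
import pandas as pd
import pytest

from replaykit.events import (StopPeriod, build_stop_periods, detect_events,
                              segment_stop, temporal_windows)


def _stationary_positions(duration=60.0, x=190.0, dt=0.02):
    t = np.arange(0.0, duration, dt)
    return pd.DataFrame({"t": t, "x_cm": np.full(t.size, x),
                         "direction": ["outbound"] * t.size,
                         "speed_cmps": np.zeros(t.size)})


def _baseline_spikes(rng, rate_hz, duration, n_cells):
    n = rng.poisson(rate_hz * duration)
    return np.sort(rng.uniform(0, duration, n)), rng.integers(0, n_cells, n)


def _burst(rng, t0, dur, n_cells, rate_hz=2500.0):
    n = max(1, rng.poisson(rate_hz * dur))
    return np.sort(rng.uniform(t0, t0 + dur, n)), rng.integers(0, n_cells, n)


def _one_stop(duration=60.0):
    return [StopPeriod(stop_id=0, corner_id=1, arrival=0.0, departure=duration,
                       current_direction="outbound",
                       sections=segment_stop(0.0, duration))]


class TestDetectEvents:
    def test_long_burst_boundaries(self):
        """100 ms burst far above baseline: one event whose mean-crossing
        boundaries bracket the burst within 10 ms."""
        rng = np.random.default_rng(0)
        pos = _stationary_positions()
        bt, bc = _baseline_spikes(rng, 100.0, 60.0, 20)
        et, ec = _burst(rng, 30.0, 0.1, 20)
        times = np.concatenate([bt, et])
        cells = np.concatenate([bc, ec])
        evs = detect_events(times, cells, 20, pos, _one_stop())
        hits = [e for e in evs if e.start < 30.05 < e.end]
        assert len(hits) == 1
        # boundaries bracket the burst; the stochastic baseline delays the
        # mean-crossing by at most a few smoothing widths
        assert 30.0 - 0.025 <= hits[0].start <= 30.005
        assert 30.095 <= hits[0].end <= 30.1 + 0.05

    def test_short_burst_rejected(self):
        """A 15 ms burst cannot satisfy the 40 ms minimum duration."""
        rng = np.random.default_rng(1)
        pos = _stationary_positions()
        bt, bc = _baseline_spikes(rng, 100.0, 60.0, 20)
        et, ec = _burst(rng, 30.0, 0.015, 20)
        evs = detect_events(np.concatenate([bt, et]), np.concatenate([bc, ec]),
                            20, pos, _one_stop())
        assert not any(e.start < 30.01 < e.end and e.duration >= 0.04 and
                       e.end - 30.0 < 0.05 for e in evs) or all(
            e.duration >= 0.04 for e in evs)
        for e in evs:
            assert e.duration >= 0.04

    def test_speed_gate(self):
        rng = np.random.default_rng(2)
        pos = _stationary_positions()
        pos["speed_cmps"] = 5.0            # moving: everything rejected
        bt, bc = _baseline_spikes(rng, 100.0, 60.0, 20)
        et, ec = _burst(rng, 30.0, 0.1, 20)
        evs = detect_events(np.concatenate([bt, et]), np.concatenate([bc, ec]),
                            20, pos, _one_stop())
        assert evs == []

    def test_cell_criterion_threshold(self):
        """With 50 cells the trajectory criterion needs max(ceil(7.5), 6) = 8
        distinct cells."""
        rng = np.random.default_rng(3)
        pos = _stationary_positions()
        ev_t = np.sort(rng.uniform(30.0, 30.1, 60))
        for n_active, expected in [(7, False), (8, True)]:
            # baseline restricted to the same cells so the participating set
            # is exactly n_active out of the 50-cell ensemble
            bt, bc = _baseline_spikes(rng, 60.0, 60.0, n_active)
            ev_c = np.resize(np.arange(n_active), ev_t.size)
            times = np.concatenate([bt, ev_t])
            cells = np.concatenate([bc, ev_c])
            evs = detect_events(times, cells, 50, pos, _one_stop())
            hit = next(e for e in evs if e.start < 30.05 < e.end)
            assert hit.passes_trajectory_cell_criterion is expected

    def test_events_sorted_nonoverlapping(self, small_session, clean_maps):
        rng = np.random.default_rng(4)
        pos = _stationary_positions(120.0)
        bt, bc = _baseline_spikes(rng, 150.0, 120.0, 30)
        parts = [bt]
        cparts = [bc]
        for k in range(8):
            et, ec = _burst(rng, 10.0 + 12 * k, 0.08, 30)
            parts.append(et)
            cparts.append(ec)
        evs = detect_events(np.concatenate(parts), np.concatenate(cparts), 30,
                            pos, _one_stop(120.0))
        for a, b in zip(evs, evs[1:]):
            assert a.end <= b.start

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        pos = _stationary_positions(120.0)
        bt, bc = _baseline_spikes(rng, 200.0, 120.0, 30)
        counts = []
        for sd in (2.0, 3.0, 4.0):
            evs = detect_events(bt, bc, 30, pos, _one_stop(120.0), threshold_sd=sd)
            counts.append(len(evs))
        assert counts[0] >= counts[1] >= counts[2]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            detect_events(np.array([]), np.array([]), 5,
                          _stationary_positions(), _one_stop())


class TestSegmentStop:
    def test_short_stop_single_engaged(self):
        assert segment_stop(0.0, 8.0) == [(0.0, 8.0, "engaged")]

    def test_long_stop_three_sections(self):
        assert segment_stop(0.0, 30.0) == [
            (0.0, 5.0, "engaged"), (5.0, 25.0, "disengaged"), (25.0, 30.0, "engaged")]

    def test_eleven_second_stop_drops_interior(self):
        secs = segment_stop(0.0, 11.0)
        assert secs == [(0.0, 5.0, "engaged"), (6.0, 11.0, "engaged")]

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            segment_stop(5.0, 5.0)

    def test_build_stop_periods_labels(self):
        stops = [{"stop_id": 0, "corner_id": 2, "arrival": 10.0, "departure": 50.0,
                  "direction": "inbound", "next_turn": "error"}]
        sp = build_stop_periods(stops)[0]
        assert sp.next_turn == "error"
        assert sp.sections[1][2] == "disengaged"


class TestTemporalWindows:
    def _stops(self, n=30, dur=40.0):
        return [StopPeriod(stop_id=i, corner_id=1, arrival=i * 100.0,
                           departure=i * 100.0 + dur, current_direction="outbound",
                           sections=segment_stop(i * 100.0, i * 100.0 + dur))
                for i in range(n)]

    def test_early_bias_detected(self):
        """Congruent probability 1 in the first 10 s, 0.5 after: significant
        windows appear only early."""
        rng = np.random.default_rng(0)
        stops = self._stops()
        evf = []
        for sp in stops:
            for off in np.arange(0.5, 39.5, 1.3):
                flag = True if off < 10 else bool(rng.random() < 0.5)
                evf.append((sp.arrival + off, sp.stop_id, flag))
        res = temporal_windows(evf, stops, chance=0.55, rng=1)
        sig = res["from_arrival"]["significant"]
        starts = res["from_arrival"]["window_starts"]
        assert sig[starts < 7.5].all()
        assert not sig[starts >= 15.0].any()

    def test_empty_bin_is_nan(self):
        stops = self._stops(n=3)
        evf = [(stops[0].arrival + 1.0, 0, True)]
        res = temporal_windows(evf, stops, chance=0.5, rng=0)
        props = res["from_arrival"]["proportions"]
        assert np.isnan(props[5:]).all()

    def test_requires_long_stops(self):
        stops = [StopPeriod(0, 1, 0.0, 12.0, "outbound",
                            sections=segment_stop(0.0, 12.0))]
        with pytest.raises(ValueError):
            temporal_windows([], stops, chance=0.5)
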