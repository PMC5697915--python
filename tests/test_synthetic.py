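"""Track geometry, tuning curves, and session-generator invariants."""

import numpy as np
import pandas as pd
import pytest

import replaykit as rk
from replaykit.synthetic_data import ReplayGroundTruth, _assign_injections


class TestTrack:
    def test_geometry(self, track):
        assert track.length_cm == 600.0
        assert track.n_bins == 300
        assert track.corner_positions_cm == (190.0, 410.0)

    def test_excluded_bin_count(self, track):
        # 5 bins at each end plus 5 around each corner = 20 per direction
        assert int(track.excluded_mask.sum()) == 20

    def test_arm_membership_boundaries(self, track):
        assert track.arm_of(189.0) == 1
        assert track.arm_of(190.0) == 2
        assert track.arm_of(409.9) == 2
        assert track.arm_of(410.0) == 3
        with pytest.raises(ValueError):
            track.arm_of(601.0)

    def test_adjacency(self, track):
        assert track.adjacent_arms(1) == (1, 2)
        assert track.adjacent_arms(2) == (2, 3)


class TestTuning:
    def test_shapes_and_peaks(self, track):
        spec = rk.SessionSpec(seed=0, n_place_cells=40)
        tun = rk.generate_tuning(spec, track)
        for d in ("outbound", "inbound"):
            assert tun.place[d].shape == (40, 300)
            assert (tun.place[d].max(axis=1) > 1.0).all()

    def test_deterministic(self, track):
        spec = rk.SessionSpec(seed=42)
        a = rk.generate_tuning(spec, track)
        b = rk.generate_tuning(spec, track)
        np.testing.assert_array_equal(a.place["outbound"], b.place["outbound"])
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_directions_uncorrelated(self, track):
        # directional place code: inbound/outbound fields independent
        spec = rk.SessionSpec(seed=1, n_place_cells=1000)
        tun = rk.generate_tuning(spec, track)
        corrs = [np.corrcoef(tun.place["outbound"][i], tun.place["inbound"][i])[0, 1]
                 for i in range(1000)]
        assert abs(np.mean(corrs)) < 0.05

    def test_invalid_spec_rejected(self, track):
        with pytest.raises(ValueError):
            rk.generate_tuning(rk.SessionSpec(n_place_cells=0), track)
        with pytest.raises(ValueError):
            rk.SessionSpec(error_rate=1.5).validate()


class TestSession:
    def test_deterministic_bundle(self):
        spec = rk.SessionSpec(seed=9, n_laps=4)
        a = rk.simulate_session(spec)
        b = rk.simulate_session(spec)
        pd.testing.assert_frame_equal(a.positions, b.positions)
        pd.testing.assert_frame_equal(a.spikes, b.spikes)
        pd.testing.assert_frame_equal(a.lfp, b.lfp)
        assert a.truth == b.truth

    def test_lap_count(self):
        spec = rk.SessionSpec(seed=2, n_laps=22)
        s = rk.simulate_session(spec)
        dirs = s.positions["direction"].to_numpy()
        n_traversals = 1 + int((dirs[1:] != dirs[:-1]).sum())
        assert n_traversals == 22

    def test_speed_profile(self, small_session):
        s = small_session
        t = s.positions["t"].to_numpy()
        speed = s.positions["speed_cmps"].to_numpy()
        in_stop = np.zeros(t.size, dtype=bool)
        for st in s.stops:
            in_stop |= (t >= st["arrival"] + 0.5) & (t <= st["departure"] - 0.5)
        # interiors of stops are immobile; running excludes stop neighborhoods
        assert (speed[in_stop] < 3.0).mean() > 0.95
        from scipy.ndimage import binary_erosion
        raw = np.abs(np.gradient(s.positions["x_cm"].to_numpy(), t))
        running = binary_erosion(raw > 15.0, np.ones(25))   # run interiors
        assert (speed[running] > 10.0).mean() > 0.90

    def test_injections_lie_inside_stops(self, small_session):
        stops = {x["stop_id"]: x for x in small_session.stops}
        for inj in small_session.truth["injections"]:
            st = stops[inj["stop_id"]]
            assert st["arrival"] + inj["onset_s"] >= st["arrival"]
            assert st["arrival"] + inj["onset_s"] + inj["duration_s"] <= st["departure"]

    def test_explicit_injection_outside_stop_raises(self):
        bad = ReplayGroundTruth(stop_id=0, onset_s=1e5, velocity_mps=5.0,
                                intercept_m=1.0, direction="outbound", arm=1,
                                order="forward", duration_s=0.2)
        spec2 = rk.SessionSpec(seed=0, n_laps=4, replay_injections=[bad])
        with pytest.raises(ValueError, match="outside stop"):
            rk.simulate_session(spec2)

    def test_ground_truth_validation(self):
        with pytest.raises(ValueError):
            ReplayGroundTruth(0, 1.0, 1.0, 1.0, "outbound", 1, "forward").validate()
        with pytest.raises(ValueError):
            ReplayGroundTruth(0, 1.0, 5.0, 5.9, "outbound", 3, "forward",
                              duration_s=0.3).validate()

    def test_injected_spike_order_follows_line(self, clean_session, clean_maps,
                                               clean_place_spikes):
        """Within an injected event, cells fire in the order the line crosses
        their fields: forward events in increasing position, reverse events in
        decreasing position."""
        s = clean_session
        st, sc = clean_place_spikes
        stops = {x["stop_id"]: x for x in s.stops}
        checked = 0
        for inj in s.truth["injections"][:20]:
            t0 = stops[inj["stop_id"]]["arrival"] + inj["onset_s"]
            sel = (st >= t0) & (st <= t0 + inj["duration_s"])
            if sel.sum() < 6:
                continue
            centers = s.tuning.place_centers_cm[inj["direction"]]
            first_t, counts = {}, {}
            for tt, cc in zip(st[sel], sc[sel]):
                first_t[cc] = min(first_t.get(cc, np.inf), tt)
                counts[cc] = counts.get(cc, 0) + 1
            # injected participants fire bursts; stray baseline singletons are
            # not part of the trajectory
            cells = sorted(c for c in first_t if counts[c] >= 2)
            if len(cells) < 5:
                continue
            pos = np.array([centers[c] for c in cells])
            times = np.array([first_t[c] for c in cells])
            r = np.corrcoef(times, pos)[0, 1]
            assert (r > 0.8) if inj["velocity_mps"] > 0 else (r < -0.8)
            checked += 1
        assert checked >= 5

    def test_congruence_effect_zero_decouples_outcomes(self):
        """With no content-outcome coupling the error rate matches the base
        rate regardless of event content."""
        errs = []
        for seed in range(6):
            s = rk.simulate_session(rk.SessionSpec(seed=seed, n_laps=8,
                                                   error_rate=0.3,
                                                   congruence_effect=0.0))
            errs.extend(st["next_turn"] == "error" for st in s.stops)
        assert abs(np.mean(errs) - 0.3) < 0.1

    def test_save_load_roundtrip(self, small_session, tmp_path):
        rk.save_session(small_session, tmp_path)
        loaded = rk.load_session(tmp_path)
        pd.testing.assert_frame_equal(loaded.positions, small_session.positions)
        pd.testing.assert_frame_equal(loaded.spikes, small_session.spikes)
        assert loaded.stops == small_session.stops
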