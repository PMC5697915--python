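"""Synthetic Z-track sessions with known ground truth.

Emulates a self-paced spatial decision task on an elevated 600 cm Z-shaped
track (two 190 cm parallel arms joined by a 220 cm diagonal).  A simulated rat
alternates outbound (arm 1 -> arm 3) and inbound traversals, pausing at the
two corners where it must choose the correct turn to be rewarded.  The
generator produces 50 Hz tracking, place/grid-cell spike trains (inhomogeneous
Poisson during running, injected burst events with exactly known replay
trajectories during corner stops), an LFP composed of theta/delta/ripple
components, and per-stop turn outcomes optionally coupled to the reactivation
content - so every downstream stage of the analysis can be checked against
ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .utils import compute_speed, read_json, write_json

OUTBOUND = "outbound"
INBOUND = "inbound"
DIRECTIONS = (OUTBOUND, INBOUND)


# ---------------------------------------------------------------------------
# Track geometry
# ---------------------------------------------------------------------------

@dataclass
class TrackModel:
    """Linearized Z-track: three arms, two corners, 2 cm bins per direction.

    Arm 1 covers [0, 190) cm, arm 2 (the diagonal) [190, 410) cm and arm 3
    [410, 600] cm.  The final 10 cm at either end and +-5 cm around each
    corner are excluded from ratemaps (sites of eating/grooming).  A bin is
    excluded iff its center falls inside an excluded zone.
    """

    length_cm: float = 600.0
    bin_size_cm: float = 2.0
    arm_edges_cm: tuple = (0.0, 190.0, 410.0, 600.0)
    end_exclusion_cm: float = 10.0
    corner_exclusion_cm: float = 5.0

    @property
    def n_bins(self) -> int:
        return int(round(self.length_cm / self.bin_size_cm))

    @property
    def bin_centers_cm(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_size_cm

    @property
    def corner_positions_cm(self) -> tuple:
        return (self.arm_edges_cm[1], self.arm_edges_cm[2])

    @property
    def excluded_mask(self) -> np.ndarray:
        """Boolean per bin, True where the bin is excluded from analysis."""
        c = self.bin_centers_cm
        mask = (c < self.end_exclusion_cm) | (c >= self.length_cm - self.end_exclusion_cm)
        for corner in self.corner_positions_cm:
            # half-open zone [corner-5, corner+5), matching the bin convention
            mask |= (c >= corner - self.corner_exclusion_cm) & (c < corner + self.corner_exclusion_cm)
        return mask

    def arm_of(self, x_cm: float) -> int:
        """Arm index (1-3) containing a linearized position; half-open bounds."""
        e = self.arm_edges_cm
        if x_cm < e[0] or x_cm > e[3]:
            raise ValueError(f"position {x_cm} cm off track")
        if x_cm < e[1]:
            return 1
        if x_cm < e[2]:
            return 2
        return 3

    def arm_of_bins(self) -> np.ndarray:
        """Arm index per position bin (by bin center)."""
        c = self.bin_centers_cm
        return np.where(c < self.arm_edges_cm[1], 1, np.where(c < self.arm_edges_cm[2], 2, 3))

    def adjacent_arms(self, corner_id: int) -> tuple:
        """Arms flanking a corner: corner 1 -> (1, 2); corner 2 -> (2, 3)."""
        if corner_id == 1:
            return (1, 2)
        if corner_id == 2:
            return (2, 3)
        raise ValueError(f"unknown corner {corner_id}")


def make_track(**kwargs) -> TrackModel:
    return TrackModel(**kwargs)


# ---------------------------------------------------------------------------
# Session specification
# ---------------------------------------------------------------------------

@dataclass
class ReplayGroundTruth:
    """One injected burst event realizing a constant-velocity trajectory
    x(t) = V*t + c (x in meters on the linearized track, t from event onset)."""

    stop_id: int
    onset_s: float              # seconds from stop arrival
    velocity_mps: float
    intercept_m: float
    direction: str              # outbound | inbound (which ratemaps it expresses)
    arm: int                    # arm containing the trajectory midpoint
    order: str                  # forward | reverse (sign of velocity)
    n_cells: int = 0            # filled in at simulation time
    duration_s: float = 0.12
    section: str = ""           # engaged | disengaged, filled at simulation time
    has_ripple: bool = True
    grid_yoked: bool = False

    def validate(self):
        if not (2.0 <= abs(self.velocity_mps) <= 50.0):
            raise ValueError("|velocity| must lie in [2, 50] m/s")
        x0 = self.intercept_m
        x1 = self.intercept_m + self.velocity_mps * self.duration_s
        if not (0.0 <= min(x0, x1) and max(x0, x1) <= 6.0):
            raise ValueError("trajectory leaves the [0, 6] m track")
        if (self.order == "forward") != (self.velocity_mps > 0):
            raise ValueError("order inconsistent with velocity sign")


@dataclass
class SessionSpec:
    """Conditions of a simulated session.

    Defaults follow the recorded task statistics: ensembles of a few dozen
    place cells, 22 traversals, a 10.71 s mean corner-stop duration, and
    reactivation-content biases of 62%/52% congruent and 81%/71% local for
    engaged/disengaged events.
    """

    n_place_cells: int = 40
    n_grid_cells: int = 8
    n_laps: int = 22
    mean_stop_duration_s: float = 10.71
    replay_injections: list = None          # explicit ReplayGroundTruth list, or None = auto
    lfp_components: dict = field(default_factory=lambda: {
        "theta": (8.0, 60.0),     # (center frequency Hz, amplitude uV)
        "delta": (3.0, 40.0),
        "ripple": (200.0, 80.0),
    })
    error_rate: float = 0.1
    congruence_effect: float = 0.0
    seed: int = 0
    # behavior
    run_speed_cmps: float = 40.0
    end_stop_s: float = 3.0
    min_stop_s: float = 3.0
    # spiking
    baseline_stop_rate_hz: float = 0.4
    injection_rate_hz: float = 0.25
    p_congruent: dict = field(default_factory=lambda: {"engaged": 0.62, "disengaged": 0.52})
    p_local_given_congruent: dict = field(default_factory=lambda: {"engaged": 0.81, "disengaged": 0.71})
    p_forward: dict = field(default_factory=lambda: {"engaged": 0.76, "disengaged": 0.53})
    # LFP
    lfp_fs_hz: float = 1200.0
    lfp_noise_uv: float = 8.0
    stop_theta_factor: float = 0.5
    ripple_fraction: float = 0.8
    ripple_duration_s: float = 0.1
    # grid replay coupling per section
    grid_yoked: dict = field(default_factory=lambda: {"engaged": False, "disengaged": True})

    def validate(self):
        if self.n_place_cells < 1:
            raise ValueError("need at least one place cell")
        for p in (self.error_rate, self.congruence_effect, self.ripple_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_laps < 1 or self.mean_stop_duration_s <= 0:
            raise ValueError("invalid behavioral parameters")
        if self.replay_injections is not None:
            for inj in self.replay_injections:
                inj.validate()


# ---------------------------------------------------------------------------
# Tuning curves
# ---------------------------------------------------------------------------

@dataclass
class TuningSet:
    """Ground-truth firing-rate profiles over track bins.

    ``place[direction]`` is (n_place_cells, n_bins) in Hz; inbound and
    outbound fields are drawn independently (directional place code).
    ``grid`` is (n_grid_cells, n_bins), shared between directions.
    """

    place: dict                      # direction -> (n_cells, n_bins)
    place_centers_cm: dict           # direction -> (n_cells,) field centers
    place_sigmas_cm: dict
    grid: np.ndarray
    grid_period_cm: np.ndarray
    grid_phase_cm: np.ndarray
    grid_field_size_cm: float

    @property
    def n_place_cells(self) -> int:
        return self.place[OUTBOUND].shape[0]


def generate_tuning(spec: SessionSpec, track: TrackModel, rng=None) -> TuningSet:
    """Draw Gaussian place fields (independent per direction) and periodic
    grid profiles.  Field widths 15-30 cm (sigma 7.5-15 cm), peaks 2-20 Hz."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    centers_lo, centers_hi = 15.0, track.length_cm - 15.0
    x = track.bin_centers_cm
    place, centers_d, sigmas_d = {}, {}, {}
    for direction in DIRECTIONS:
        centers = rng.uniform(centers_lo, centers_hi, spec.n_place_cells)
        sigmas = rng.uniform(7.5, 15.0, spec.n_place_cells)
        peaks = rng.uniform(2.0, 20.0, spec.n_place_cells)
        rates = peaks[:, None] * np.exp(-0.5 * ((x[None, :] - centers[:, None]) / sigmas[:, None]) ** 2)
        place[direction] = rates
        centers_d[direction] = centers
        sigmas_d[direction] = sigmas

    field_size = 40.0
    periods = rng.uniform(80.0, 120.0, max(spec.n_grid_cells, 1))
    phases = rng.uniform(0.0, periods)
    gpeaks = rng.uniform(3.0, 15.0, max(spec.n_grid_cells, 1))
    sigma_g = field_size / 4.0
    grid = np.zeros((spec.n_grid_cells, track.n_bins))
    for i in range(spec.n_grid_cells):
        for fc in np.arange(phases[i] - periods[i], track.length_cm + periods[i], periods[i]):
            grid[i] += gpeaks[i] * np.exp(-0.5 * ((x - fc) / sigma_g) ** 2)
    return TuningSet(place=place, place_centers_cm=centers_d, place_sigmas_cm=sigmas_d,
                     grid=grid, grid_period_cm=periods[: spec.n_grid_cells],
                     grid_phase_cm=phases[: spec.n_grid_cells], grid_field_size_cm=field_size)


def grid_field_centers(tuning: TuningSet, cell: int, length_cm: float) -> np.ndarray:
    """Ground-truth field centers of one grid cell along the track."""
    lam, phi = tuning.grid_period_cm[cell], tuning.grid_phase_cm[cell]
    ks = np.arange(-1, int(length_cm / lam) + 2)
    centers = phi + ks * lam
    return centers[(centers >= 0) & (centers <= length_cm)]


# ---------------------------------------------------------------------------
# Session bundle
# ---------------------------------------------------------------------------

@dataclass
class Session:
    positions: pd.DataFrame     # t, x_cm, direction, speed_cmps
    spikes: pd.DataFrame        # cell_id, cell_type, t
    lfp: pd.DataFrame           # t, value (uV)
    stops: list                 # dicts: stop_id, corner_id, arrival, departure, direction, next_turn
    truth: dict
    track: TrackModel
    tuning: TuningSet = None


def simulate_session(spec: SessionSpec, track: TrackModel = None, tuning: TuningSet = None) -> Session:
    """Generate a full session bundle; the seed fully determines the output."""
    spec.validate()
    if track is None:
        track = make_track()
    rng = np.random.default_rng(spec.seed)
    if tuning is None:
        tuning = generate_tuning(spec, track, rng)

    positions, stops = _simulate_behavior(spec, track, rng)
    injections = _assign_injections(spec, track, tuning, stops, rng)
    _assign_outcomes(spec, stops, injections, rng)
    spikes = _simulate_spikes(spec, track, tuning, positions, stops, injections, rng)
    lfp = _simulate_lfp(spec, positions, injections, stops, rng)

    truth = {
        "injections": [dataclasses.asdict(inj) for inj in injections],
        "grid_field_size_cm": tuning.grid_field_size_cm,
        "n_place_cells": spec.n_place_cells,
        "n_grid_cells": spec.n_grid_cells,
        "seed": spec.seed,
    }
    return Session(positions=positions, spikes=spikes, lfp=lfp, stops=stops,
                   truth=truth, track=track, tuning=tuning)


def _simulate_behavior(spec, track, rng):
    """50 Hz tracking: alternating traversals with corner stops.

    Stop durations are exponential with the specified mean (truncated below at
    ``min_stop_s``), reproducing a heavy tail of long, disengaged stops."""
    dt = 0.02
    margin = 3.0
    x_lo, x_hi = margin, track.length_cm - margin
    xs, dirs_ = [], []
    stops = []
    t_cursor = 0.0
    stop_id = 0

    def run_segment(x0, x1):
        nonlocal t_cursor
        n_est = int(abs(x1 - x0) / (spec.run_speed_cmps * dt)) + 10
        noise = rng.normal(0.0, 4.0, n_est)
        pos = x0
        out = []
        sgn = 1.0 if x1 > x0 else -1.0
        i = 0
        while (pos - x1) * sgn < 0:
            v = max(spec.run_speed_cmps + noise[i % n_est], 15.0)
            pos += sgn * v * dt
            if (pos - x1) * sgn >= 0:
                break
            out.append(pos)
            i += 1
        return out

    def stop_segment(x_stop, duration):
        nonlocal t_cursor
        n = max(1, int(round(duration / dt)))
        return list(x_stop + 0.05 * rng.standard_normal(n))

    direction = OUTBOUND
    for _ in range(spec.n_laps):
        if direction == OUTBOUND:
            waypoints = [x_lo, track.corner_positions_cm[0], track.corner_positions_cm[1], x_hi]
            corner_ids = [1, 2]
        else:
            waypoints = [x_hi, track.corner_positions_cm[1], track.corner_positions_cm[0], x_lo]
            corner_ids = [2, 1]
        for k in range(3):
            seg = run_segment(waypoints[k], waypoints[k + 1])
            xs.extend(seg)
            dirs_.extend([direction] * len(seg))
            t_cursor = len(xs) * dt
            if k < 2:
                dur = max(spec.min_stop_s, rng.exponential(spec.mean_stop_duration_s))
                arrival = t_cursor
                seg = stop_segment(waypoints[k + 1], dur)
                xs.extend(seg)
                dirs_.extend([direction] * len(seg))
                t_cursor = len(xs) * dt
                stops.append({"stop_id": stop_id, "corner_id": corner_ids[k],
                              "arrival": arrival, "departure": t_cursor,
                              "direction": direction, "next_turn": "correct"})
                stop_id += 1
            else:
                seg = stop_segment(waypoints[3], spec.end_stop_s)
                xs.extend(seg)
                dirs_.extend([direction] * len(seg))
                t_cursor = len(xs) * dt
        direction = INBOUND if direction == OUTBOUND else OUTBOUND

    t = np.arange(len(xs)) * dt
    x = np.clip(np.asarray(xs), 0.0, track.length_cm)
    speed = compute_speed(t, x)
    positions = pd.DataFrame({"t": t, "x_cm": x, "direction": dirs_, "speed_cmps": speed})
    return positions, stops


def _section_of(onset, stop_dur, engaged_window=5.0, min_split=10.0):
    if stop_dur < min_split or onset <= engaged_window or onset >= stop_dur - engaged_window:
        return "engaged"
    return "disengaged"


def _assign_injections(spec, track, tuning, stops, rng):
    """Materialize ground-truth replay events for every corner stop."""
    if spec.replay_injections is not None:
        out = []
        for inj in spec.replay_injections:
            inj = dataclasses.replace(inj)
            stop = stops[inj.stop_id]
            inj.section = _section_of(inj.onset_s, stop["departure"] - stop["arrival"])
            out.append(inj)
        return out

    injections = []
    arm_edges = track.arm_edges_cm
    for stop in stops:
        dur = stop["departure"] - stop["arrival"]
        n_ev = rng.poisson(spec.injection_rate_hz * dur)
        onsets = np.sort(rng.uniform(0.5, max(0.6, dur - 0.7), n_ev))
        t_last_end = -np.inf
        for onset in onsets:
            if onset < t_last_end + 0.3:       # keep events from overlapping
                continue
            section = _section_of(onset, dur)
            congruent = rng.random() < spec.p_congruent[section]
            if congruent:
                direction = stop["direction"]
                local = rng.random() < spec.p_local_given_congruent[section]
                adjacent = track.adjacent_arms(stop["corner_id"])
                if local:
                    arm = int(rng.choice(adjacent))
                else:
                    remote = [a for a in (1, 2, 3) if a not in adjacent]
                    arm = int(rng.choice(remote))
            else:
                direction = INBOUND if stop["direction"] == OUTBOUND else OUTBOUND
                arm = int(rng.integers(1, 4))
            forward = rng.random() < spec.p_forward[section]
            lo, hi = arm_edges[arm - 1] / 100.0, arm_edges[arm] / 100.0
            # keep trajectories clear of the masked end/corner zones, where
            # the decoder carries no probability
            excl_lo = (track.end_exclusion_cm if arm == 1 else track.corner_exclusion_cm) / 100.0
            excl_hi = (track.end_exclusion_cm if arm == 3 else track.corner_exclusion_cm) / 100.0
            lo, hi = lo + excl_lo + 0.10, hi - excl_hi - 0.10
            # trajectories span >= 1.2 m (twice the 60 cm scoring band) so the
            # velocity is identifiable; |V| in [5, 12] m/s on the 0.5 grid
            # sample (duration, |V|) uniformly from the arm's feasible set so
            # no (direction, arm) category is dropped preferentially
            durs = 0.01 * np.arange(20, 31)
            vmags = 0.5 * np.arange(10, 25)
            dd, vv = np.meshgrid(durs, vmags)
            spans = dd * vv
            feas = np.nonzero((spans >= 1.2) & (spans <= hi - lo - 0.05))
            if feas[0].size == 0:
                continue
            k = int(rng.integers(feas[0].size))
            v = float(vv[feas[0][k], feas[1][k]])
            duration = float(dd[feas[0][k], feas[1][k]])
            span = v * duration
            if not forward:
                v = -v
            x0 = rng.uniform(lo, hi - span)
            c = x0 + (span if v < 0 else 0.0)
            c = round(c * 100) / 100.0                    # snap to the 1 cm intercept grid
            t_last_end = onset + duration
            injections.append(ReplayGroundTruth(
                stop_id=stop["stop_id"], onset_s=float(onset), velocity_mps=v,
                intercept_m=c, direction=direction, arm=arm,
                order="forward" if forward else "reverse", duration_s=duration,
                section=section, has_ripple=bool(rng.random() < spec.ripple_fraction),
                grid_yoked=bool(spec.grid_yoked.get(section, False)),
            ))
    return injections


def _assign_outcomes(spec, stops, injections, rng):
    """Turn outcome after each stop; congruence_effect couples the error
    probability to whether the stop contained engaged congruent content."""
    by_stop = {}
    for inj in injections:
        by_stop.setdefault(inj.stop_id, []).append(inj)
    for stop in stops:
        p_err = spec.error_rate
        engaged = [i for i in by_stop.get(stop["stop_id"], []) if i.section == "engaged"]
        if engaged and spec.congruence_effect > 0:
            congruent = any(i.direction == stop["direction"] for i in engaged)
            if congruent:
                p_err *= (1.0 - spec.congruence_effect)
            else:
                p_err = min(1.0, p_err * (1.0 + spec.congruence_effect))
        stop["next_turn"] = "error" if rng.random() < p_err else "correct"


def _poisson_spikes(rates, t, dt, rng):
    """Spike times from per-sample rates (n_samples, n_cells)."""
    counts = rng.poisson(rates * dt)
    cell_idx, times = [], []
    samp, cell = np.nonzero(counts)
    for s, c in zip(samp, cell):
        k = counts[s, c]
        times.append(t[s] + rng.uniform(0.0, dt, k))
        cell_idx.append(np.full(k, c))
    if not times:
        return np.array([]), np.array([], dtype=int)
    return np.concatenate(times), np.concatenate(cell_idx).astype(int)


def _simulate_spikes(spec, track, tuning, positions, stops, injections, rng):
    dt = float(np.median(np.diff(positions["t"].to_numpy())))
    t = positions["t"].to_numpy()
    x = positions["x_cm"].to_numpy()
    speed = positions["speed_cmps"].to_numpy()
    dirs_ = positions["direction"].to_numpy()
    bin_idx = np.clip((x / track.bin_size_cm).astype(int), 0, track.n_bins - 1)
    running = speed >= 10.0

    rows_t, rows_cell, rows_type = [], [], []

    # place cells: tuned Poisson while running, low baseline otherwise
    for direction in DIRECTIONS:
        sel = running & (dirs_ == direction)
        if not sel.any():
            continue
        rates = tuning.place[direction][:, bin_idx[sel]].T      # (n_samp, n_cells)
        times, cells = _poisson_spikes(rates, t[sel], dt, rng)
        rows_t.append(times)
        rows_cell.append(cells)
    sel = ~running
    if sel.any():
        base = np.full((sel.sum(), spec.n_place_cells), spec.baseline_stop_rate_hz)
        times, cells = _poisson_spikes(base, t[sel], dt, rng)
        rows_t.append(times)
        rows_cell.append(cells)
    place_t = np.concatenate(rows_t) if rows_t else np.array([])
    place_c = np.concatenate(rows_cell) if rows_cell else np.array([], dtype=int)

    # grid cells: tuned while running, sparse baseline otherwise
    gt_list, gc_list = [], []
    if spec.n_grid_cells:
        rates = tuning.grid[:, bin_idx[running]].T
        times, cells = _poisson_spikes(rates, t[running], dt, rng)
        gt_list.append(times)
        gc_list.append(cells)
        base = np.full(((~running).sum(), spec.n_grid_cells), 0.2)
        times, cells = _poisson_spikes(base, t[~running], dt, rng)
        gt_list.append(times)
        gc_list.append(cells)
    grid_t = np.concatenate(gt_list) if gt_list else np.array([])
    grid_c = np.concatenate(gc_list) if gc_list else np.array([], dtype=int)

    # injected replay bursts
    inj_t, inj_c, gin_t, gin_c = [], [], [], []
    stop_by_id = {s["stop_id"]: s for s in stops}
    for inj in injections:
        stop = stop_by_id[inj.stop_id]
        t0 = stop["arrival"] + inj.onset_s
        if t0 + inj.duration_s > stop["departure"]:
            raise ValueError("replay injection outside stop interval")
        v, c, dur = inj.velocity_mps, inj.intercept_m, inj.duration_s
        T = 0.01                                                   # decoding bin
        n_tb = max(1, int(round(dur / T)))
        x_ends = sorted((c, c + v * dur))
        centers = tuning.place_centers_cm[inj.direction] / 100.0   # meters
        # participants: cells whose chosen-direction field center lies within
        # 5 cm of the trajectory path
        active = np.nonzero((centers >= x_ends[0] - 0.05) & (centers <= x_ends[1] + 0.05))[0]
        inj.n_cells = int(active.size)
        for ci in active:
            tc = np.clip((centers[ci] - c) / v, 0.0, dur)
            # one spike in the decoding bin whose index time is nearest the
            # line crossing (keeps the fitted intercept unbiased) and one in
            # the neighboring bin on the crossing's side, so most time bins
            # are occupied and the velocity stays identifiable
            k = min(n_tb - 1, int(round(tc / T)))
            k2 = k + (1 if tc / T - k > 0 else -1)
            k2 = min(n_tb - 1, max(0, k2))
            times = np.array([(k + rng.uniform(0.15, 0.85)) * T,
                              (k2 + rng.uniform(0.15, 0.85)) * T])
            inj_t.append(t0 + times)
            inj_c.append(np.full(times.size, ci))
        if inj.grid_yoked and spec.n_grid_cells:
            for gi in range(spec.n_grid_cells):
                for fc in grid_field_centers(tuning, gi, track.length_cm) / 100.0:
                    if x_ends[0] - 0.15 <= fc <= x_ends[1] + 0.15:
                        tc = np.clip((fc - c) / v, 0.0, dur - 1e-4)
                        gin_t.append(np.array([t0 + tc + rng.normal(0.0, 0.003)]))
                        gin_c.append(np.array([gi]))

    if inj_t:
        place_t = np.concatenate([place_t, np.concatenate(inj_t)])
        place_c = np.concatenate([place_c, np.concatenate(inj_c).astype(int)])
    if gin_t:
        grid_t = np.concatenate([grid_t, np.concatenate(gin_t)])
        grid_c = np.concatenate([grid_c, np.concatenate(gin_c).astype(int)])

    frames = [pd.DataFrame({"cell_id": [f"p{c:03d}" for c in place_c],
                            "cell_type": "place", "t": place_t})]
    if grid_t.size:
        frames.append(pd.DataFrame({"cell_id": [f"g{c:03d}" for c in grid_c],
                                    "cell_type": "grid", "t": grid_t}))
    spikes = pd.concat(frames, ignore_index=True).sort_values("t", kind="stable")
    return spikes.reset_index(drop=True)


def _simulate_lfp(spec, positions, injections, stops, rng):
    """Sum of band-limited components plus white noise (no 1/f background).

    Theta amplitude is reduced during immobility; ripple bursts (Hann
    envelope) coincide with the flagged injected events."""
    fs = spec.lfp_fs_hz
    t_end = positions["t"].iloc[-1]
    t = np.arange(0.0, t_end, 1.0 / fs)
    f_theta, a_theta = spec.lfp_components["theta"]
    f_delta, a_delta = spec.lfp_components["delta"]
    f_rip, a_rip = spec.lfp_components["ripple"]

    running = np.interp(t, positions["t"], (positions["speed_cmps"] >= 10.0).astype(float)) > 0.5
    theta_amp = np.where(running, a_theta, a_theta * spec.stop_theta_factor)
    value = (theta_amp * np.sin(2 * np.pi * f_theta * t + rng.uniform(0, 2 * np.pi))
             + a_delta * np.sin(2 * np.pi * f_delta * t + rng.uniform(0, 2 * np.pi))
             + spec.lfp_noise_uv * rng.standard_normal(t.size))

    stop_by_id = {s["stop_id"]: s for s in stops}
    for inj in injections:
        if not inj.has_ripple:
            continue
        t0 = stop_by_id[inj.stop_id]["arrival"] + inj.onset_s + inj.duration_s / 2.0
        n = int(spec.ripple_duration_s * fs)
        i0 = int((t0 - spec.ripple_duration_s / 2.0) * fs)
        if i0 < 0 or i0 + n > t.size:
            continue
        env = np.hanning(n)
        value[i0:i0 + n] += a_rip * env * np.sin(2 * np.pi * f_rip * t[i0:i0 + n])
    return pd.DataFrame({"t": t, "value": value})


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

def save_session(session: Session, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.positions.to_csv(out / "positions.csv", index=False)
    session.spikes.to_csv(out / "spikes.csv", index=False)
    session.lfp.to_csv(out / "lfp.csv", index=False)
    write_json(out / "stops.json", session.stops)
    write_json(out / "truth.json", session.truth)


def load_session(in_dir: str | Path, track: TrackModel = None) -> Session:
    d = Path(in_dir)
    return Session(
        positions=pd.read_csv(d / "positions.csv"),
        spikes=pd.read_csv(d / "spikes.csv"),
        lfp=pd.read_csv(d / "lfp.csv"),
        stops=read_json(d / "stops.json"),
        truth=read_json(d / "truth.json"),
        track=track or make_track(),
    )
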