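"""Candidate reactivation events and corner-stop segmentation.

Events are bursts of multi-unit (MU) place-cell activity: spike counts in
1 ms bins, Gaussian-smoothed (sigma = 5 ms), thresholded at the session mean
plus 3 SD, with boundaries extended outward to the mean-crossing.  Bursts
shorter than 40 ms, with mean speed >= 3 cm/s, or whose midpoint falls outside
a corner stop are rejected.  Corner stops are segmented into engaged (first
and last 5 s) and disengaged (interior) sections; stops under 10 s are wholly
engaged, and sections under 2 s are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

SPEED_STOP_CMPS = 3.0
MIN_EVENT_S = 0.04


@dataclass
class StopPeriod:
    stop_id: int
    corner_id: int
    arrival: float
    departure: float
    current_direction: str
    next_turn: str = "correct"
    sections: list = field(default_factory=list)    # (t0, t1, label)

    @property
    def duration(self) -> float:
        return self.departure - self.arrival


@dataclass
class CandidateEvent:
    event_id: int
    start: float
    end: float
    participating_cells: set
    spike_times: np.ndarray
    spike_cells: np.ndarray          # integer indices into the place-cell ensemble
    stop_id: int
    corner_id: int
    section: str
    mean_speed: float
    passes_trajectory_cell_criterion: bool
    current_direction: str
    next_turn: str
    animal_x_cm: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def segment_stop(arrival: float, departure: float, engaged_window_s: float = 5.0,
                 min_split_s: float = 10.0, min_section_s: float = 2.0) -> list:
    """Engaged/disengaged sections of one corner stop."""
    if arrival >= departure:
        raise ValueError("arrival must precede departure")
    dur = departure - arrival
    if dur < min_split_s:
        secs = [(arrival, departure, "engaged")]
    else:
        secs = [
            (arrival, arrival + engaged_window_s, "engaged"),
            (arrival + engaged_window_s, departure - engaged_window_s, "disengaged"),
            (departure - engaged_window_s, departure, "engaged"),
        ]
    return [(a, b, lab) for a, b, lab in secs if b - a >= min_section_s]


def build_stop_periods(stops: list, engaged_window_s: float = 5.0,
                       min_split_s: float = 10.0, min_section_s: float = 2.0) -> list:
    """StopPeriod objects (with sections) from the session stop table."""
    out = []
    for s in stops:
        sp = StopPeriod(stop_id=s["stop_id"], corner_id=s["corner_id"],
                        arrival=s["arrival"], departure=s["departure"],
                        current_direction=s["direction"], next_turn=s.get("next_turn", "correct"))
        sp.sections = segment_stop(sp.arrival, sp.departure, engaged_window_s,
                                   min_split_s, min_section_s)
        out.append(sp)
    return out


def _section_label(stop: StopPeriod, t_mid: float):
    for a, b, lab in stop.sections:
        if a <= t_mid < b:
            return lab
    return None


def detect_events(spike_times, spike_cells, n_ensemble: int, positions, stops: list,
                  *, bin_ms: float = 1.0, sigma_ms: float = 5.0, threshold_sd: float = 3.0,
                  min_duration_s: float = MIN_EVENT_S, speed_limit_cmps: float = SPEED_STOP_CMPS,
                  min_cells_fraction: float = 0.15, min_cells_floor: int = 6) -> list:
    """Detect candidate reactivation events from place-cell MU activity.

    The MU mean/SD baseline is computed over the whole session (running and
    stops).  The trajectory-analysis cell criterion requires at least
    max(ceil(0.15 * ensemble), 6) distinct active cells.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    spike_cells = np.asarray(spike_cells, dtype=int)
    if spike_times.size == 0:
        raise ValueError("no place-cell spikes")
    order = np.argsort(spike_times, kind="stable")
    spike_times, spike_cells = spike_times[order], spike_cells[order]

    t = positions["t"].to_numpy()
    speed = positions["speed_cmps"].to_numpy()
    x = positions["x_cm"].to_numpy()

    dt = bin_ms / 1000.0
    t0, t1 = t[0], t[-1]
    n_bins = int(np.ceil((t1 - t0) / dt)) + 1
    counts = np.bincount(np.clip(((spike_times - t0) / dt).astype(int), 0, n_bins - 1),
                         minlength=n_bins).astype(float)
    mu = gaussian_filter1d(counts, sigma_ms / bin_ms) / dt    # smoothed rate, Hz
    mean, sd = float(mu.mean()), float(mu.std())
    thresh = mean + threshold_sd * sd

    above = mu > thresh
    if not above.any():
        return []
    # candidate cores -> extend outward to the mean-crossing on both sides
    d = np.diff(above.astype(int))
    starts = list(np.nonzero(d == 1)[0] + 1)
    ends = list(np.nonzero(d == -1)[0] + 1)
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        ends = ends + [n_bins]
    below = mu <= mean
    below_cum = np.cumsum(below)
    events = []
    last_end = -1
    eid = 0
    min_cells = max(int(np.ceil(min_cells_fraction * n_ensemble)), min_cells_floor)
    for s, e in zip(starts, ends):
        # walk left/right to the nearest bin at or below the mean
        left_idx = np.nonzero(below[: s + 1])[0]
        a = int(left_idx[-1]) + 1 if left_idx.size else 0
        right_idx = np.nonzero(below[e:])[0]
        b = int(e + right_idx[0]) if right_idx.size else n_bins
        if a <= last_end:          # merged with the previous extended event
            continue
        last_end = b
        ev_start, ev_end = t0 + a * dt, t0 + b * dt
        if ev_end - ev_start < min_duration_s:
            continue
        in_ev = (t >= ev_start) & (t <= ev_end)
        mean_speed = float(speed[in_ev].mean()) if in_ev.any() else float(
            np.interp((ev_start + ev_end) / 2, t, speed))
        if mean_speed >= speed_limit_cmps:
            continue
        mid = (ev_start + ev_end) / 2.0
        stop = next((sp for sp in stops if sp.arrival <= mid < sp.departure), None)
        if stop is None:
            continue
        section = _section_label(stop, mid)
        if section is None:
            continue
        sel = (spike_times >= ev_start) & (spike_times <= ev_end)
        cells = set(spike_cells[sel].tolist())
        events.append(CandidateEvent(
            event_id=eid, start=ev_start, end=ev_end,
            participating_cells=cells,
            spike_times=spike_times[sel], spike_cells=spike_cells[sel],
            stop_id=stop.stop_id, corner_id=stop.corner_id, section=section,
            mean_speed=mean_speed,
            passes_trajectory_cell_criterion=len(cells) >= min_cells,
            current_direction=stop.current_direction, next_turn=stop.next_turn,
            animal_x_cm=float(np.interp(mid, t, x)),
        ))
        eid += 1
    return events


def temporal_windows(event_times_flags, stops: list, chance: float, *,
                     bin_s: float = 2.0, win_s: float = 5.0, step_s: float = 2.5,
                     max_s: float = 30.0, min_stop_s: float = 30.0,
                     n_boot: int = 2000, alpha: float = 0.025, rng=None):
    """Proportion-of-labeled-events time courses within corner stops.

    ``event_times_flags`` is a list of (t_event, stop_id, flag).  Only stops
    at least 30 s long contribute.  Proportions are computed in 2 s bins of
    time-from-arrival and time-to-departure; significance against ``chance``
    is assessed in 5 s windows advancing by 2.5 s with a bootstrap on the
    events in each window.  Empty bins yield NaN proportions.
    """
    rng = np.random.default_rng(rng)
    stop_by_id = {s.stop_id: s for s in stops if s.duration >= min_stop_s}
    if not stop_by_id:
        raise ValueError("no stops of at least %.0f s" % min_stop_s)
    fwd, bwd = [], []
    for t_ev, sid, flag in event_times_flags:
        sp = stop_by_id.get(sid)
        if sp is None:
            continue
        fwd.append((t_ev - sp.arrival, bool(flag)))
        bwd.append((sp.departure - t_ev, bool(flag)))

    def curves(pairs):
        offs = np.array([p[0] for p in pairs])
        flags = np.array([p[1] for p in pairs], dtype=float)
        bins = np.arange(0.0, max_s + bin_s / 2, bin_s)
        props = []
        for b0 in bins[:-1]:
            sel = (offs >= b0) & (offs < b0 + bin_s)
            props.append(float(flags[sel].mean()) if sel.any() else np.nan)
        win_starts = np.arange(0.0, max_s - win_s + step_s / 2, step_s)
        sig = []
        for w0 in win_starts:
            sel = (offs >= w0) & (offs < w0 + win_s)
            n = int(sel.sum())
            if n == 0:
                sig.append(False)
                continue
            boot = rng.choice(flags[sel], size=(n_boot, n), replace=True).mean(axis=1)
            sig.append(bool((boot <= chance).mean() < alpha))
        return {"bin_edges": bins, "proportions": np.array(props),
                "window_starts": win_starts, "significant": np.array(sig)}

    return {"from_arrival": curves(fwd), "to_departure": curves(bwd)}
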