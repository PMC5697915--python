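"""Directional linearized ratemaps, place-cell classification and the
running-decode session validity check.

Dwell time and spikes are accumulated in 2 cm bins separately per running
direction, restricted to included track zones and samples with running speed
>= 10 cm/s, smoothed with a Gaussian kernel (sigma = 5 bins) and divided.
Smoothing is mass-conserving: the kernel is truncated at +-4 sigma, never
wraps across the track ends, and each source bin's kernel is renormalized
over the unmasked bins so total spike count and total dwell are preserved
before the division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic_data import DIRECTIONS, TrackModel
from .utils import compute_speed

SPEED_RUN_CMPS = 10.0


@dataclass
class DirectionalRatemap:
    cell_id: str
    direction: str
    rates: np.ndarray          # Hz per 2 cm bin; 0 at masked bins
    mask: np.ndarray           # True where the bin is excluded / has no dwell
    peak_rate: float
    mean_rate: float           # dwell-weighted mean over unmasked bins


@dataclass
class PlaceCellLabel:
    cell_id: str
    is_place_cell: bool
    field_bins: list           # per-direction list of (start, stop) runs above mean


def _mass_conserving_smooth(values: np.ndarray, valid: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Gaussian smoothing over valid bins only, conserving total mass.

    Each source bin's kernel column is normalized over the valid bins it can
    reach, so mass never leaks into masked bins or off the track ends.
    """
    if sigma_bins <= 0:
        return values.copy()
    n = values.size
    idx = np.arange(n)
    half = int(np.ceil(4 * sigma_bins))
    offsets = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (offsets / sigma_bins) ** 2)
    w = np.zeros((n, n))
    for off, k in zip(offsets, kernel):
        src = idx[(idx + off >= 0) & (idx + off < n)]
        w[src + off, src] += k
    w[~valid, :] = 0.0
    w[:, ~valid] = 0.0
    col = w.sum(axis=0)
    col[col == 0] = 1.0
    return (w / col) @ values


def build_ratemap(positions, spike_times, track: TrackModel, direction: str,
                  cell_id: str = "", sigma_bins: float = 5.0,
                  speed_threshold: float = SPEED_RUN_CMPS) -> DirectionalRatemap:
    """Smoothed firing-rate vector of one cell for one running direction."""
    t = positions["t"].to_numpy()
    x = positions["x_cm"].to_numpy()
    dirs_ = positions["direction"].to_numpy()
    speed = positions["speed_cmps"].to_numpy() if "speed_cmps" in positions else compute_speed(t, x)

    sel = (dirs_ == direction) & (speed >= speed_threshold)
    excluded = track.excluded_mask
    bin_idx = np.clip((x / track.bin_size_cm).astype(int), 0, track.n_bins - 1)
    sel &= ~excluded[bin_idx]
    if not sel.any():
        raise ValueError("no qualifying samples")

    dt = float(np.median(np.diff(t)))
    dwell = np.bincount(bin_idx[sel], minlength=track.n_bins) * dt

    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    in_range = (spike_times >= t[0]) & (spike_times <= t[-1])
    samp = np.clip(np.searchsorted(t, spike_times[in_range]) - 1, 0, t.size - 1)
    keep = sel[samp]
    spk = np.bincount(bin_idx[samp[keep]], minlength=track.n_bins).astype(float)

    valid = ~excluded
    s_dwell = _mass_conserving_smooth(dwell.astype(float), valid, sigma_bins)
    s_spk = _mass_conserving_smooth(spk, valid, sigma_bins)

    mask = excluded | (s_dwell <= 0)
    rates = np.zeros(track.n_bins)
    ok = ~mask
    rates[ok] = s_spk[ok] / s_dwell[ok]
    peak = float(rates[ok].max()) if ok.any() else 0.0
    mean = float((rates[ok] * s_dwell[ok]).sum() / s_dwell[ok].sum()) if ok.any() else 0.0
    return DirectionalRatemap(cell_id=cell_id, direction=direction, rates=rates,
                              mask=mask, peak_rate=peak, mean_rate=mean)


def build_all_ratemaps(positions, spikes, track: TrackModel, cell_type: str = "place",
                       sigma_bins: float = 5.0) -> dict:
    """Ratemaps for every cell of a type: {direction: {cell_id: DirectionalRatemap}}."""
    out = {d: {} for d in DIRECTIONS}
    for cell_id, grp in spikes[spikes["cell_type"] == cell_type].groupby("cell_id"):
        for direction in DIRECTIONS:
            out[direction][cell_id] = build_ratemap(
                positions, grp["t"].to_numpy(), track, direction,
                cell_id=cell_id, sigma_bins=sigma_bins)
    return out


def ratemap_matrix(ratemaps: dict, direction: str, cell_ids=None):
    """Stack one direction's maps into (n_cells, n_bins); returns (ids, rates, mask)."""
    maps = ratemaps[direction]
    ids = sorted(maps) if cell_ids is None else list(cell_ids)
    rates = np.stack([maps[c].rates for c in ids])
    mask = maps[ids[0]].mask.copy()
    for c in ids[1:]:
        mask |= maps[c].mask
    return ids, rates, mask


def _runs_above_mean(rates, mask, mean):
    """Contiguous runs of unmasked bins with rate strictly above the mean;
    masked bins break contiguity."""
    above = (rates > mean) & ~mask
    runs = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(above)))
    return runs


def classify_place_cells(ratemaps: dict, min_contiguous_bins: int = 20,
                         min_peak_hz: float = 1.0) -> list:
    """A cell is a place cell if, in either direction, it fires above its mean
    rate for >= 20 contiguous bins and its peak rate exceeds 1 Hz (strict)."""
    cell_ids = sorted(ratemaps[DIRECTIONS[0]])
    labels = []
    for cid in cell_ids:
        qualifies = False
        fields = []
        for direction in DIRECTIONS:
            rm = ratemaps[direction][cid]
            runs = _runs_above_mean(rm.rates, rm.mask, rm.mean_rate)
            fields.append(runs)
            if rm.peak_rate > min_peak_hz and any(b - a >= min_contiguous_bins for a, b in runs):
                qualifies = True
        labels.append(PlaceCellLabel(cell_id=cid, is_place_cell=qualifies, field_bins=fields))
    return labels


def validate_session_decoding(positions, spikes, ratemaps, track: TrackModel,
                              window_s: float = 0.5, error_bound_cm: float = 30.0,
                              cell_type: str = "place"):
    """Median running-position decode error (cm) in 500 ms bins.

    Each running window is decoded with the direction-appropriate maps by
    maximum posterior; sessions whose median error exceeds 5% of the track
    length (30 cm) are flagged for exclusion.
    Returns (median_error_cm, excluded_flag, n_windows).
    """
    from .decoding import decode_bin

    t = positions["t"].to_numpy()
    x = positions["x_cm"].to_numpy()
    dirs_ = positions["direction"].to_numpy()
    speed = positions["speed_cmps"].to_numpy()

    spk = spikes[spikes["cell_type"] == cell_type]
    mats = {}
    for direction in DIRECTIONS:
        ids, rates, mask = ratemap_matrix(ratemaps, direction)
        mats[direction] = (ids, rates, mask)
    ids = mats[DIRECTIONS[0]][0]
    id_to_idx = {c: i for i, c in enumerate(ids)}
    spike_t = spk["t"].to_numpy()
    spike_c = np.array([id_to_idx[c] for c in spk["cell_id"]])

    edges = np.arange(t[0], t[-1], window_s)
    errors = []
    centers_cm = track.bin_centers_cm
    for w0 in edges:
        w1 = w0 + window_s
        in_win = (t >= w0) & (t < w1)
        if not in_win.any():
            continue
        run = in_win & (speed >= SPEED_RUN_CMPS)
        if run.sum() < 0.8 * in_win.sum():
            continue
        d_vals, d_counts = np.unique(dirs_[run], return_counts=True)
        direction = d_vals[np.argmax(d_counts)]
        sel = (spike_t >= w0) & (spike_t < w1)
        counts = np.bincount(spike_c[sel], minlength=len(ids))
        _, rates, mask = mats[direction]
        post = decode_bin(counts, rates, mask, window_s)
        decoded = centers_cm[np.argmax(post)]
        errors.append(abs(decoded - float(np.mean(x[run]))))
    if not errors:
        raise ValueError("no running windows to decode")
    med = float(np.median(errors))
    return med, med > error_bound_cm, len(errors)
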