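"""Bayesian position decoding from place-cell spike counts.

Memoryless Poisson likelihood with a uniform prior (Zhang et al. 1998):

    P(x | n) ~ prod_i f_i(x)^{n_i} * exp(-W * sum_i f_i(x))

evaluated in log space with a small rate floor inside the logarithms.  Three
modes are exposed: a single-window decode, the event-summed decode used for
arm-level reactivation classification (both directions normalized jointly so
the six arm sums are comparable), and the 10 ms-binned trajectory decode
whose rows are normalized to one (zero-spike rows are zeroed and carry no
probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import DIRECTIONS, INBOUND, OUTBOUND, TrackModel

RATE_FLOOR_HZ = 0.01


@dataclass
class PosteriorMatrix:
    direction: str
    t_edges: np.ndarray            # len n_t + 1, seconds (absolute)
    P: np.ndarray                  # (n_t, n_pos); non-empty rows sum to 1
    empty_bins: np.ndarray         # bool per time bin
    mask: np.ndarray = None        # position-bin exclusion mask

    @property
    def n_nonempty(self) -> int:
        return int((~self.empty_bins).sum())


@dataclass
class ArmProbabilities:
    """Posterior mass per (arm 1-3) x (outbound, inbound), jointly normalized."""
    sums: dict                     # (arm, direction) -> probability
    winner_arm: int
    winner_direction: str
    tie: bool = False
    degenerate: bool = False

    def total(self) -> float:
        return float(sum(self.sums.values()))


def _log_likelihood(counts, rates, mask, window_s, rate_floor=RATE_FLOOR_HZ):
    """Unnormalized log posterior over position bins; masked bins -> -inf."""
    counts = np.asarray(counts, dtype=float)
    f = np.maximum(rates, rate_floor)
    ll = counts @ np.log(f) - window_s * rates.sum(axis=0)
    ll = np.where(mask, -np.inf, ll)
    return ll


def decode_bin(counts, rates, mask, window_s: float, rate_floor: float = RATE_FLOOR_HZ):
    """Probability vector over position for one temporal window.

    ``rates`` is (n_cells, n_pos); ``mask`` flags excluded position bins.
    Degenerate case (every spiking cell silent everywhere on the track):
    uniform over unmasked bins.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative spike counts")
    unmasked = ~np.asarray(mask)
    spiking = counts > 0
    if spiking.any() and not rates[spiking][:, unmasked].any():
        p = np.zeros(rates.shape[1])
        p[unmasked] = 1.0 / unmasked.sum()
        return p
    ll = _log_likelihood(counts, rates, mask, window_s, rate_floor)
    ll -= ll[unmasked].max()
    p = np.exp(ll, where=np.isfinite(ll), out=np.zeros_like(ll))
    return p / p.sum()


def decode_event_summed(counts, ratemap_mats: dict, duration_s: float,
                        track: TrackModel) -> ArmProbabilities:
    """Arm-level decode of an event from its summed spike counts.

    ``ratemap_mats[direction] = (rates, mask)``.  The two per-direction
    likelihoods are normalized jointly over the concatenated 600-bin space;
    probabilities are then summed per arm.  Winning (arm, direction) ties are
    broken lexicographically (arm index, outbound first) and flagged.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("event has no spikes")
    lls, masks = {}, {}
    for d in DIRECTIONS:
        rates, mask = ratemap_mats[d]
        lls[d] = _log_likelihood(counts, rates, mask, duration_s)
        masks[d] = np.asarray(mask)
    peak = max(ll[~masks[d]].max() for d, ll in lls.items())
    degenerate = not np.isfinite(peak)
    probs = {}
    for d in DIRECTIONS:
        p = np.exp(lls[d] - peak, where=np.isfinite(lls[d]), out=np.zeros_like(lls[d]))
        probs[d] = p
    total = sum(p.sum() for p in probs.values())
    if total <= 0:
        degenerate = True
        for d in DIRECTIONS:
            um = ~masks[d]
            probs[d] = um.astype(float)
        total = sum(p.sum() for p in probs.values())
    arm_idx = track.arm_of_bins()
    sums = {}
    for d in DIRECTIONS:
        p = probs[d] / total
        for arm in (1, 2, 3):
            sums[(arm, d)] = float(p[arm_idx == arm].sum())
    order = [(arm, d) for arm in (1, 2, 3) for d in (OUTBOUND, INBOUND)]
    vals = np.array([sums[k] for k in order])
    best = int(np.argmax(vals))
    tie = bool(np.sum(vals == vals[best]) > 1)
    return ArmProbabilities(sums=sums, winner_arm=order[best][0],
                            winner_direction=order[best][1], tie=tie,
                            degenerate=degenerate)


def bin_event_spikes(spike_times, spike_cells, n_cells: int, start: float, end: float,
                     t_bin_s: float = 0.01):
    """Spike-count matrix (n_t, n_cells) over 10 ms bins spanning [start, end].

    A final partial bin (< t_bin_s) is retained.
    """
    n_t = max(1, int(np.ceil((end - start) / t_bin_s - 1e-9)))
    edges = start + t_bin_s * np.arange(n_t + 1)
    edges[-1] = end
    counts = np.zeros((n_t, n_cells))
    ti = np.clip(((np.asarray(spike_times) - start) / t_bin_s).astype(int), 0, n_t - 1)
    for b, c in zip(ti, np.asarray(spike_cells, dtype=int)):
        counts[b, c] += 1
    return counts, edges


def decode_trajectory(counts, edges, rates, mask, direction: str,
                      rate_floor: float = RATE_FLOOR_HZ) -> PosteriorMatrix:
    """Row-normalized 10 ms-binned posterior for one direction.

    ``counts`` is (n_t, n_cells).  Rows with no spikes are zeroed and flagged
    so they contribute nothing downstream.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("event has no spikes")
    n_t = counts.shape[0]
    widths = np.diff(edges)
    unmasked = ~np.asarray(mask)
    f = np.maximum(rates, rate_floor)
    ll = counts @ np.log(f) - widths[:, None] * rates.sum(axis=0)[None, :]
    ll[:, ~unmasked] = -np.inf
    empty = counts.sum(axis=1) == 0
    P = np.zeros((n_t, rates.shape[1]))
    if (~empty).any():
        sub = ll[~empty]
        sub = sub - sub.max(axis=1, keepdims=True)
        p = np.exp(sub, where=np.isfinite(sub), out=np.zeros_like(sub))
        P[~empty] = p / p.sum(axis=1, keepdims=True)
    return PosteriorMatrix(direction=direction, t_edges=np.asarray(edges), P=P,
                           empty_bins=empty, mask=np.asarray(mask))


def decode_event_trajectories(spike_times, spike_cells, ratemap_mats: dict,
                              start: float, end: float, t_bin_s: float = 0.01) -> dict:
    """Per-direction PosteriorMatrix pair for one candidate event."""
    n_cells = ratemap_mats[OUTBOUND][0].shape[0]
    counts, edges = bin_event_spikes(spike_times, spike_cells, n_cells, start, end, t_bin_s)
    out = {}
    for d in DIRECTIONS:
        rates, mask = ratemap_mats[d]
        out[d] = decode_trajectory(counts, edges, rates, mask, d)
    return out
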