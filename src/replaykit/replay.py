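"""Replay-trajectory detection by exhaustive constant-velocity line fitting.

A candidate event's 10 ms-binned posterior matrix is scored against every
line x(t) = V*t*T + c on a grid of velocities (+-2 to +-50 m/s in 0.5 m/s
steps) and intercepts (-15 to 21 m in 0.01 m steps).  The score of a line is
the posterior mass lying within 30 cm of it, divided by the total mass of the
matrix (empty time bins are zeroed and contribute nothing).  Significance is
assessed by re-decoding and re-fitting after independently rotating every
cell's ratemap along the track (spatial shuffle, 100 repeats, add-one
p-value, replay iff p < 0.025).

All grid velocities and intercepts are exact multiples of 5 mm per time step,
so band membership is decided in integer arithmetic (5 mm units): the
exhaustive search is exact, not approximate, and the reported best score is
recomputed by direct summation at the winning line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoding import PosteriorMatrix, decode_trajectory

V_MAX_MPS = 50.0
V_STEP_MPS = 0.5
V_MIN_ABS_MPS = 2.0
C_MIN_M = -15.0
C_MAX_M = 21.0
C_STEP_M = 0.01
BAND_CM = 30.0
T_BIN_S = 0.01
ALPHA = 0.025


def velocity_grid(v_max: float = V_MAX_MPS, v_step: float = V_STEP_MPS,
                  v_min_abs: float = V_MIN_ABS_MPS) -> np.ndarray:
    """Velocities -50..50 m/s in 0.5 m/s steps, excluding the open interval
    (-2, 2) (slow trajectories); +-2.0 itself is kept."""
    v = np.round(np.arange(-v_max, v_max + v_step / 2, v_step), 6)
    return v[np.abs(v) >= v_min_abs - 1e-9]


def intercept_grid(c_min: float = C_MIN_M, c_max: float = C_MAX_M,
                   c_step: float = C_STEP_M) -> np.ndarray:
    n = int(round((c_max - c_min) / c_step)) + 1
    return np.round(c_min + c_step * np.arange(n), 6)


@dataclass
class LineFit:
    v_mps: float
    c_m: float
    score: float
    direction: str
    n_nonempty: int
    tie_broken_randomly: bool = False


@dataclass
class ReplayEvent:
    event_id: int
    fit: LineFit
    p_value: float
    is_replay: bool
    order: str                     # forward | reverse
    congruent: bool
    local: bool
    prospective: bool
    start_distance_cm: float
    end_distance_cm: float
    mean_distance_cm: float
    section: str = ""
    shuffle_scores: np.ndarray = None


def _band_bounds(ks, d_units, n_pos):
    """Inclusive position-bin bounds for band membership |4j+2 - k| <= d."""
    j_lo = -((d_units + 2 - ks) // 4)
    j_hi = (ks + d_units - 2) // 4
    return j_lo, j_hi


def _score_matrix(P, nonempty, t_bin_s, bin_size_cm, band_cm, v_grid, c_grid):
    """Within-band mass (unnormalized) for every (V, c) on the grid."""
    n_t, n_pos = P.shape
    u = bin_size_cm / 4.0                                   # quantization unit (cm)
    d_units = int(round(band_cm / u))
    c_units = np.rint(np.asarray(c_grid) * 100.0 / u).astype(np.int64)
    shifts = np.rint(np.outer(v_grid, np.arange(n_t)) * (100.0 * t_bin_s / u)).astype(np.int64)
    k_lo = int(c_units.min() + shifts.min())
    k_hi = int(c_units.max() + shifts.max())
    ks = np.arange(k_lo, k_hi + 1)
    j_lo, j_hi = _band_bounds(ks, d_units, n_pos)
    lo = np.clip(j_lo, 0, n_pos)
    hi = np.maximum(np.clip(j_hi + 1, 0, n_pos), lo)

    base = c_units - k_lo
    n_c = c_units.size
    dsteps = np.diff(c_units)
    uniform = dsteps.size == 0 or np.all(dsteps == dsteps[0])
    cstride = int(dsteps[0]) if dsteps.size else 1

    score = np.zeros((v_grid.size, n_c))
    cum = np.zeros(n_pos + 1)
    for t in np.nonzero(nonempty)[0]:
        np.cumsum(P[t], out=cum[1:])
        band = cum[hi] - cum[lo]
        if uniform:
            b0 = int(base[0])
            for iv in range(v_grid.size):
                s0 = b0 + int(shifts[iv, t])
                score[iv] += band[s0: s0 + cstride * n_c: cstride]
        else:
            idx = base[None, :] + shifts[:, t][:, None]
            score += band[idx]
    return score


def _direct_score(P, v, c, t_bin_s, bin_size_cm, band_cm):
    """Score of a single line by direct mask summation (exact, oracle-grade)."""
    n_t, n_pos = P.shape
    u = bin_size_cm / 4.0
    d_units = int(round(band_cm / u))
    masses = np.empty(n_t)
    for ti in range(n_t):
        k = int(round((v * ti * t_bin_s + c) * 100.0 / u))
        j_lo, j_hi = _band_bounds(np.array([k]), d_units, n_pos)
        lo = max(0, int(j_lo[0]))
        hi = min(n_pos - 1, int(j_hi[0]))
        masses[ti] = P[ti, lo:hi + 1].sum() if hi >= lo else 0.0
    return float(np.sum(masses) / np.sum(P))


def _as_matrix(P):
    if isinstance(P, PosteriorMatrix):
        return P.P, ~P.empty_bins, P.direction
    P = np.asarray(P, dtype=float)
    return P, P.sum(axis=1) > 0, ""


def fit_line(P, *, t_bin_s: float = T_BIN_S, bin_size_cm: float = 2.0,
             band_cm: float = BAND_CM, v_grid=None, c_grid=None,
             direction: str = None) -> LineFit:
    """Exhaustive best-line search over the velocity/intercept grid.

    Ties in score are resolved to the lowest (V, c) in grid order.  Requires
    at least two non-empty time bins.
    """
    mat, nonempty, d = _as_matrix(P)
    if direction is None:
        direction = d
    if not nonempty.any():
        raise ValueError("all rows empty")
    if nonempty.sum() < 2:
        raise ValueError("need at least two non-empty time bins")
    if v_grid is None:
        v_grid = velocity_grid()
    if c_grid is None:
        c_grid = intercept_grid()
    score = _score_matrix(mat, nonempty, t_bin_s, bin_size_cm, band_cm,
                          np.asarray(v_grid, dtype=float), np.asarray(c_grid, dtype=float))
    iv, ic = np.unravel_index(int(np.argmax(score)), score.shape)
    v, c = float(v_grid[iv]), float(c_grid[ic])
    exact = _direct_score(mat, v, c, t_bin_s, bin_size_cm, band_cm)
    return LineFit(v_mps=v, c_m=c, score=exact, direction=direction,
                   n_nonempty=int(nonempty.sum()))


def _max_score(P, nonempty, t_bin_s, bin_size_cm, band_cm, v_grid, c_grid):
    score = _score_matrix(P, nonempty, t_bin_s, bin_size_cm, band_cm, v_grid, c_grid)
    return float(score.max() / np.sum(P))


def fit_event(posteriors: dict, rng=None, **fit_kwargs):
    """Fit both directions; the higher normalized score wins.

    Exact ties are broken at random (seeded) and flagged.
    Returns (chosen LineFit, {direction: LineFit}).
    """
    fits = {d: fit_line(pm, direction=d, **fit_kwargs) for d, pm in posteriors.items()}
    ds = sorted(fits)
    scores = [fits[d].score for d in ds]
    if len(ds) == 2 and scores[0] == scores[1]:
        rng = np.random.default_rng(rng)
        chosen = fits[ds[int(rng.integers(2))]]
        chosen.tie_broken_randomly = True
    else:
        chosen = fits[ds[int(np.argmax(scores))]]
    return chosen, fits


def rotate_ratemaps(rates, shifts):
    """Rotate each cell's ratemap along the track with wraparound."""
    n_cells, n_pos = rates.shape
    idx = (np.arange(n_pos)[None, :] - np.asarray(shifts)[:, None]) % n_pos
    return rates[np.arange(n_cells)[:, None], idx]


def spatial_shuffle_test(counts, edges, rates, mask, direction: str,
                         observed_score: float = None, *, n_shuffles: int = 100,
                         rng=None, t_bin_s: float = T_BIN_S, bin_size_cm: float = 2.0,
                         band_cm: float = BAND_CM, v_grid=None, c_grid=None,
                         alpha: float = ALPHA):
    """Spatial (ratemap-rotation) significance test for one event.

    Per shuffle every cell's chosen-direction ratemap is rotated by an
    independent uniform shift in [1, L-1] bins (wraparound), the event is
    re-decoded and re-fit, and the best score recorded.  Add-one estimator:
    p = (1 + #{shuffle >= observed}) / (1 + n_shuffles).
    Returns (p_value, is_replay, shuffle_scores).
    """
    rng = np.random.default_rng(rng)
    if v_grid is None:
        v_grid = velocity_grid()
    if c_grid is None:
        c_grid = intercept_grid()
    v_grid = np.asarray(v_grid, dtype=float)
    c_grid = np.asarray(c_grid, dtype=float)
    if observed_score is None:
        pm = decode_trajectory(counts, edges, rates, mask, direction)
        observed_score = fit_line(pm, t_bin_s=t_bin_s, bin_size_cm=bin_size_cm,
                                  band_cm=band_cm, v_grid=v_grid, c_grid=c_grid).score
    n_cells, n_pos = rates.shape
    scores = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shifts = rng.integers(1, n_pos, size=n_cells)
        pm = decode_trajectory(counts, edges, rotate_ratemaps(rates, shifts), mask, direction)
        scores[s] = _max_score(pm.P, ~pm.empty_bins, t_bin_s, bin_size_cm,
                               band_cm, v_grid, c_grid)
    p = (1.0 + float((scores >= observed_score).sum())) / (1.0 + n_shuffles)
    return p, p < alpha, scores


def label_replay(event_id: int, fit: LineFit, p_value: float, posterior: PosteriorMatrix,
                 animal_x_cm: float, current_direction: str, duration_s: float,
                 section: str = "", local_radius_cm: float = 60.0,
                 bin_size_cm: float = 2.0, alpha: float = ALPHA) -> ReplayEvent:
    """Attach congruent/local/order/prospective labels to a fitted event.

    Local: mean decoded position within 60 cm of the animal (inclusive).
    Order: forward iff V > 0.  Prospective: mean decoded position ahead of the
    animal along its current heading.
    """
    P = posterior.P
    total = P.sum()
    n_pos = P.shape[1]
    centers_cm = (np.arange(n_pos) + 0.5) * bin_size_cm
    mean_pos_cm = float((P.sum(axis=0) * centers_cm).sum() / total)
    congruent = fit.direction == current_direction
    local = abs(mean_pos_cm - animal_x_cm) <= local_radius_cm
    ahead = (mean_pos_cm > animal_x_cm) if current_direction == "outbound" else (mean_pos_cm < animal_x_cm)
    start_cm = fit.c_m * 100.0
    end_cm = (fit.v_mps * duration_s + fit.c_m) * 100.0
    return ReplayEvent(
        event_id=event_id, fit=fit, p_value=p_value, is_replay=p_value < alpha,
        order="forward" if fit.v_mps > 0 else "reverse",
        congruent=congruent, local=local, prospective=bool(ahead),
        start_distance_cm=abs(start_cm - animal_x_cm),
        end_distance_cm=abs(end_cm - animal_x_cm),
        mean_distance_cm=abs(mean_pos_cm - animal_x_cm),
        section=section)


def period_label_shuffle(sections, flags, n_shuffles: int = 100, rng=None) -> dict:
    """Chance proportions from random reassignment of events to engaged /
    disengaged periods (group sizes preserved).

    Returns per-section observed proportions and the mean shuffled
    proportion (the chance level).
    """
    rng = np.random.default_rng(rng)
    sections = np.asarray(sections)
    flags = np.asarray(flags, dtype=float)
    labels = np.unique(sections)
    if any((sections == lab).sum() == 0 for lab in labels) or labels.size < 2:
        raise ValueError("need events in both sections")
    observed = {lab: float(flags[sections == lab].mean()) for lab in labels}
    acc = {lab: 0.0 for lab in labels}
    for _ in range(n_shuffles):
        perm = rng.permutation(sections)
        for lab in labels:
            acc[lab] += flags[perm == lab].mean()
    chance = {lab: acc[lab] / n_shuffles for lab in labels}
    return {"observed": observed, "chance": chance}
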