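"""Arm-level reactivation classification and the resampling statistics layer.

Classification: an event is congruent if the winning decoded (arm, direction)
matches the animal's current run direction, and local if, in addition, the
winning arm is adjacent to the corner the animal occupies (the diagonal arm 2
is adjacent to both corners).  Chance levels come from a cell-identity
shuffle: spikes of the cells active in an event are reassigned to ratemaps of
cells not active in it and the event is re-decoded.

Statistics: bootstrap proportions/means (10,000 resamples with replacement,
95% CI from the 2.5/97.5 percentiles), one-sided comparison against chance
(significant when more than 97.5% of the bootstrap distribution exceeds
chance), a bootstrap interaction test on section x outcome difference
distributions, and two-sample Kolmogorov-Smirnov comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .decoding import decode_event_summed
from .synthetic_data import TrackModel

N_BOOT = 10_000
ALPHA = 0.025


@dataclass
class ReactivationLabel:
    event_id: int
    congruent: bool
    local: bool
    section: str = ""
    outcome_context: str = ""


@dataclass
class BootstrapResult:
    observed: float
    ci95: tuple
    chance: float
    p_vs_chance: float
    n_boot: int
    significant: bool


def classify_reactivation(winner_arm: int, winner_direction: str, corner_id: int,
                          run_direction: str, track: TrackModel = None,
                          event_id: int = -1, section: str = "",
                          outcome: str = "") -> ReactivationLabel:
    """Pure function of the decode winner and the behavioral context."""
    track = track or TrackModel()
    congruent = winner_direction == run_direction
    local = congruent and winner_arm in track.adjacent_arms(corner_id)
    return ReactivationLabel(event_id=event_id, congruent=congruent, local=local,
                             section=section, outcome_context=outcome)


def cellid_shuffle_chance(counts, active_cells, ratemap_mats: dict, duration_s: float,
                          corner_id: int, run_direction: str, track: TrackModel,
                          n_shuffles: int = 100, rng=None):
    """Chance congruent/local probabilities for one event via cell-ID shuffle.

    Each active cell's spikes are reassigned (without replacement) to the
    ratemap of a distinct cell *not* active in the event; the event is then
    re-decoded and re-classified.  Returns (chance_congruent, chance_local).
    """
    rng = np.random.default_rng(rng)
    counts = np.asarray(counts, dtype=float)
    active = np.asarray(sorted(active_cells), dtype=int)
    n_cells = counts.size
    inactive = np.setdiff1d(np.arange(n_cells), active)
    if inactive.size < active.size:
        raise ValueError("not enough inactive cells to reassign")
    cong = loc = 0.0
    for _ in range(n_shuffles):
        targets = rng.choice(inactive, size=active.size, replace=False)
        sh_counts = np.zeros_like(counts)
        sh_counts[targets] = counts[active]
        arm = decode_event_summed(sh_counts, ratemap_mats, duration_s, track)
        lab = classify_reactivation(arm.winner_arm, arm.winner_direction,
                                    corner_id, run_direction, track)
        cong += lab.congruent
        loc += lab.local
    return cong / n_shuffles, loc / n_shuffles


def bootstrap_proportion(labels, chance: float, n_boot: int = N_BOOT, rng=None,
                         alpha: float = ALPHA) -> BootstrapResult:
    """Bootstrap a proportion and test it against chance (one-sided)."""
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels, dtype=float)
    n = labels.size
    if n < 1:
        raise ValueError("empty sample")
    boot = labels[rng.integers(0, n, size=(n_boot, n))].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    p = float((boot <= chance).mean())
    return BootstrapResult(observed=float(labels.mean()), ci95=(float(lo), float(hi)),
                           chance=float(chance), p_vs_chance=p, n_boot=n_boot,
                           significant=p < alpha)


def bootstrap_mean(values, chance: float = np.nan, n_boot: int = N_BOOT, rng=None,
                   alpha: float = ALPHA) -> BootstrapResult:
    """Same machinery for a mean of a continuous quantity (LFP power,
    coherence scores)."""
    rng = np.random.default_rng(rng)
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 1:
        raise ValueError("empty sample")
    boot = values[rng.integers(0, n, size=(n_boot, n))].mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    p = float((boot <= chance).mean()) if np.isfinite(chance) else np.nan
    return BootstrapResult(observed=float(values.mean()), ci95=(float(lo), float(hi)),
                           chance=float(chance), p_vs_chance=p, n_boot=n_boot,
                           significant=bool(p < alpha) if np.isfinite(chance) else False)


def compare_sections(labels_a, labels_b, n_boot: int = N_BOOT, rng=None,
                     alpha: float = ALPHA):
    """One-sided bootstrap comparison of two proportions (a greater than b).

    p = fraction of paired bootstrap differences (a - b) that are <= 0;
    significant when more than 97.5% of differences exceed zero.
    """
    rng = np.random.default_rng(rng)
    a = np.asarray(labels_a, dtype=float)
    b = np.asarray(labels_b, dtype=float)
    boot_a = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    boot_b = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    diff = boot_a - boot_b
    p = float((diff <= 0).mean())
    return p, p < alpha


def interaction_test(engaged_correct, engaged_error, disengaged_correct,
                     disengaged_error, n_boot: int = N_BOOT, rng=None,
                     alpha: float = ALPHA):
    """Bootstrap interaction between task engagement and decision accuracy.

    Four independent bootstrap distributions; per section a (correct - error)
    difference distribution; one-sided p = fraction of engaged differences
    that do not exceed the disengaged differences.
    """
    rng = np.random.default_rng(rng)
    cells = [np.asarray(c, dtype=float) for c in
             (engaged_correct, engaged_error, disengaged_correct, disengaged_error)]
    if any(c.size == 0 for c in cells):
        raise ValueError("all four cells must be non-empty")
    boots = [c[rng.integers(0, c.size, size=(n_boot, c.size))].mean(axis=1) for c in cells]
    diff_eng = boots[0] - boots[1]
    diff_dis = boots[2] - boots[3]
    p = float((diff_eng <= diff_dis).mean())
    return p, p < alpha


def ks_compare(data_scores, shuffle_scores):
    """Two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(data_scores, dtype=float)
    b = np.asarray(shuffle_scores, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two samples per side")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def behavior_fluency(days, errors_per_session, lap_durations_s):
    """Task-learning indices: Pearson correlations of errors-per-session and
    mean lap duration with experimental day."""
    r_err, p_err = sps.pearsonr(days, errors_per_session)
    r_lap, p_lap = sps.pearsonr(days, lap_durations_s)
    return {"errors_vs_day": {"r": float(r_err), "p": float(p_err)},
            "lap_duration_vs_day": {"r": float(r_lap), "p": float(p_lap)}}
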