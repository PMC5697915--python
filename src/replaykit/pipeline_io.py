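"""End-to-end orchestration: simulate -> ratemaps -> events -> decode ->
replay -> stats -> lfp -> grid -> predict, with a single config object
holding every analysis constant.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify_stats, events as ev, grid_coherence as gc, lfp as lfp_mod
from . import prediction as pred, ratemaps as rm, replay as rp
from .decoding import bin_event_spikes, decode_event_summed, decode_trajectory
from .synthetic_data import (DIRECTIONS, Session, SessionSpec, TrackModel,
                             load_session, make_track, save_session,
                             simulate_session)
from .utils import write_json


@dataclass
class PipelineConfig:
    """Every analysis constant, at its standard default."""

    # ratemaps
    bin_size_cm: float = 2.0
    ratemap_sigma_bins: float = 5.0
    speed_run_cmps: float = 10.0
    # event detection
    mu_bin_ms: float = 1.0
    mu_sigma_ms: float = 5.0
    mu_threshold_sd: float = 3.0
    min_event_s: float = 0.04
    speed_stop_cmps: float = 3.0
    min_cells_fraction: float = 0.15
    min_cells_floor: int = 6
    # stop segmentation
    engaged_window_s: float = 5.0
    min_split_s: float = 10.0
    min_section_s: float = 2.0
    # decoding / line fit
    t_bin_s: float = 0.01
    band_cm: float = 30.0
    v_max_mps: float = 50.0
    v_step_mps: float = 0.5
    v_min_abs_mps: float = 2.0
    c_min_m: float = -15.0
    c_max_m: float = 21.0
    c_step_m: float = 0.01
    local_radius_cm: float = 60.0
    # shuffles & stats
    n_spatial_shuffles: int = 100
    n_cellid_shuffles: int = 100
    n_period_shuffles: int = 100
    n_pairing_shuffles: int = 100
    n_boot: int = 10_000
    alpha: float = 0.025
    # LFP
    ripple_threshold_sd: float = 2.5
    ripple_min_s: float = 0.04
    ripple_max_s: float = 0.5
    ripple_merge_gap_s: float = 0.04
    # prediction
    n_subsample_iterations: int = 10
    cv_folds: int = 10
    n_label_shuffles: int = 100
    # decode validation
    decode_window_s: float = 0.5
    decode_error_bound_cm: float = 30.0
    seed: int = 0

    def validate(self):
        for name in ("n_spatial_shuffles", "n_cellid_shuffles", "n_period_shuffles",
                     "n_pairing_shuffles", "n_boot", "n_label_shuffles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.c_step_m <= 0 or self.v_step_mps <= 0:
            raise ValueError("grid steps must be positive")

    def with_test_mode(self) -> "PipelineConfig":
        """Coarsened intercept grid (0.05 m) and reduced bootstrap count for
        fast continuous-integration runs; all scientific rules unchanged."""
        return dataclasses.replace(self, c_step_m=0.05, n_boot=2000)

    def v_grid(self):
        return rp.velocity_grid(self.v_max_mps, self.v_step_mps, self.v_min_abs_mps)

    def c_grid(self):
        return rp.intercept_grid(self.c_min_m, self.c_max_m, self.c_step_m)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


def run_pipeline(config: PipelineConfig, session: Session, out_dir=None, seed=None,
                 verbose: bool = False) -> dict:
    """Run every analysis stage on a session bundle; returns the summary dict.

    Deterministic given ``seed`` (defaults to ``config.seed``).
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    track = session.track
    report: dict = {"seed": seed}
    t_start = time.time()

    def log(stage):
        if verbose:
            print(f"[{time.time() - t_start:7.1f}s] {stage}")

    # --- ratemaps & place-cell classification -----------------------------
    log("ratemaps")
    place_maps = rm.build_all_ratemaps(session.positions, session.spikes, track,
                                       cell_type="place", sigma_bins=config.ratemap_sigma_bins)
    labels = rm.classify_place_cells(place_maps)
    place_ids = [l.cell_id for l in labels if l.is_place_cell]
    if not place_ids:
        raise RuntimeError("ratemaps stage: no place cells classified")
    mats = {}
    for d in DIRECTIONS:
        ids, rates, mask = rm.ratemap_matrix(place_maps, d, cell_ids=place_ids)
        mats[d] = (rates, mask)
    id_to_idx = {c: i for i, c in enumerate(place_ids)}

    median_err, excluded, n_win = rm.validate_session_decoding(
        session.positions, session.spikes[session.spikes["cell_id"].isin(place_ids)],
        place_maps, track, window_s=config.decode_window_s,
        error_bound_cm=config.decode_error_bound_cm)
    report["n_place_cells"] = len(place_ids)
    report["median_decode_error_cm"] = median_err
    report["session_excluded"] = bool(excluded)

    # --- stops & candidate events -----------------------------------------
    log("events")
    stops = ev.build_stop_periods(session.stops, config.engaged_window_s,
                                  config.min_split_s, config.min_section_s)
    place_spk = session.spikes[session.spikes["cell_id"].isin(place_ids)]
    spike_t = place_spk["t"].to_numpy()
    spike_c = np.array([id_to_idx[c] for c in place_spk["cell_id"]])
    cands = ev.detect_events(spike_t, spike_c, len(place_ids), session.positions, stops,
                             bin_ms=config.mu_bin_ms, sigma_ms=config.mu_sigma_ms,
                             threshold_sd=config.mu_threshold_sd,
                             min_duration_s=config.min_event_s,
                             speed_limit_cmps=config.speed_stop_cmps,
                             min_cells_fraction=config.min_cells_fraction,
                             min_cells_floor=config.min_cells_floor)
    report["n_candidate_events"] = len(cands)

    # --- LFP ---------------------------------------------------------------
    log("lfp")
    fs = 1.0 / float(np.median(np.diff(session.lfp["t"].iloc[:100])))
    lfp_vals = session.lfp["value"].to_numpy()
    ripple_bp = lfp_mod.band_power(lfp_vals, fs, lfp_mod.RIPPLE_BAND, "ripple")
    ripples = lfp_mod.detect_ripples(ripple_bp.power, fs,
                                     threshold_sd=config.ripple_threshold_sd,
                                     min_duration_s=config.ripple_min_s,
                                     max_duration_s=config.ripple_max_s,
                                     merge_gap_s=config.ripple_merge_gap_s,
                                     t0=float(session.lfp["t"].iloc[0]))
    report["n_ripples"] = len(ripples)
    td_ratio = lfp_mod.theta_delta_ratio(lfp_vals, fs)

    # --- arm-level reactivation classification ----------------------------
    log("classification")
    rows, cellid_cong, cellid_loc = [], [], []
    arm_probs_by_event = {}
    for c in cands:
        counts = np.bincount(c.spike_cells, minlength=len(place_ids)).astype(float)
        arm = decode_event_summed(counts, mats, c.duration, track)
        arm_probs_by_event[c.event_id] = arm
        lab = classify_stats.classify_reactivation(
            arm.winner_arm, arm.winner_direction, c.corner_id, c.current_direction,
            track, event_id=c.event_id, section=c.section, outcome=c.next_turn)
        try:
            ch_c, ch_l = classify_stats.cellid_shuffle_chance(
                counts, c.participating_cells, mats, c.duration, c.corner_id,
                c.current_direction, track, n_shuffles=config.n_cellid_shuffles,
                rng=rng)
            cellid_cong.append(ch_c)
            cellid_loc.append(ch_l)
        except ValueError:
            pass
        cong_m, loc_m = pred.measures_from_arm_probs(arm, c.corner_id,
                                                     c.current_direction, track)
        rip_pw = lfp_mod.event_mean(ripple_bp.power, fs, c.start, c.end,
                                    t0=float(session.lfp["t"].iloc[0]))
        td = lfp_mod.event_mean(td_ratio, fs, c.start, c.end,
                                t0=float(session.lfp["t"].iloc[0]))
        rows.append({"event_id": c.event_id, "section": c.section,
                     "outcome": c.next_turn, "congruent": lab.congruent,
                     "local": lab.local, "congruence": cong_m, "locality": loc_m,
                     "ripple_power": rip_pw, "theta_delta": td,
                     "stop_id": c.stop_id, "corner_id": c.corner_id,
                     "n_cells": len(c.participating_cells),
                     "passes_cell_criterion": c.passes_trajectory_cell_criterion,
                     "start": c.start, "end": c.end})
    table = pd.DataFrame(rows)
    chance_cong = float(np.mean(cellid_cong)) if cellid_cong else 0.5
    chance_loc = float(np.mean(cellid_loc)) if cellid_loc else 0.5
    report["cellid_chance"] = {"congruent": chance_cong, "local": chance_loc}

    def section_stats(col, chance):
        out = {}
        for sec in ("engaged", "disengaged"):
            sel = table[table["section"] == sec]
            if len(sel) == 0:
                continue
            res = classify_stats.bootstrap_proportion(
                sel[col].to_numpy(), chance, n_boot=config.n_boot, rng=rng)
            out[sec] = {"observed": res.observed, "ci95": list(res.ci95),
                        "p_vs_chance": res.p_vs_chance, "n": int(len(sel))}
        return out

    if len(table):
        report["reactivation"] = {
            "congruent": section_stats("congruent", chance_cong),
            "local": section_stats("local", chance_loc),
        }

    # temporal dynamics of congruent content within long stops
    if len(table):
        evf = [((r["start"] + r["end"]) / 2, r["stop_id"], r["congruent"])
               for r in rows]
        try:
            tw = ev.temporal_windows(evf, stops, chance=chance_cong,
                                     n_boot=min(config.n_boot, 2000),
                                     rng=rng)
            report["temporal_dynamics"] = {
                side: {"proportions": [None if np.isnan(x) else x
                                       for x in tw[side]["proportions"]],
                       "significant": tw[side]["significant"].tolist()}
                for side in ("from_arrival", "to_departure")}
        except ValueError:
            report["temporal_dynamics"] = {}

    # --- replay trajectory analysis ----------------------------------------
    log("replay")
    v_grid, c_grid = config.v_grid(), config.c_grid()
    replay_rows, replay_events = [], []
    fits_by_event = {}
    for c in cands:
        if not c.passes_trajectory_cell_criterion:
            continue
        counts, edges = bin_event_spikes(c.spike_times, c.spike_cells,
                                         len(place_ids), c.start, c.end, config.t_bin_s)
        posts = {d: decode_trajectory(counts, edges, mats[d][0], mats[d][1], d)
                 for d in DIRECTIONS}
        if posts[DIRECTIONS[0]].n_nonempty < 2:
            continue
        fit, _ = rp.fit_event(posts, rng=rng, t_bin_s=config.t_bin_s,
                              bin_size_cm=config.bin_size_cm, band_cm=config.band_cm,
                              v_grid=v_grid, c_grid=c_grid)
        p, is_rep, _ = rp.spatial_shuffle_test(
            counts, edges, mats[fit.direction][0], mats[fit.direction][1],
            fit.direction, observed_score=fit.score,
            n_shuffles=config.n_spatial_shuffles, rng=rng, t_bin_s=config.t_bin_s,
            bin_size_cm=config.bin_size_cm, band_cm=config.band_cm,
            v_grid=v_grid, c_grid=c_grid, alpha=config.alpha)
        rev = rp.label_replay(c.event_id, fit, p, posts[fit.direction], c.animal_x_cm,
                              c.current_direction, c.duration, section=c.section,
                              local_radius_cm=config.local_radius_cm,
                              bin_size_cm=config.bin_size_cm, alpha=config.alpha)
        fits_by_event[c.event_id] = (fit, posts, c)
        replay_events.append(rev)
        replay_rows.append({"event_id": c.event_id, "V_mps": fit.v_mps,
                            "c_m": fit.c_m, "score": fit.score, "p": p,
                            "is_replay": rev.is_replay, "order": rev.order,
                            "congruent": rev.congruent, "local": rev.local,
                            "prospective": rev.prospective, "section": c.section,
                            "start_distance_cm": rev.start_distance_cm,
                            "end_distance_cm": rev.end_distance_cm})
    replay_table = pd.DataFrame(replay_rows)
    report["n_trajectory_candidates"] = int(len(replay_table))
    report["n_replay_events"] = int(replay_table["is_replay"].sum()) if len(replay_table) else 0
    sig = replay_table[replay_table["is_replay"]] if len(replay_table) else replay_table
    if len(sig) >= 2 and sig["section"].nunique() == 2:
        shuf = rp.period_label_shuffle(sig["section"].to_numpy(),
                                       sig["congruent"].to_numpy(),
                                       n_shuffles=config.n_period_shuffles, rng=rng)
        report["replay_congruent"] = shuf

    # --- grid coherence -----------------------------------------------------
    log("grid")
    grid_spk = session.spikes[session.spikes["cell_type"] == "grid"]
    grid_summary = {}
    if len(grid_spk) and len(sig):
        grid_maps = rm.build_all_ratemaps(session.positions, session.spikes, track,
                                          cell_type="grid",
                                          sigma_bins=config.ratemap_sigma_bins)
        gs_t = grid_spk["t"].to_numpy()
        gid_list = sorted(grid_spk["cell_id"].unique())
        gid_to_idx = {g: i for i, g in enumerate(gid_list)}
        gs_c = np.array([gid_to_idx[g] for g in grid_spk["cell_id"]])
        field_size = session.truth.get("grid_field_size_cm") if session.truth else None
        scores = []
        for eid in sig["event_id"]:
            fit, posts, c = fits_by_event[eid]
            in_ev = (gs_t >= c.start) & (gs_t <= c.end)
            if not in_ev.any():
                continue
            gids, grates, gmask = rm.ratemap_matrix(grid_maps, fit.direction,
                                                    cell_ids=gid_list)
            if field_size is None:
                field_size = gc.estimate_grid_field_size(grates, gmask,
                                                         config.bin_size_cm)
            gp = gc.grid_event_posterior(gs_t[in_ev], gs_c[in_ev], grates, gmask,
                                         c.start, c.end, fit.direction, config.t_bin_s)
            others = [fits_by_event[e][0] for e in fits_by_event if e != eid]
            if not others:
                continue
            cs = gc.pairing_shuffle(eid, gp, fit, others, field_size,
                                    n_shuffles=config.n_pairing_shuffles, rng=rng)
            scores.append({"event_id": int(eid), "score": cs.score,
                           "significant": bool(cs.significant),
                           "chance": float(cs.shuffle_scores.mean()),
                           "section": str(sig[sig["event_id"] == eid]["section"].iloc[0])})
        if scores:
            gdf = pd.DataFrame(scores)
            grid_summary = {
                "mean_score": float(gdf["score"].mean()),
                "mean_chance": float(gdf["chance"].mean()),
                "fraction_significant": float(gdf["significant"].mean()),
                "by_section": {s: float(g["score"].mean())
                               for s, g in gdf.groupby("section")},
                "n": int(len(gdf)),
            }
    report["grid_coherence"] = grid_summary

    # --- prediction ----------------------------------------------------------
    log("prediction")
    report["prediction"] = {}
    eng = table[table["section"] == "engaged"].dropna(subset=["ripple_power"]) \
        if len(table) else table
    if len(eng) and (eng["outcome"] == "error").sum() >= 2 \
            and (eng["outcome"] == "correct").sum() >= 2:
        res = pred.train_predict(eng, seed=int(rng.integers(2**31 - 1)),
                                 n_iterations=config.n_subsample_iterations,
                                 cv_folds=config.cv_folds,
                                 n_shuffles_per_iteration=config.n_label_shuffles)
        report["prediction"] = {"accuracy": res.accuracy, "p": res.p_value,
                                "mean_shuffle_accuracy": float(res.shuffle_accuracies.mean()),
                                "n_per_class": res.n_events_per_class}

    # --- outputs -------------------------------------------------------------
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rm_rows = []
        for d in DIRECTIONS:
            rates, mask = mats[d]
            for i, cid in enumerate(place_ids):
                for b in range(rates.shape[1]):
                    rm_rows.append((cid, d, b, rates[i, b], bool(mask[b])))
        pd.DataFrame(rm_rows, columns=["cell_id", "direction", "bin", "rate",
                                       "masked"]).to_csv(out / "ratemaps.csv",
                                                         index=False)
        if len(table):
            table.to_csv(out / "events.csv", index=False)
            table[["event_id", "section", "outcome", "congruent",
                   "local"]].to_csv(out / "labels.csv", index=False)
        if len(replay_table):
            replay_table.to_csv(out / "replay.csv", index=False)
        pd.DataFrame([{"start": r.start, "end": r.end, "peak_power": r.peak_power}
                      for r in ripples]).to_csv(out / "lfp_events.csv", index=False)
        if grid_summary:
            pd.DataFrame(scores).to_csv(out / "grid_coherence.csv", index=False)
        write_json(out / "stats_summary.json",
                   {"reactivation": report.get("reactivation", {}),
                    "cellid_chance": report["cellid_chance"]})
        write_json(out / "prediction_report.json", report.get("prediction", {}))
        _write_posteriors(out / "posteriors.h5", fits_by_event)
        write_json(out / "summary.json", report)
    log("done")
    return report


def _write_posteriors(path, fits_by_event):
    try:
        import h5py
    except ImportError:                      # pragma: no cover
        return
    with h5py.File(path, "w") as f:
        for eid, (fit, posts, _) in fits_by_event.items():
            grp = f.create_group(str(eid))
            for d, pm in posts.items():
                grp.create_dataset(d, data=pm.P, compression="gzip")
            grp.attrs["V_mps"] = fit.v_mps
            grp.attrs["c_m"] = fit.c_m
            grp.attrs["direction"] = fit.direction


def simulate_to_dir(spec: SessionSpec, out_dir) -> Session:
    session = simulate_session(spec)
    save_session(session, out_dir)
    return session
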