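"""End-to-end pipeline: raw session streams -> classified theta cycles,
decoding quality, and incidence/phase/clustering statistics.

Stage order mirrors the analysis protocol: reference templates from the
first halves of the two baseline (PRE) sessions -> exclusion of remapped
cells -> theta segmentation and population vectors -> specificity-based
classification -> position/context decoding -> temporal, spatial and
phase statistics.  PRE sessions are analysed on their second halves (the
baseline periods); teleportation sessions provide the context-switch
experience and are not classified.  Everything is deterministic given the
configuration (which carries the seed) and is stamped with the config
hash.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .arena import Arena
from .classify import (
    Eligibility,
    classify_pvs,
    compute_pesi,
    eligible_bins,
    incidence_per_1000tc,
    session_thirds,
)
from .config import AnalysisConfig
from .decode import bayes_decode, correlation_decode, field_metrics
from .preprocess import (
    PositionTrack,
    TemplateSet,
    _occupancy,
    build_ratemap,
    build_templates,
    detect_remapped_cells,
    smooth_ratemap,
)
from .stats import (
    cycle_autocorrelogram,
    downsample_events,
    interevent_interval_test,
    phase_shift_summary,
    spatial_clustering_controlmatch,
    spatial_clustering_trackshift,
    velocity_by_pattern,
)
from .theta import bandpass_theta, build_population_vectors, segment_cycles

__all__ = ["SessionResult", "ResultsReport", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class SessionResult:
    """Per-session pipeline outputs."""

    name: str
    phase: str
    env: str
    labels: pd.DataFrame
    incidence: pd.DataFrame
    thirds: pd.DataFrame
    decode: pd.DataFrame
    spike_phases: pd.DataFrame
    eligibility: Eligibility
    coverage: np.ndarray
    temporal_stats: dict = field(default_factory=dict)
    window: Tuple[float, float] = (0.0, 0.0)


@dataclass
class ResultsReport:
    """All tables of one pipeline run, stamped with the config hash."""

    config: AnalysisConfig
    templates: TemplateSet
    excluded_cells: Dict[object, str]
    sessions: Dict[str, SessionResult]
    phase_comparisons: pd.DataFrame
    velocity: pd.DataFrame
    clustering: pd.DataFrame

    def incidence_table(self) -> pd.DataFrame:
        rows = []
        for name, s in self.sessions.items():
            t = s.incidence.copy()
            t.insert(0, "session", name)
            t.insert(1, "phase", s.phase)
            t.insert(2, "environment", s.env)
            rows.append(t)
        return pd.concat(rows, ignore_index=True)

    def thirds_table(self) -> pd.DataFrame:
        rows = []
        for name, s in self.sessions.items():
            t = s.thirds.copy()
            t.insert(0, "session", name)
            t.insert(1, "phase", s.phase)
            rows.append(t)
        return pd.concat(rows, ignore_index=True)

    def write(self, out_dir) -> Path:
        """Dump the tidy tables as CSVs, each headed by the config hash."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = f"# config_hash={self.config.hash}\n"

        def dump(df: pd.DataFrame, name: str) -> None:
            with open(out / name, "w") as fh:
                fh.write(stamp)
                df.to_csv(fh, index=False)

        dump(self.incidence_table(), "incidence.csv")
        dump(self.thirds_table(), "thirds.csv")
        dump(self.phase_comparisons, "phase_comparisons.csv")
        dump(self.velocity, "velocity.csv")
        dump(self.clustering, "clustering.csv")
        for name, s in self.sessions.items():
            dump(s.labels, f"labels_{name}.csv")
            dump(s.decode, f"decode_{name}.csv")
        (out / "config.yaml").write_text(stamp + self.config.to_yaml())
        return out


def _session_maps(
    track: PositionTrack, spikes: Mapping, cell_ids, arena: Arena, cfg: AnalysisConfig
) -> Tuple[np.ndarray, np.ndarray]:
    maps = np.empty((len(cell_ids), arena.n_bins, arena.n_bins))
    occ = None
    for i, cid in enumerate(cell_ids):
        occ, rate = build_ratemap(
            track, spikes.get(cid, np.empty(0)), arena, cfg.speed_min_cms, cfg.occupancy_floor_s
        )
        maps[i] = smooth_ratemap(rate)
    return maps, occ


def _analyse_session(
    name: str,
    sess,
    window: Tuple[float, float],
    templates: TemplateSet,
    pesi: np.ndarray,
    arena: Arena,
    cfg: AnalysisConfig,
) -> SessionResult:
    env = sess.manifest["environment"]
    phase = sess.manifest["phase"]
    t0, t1 = window
    cell_ids = templates.cell_ids

    filtered = bandpass_theta(sess.lfp, cfg.theta_low_hz, cfg.theta_high_hz)
    pooled = np.concatenate(
        [sess.spikes[c][(sess.spikes[c] >= t0) & (sess.spikes[c] <= t1)] for c in cell_ids]
    ) if cell_ids else np.empty(0)
    cycles = segment_cycles(
        filtered,
        sess.lfp.fs,
        sess.lfp.t0,
        pooled,
        cfg.n_phase_bins,
        cfg.cycle_min_s,
        cfg.cycle_max_s,
    )
    in_win = (cycles.start >= t0) & (cycles.end <= t1)
    cycles.start, cycles.end = cycles.start[in_win], cycles.end[in_win]

    spikes_win = {
        c: sess.spikes[c][(sess.spikes[c] >= t0) & (sess.spikes[c] <= t1)] for c in cell_ids
    }
    pvs = build_population_vectors(cycles, spikes_win, sess.track, arena, cfg.speed_min_cms)

    win_track = sess.track.slice(t0, t1 + 1e-9)
    coverage = _occupancy(win_track, arena, cfg.speed_min_cms) >= cfg.occupancy_floor_s
    elig = eligible_bins(pesi, coverage, cfg.min_specific_cells)

    labels = classify_pvs(
        pvs, pesi, elig, env, cfg.min_specific_cells, cfg.mpv_min_per_side
    )
    incidence = incidence_per_1000tc(labels, cfg.incidence_mode)
    thirds = session_thirds(labels, cfg.thirds_mode)

    # --- decoding: correlation error (ICPV -> current map, OCPV -> alternative)
    alt = "B" if env == "A" else "A"
    dec = pd.DataFrame(index=labels.index)
    dec["label"] = labels["label"]
    dec["error_cm"] = np.nan
    for lab, map_env in (("ICPV", env), ("OCPV", alt)):
        m = (labels["label"] == lab).to_numpy()
        if m.any():
            d = correlation_decode(
                pvs.counts[m], templates, map_env, arena, pvs.x[m], pvs.y[m], cfg.min_specific_cells
            )
            dec.loc[m, "error_cm"] = d["error_cm"].to_numpy()
            dec.loc[m, "decoded_bin"] = d["decoded_bin"].to_numpy()
            fm = field_metrics(
                pvs.counts[m], templates, map_env, pesi,
                1.0 if map_env == "A" else -1.0,
                pvs.bin_flat[m], pvs.x[m], pvs.y[m], arena, cfg.periphery_frac,
            )
            for col in fm.columns:
                dec.loc[m, col] = fm[col].to_numpy()
    usable = (labels["included"] & labels["eligible_bin"]).to_numpy()
    if usable.any():
        bd = bayes_decode(
            pvs.counts[usable], templates, pvs.duration[usable],
            cfg.bayes_rate_floor_hz, cfg.bayes_threshold,
        )
        dec.loc[usable, "p_a"] = bd["p_a"].to_numpy()
        dec.loc[usable, "p_b"] = bd["p_b"].to_numpy()
        dec.loc[usable, "detected_context"] = bd["detected_context"].to_numpy()

    # --- spike-level phases for classified cycles
    sp_rows = []
    s_sign = 1.0 if env == "A" else -1.0
    n_side = arena.n_bins
    lab_arr = labels["label"].to_numpy()
    for j, cid in enumerate(cell_ids):
        st = spikes_win[cid]
        if st.size == 0:
            continue
        cyc = cycles.cycle_of(st)
        ok = cyc >= 0
        st, cyc = st[ok], cyc[ok]
        ph = 360.0 * (st - cycles.start[cyc]) / (cycles.end[cyc] - cycles.start[cyc])
        iy, ix = np.divmod(pvs.bin_flat[cyc], n_side)
        pv_pesi = pesi[j, iy, ix]
        side = np.where(
            np.abs(pv_pesi - s_sign) < 1e-12, "in",
            np.where(np.abs(pv_pesi + s_sign) < 1e-12, "out", "nonspecific"),
        )
        lab = lab_arr[cyc]
        group = np.full(st.size, "", dtype=object)
        group[(lab == "ICPV") & (side == "in")] = "ICPV"
        group[(lab == "OCPV") & (side == "out")] = "OCPV"
        group[(lab == "MPV") & (side == "in")] = "MPV-in"
        group[(lab == "MPV") & (side == "out")] = "MPV-out"
        keep = group != ""
        if keep.any():
            sp_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cid,
                        "t": st[keep],
                        "cycle_index": cyc[keep],
                        "phase_deg": ph[keep],
                        "group": group[keep],
                    }
                )
            )
    spike_phases = (
        pd.concat(sp_rows, ignore_index=True)
        if sp_rows
        else pd.DataFrame(columns=["cell_id", "t", "cycle_index", "phase_deg", "group"])
    )

    # --- temporal statistics of OCPV expression
    temporal: dict = {}
    ev_t = labels.loc[labels["label"] == "OCPV", "t_start"].to_numpy()
    if ev_t.size >= 2:
        temporal["interevent"] = interevent_interval_test(
            ev_t, (t0, t1), cfg.n_interval_sim, seed=cfg.seed
        )
    events_mask = labels["label"].isin(["OCPV", "MPV"]).to_numpy()
    shuffle_ok = (
        usable & ((labels["n_in_specific"] + labels["n_out_specific"]) >= cfg.min_specific_cells).to_numpy()
    )
    ac = cycle_autocorrelogram(
        events_mask.astype(int),
        shuffle_ok | events_mask,
        cfg.autocorr_max_lag,
        cfg.n_shuffle,
        seed=cfg.seed,
    )
    temporal["autocorr"] = ac

    return SessionResult(
        name=name,
        phase=phase,
        env=env,
        labels=labels,
        incidence=incidence,
        thirds=thirds,
        decode=dec,
        spike_phases=spike_phases,
        eligibility=elig,
        coverage=coverage,
        temporal_stats=temporal,
        window=window,
    )


def run_pipeline(
    sessions: Mapping[str, object],
    config: Optional[AnalysisConfig] = None,
    arena: Optional[Arena] = None,
) -> ResultsReport:
    """Run the full analysis over one experiment's sessions.

    ``sessions`` maps name -> session-like object with attributes
    ``track`` (PositionTrack), ``spikes`` ({cell_id: times}), ``lfp``
    (LFPSignal) and ``manifest`` (with ``phase`` and ``environment``), e.g.
    simulated sessions or loaded bundles.  Two PRE sessions (phases
    starting with ``PRE``, different environments) are required for
    template construction; sessions with phases starting with ``POST`` are
    analysed in full, PRE sessions on their second halves, anything else
    (teleportation / control interludes) is skipped.
    """
    cfg = config or AnalysisConfig()
    arena = arena or Arena(cfg.arena_side_cm, cfg.bin_cm)

    pre = {
        s.manifest["environment"]: s
        for s in sessions.values()
        if str(s.manifest["phase"]).upper().startswith("PRE")
    }
    if len(pre) < 2:
        raise ValueError("pipeline needs PRE sessions in both environments for templates")

    templates, baseline = build_templates(
        {env: (s.track, s.spikes) for env, s in pre.items()},
        arena,
        cfg.speed_min_cms,
        cfg.occupancy_floor_s,
        cfg.coverage_min,
    )

    post_maps: Dict[str, np.ndarray] = {}
    for name, s in sessions.items():
        if str(s.manifest["phase"]).upper().startswith("POST"):
            env = s.manifest["environment"]
            post_maps[env] = _session_maps(s.track, s.spikes, templates.cell_ids, arena, cfg)
    excluded = (
        detect_remapped_cells(templates, post_maps, cfg.remap_r_threshold) if post_maps else {}
    )
    retained = [c for c in templates.cell_ids if c not in excluded]
    if len(retained) < 4:
        raise ValueError("too few cells retained after remapping exclusion")
    templates = templates.subset(retained)
    pesi = compute_pesi(templates)

    results: Dict[str, SessionResult] = {}
    for name, s in sessions.items():
        ph = str(s.manifest["phase"]).upper()
        if ph.startswith("PRE"):
            t0 = float(s.track.t[0])
            t1 = float(s.track.t[-1])
            window = (t0 + (t1 - t0) / 2.0, t1)
        elif ph.startswith("POST"):
            window = (float(s.track.t[0]), float(s.track.t[-1]))
        else:
            log.info("session %s (phase %s) not classified", name, ph)
            continue
        try:
            results[name] = _analyse_session(name, s, window, templates, pesi, arena, cfg)
        except Exception:
            log.exception("session %s failed; continuing with the rest", name)
            continue

    # --- pooled phase statistics
    pooled = [
        r.spike_phases.assign(session=n, phase=r.phase) for n, r in results.items()
    ]
    pooled_df = pd.concat(pooled, ignore_index=True) if pooled else pd.DataFrame(
        columns=["phase_deg", "group"]
    )
    try:
        phase_cmp = phase_shift_summary(pooled_df)
    except Exception:
        phase_cmp = pd.DataFrame()

    vel_rows = []
    for n, r in results.items():
        v = velocity_by_pattern(r.labels)
        v.insert(0, "session", n)
        vel_rows.append(v)
    velocity = pd.concat(vel_rows, ignore_index=True) if vel_rows else pd.DataFrame()

    # --- spatial clustering (both randomisations; called only if both agree)
    clust_rows = []
    for n, r in results.items():
        sess = sessions[n]
        ev_t = r.labels.loc[r.labels["label"] == "OCPV", "t_start"].to_numpy()
        kept = downsample_events(ev_t, sess.track, cfg.downsample_min_s, cfg.downsample_min_cm)
        ts = spatial_clustering_trackshift(
            kept, sess.track, arena, r.eligibility.eligible, cfg.n_shuffle, seed=cfg.seed
        )
        row = {
            "session": n,
            "n_events": ts.n_events,
            "p_trackshift": ts.p,
            "trackshift_skipped": ts.skipped or "",
        }
        # control = the analysed session of the alternative environment in
        # the same protocol phase family (PRE vs POST)
        fam = "PRE" if r.phase.upper().startswith("PRE") else "POST"
        ctrl = next(
            (
                rc
                for nc, rc in results.items()
                if nc != n and rc.env != r.env and rc.phase.upper().startswith(fam)
            ),
            None,
        )
        if ctrl is not None and kept.size >= 5:
            ex, ey = sess.track.interp(kept)
            ctrl_sess = sessions[ctrl.name]
            ctrl_ic = ctrl.labels[ctrl.labels["label"] == "ICPV"]
            m = sess.track.speed > cfg.speed_min_cms
            cm = spatial_clustering_controlmatch(
                np.column_stack([ex, ey]),
                np.column_stack([sess.track.x[m], sess.track.y[m]]),
                ctrl_ic[["x", "y"]].to_numpy(),
                arena,
                n=cfg.n_shuffle,
                seed=cfg.seed,
            )
            row["p_controlmatch"] = cm.p
            row["controlmatch_skipped"] = cm.skipped or ""
        else:
            row["p_controlmatch"] = np.nan
            row["controlmatch_skipped"] = "no control session or too few events"
        both = (
            np.isfinite(row["p_trackshift"])
            and np.isfinite(row["p_controlmatch"])
            and row["p_trackshift"] < 0.05
            and row["p_controlmatch"] < 0.05
        )
        row["clustered"] = bool(both)
        clust_rows.append(row)
    clustering = pd.DataFrame(clust_rows)

    return ResultsReport(
        config=cfg,
        templates=templates,
        excluded_cells=excluded,
        sessions=results,
        phase_comparisons=phase_cmp,
        velocity=velocity,
        clustering=clustering,
    )
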