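#!/usr/bin/env python
"""Diagnostic figures for the simulated study day.

Template ratemap pairs for a few example cells, the classification raster
of the first post-teleportation session, and the spike-phase histograms
per pattern class.  PNGs land in scratch/figures/.
"""
from pathlib import Path

import pandas as pd

from thetaflicker import AnalysisConfig, run_pipeline
from thetaflicker.arena import Arena
from thetaflicker.plotting import (
    plot_classification_raster,
    plot_phase_histograms,
    plot_ratemap_pair,
)
from thetaflicker.session_io import read_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    arena = Arena()
    sess_dir = ROOT / "scratch" / "sessions"
    if not sess_dir.exists():
        raise SystemExit("run analysis/01_simulate_experiment.py first")
    sessions = {p.name: read_session(p, arena) for p in sorted(sess_dir.iterdir())}
    report = run_pipeline(sessions, AnalysisConfig(seed=1), arena)

    out = ROOT / "scratch" / "figures"
    out.mkdir(parents=True, exist_ok=True)
    for cid in report.templates.cell_ids[:4]:
        fig = plot_ratemap_pair(report.templates, cid)
        fig.savefig(out / f"ratemaps_cell{cid}.png", dpi=120)
    fig = plot_classification_raster(report.sessions["POST1"].labels)
    fig.savefig(out / "raster_POST1.png", dpi=120)
    pooled = pd.concat(
        [report.sessions[n].spike_phases for n in ("POST1", "POST2")], ignore_index=True
    )
    fig = plot_phase_histograms(pooled)
    fig.savefig(out / "phase_histograms.png", dpi=120)
    print(f"wrote {len(list(out.glob('*.png')))} figures to {out}")


if __name__ == "__main__":
    main()
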