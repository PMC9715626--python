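"""Plain-text session formats and validated loading.

A session on disk is a directory with:

* ``tracking.csv`` -- columns ``t,x,y`` (seconds, cm; 40 ms sampling);
* ``spikes.csv``   -- columns ``cell_id,t``;
* ``lfp.bin`` + ``lfp.json`` -- float32 sample stream with a JSON sidecar
  (``fs``, ``t0``, ``n``), or alternatively ``lfp.csv`` with a single
  ``sample`` column and the same sidecar;
* ``manifest.json`` -- session/phase/environment identity and the
  environment schedule (switch times);
* optionally ``ground_truth.csv`` for simulated sessions
  (``cycle_index,t_start,t_end,true_map,injected,kind``).

Times are written to 0.1 ms and positions to 0.01 cm; a write -> read
round trip is lossless at that declared precision.  Loading validates
monotonic timestamps, in-arena positions and in-span spike times (spikes
outside the tracked span are dropped with a logged count).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .arena import Arena
from .preprocess import PositionTrack
from .theta import LFPSignal

__all__ = ["SessionBundle", "write_session", "read_session"]

log = logging.getLogger(__name__)


@dataclass
class SessionBundle:
    """Validated in-memory session streams."""

    manifest: dict
    track: PositionTrack
    spikes: Dict[int, np.ndarray]
    lfp: LFPSignal
    ground_truth: Optional[pd.DataFrame] = None
    n_dropped_spikes: int = 0

    @property
    def env(self) -> str:
        return self.manifest["environment"]

    @property
    def phase(self) -> str:
        return self.manifest["phase"]


def write_session(
    path,
    track: PositionTrack,
    spikes: Dict[int, np.ndarray],
    lfp: LFPSignal,
    manifest: dict,
    ground_truth: Optional[pd.DataFrame] = None,
    lfp_format: str = "bin",
) -> Path:
    """Write one session directory in the plain-text exchange format."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t": track.t, "x": track.x, "y": track.y}).to_csv(
        path / "tracking.csv", index=False, float_format="%.4f"
    )
    rows = [
        pd.DataFrame({"cell_id": cid, "t": np.asarray(st, dtype=float)})
        for cid, st in sorted(spikes.items())
    ]
    sp = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=["cell_id", "t"])
    sp.to_csv(path / "spikes.csv", index=False, float_format="%.4f")
    sidecar = {"fs": lfp.fs, "t0": lfp.t0, "n": int(lfp.samples.size), "format": lfp_format}
    if lfp_format == "bin":
        lfp.samples.astype(np.float32).tofile(path / "lfp.bin")
    elif lfp_format == "csv":
        pd.DataFrame({"sample": lfp.samples}).to_csv(path / "lfp.csv", index=False, float_format="%.6f")
    else:
        raise ValueError("lfp_format must be 'bin' or 'csv'")
    (path / "lfp.json").write_text(json.dumps(sidecar, indent=1))
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if ground_truth is not None:
        ground_truth.to_csv(path / "ground_truth.csv", index=False, float_format="%.4f")
    return path


def read_session(path, arena: Optional[Arena] = None, position_slack_cm: float = 1.0) -> SessionBundle:
    """Load and validate a session directory.

    Raises descriptive errors on missing files, non-monotonic timestamps or
    out-of-arena positions; spikes outside the tracked time span are
    dropped and counted.
    """
    path = Path(path)
    for fname in ("tracking.csv", "spikes.csv", "manifest.json", "lfp.json"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"session file missing: {path / fname}")
    manifest = json.loads((path / "manifest.json").read_text())

    tr = pd.read_csv(path / "tracking.csv")
    for col in ("t", "x", "y"):
        if col not in tr.columns:
            raise ValueError(f"tracking.csv lacks required column {col!r}")
    t = tr["t"].to_numpy(float)
    if np.any(~np.isfinite(t)) or np.any(np.diff(t) <= 0):
        raise ValueError("tracking timestamps must be finite and strictly increasing")
    if arena is not None:
        inside = arena.contains(tr["x"].to_numpy(float), tr["y"].to_numpy(float))
        bad = np.sum(
            (tr["x"] < -position_slack_cm)
            | (tr["x"] > arena.side_cm + position_slack_cm)
            | (tr["y"] < -position_slack_cm)
            | (tr["y"] > arena.side_cm + position_slack_cm)
        )
        if bad:
            raise ValueError(f"{bad} tracking samples outside the arena (+{position_slack_cm} cm slack)")
    track = PositionTrack(
        t, np.clip(tr["x"].to_numpy(float), 0, None), np.clip(tr["y"].to_numpy(float), 0, None)
    )

    sp = pd.read_csv(path / "spikes.csv")
    if not {"cell_id", "t"} <= set(sp.columns):
        raise ValueError("spikes.csv must have columns cell_id,t")
    span = (t[0], t[-1])
    in_span = (sp["t"] >= span[0]) & (sp["t"] <= span[1])
    n_dropped = int((~in_span).sum())
    if n_dropped:
        log.info("dropped %d spikes outside the tracked span %s", n_dropped, span)
    sp = sp[in_span]
    spikes = {
        int(cid): np.sort(sub["t"].to_numpy(float)) for cid, sub in sp.groupby("cell_id")
    }
    # silent sorted units carry no spike rows; restore them from the manifest
    for cid in manifest.get("cell_ids", []):
        spikes.setdefault(int(cid), np.empty(0))

    sidecar = json.loads((path / "lfp.json").read_text())
    if sidecar.get("format", "bin") == "bin":
        samples = np.fromfile(path / "lfp.bin", dtype=np.float32).astype(float)
    else:
        samples = pd.read_csv(path / "lfp.csv")["sample"].to_numpy(float)
    if sidecar.get("n") is not None and samples.size != sidecar["n"]:
        raise ValueError("LFP sample count does not match its sidecar")
    lfp = LFPSignal(samples, fs=float(sidecar["fs"]), t0=float(sidecar.get("t0", 0.0)))

    gt = None
    if (path / "ground_truth.csv").exists():
        gt = pd.read_csv(path / "ground_truth.csv")
    return SessionBundle(
        manifest=manifest,
        track=track,
        spikes=spikes,
        lfp=lfp,
        ground_truth=gt,
        n_dropped_spikes=n_dropped,
    )
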