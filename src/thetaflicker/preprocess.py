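"""Occupancy maps, place-cell ratemaps and reference (template) maps.

A cell's spatial tuning is estimated as spikes per second of dwell per
position bin, restricted to locomotion periods (speed above 2 cm/s), and
smoothed with a fixed 5x5 Gaussian boxcar kernel.  Reference "template"
maps for the two environments are built from the first halves of the two
baseline (PRE) sessions; the second halves are reserved for baseline
measurements.  Cells whose tuning changes between PRE and POST sessions
(field shift, expansion, or a new field) are excluded from the analysis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .arena import Arena

__all__ = [
    "SMOOTHING_KERNEL",
    "PositionTrack",
    "TemplateSet",
    "CoverageError",
    "compute_velocity",
    "build_ratemap",
    "smooth_ratemap",
    "build_templates",
    "detect_remapped_cells",
]

#: 5x5 Gaussian boxcar smoothing kernel (weights sum to 1, 4-fold symmetric).
SMOOTHING_KERNEL = np.array(
    [
        [0.0025, 0.0125, 0.0200, 0.0125, 0.0025],
        [0.0125, 0.0625, 0.1000, 0.0625, 0.0125],
        [0.0200, 0.1000, 0.1600, 0.1000, 0.0200],
        [0.0125, 0.0625, 0.1000, 0.0625, 0.0125],
        [0.0025, 0.0125, 0.0200, 0.0125, 0.0025],
    ]
)


class CoverageError(ValueError):
    """Raised when a template period leaves too much of the arena unvisited."""


def compute_velocity(t, x, y, smooth_window_ms: float = 200.0) -> np.ndarray:
    """Movement speed (cm/s) per tracking sample.

    Positions are boxcar-smoothed over ``smooth_window_ms`` to suppress
    tracking jitter before differentiating.  Returns an array the same
    length as the track.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 tracking samples to estimate speed")
    dt = np.median(np.diff(t))
    w = max(1, int(round(smooth_window_ms / 1000.0 / dt)))
    if w > 1:
        kernel = np.ones(w) / w
        # reflect-pad so the ends are not deflated by the boxcar
        xs = np.convolve(np.pad(x, w, mode="edge"), kernel, mode="same")[w:-w]
        ys = np.convolve(np.pad(y, w, mode="edge"), kernel, mode="same")[w:-w]
    else:
        xs, ys = x, y
    return np.hypot(np.gradient(xs, t), np.gradient(ys, t))


@dataclass
class PositionTrack:
    """Position tracking stream: timestamps (s), coordinates (cm), speed (cm/s)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.size == self.x.size == self.y.size):
            raise ValueError("t, x, y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.speed is None:
            self.speed = compute_velocity(self.t, self.x, self.y)
        else:
            self.speed = np.asarray(self.speed, dtype=float)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def interp(self, times) -> Tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated position at arbitrary times."""
        times = np.asarray(times, dtype=float)
        return np.interp(times, self.t, self.x), np.interp(times, self.t, self.y)

    def interp_speed(self, times) -> np.ndarray:
        return np.interp(np.asarray(times, dtype=float), self.t, self.speed)

    def slice(self, t0: float, t1: float) -> "PositionTrack":
        m = (self.t >= t0) & (self.t < t1)
        return PositionTrack(self.t[m], self.x[m], self.y[m], self.speed[m])


def _occupancy(track: PositionTrack, arena: Arena, speed_min: float) -> np.ndarray:
    """Dwell time (s) per bin from speed-filtered tracking samples."""
    n = arena.n_bins
    dt = np.diff(track.t, append=track.t[-1] + np.median(np.diff(track.t)))
    m = track.speed > speed_min
    ix, iy = arena.bin_index(track.x[m], track.y[m])
    occ = np.zeros((n, n))
    np.add.at(occ, (iy, ix), dt[m])
    return occ


def build_ratemap(
    track: PositionTrack,
    spike_times,
    arena: Arena,
    speed_min: float = 2.0,
    occupancy_floor: float = 0.2,
) -> Tuple[np.ndarray, np.ndarray]:
    """Occupancy map and unsmoothed ratemap for one cell.

    Rate per bin is the spike count divided by the dwell time there, both
    restricted to periods of movement above ``speed_min`` (cm/s).  Bins with
    dwell below ``occupancy_floor`` (s) are treated as unvisited (NaN rate).

    Returns ``(occupancy, rate)``, two ``(n, n)`` arrays indexed ``[iy, ix]``.
    """
    if track.t.size == 0:
        raise ValueError("empty position track")
    n = arena.n_bins
    occ = _occupancy(track, arena, speed_min)
    spike_times = np.asarray(spike_times, dtype=float)
    in_span = (spike_times >= track.t[0]) & (spike_times <= track.t[-1])
    st = spike_times[in_span]
    st = st[track.interp_speed(st) > speed_min]
    sx, sy = track.interp(st)
    ix, iy = arena.bin_index(sx, sy)
    counts = np.zeros((n, n))
    np.add.at(counts, (iy, ix), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = counts / occ
    rate[occ < occupancy_floor] = np.nan
    return occ, rate


def smooth_ratemap(rate: np.ndarray, kernel: np.ndarray = SMOOTHING_KERNEL) -> np.ndarray:
    """NaN-aware smoothing with a normalised kernel.

    The kernel weights over defined (non-NaN, in-grid) neighbours are
    rescaled to sum to one, so edge bins and bins adjacent to unvisited
    regions are not deflated.  Output is NaN exactly where the input is NaN.
    """
    kernel = np.asarray(kernel, dtype=float)
    if not np.isclose(kernel.sum(), 1.0, atol=1e-12):
        raise ValueError("smoothing kernel weights must sum to 1")
    rate = np.asarray(rate, dtype=float)
    valid = np.isfinite(rate)
    filled = np.where(valid, rate, 0.0)
    num = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    return out


@dataclass
class TemplateSet:
    """Per-cell, per-environment smoothed reference ratemaps.

    ``rates[env]`` has shape ``(n_cells, n, n)``; ``visited[env]`` marks the
    bins with sufficient dwell during the template period.
    """

    cell_ids: List
    rates: Dict[str, np.ndarray]
    visited: Dict[str, np.ndarray]
    provenance: Dict[str, Tuple[float, float]] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def envs(self) -> Tuple[str, ...]:
        return tuple(sorted(self.rates))

    def subset(self, cell_ids: Sequence) -> "TemplateSet":
        idx = [self.cell_ids.index(c) for c in cell_ids]
        return TemplateSet(
            cell_ids=list(cell_ids),
            rates={e: r[idx] for e, r in self.rates.items()},
            visited=dict(self.visited),
            provenance=dict(self.provenance),
        )


def build_templates(
    pre_sessions: Mapping[str, Tuple[PositionTrack, Mapping[object, np.ndarray]]],
    arena: Arena,
    speed_min: float = 2.0,
    occupancy_floor: float = 0.2,
    coverage_min: float = 0.9,
    kernel: np.ndarray = SMOOTHING_KERNEL,
):
    """Build template maps from the first halves of the two PRE sessions.

    Parameters
    ----------
    pre_sessions : mapping
        ``{env: (track, {cell_id: spike_times})}`` with one entry per
        environment.  Cell id sets must agree across environments.
    coverage_min : float
        Minimum fraction of bins that must be visited (any dwell) during
        each template half; only sparse unvisited bins are tolerated.

    Returns
    -------
    (TemplateSet, baseline)
        ``baseline`` maps env to ``(track_2nd_half, spikes_2nd_half)`` for
        baseline measurements.
    """
    if len(pre_sessions) < 2:
        raise ValueError("need PRE sessions for both environments")
    envs = sorted(pre_sessions)
    cell_ids = sorted(pre_sessions[envs[0]][1])
    for env in envs[1:]:
        if sorted(pre_sessions[env][1]) != cell_ids:
            raise ValueError("cell ids differ across PRE sessions")

    rates: Dict[str, np.ndarray] = {}
    visited: Dict[str, np.ndarray] = {}
    baseline = {}
    provenance = {}
    for env in envs:
        track, spikes = pre_sessions[env]
        t0, t1 = track.t[0], track.t[-1]
        half = t0 + (t1 - t0) / 2.0
        tr1 = track.slice(t0, half)
        # coverage counts any visit, irrespective of running speed
        frac = float(np.mean(_occupancy(tr1, arena, -np.inf) > 0))
        occ = _occupancy(tr1, arena, speed_min)
        if frac < coverage_min:
            raise CoverageError(
                f"insufficient arena coverage in PRE session {env!r}: "
                f"{frac:.0%} of bins visited (< {coverage_min:.0%})"
            )
        maps = np.empty((len(cell_ids), arena.n_bins, arena.n_bins))
        for i, cid in enumerate(cell_ids):
            st = np.asarray(spikes[cid], dtype=float)
            st = st[(st >= t0) & (st < half)]
            _, rate = build_ratemap(tr1, st, arena, speed_min, occupancy_floor)
            maps[i] = smooth_ratemap(rate, kernel)
        rates[env] = maps
        visited[env] = occ >= occupancy_floor
        provenance[env] = (float(t0), float(half))
        tr2 = track.slice(half, t1 + 1e-9)
        sp2 = {
            cid: np.asarray(spikes[cid], dtype=float)[
                (np.asarray(spikes[cid], dtype=float) >= half)
                & (np.asarray(spikes[cid], dtype=float) <= t1)
            ]
            for cid in cell_ids
        }
        baseline[env] = (tr2, sp2)
    return TemplateSet(cell_ids, rates, visited, provenance), baseline


def _spatial_corr(a: np.ndarray, b: np.ndarray) -> float:
    m = np.isfinite(a) & np.isfinite(b)
    if m.sum() < 10:
        return np.nan
    av, bv = a[m], b[m]
    if av.std() == 0 or bv.std() == 0:
        return np.nan
    return float(np.corrcoef(av, bv)[0, 1])


def detect_remapped_cells(
    templates: TemplateSet,
    post_maps: Mapping[str, Tuple[np.ndarray, np.ndarray]],
    r_threshold: float = 0.5,
    quiet_frac: float = 0.1,
    new_field_mass_frac: float = 0.3,
    min_mean_rate_hz: float = 0.2,
    min_peak_hz: float = 1.0,
) -> Dict[object, str]:
    """Cells whose spatial tuning changed between PRE and POST.

    An environment is *judgeable* for a cell when its occupancy-weighted
    mean POST rate there reaches ``min_mean_rate_hz`` -- a handful of
    spikes (e.g. sparse out-context events) cannot establish a tuning
    change.  In a judgeable environment a cell is excluded if (a) the
    spatial correlation between template and POST ratemap falls below
    ``r_threshold`` (field shift / expansion), or (b) more than
    ``new_field_mass_frac`` of its POST rate mass lies in bins where the
    template was quiet (below ``quiet_frac`` of the template peak) -- a
    new field.  Cells with essentially no POST firing anywhere are
    excluded with reason ``"no POST activity"``.  Pure rate scaling (same
    field shape) is retained, since correlation is scale invariant.

    ``post_maps[env]`` is ``(smoothed_maps, occupancy)`` with maps of
    shape ``(n_cells, n, n)``, cell order matching ``templates.cell_ids``.

    Returns ``{cell_id: reason}`` for the excluded cells.
    """
    excluded: Dict[object, str] = {}
    envs = [e for e in templates.envs if e in post_maps]
    for i, cid in enumerate(templates.cell_ids):
        mean_rates = {}
        for env in envs:
            post, occ = post_maps[env]
            m = np.isfinite(post[i]) & (occ > 0)
            tot = occ[m].sum()
            mean_rates[env] = float((post[i][m] * occ[m]).sum() / tot) if tot > 0 else 0.0
        # silence counts against the cell only where its template predicted
        # activity (a B-tuned cell is rightly silent in an A-only POST set)
        expected = [
            e
            for e in envs
            if np.isfinite(templates.rates[e][i]).any()
            and np.nanmax(templates.rates[e][i]) >= min_peak_hz
        ]
        if expected and all(mean_rates[e] < 0.02 for e in expected):
            excluded[cid] = "no POST activity"
            continue
        for env in envs:
            if mean_rates[env] < min_mean_rate_hz:
                continue  # too little POST activity in this env to judge
            tmpl = templates.rates[env][i]
            post = post_maps[env][0][i]
            t_peak = np.nanmax(tmpl) if np.isfinite(tmpl).any() else 0.0
            if not np.isfinite(t_peak):
                t_peak = 0.0
            if t_peak >= min_peak_hz:
                r = _spatial_corr(tmpl, post)
                if np.isfinite(r) and r < r_threshold:
                    excluded[cid] = f"tuning shift in {env} (r={r:.2f})"
                    break
            # only bins estimated in BOTH maps can witness a new field
            judge = np.isfinite(tmpl) & np.isfinite(post)
            quiet = judge & (np.nan_to_num(tmpl) < quiet_frac * t_peak) if t_peak > 0 else judge
            mass = float(np.nan_to_num(post)[judge].sum())
            if mass > 0:
                frac = float(np.nan_to_num(post)[quiet].sum() / mass)
                if frac > new_field_mass_frac:
                    excluded[cid] = f"new field in {env} ({frac:.0%} of rate mass)"
                    break
    return excluded
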