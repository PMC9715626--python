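"""Bespoke statistics of out-context / mixed pattern expression.

Temporal structure: the mean interval between consecutive out-context
events is compared to 5000 samples of equally many uniformly placed
events; short-timescale clustering uses binary theta-bin arrays, their
dot-product autocorrelation ``C(lag)``, a shuffle null that relocates the
events within the detection-eligible theta bins, the z-score
``z = (C - mean(|Cshuffle|)) / std(|Cshuffle|)`` and the one-sided
empirical ``p = (n + 1) / (n_shuffle + 1)`` at lag 1.

Spatial structure: the mean nearest-neighbour distance among event
locations is compared against two complementary randomisations -- random
relocation along the session's own track restricted to eligible moments,
and occupancy-matched draws from a control session -- after down-sampling
events to at least 5 s and 20 cm of trajectory apart.  Clustering is
called only when both methods agree.

Theta-phase structure: circular means per pattern class and pairwise
Watson-Williams tests (circular one-way ANOVA) with Bonferroni correction.

Empirical p-values use the +1 convention throughout.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .arena import Arena
from .preprocess import PositionTrack

__all__ = [
    "circ_mean_deg",
    "circ_r",
    "rayleigh_test",
    "watson_williams",
    "bonferroni",
    "interevent_interval_test",
    "cycle_autocorrelogram",
    "AutocorrResult",
    "downsample_events",
    "spatial_clustering_trackshift",
    "spatial_clustering_controlmatch",
    "ClusteringResult",
    "phase_shift_summary",
    "velocity_by_pattern",
]


# ---------------------------------------------------------------- circular


def circ_mean_deg(phases_deg) -> float:
    """Circular mean direction in degrees, in [0, 360)."""
    ph = np.radians(np.asarray(phases_deg, dtype=float))
    m = float(np.degrees(np.angle(np.mean(np.exp(1j * ph))))) % 360.0
    return m if m < 360.0 else 0.0


def circ_r(phases_deg) -> float:
    """Mean resultant length in [0, 1]."""
    ph = np.radians(np.asarray(phases_deg, dtype=float))
    return float(np.abs(np.mean(np.exp(1j * ph))))


def rayleigh_test(phases_deg) -> Tuple[float, float]:
    """Rayleigh test of circular uniformity: returns (z, p)."""
    n = np.asarray(phases_deg).size
    r = circ_r(phases_deg)
    z = n * r * r
    p = np.exp(-z) * (1 + (2 * z - z * z) / (4 * n) - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n * n))
    return float(z), float(min(max(p, 0.0), 1.0))


def _kappa_from_r(r: float) -> float:
    """Maximum-likelihood-style von Mises concentration (Fisher approximation)."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def watson_williams(*groups, min_n: int = 10, warn_concentration: float = 0.45):
    """Watson-Williams test for equality of circular means (degrees).

    The circular analogue of one-way ANOVA: with group resultant lengths
    ``R_j`` and pooled resultant ``R``, the statistic is

        F = K * (N - k) * (sum R_j - R) / ((k - 1) * (N - sum R_j))

    with the concentration correction ``K = 1 + 3 / (8 kappa)``, ``kappa``
    estimated from the within-group mean resultant length, and
    ``p = sf(F; k-1, N-k)``.  The test assumes reasonably concentrated
    samples; a warning is issued when the within-group mean resultant
    length drops below ``warn_concentration``.

    Returns ``(F, p)``.
    """
    groups = [np.radians(np.asarray(g, dtype=float)) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.size for g in groups])
    if np.any(ns < min_n):
        raise ValueError(f"each group needs at least {min_n} observations")
    N = int(ns.sum())
    Rj = np.array([np.abs(np.sum(np.exp(1j * g))) for g in groups])
    R = np.abs(np.sum(np.concatenate([np.exp(1j * g) for g in groups])))
    rw = float(Rj.sum() / N)
    if rw < warn_concentration:
        warnings.warn(
            f"Watson-Williams assumption: within-group resultant length {rw:.2f} is low; "
            "the F approximation may be inaccurate"
        )
    kappa = _kappa_from_r(rw)
    K = 1 + 3 / (8 * kappa) if kappa > 0 else 1.0
    num = (N - k) * (Rj.sum() - R)
    den = (k - 1) * (N - Rj.sum())
    if den <= 0:
        return np.inf, 0.0
    F = max(K * num / den, 0.0)
    p = float(sps.f.sf(F, k - 1, N - k))
    return float(F), p


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value, capped at 1."""
    return float(min(1.0, p * m))


# ---------------------------------------------------------------- temporal


def interevent_interval_test(
    event_times,
    session_span: Tuple[float, float],
    n_sim: int = 5000,
    seed: int = 0,
):
    """Mean inter-event interval vs uniformly placed events.

    The observed mean gap between consecutive events is ranked within
    ``n_sim`` null means obtained by placing the same number of events
    uniformly over the session span.  Returns a dict with the observed
    mean, the null mean, a two-sided empirical p (with the +1 convention)
    and the normal-approximation z of the observed value within the null.
    """
    t = np.sort(np.asarray(event_times, dtype=float))
    if t.size < 2:
        raise ValueError("need at least 2 events")
    obs = float(np.diff(t).mean())
    rng = np.random.default_rng(seed)
    k = t.size
    sims = rng.uniform(session_span[0], session_span[1], size=(n_sim, k))
    sims.sort(axis=1)
    null = np.diff(sims, axis=1).mean(axis=1)
    n_lo = int(np.sum(null <= obs))
    n_hi = int(np.sum(null >= obs))
    p = min(1.0, 2.0 * (min(n_lo, n_hi) + 1) / (n_sim + 1))
    sd = float(null.std())
    z = (obs - float(null.mean())) / sd if sd > 0 else np.nan
    return {
        "observed_mean_s": obs,
        "null_mean_s": float(null.mean()),
        "p": p,
        "z": z,
        "n_events": k,
        "n_sim": n_sim,
    }


@dataclass
class AutocorrResult:
    """Binary theta-bin autocorrelation with its shuffle null."""

    lags: np.ndarray
    C: np.ndarray
    z: np.ndarray
    shuffle_mean: np.ndarray
    shuffle_std: np.ndarray
    p_lag1: float
    n_events: int
    n_shuffle: int
    skipped: Optional[str] = None


def cycle_autocorrelogram(
    events: np.ndarray,
    eligible: np.ndarray,
    max_lag: int = 20,
    n_shuffle: int = 1000,
    seed: int = 0,
    min_events: int = 12,
) -> AutocorrResult:
    """Dot-product autocorrelation of a binary theta-bin array vs shuffles.

    ``events`` is the 0/1 array over the session's theta bins; ``eligible``
    marks the bins where an event could have been detected (sufficient
    population activity at a covered position).  The shuffle relocates the
    events uniformly within the eligible bins, preserving their number.
    ``z(lag) = (C - mean(|Cshuffle|)) / std(|Cshuffle|)`` and the one-sided
    lag-1 p-value is ``(n + 1)/(n_shuffle + 1)`` with ``n`` the number of
    shuffles reaching the observed lag-1 value.

    Sessions with fewer than ``min_events`` events are skipped (the result
    carries the reason).
    """
    events = np.asarray(events).astype(int)
    eligible = np.asarray(eligible, dtype=bool)
    if events.size != eligible.size:
        raise ValueError("events and eligibility arrays must have equal length")
    if np.any(events[~eligible] == 1):
        raise ValueError("events occur outside eligible bins")
    k = int(events.sum())
    lags = np.arange(max_lag + 1)
    if k < min_events:
        nanarr = np.full(max_lag + 1, np.nan)
        return AutocorrResult(
            lags, nanarr, nanarr, nanarr, nanarr, np.nan, k, n_shuffle,
            skipped=f"only {k} events (< {min_events})",
        )

    def autocorr(a: np.ndarray) -> np.ndarray:
        return np.array([a.dot(a) if l == 0 else a[:-l].dot(a[l:]) for l in lags])

    C = autocorr(events).astype(float)
    rng = np.random.default_rng(seed)
    elig_idx = np.nonzero(eligible)[0]
    Cs = np.empty((n_shuffle, max_lag + 1))
    for s in range(n_shuffle):
        a = np.zeros_like(events)
        a[rng.choice(elig_idx, size=k, replace=False)] = 1
        Cs[s] = autocorr(a)
    absCs = np.abs(Cs)
    mu, sd = absCs.mean(axis=0), absCs.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (C - mu) / sd
    z[sd == 0] = np.nan
    n_ge = int(np.sum(Cs[:, 1] >= C[1]))
    p1 = (n_ge + 1) / (n_shuffle + 1)
    return AutocorrResult(lags, C, z, mu, sd, p1, k, n_shuffle)


# ----------------------------------------------------------------- spatial


def _path_length_at(track: PositionTrack, times: np.ndarray) -> np.ndarray:
    """Cumulative trajectory length (cm) interpolated at the given times."""
    step = np.hypot(np.diff(track.x), np.diff(track.y))
    cum = np.concatenate([[0.0], np.cumsum(step)])
    return np.interp(times, track.t, cum)


def downsample_events(event_times, track: PositionTrack, min_dt: float = 5.0, min_path: float = 20.0) -> np.ndarray:
    """Greedy earliest-first thinning enforcing temporal AND path-length gaps.

    An event is kept only if at least ``min_dt`` seconds *and* ``min_path``
    cm of trajectory have elapsed since the last kept event, so co-located
    events reflect a genuine return to the place.
    """
    t = np.sort(np.asarray(event_times, dtype=float))
    s = _path_length_at(track, t)
    keep = []
    last_t = last_s = -np.inf
    for ti, si in zip(t, s):
        if (ti - last_t) >= min_dt and (si - last_s) >= min_path:
            keep.append(ti)
            last_t, last_s = ti, si
    return np.asarray(keep)


def _mean_nn_distance(xy: np.ndarray) -> float:
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


@dataclass
class ClusteringResult:
    """Nearest-neighbour spatial clustering statistic vs a randomised null."""

    observed: float
    null: np.ndarray
    p: float
    method: str
    n_events: int
    skipped: Optional[str] = None
    log: List[str] = field(default_factory=list)


def spatial_clustering_trackshift(
    event_times,
    track: PositionTrack,
    arena: Arena,
    eligible_map: np.ndarray,
    n: int = 1000,
    seed: int = 0,
    min_events: int = 5,
    speed_min: float = 2.0,
) -> ClusteringResult:
    """Track-shift randomisation of event locations.

    The observed statistic is the mean nearest-neighbour distance among the
    (down-sampled) event positions.  Null draws relocate the events to
    random moments of the same track, restricted to samples at eligible
    bins with the animal moving, preserving the session's own occupancy.
    One-sided empirical ``p = (n_below + 1)/(n + 1)`` (small distances =
    clustering).
    """
    t = np.asarray(event_times, dtype=float)
    if t.size < min_events:
        return ClusteringResult(
            np.nan, np.empty(0), np.nan, "trackshift", t.size,
            skipped=f"only {t.size} events (< {min_events})",
        )
    ex, ey = track.interp(t)
    obs = _mean_nn_distance(np.column_stack([ex, ey]))
    bins = arena.flat_index(track.x, track.y)
    pool = np.nonzero(eligible_map.ravel()[bins] & (track.speed > speed_min))[0]
    if pool.size < t.size:
        return ClusteringResult(
            obs, np.empty(0), np.nan, "trackshift", t.size, skipped="too few eligible track samples"
        )
    rng = np.random.default_rng(seed)
    null = np.empty(n)
    for i in range(n):
        pick = rng.choice(pool, size=t.size, replace=False)
        null[i] = _mean_nn_distance(np.column_stack([track.x[pick], track.y[pick]]))
    p = (int(np.sum(null <= obs)) + 1) / (n + 1)
    return ClusteringResult(obs, null, p, "trackshift", t.size)


def spatial_clustering_controlmatch(
    event_xy: np.ndarray,
    session_occupancy_xy: np.ndarray,
    control_pool_xy: np.ndarray,
    arena: Arena,
    coarse_bins: int = 5,
    n: int = 1000,
    seed: int = 0,
    min_events: int = 5,
) -> ClusteringResult:
    """Control-session randomisation with coarse occupancy equalisation.

    Occupancy of the examined and control sessions is compared on a
    ``coarse_bins x coarse_bins`` grid (12 cm blocks on a 60 cm arena) and
    the control pool of same-map population-vector positions is re-weighted
    so that draws reproduce the examined session's occupancy profile.
    Null draws take as many control positions as there are events.  Blocks
    the control never visited are excluded and logged.
    """
    event_xy = np.asarray(event_xy, dtype=float)
    if event_xy.shape[0] < min_events:
        return ClusteringResult(
            np.nan, np.empty(0), np.nan, "controlmatch", event_xy.shape[0],
            skipped=f"only {event_xy.shape[0]} events (< {min_events})",
        )
    block = arena.side_cm / coarse_bins

    def block_of(xy):
        b = np.clip((xy / block).astype(int), 0, coarse_bins - 1)
        return b[:, 1] * coarse_bins + b[:, 0]

    occ_s = np.bincount(block_of(np.asarray(session_occupancy_xy)), minlength=coarse_bins**2)
    ctrl_blocks = block_of(np.asarray(control_pool_xy))
    occ_c = np.bincount(ctrl_blocks, minlength=coarse_bins**2)
    log = []
    target = np.minimum(occ_s, occ_c).astype(float)
    dropped = np.nonzero((occ_s > 0) & (occ_c == 0))[0]
    if dropped.size:
        log.append(f"blocks without control occupancy excluded: {dropped.tolist()}")
    with np.errstate(invalid="ignore", divide="ignore"):
        w_block = np.where(occ_c > 0, target / occ_c, 0.0)
    w = w_block[ctrl_blocks]
    if w.sum() <= 0 or np.count_nonzero(w) < event_xy.shape[0]:
        return ClusteringResult(
            _mean_nn_distance(event_xy), np.empty(0), np.nan, "controlmatch",
            event_xy.shape[0], skipped="control pool too small after equalisation", log=log,
        )
    w = w / w.sum()
    obs = _mean_nn_distance(event_xy)
    rng = np.random.default_rng(seed)
    null = np.empty(n)
    ctrl = np.asarray(control_pool_xy, dtype=float)
    for i in range(n):
        pick = rng.choice(ctrl.shape[0], size=event_xy.shape[0], replace=False, p=w)
        null[i] = _mean_nn_distance(ctrl[pick])
    p = (int(np.sum(null <= obs)) + 1) / (n + 1)
    return ClusteringResult(obs, null, p, "controlmatch", event_xy.shape[0], log=log)


# ------------------------------------------------------------------- phase


def phase_shift_summary(spike_table: pd.DataFrame, min_n: int = 10) -> pd.DataFrame:
    """Circular means per pattern class and pairwise Watson-Williams tests.

    ``spike_table`` needs columns ``phase_deg`` and ``group`` with groups
    among {'ICPV', 'OCPV', 'MPV-in', 'MPV-out'} (spikes of mixed cycles are
    split into their in-context and out-context components).  Pairwise
    p-values are Bonferroni-corrected for the number of comparisons.
    Returns a tidy frame of the comparisons; per-group circular means are
    attached as a ``.attrs['group_means']`` dict.
    """
    groups = {
        g: sub["phase_deg"].to_numpy()
        for g, sub in spike_table.groupby("group")
        if len(sub) >= min_n
    }
    means = {g: circ_mean_deg(v) for g, v in groups.items()}
    names = sorted(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rows = []
    for a, b in pairs:
        F, p = watson_williams(groups[a], groups[b], min_n=min_n)
        rows.append(
            {
                "group_1": a,
                "group_2": b,
                "mean_1_deg": means[a],
                "mean_2_deg": means[b],
                "shift_deg": (means[b] - means[a]) % 360.0,
                "F": F,
                "p": p,
                "p_bonferroni": bonferroni(p, len(pairs)),
                "n_1": groups[a].size,
                "n_2": groups[b].size,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["group_means"] = means
    return out


def velocity_by_pattern(labels: pd.DataFrame) -> pd.DataFrame:
    """Mean linked movement speed per pattern class (excluded cycles never count)."""
    usable = labels[labels["included"] & labels["eligible_bin"]]
    out = (
        usable.groupby("label")["speed"]
        .agg(["mean", "std", "count"])
        .reindex(["ICPV", "OCPV", "MPV", "unclassified"])
        .rename(columns={"mean": "speed_mean", "std": "speed_std", "count": "n"})
        .reset_index()
    )
    return out
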