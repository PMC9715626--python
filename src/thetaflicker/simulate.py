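"""Synthetic dual-context place-cell sessions with ground-truth flickers.

The generator emulates the experimental recordings the pipeline analyses:
a rat exploring one of two visually defined 60 x 60 cm environments (A and
B) whose hippocampal CA3 population holds near-orthogonal place maps, a
theta-band LFP at 2 kHz, and per-cell spike trains.  Place cells fire as
spatially inhomogeneous Poisson processes whose rate is the product of the
cell's tuning in the *currently expressed* map and a theta modulation
``1 + d cos(phase - preferred)``.  Sessions follow the baseline ->
teleportation -> test protocol (PRE1, PRE2, TELEPORT, POST1, POST2), with
the expressed map switching at teleportation cue switches.

Out-of-context events ("flickers") are injected at a controllable rate per
1000 theta cycles: in an injected cycle the population transiently
expresses the *alternative* map (pure out-context cycle) or both maps with
the out-context component placed later in the cycle (mixed cycle).  Every
theta cycle carries a ground-truth label of the expressed map, so detector
sensitivity and incidence recovery can be measured exactly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .arena import Arena
from .preprocess import PositionTrack
from .theta import LFPSignal

__all__ = [
    "GaussField",
    "CellSpec",
    "SessionSpec",
    "SimSession",
    "make_cell_library",
    "true_ratemap",
    "true_specificity",
    "true_eligibility",
    "simulate_trajectory",
    "simulate_lfp",
    "simulate_session",
    "inject_flicker_cycles",
    "default_protocol",
    "simulate_experiment",
]

TRACK_DT = 0.04  # tracking sample period (s): one position fix every 40 ms
LFP_FS = 2000.0  # LFP sampling rate (Hz)
FIELD_CUTOFF_SIGMA = 3.0  # Gaussian fields are truncated to exact zero beyond 3 sigma


@dataclass(frozen=True)
class GaussField:
    """One 2-D Gaussian place field (truncated at 3 sigma to compact support)."""

    cx: float
    cy: float
    sigma: float
    peak: float

    def __post_init__(self) -> None:
        if self.peak <= 0:
            raise ValueError("field peak rate must be positive")
        if self.sigma <= 0:
            raise ValueError("field width must be positive")

    def rate(self, x, y) -> np.ndarray:
        d2 = (np.asarray(x) - self.cx) ** 2 + (np.asarray(y) - self.cy) ** 2
        r = self.peak * np.exp(-d2 / (2.0 * self.sigma**2))
        return np.where(d2 <= (FIELD_CUTOFF_SIGMA * self.sigma) ** 2, r, 0.0)


@dataclass(frozen=True)
class CellSpec:
    """Tuning of one simulated place cell in the two environments.

    ``fields`` maps environment name ('A'/'B') to a tuple of Gaussian
    fields; a cell may be silent (no fields) in either environment.  Theta
    modulation follows ``1 + depth * cos(phase - preferred)``.
    """

    cell_id: int
    fields: Mapping[str, Tuple[GaussField, ...]]
    pref_phase_deg: float = 180.0
    mod_depth: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 <= self.mod_depth <= 1.0):
            raise ValueError("theta modulation depth must be in [0, 1]")
        if not (0.0 <= self.pref_phase_deg < 360.0):
            raise ValueError("preferred phase must be in [0, 360)")

    def rate(self, env: str, x, y) -> np.ndarray:
        flds = self.fields.get(env, ())
        if not flds:
            return np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape)
        return np.sum([f.rate(x, y) for f in flds], axis=0)

    def max_rate(self) -> float:
        return max(
            (sum(f.peak for f in flds) for flds in self.fields.values() if flds),
            default=0.0,
        )

    def theta_gain(self, phase_deg) -> np.ndarray:
        return 1.0 + self.mod_depth * np.cos(np.radians(np.asarray(phase_deg) - self.pref_phase_deg))


def make_cell_library(
    n_cells: int = 30,
    frac_both: float = 0.2,
    n_fields: Tuple[int, int] = (1, 2),
    sigma_cm: float = 6.0,
    peak_range_hz: Tuple[float, float] = (4.0, 12.0),
    arena: Arena = Arena(),
    pref_phase_deg: float = 180.0,
    mod_depth: float = 0.8,
    seed: int = 0,
) -> List[CellSpec]:
    """Default CA3-like cell library with globally remapped environments.

    Most cells carry fields in only one environment (split evenly between A
    and B); a fraction carries independent fields in both, mirroring cells
    active in both contexts.  Field centres are uniform over the arena,
    widths fixed, peak rates uniform in ``peak_range_hz``.
    """
    rng = np.random.default_rng(seed)
    n_both = int(round(frac_both * n_cells))
    n_a = (n_cells - n_both + 1) // 2
    n_b = n_cells - n_both - n_a
    kinds = ["A"] * n_a + ["B"] * n_b + ["AB"] * n_both

    def draw_fields() -> Tuple[GaussField, ...]:
        k = int(rng.integers(n_fields[0], n_fields[1] + 1))
        return tuple(
            GaussField(
                cx=float(rng.uniform(0, arena.side_cm)),
                cy=float(rng.uniform(0, arena.side_cm)),
                sigma=sigma_cm,
                peak=float(rng.uniform(*peak_range_hz)),
            )
            for _ in range(k)
        )

    cells = []
    for cid, kind in enumerate(kinds):
        fields = {"A": (), "B": ()}
        if "A" in kind:
            fields["A"] = draw_fields()
        if "B" in kind:
            fields["B"] = draw_fields()
        cells.append(
            CellSpec(cell_id=cid, fields=fields, pref_phase_deg=pref_phase_deg, mod_depth=mod_depth)
        )
    return cells


def true_ratemap(cell: CellSpec, env: str, arena: Arena) -> np.ndarray:
    """Ground-truth tuning of a cell evaluated at bin centres, shape (n, n)."""
    c = arena.bin_centers()
    return cell.rate(env, c[:, 0], c[:, 1]).reshape(arena.n_bins, arena.n_bins)


def true_specificity(cells: Sequence[CellSpec], arena: Arena) -> np.ndarray:
    """Ground-truth per-cell, per-bin specificity index on the true maps."""
    fa = np.stack([true_ratemap(c, "A", arena) for c in cells])
    fb = np.stack([true_ratemap(c, "B", arena) for c in cells])
    tot = fa + fb
    with np.errstate(invalid="ignore", divide="ignore"):
        pesi = (fa - fb) / tot
    pesi[tot == 0] = np.nan
    return pesi


def true_eligibility(cells: Sequence[CellSpec], arena: Arena, min_each: int = 2) -> np.ndarray:
    """Bins where both context codes are detectable on the true maps."""
    pesi = true_specificity(cells, arena)
    n_plus = np.nansum(pesi == 1.0, axis=0)
    n_minus = np.nansum(pesi == -1.0, axis=0)
    return (n_plus >= min_each) & (n_minus >= min_each)


def simulate_trajectory(
    arena: Arena,
    duration: float,
    mean_speed: float = 10.0,
    seed: int = 0,
    tau: float = 3.0,
    dt: float = TRACK_DT,
) -> PositionTrack:
    """Smoothed random-walk foraging exploration with reflecting walls.

    Velocity follows a 2-D Ornstein-Uhlenbeck process with relaxation time
    ``tau`` (s), scaled so the stationary mean speed equals ``mean_speed``
    (cm/s), plus a weak drift toward a "foraging goal" that is resampled
    uniformly over the arena every few seconds (food crumbs scattered
    throughout keep the animal covering the whole floor).  Positions are
    integrated at the 40 ms tracking period and reflected at the walls.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if mean_speed <= 0:
        raise ValueError("mean_speed must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    # per-axis stationary std so that E|v| = mean_speed for 2-D Gaussian v
    s = mean_speed / np.sqrt(np.pi / 2.0)
    a = np.exp(-dt / tau)
    b = s * np.sqrt(1.0 - a * a)
    noise = rng.standard_normal((n, 2))
    side = arena.side_cm
    pos = np.empty((n, 2))
    pos[0] = rng.uniform(0.2 * side, 0.8 * side, size=2)
    vx, vy = rng.standard_normal(2) * s
    x, y = pos[0]
    goal = rng.uniform(0, side, size=2)
    goal_gain = 0.6 * mean_speed  # cm/s of drift toward the current goal
    for i in range(1, n):
        if rng.random() < dt / 8.0 or np.hypot(goal[0] - x, goal[1] - y) < 5.0:
            goal = rng.uniform(0, side, size=2)  # new crumb every ~6 s or on arrival
        gx, gy = goal[0] - x, goal[1] - y
        gnorm = max(np.hypot(gx, gy), 1e-9)
        vx = a * vx + (1 - a) * goal_gain * gx / gnorm + b * noise[i, 0]
        vy = a * vy + (1 - a) * goal_gain * gy / gnorm + b * noise[i, 1]
        x += vx * dt
        y += vy * dt
        if x < 0:
            x, vx = -x, abs(vx)
        elif x > side:
            x, vx = 2 * side - x, -abs(vx)
        if y < 0:
            y, vy = -y, abs(vy)
        elif y > side:
            y, vy = 2 * side - y, -abs(vy)
        pos[i] = (x, y)
    t = np.arange(n) * dt
    return PositionTrack(t, pos[:, 0], pos[:, 1])


@dataclass
class LFPSim:
    """Simulated theta LFP with its ground-truth phase."""

    lfp: LFPSignal
    phase_rad: np.ndarray  # unwrapped true theta phase per LFP sample

    def phase_at(self, times) -> np.ndarray:
        """True unwrapped phase (rad) at arbitrary times (linear interp)."""
        times = np.asarray(times, dtype=float)
        idx = (times - self.lfp.t0) * self.lfp.fs
        return np.interp(idx, np.arange(self.phase_rad.size), self.phase_rad)

    def cycle_bounds(self) -> np.ndarray:
        """Times where the true phase crosses multiples of 2*pi."""
        k = np.floor(self.phase_rad / (2 * np.pi))
        steps = np.nonzero(np.diff(k) >= 1)[0]
        targets = k[steps + 1] * 2 * np.pi
        denom = self.phase_rad[steps + 1] - self.phase_rad[steps]
        frac = np.where(denom > 0, (targets - self.phase_rad[steps]) / denom, 0.5)
        return self.lfp.t0 + (steps + np.clip(frac, 0, 1)) / self.lfp.fs


def simulate_lfp(
    duration: float,
    fs: float = LFP_FS,
    f0: float = 8.0,
    freq_drift_hz: float = 0.5,
    amp_noise: float = 0.1,
    noise_uv: float = 0.2,
    seed: int = 0,
) -> LFPSim:
    """Theta-band LFP: ~8 Hz oscillation with slow frequency drift and
    amplitude jitter, plus broadband noise, sampled at 2 kHz."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))

    from scipy.signal import lfilter

    def slow(tau_s: float) -> np.ndarray:
        # OU noise with long relaxation, unit stationary std (IIR recursion)
        a = np.exp(-1.0 / (tau_s * fs))
        w = rng.standard_normal(n) * np.sqrt(1 - a * a)
        zi = np.array([a * rng.standard_normal()])
        out, _ = lfilter([1.0], [1.0, -a], w, zi=zi)
        return out

    freq = f0 + freq_drift_hz * np.clip(slow(10.0), -2.0, 2.0) / 2.0
    phase = np.concatenate([[0.0], np.cumsum(2 * np.pi * freq[:-1] / fs)])
    amp = 1.0 + amp_noise * np.clip(slow(2.0), -3.0, 3.0) / 3.0
    samples = amp * np.cos(phase) + noise_uv * rng.standard_normal(n)
    return LFPSim(lfp=LFPSignal(samples, fs=fs, t0=0.0), phase_rad=phase)


@dataclass
class SessionSpec:
    """One session of the simulated protocol."""

    name: str
    phase: str  # PRE1 / PRE2 / TELEPORT / POST1 / POST2 / CONTROL1 / CONTROL2
    env: str  # environment identity ('A' or 'B'; starting identity for TELEPORT)
    duration: float = 600.0
    flicker_rate_per_1000tc: float = 0.0
    mixed_fraction: float = 0.0
    rate_decay: float = 1.0  # start/end injection-rate ratio across the session
    switch_interval_s: Tuple[float, float] = (40.0, 60.0)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("session duration must be positive")
        if self.flicker_rate_per_1000tc < 0:
            raise ValueError("flicker rate must be non-negative")
        if not (self.switch_interval_s[0] <= self.switch_interval_s[1]):
            raise ValueError("invalid switch interval range")


@dataclass
class SimSession:
    """A complete simulated session: streams + manifest + ground truth."""

    spec: SessionSpec
    arena: Arena
    cells: List[CellSpec]
    track: PositionTrack
    spikes: Dict[int, np.ndarray]
    lfp: LFPSignal
    lfp_phase_rad: np.ndarray
    ground_truth: pd.DataFrame  # cycle_index, t_start, t_end, true_map, injected, kind
    env_schedule: List[Tuple[float, str]]  # (switch time, env from then on)

    @property
    def manifest(self) -> dict:
        return {
            "session": self.spec.name,
            "phase": self.spec.phase,
            "environment": self.spec.env,
            "duration_s": self.spec.duration,
            "env_schedule": [[float(t), e] for t, e in self.env_schedule],
            "cell_ids": sorted(int(c.cell_id) for c in self.cells),
        }

    def env_at(self, times) -> np.ndarray:
        """Cued environment identity at each time."""
        ts = np.array([t for t, _ in self.env_schedule])
        envs = np.array([e for _, e in self.env_schedule])
        idx = np.clip(np.searchsorted(ts, np.asarray(times), side="right") - 1, 0, len(ts) - 1)
        return envs[idx]


def _draw_poisson_spikes(
    cells: Sequence[CellSpec],
    track: PositionTrack,
    lfp_sim: LFPSim,
    env_of_t,
    duration: float,
    rng: np.random.Generator,
) -> Dict[int, np.ndarray]:
    """Inhomogeneous Poisson spikes by thinning, one train per cell."""
    spikes: Dict[int, np.ndarray] = {}
    for cell in cells:
        rmax = cell.max_rate() * (1.0 + cell.mod_depth)
        if rmax <= 0:
            spikes[cell.cell_id] = np.empty(0)
            continue
        n_cand = rng.poisson(rmax * duration)
        t_cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        x, y = track.interp(t_cand)
        envs = env_of_t(t_cand)
        phase_deg = np.degrees(lfp_sim.phase_at(t_cand)) % 360.0
        rate = np.zeros(t_cand.size)
        for env in np.unique(envs):
            m = envs == env
            rate[m] = cell.rate(env, x[m], y[m])
        rate *= cell.theta_gain(phase_deg)
        keep = rng.uniform(0.0, rmax, size=n_cand) < rate
        spikes[cell.cell_id] = t_cand[keep]
    return spikes


def simulate_session(
    spec: SessionSpec,
    cells: Sequence[CellSpec],
    arena: Arena = Arena(),
    mean_speed: float = 10.0,
    seed: int = 0,
) -> SimSession:
    """Simulate one full session (trajectory, LFP, spikes, ground truth).

    The expressed map equals the cued environment; for TELEPORT sessions
    the cue switches every 40-60 s (uniform).  Flicker injection is a
    separate step (:func:`inject_flicker_cycles`).
    """
    if len(cells) == 0:
        raise ValueError("need at least one cell")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_traj, s_lfp, s_spk = ss.spawn(3)
    rng = np.random.default_rng(s_spk)

    track = simulate_trajectory(arena, spec.duration, mean_speed, seed=s_traj)
    lfp_sim = simulate_lfp(spec.duration, seed=s_lfp)

    schedule: List[Tuple[float, str]] = [(0.0, spec.env)]
    if spec.phase.upper() == "TELEPORT":
        t = float(rng.uniform(60.0, 90.0))  # initial free exploration
        cur = spec.env
        while t < spec.duration:
            cur = "B" if cur == "A" else "A"
            schedule.append((t, cur))
            t += float(rng.uniform(*spec.switch_interval_s))

    ts = np.array([t for t, _ in schedule])
    envs = np.array([e for _, e in schedule])

    def env_of_t(times):
        idx = np.clip(np.searchsorted(ts, np.asarray(times), side="right") - 1, 0, len(ts) - 1)
        return envs[idx]

    spikes = _draw_poisson_spikes(cells, track, lfp_sim, env_of_t, spec.duration, rng)

    bounds = lfp_sim.cycle_bounds()
    bounds = np.concatenate([[0.0], bounds, [spec.duration]])
    bounds = np.unique(bounds[(bounds >= 0) & (bounds <= spec.duration)])
    t0s, t1s = bounds[:-1], bounds[1:]
    mid = 0.5 * (t0s + t1s)
    gt = pd.DataFrame(
        {
            "cycle_index": np.arange(t0s.size),
            "t_start": t0s,
            "t_end": t1s,
            "true_map": env_of_t(mid),
            "injected": False,
            "kind": "",
        }
    )
    return SimSession(
        spec=spec,
        arena=arena,
        cells=list(cells),
        track=track,
        spikes=spikes,
        lfp=lfp_sim.lfp,
        lfp_phase_rad=lfp_sim.phase_rad,
        ground_truth=gt,
        env_schedule=schedule,
    )


def _vonmises_phase_to_time(
    rng: np.random.Generator, mu_deg: float, kappa: float, t0: float, t1: float, n: int
) -> np.ndarray:
    """Spike times at von Mises phases within one cycle (phase linear in time)."""
    ph = np.degrees(rng.vonmises(np.radians(mu_deg), kappa, size=n)) % 360.0
    return t0 + (ph / 360.0) * (t1 - t0)


def _conditioned_counts(
    rng: np.random.Generator,
    rates: np.ndarray,
    specific: np.ndarray,
    dur: float,
    min_active: int = 2,
    max_tries: int = 50,
    order_rates: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Poisson counts conditioned on >= min_active distinct specific cells firing.

    ``rates`` are per-cell expected rates (Hz) for the expressed component,
    ``specific`` flags the cells whose activity makes the event detectable.
    If the condition is never met (vanishing rates), the highest-rate
    specific cells (ranked by ``order_rates``, default ``rates``) are
    forced to one spike each.
    """
    lam = rates * dur
    for _ in range(max_tries):
        counts = rng.poisson(lam)
        if int(np.sum(specific & (counts > 0))) >= min_active:
            return counts
    counts = rng.poisson(lam)
    ranking = rates if order_rates is None else order_rates
    order = np.argsort(np.where(specific, ranking, -np.inf))[::-1]
    for j in order[:min_active]:
        if specific[j]:
            counts[j] = max(counts[j], 1)
    return counts


def inject_flicker_cycles(
    session: SimSession,
    rate_per_1000tc: float,
    mixed_fraction: float = 0.0,
    seed: int = 0,
    rate_decay: Optional[float] = None,
    ocpv_phase_offset_deg: float = 25.0,
    mixed_phase_offset_deg: float = 90.0,
    inject_kappa: float = 4.0,
    ocpv_position_jitter_cm: float = 6.0,
    speed_min: float = 2.0,
    eligibility: Optional[np.ndarray] = None,
    specificity: Optional[np.ndarray] = None,
) -> SimSession:
    """Inject out-context and mixed theta cycles into a simulated session.

    ``rate_per_1000tc`` is the target number of injected events per 1000
    *eligible* theta cycles (cycles at detectable positions with the animal
    moving), matching the normalisation of the incidence measure.  A
    fraction ``mixed_fraction`` of events are mixed cycles; the rest purely
    out-context.  ``rate_decay`` > 1 concentrates events at the start of
    the session with an exponential profile (start/end rate ratio).

    Pure out-context cycles: the in-context spikes of the cycle are removed
    and spikes are regenerated from the alternative map's tuning, evaluated
    at a spatially jittered position (out-context expression is noisier
    than in-context coding), at theta phases von Mises-distributed around
    the population preferred phase plus ``ocpv_phase_offset_deg``.

    Mixed cycles: the original in-context spikes are kept (topped up to at
    least two distinct in-context cells at the preferred phase if needed)
    and out-context spikes are superimposed later in the cycle, offset by
    ``mixed_phase_offset_deg``.

    Spike draws are conditioned on at least two distinct context-specific
    cells firing, so a ground-truth event is by construction an expressed
    pattern.  Returns a new session; the input is left untouched.
    """
    rng = np.random.default_rng(seed)
    gt = session.ground_truth.copy()
    spikes = {cid: st.copy() for cid, st in session.spikes.items()}
    if rate_per_1000tc == 0:
        return replace(session, spikes=spikes, ground_truth=gt)
    if rate_decay is None:
        rate_decay = session.spec.rate_decay

    arena = session.arena
    cells = session.cells
    # target cycles are restricted to bins where both context codes are
    # detectable; by default the ground-truth eligibility of the cell
    # library, or a caller-supplied (e.g. template-estimated) mask
    elig = true_eligibility(cells, arena) if eligibility is None else np.asarray(eligibility, bool)
    # which cells count as context-specific where: the ground-truth maps by
    # default, or the analysis' own template-estimated specificity so that
    # injected expression involves cells the detector can recognise
    pesi = true_specificity(cells, arena) if specificity is None else np.asarray(specificity)

    dur = (gt["t_end"] - gt["t_start"]).to_numpy()
    mid = 0.5 * (gt["t_start"] + gt["t_end"]).to_numpy()
    mx, my = session.track.interp(mid)
    speed = session.track.interp_speed(mid)
    ix, iy = arena.bin_index(mx, my)
    ok = (
        (dur >= 1.0 / 12.0)
        & (dur <= 0.2)
        & (speed > speed_min)
        & elig[iy, ix]
        & (~gt["injected"].to_numpy())
    )
    candidates = np.nonzero(ok)[0]
    n_target = int(round(rate_per_1000tc / 1000.0 * candidates.size))
    if n_target == 0:
        return replace(session, spikes=spikes, ground_truth=gt)
    if n_target > candidates.size:
        warnings.warn(
            f"requested {n_target} flicker cycles but only {candidates.size} eligible; "
            "injecting all eligible cycles"
        )
        n_target = candidates.size

    T = session.spec.duration
    if rate_decay and rate_decay != 1.0:
        lam = np.log(rate_decay) / T
        w = np.exp(-lam * mid[candidates])
    else:
        w = np.ones(candidates.size)
    chosen = rng.choice(candidates, size=n_target, replace=False, p=w / w.sum())
    chosen = np.sort(chosen)
    n_mixed = int(round(mixed_fraction * n_target))
    mixed_set = set(rng.choice(chosen, size=n_mixed, replace=False).tolist()) if n_mixed else set()

    cell_ids = [c.cell_id for c in cells]
    pref = np.array([c.pref_phase_deg for c in cells])
    pop_pref = float(np.degrees(np.angle(np.mean(np.exp(1j * np.radians(pref)))))) % 360.0

    removals: Dict[int, list] = {cid: [] for cid in spikes}
    additions: Dict[int, list] = {cid: [] for cid in spikes}

    for c_idx in chosen:
        t0, t1 = float(gt.at[c_idx, "t_start"]), float(gt.at[c_idx, "t_end"])
        d = t1 - t0
        cur_env = str(gt.at[c_idx, "true_map"])
        alt_env = "B" if cur_env == "A" else "A"
        bx, by = int(ix[c_idx]), int(iy[c_idx])
        is_mixed = c_idx in mixed_set

        sgn_in = 1.0 if cur_env == "A" else -1.0
        spec_in = pesi[:, by, bx] == sgn_in
        spec_out = pesi[:, by, bx] == -sgn_in

        # out-context expression at a jittered position (noisier spatial code)
        q = np.clip(
            np.array([mx[c_idx], my[c_idx]]) + rng.normal(0, ocpv_position_jitter_cm, 2),
            0.0,
            arena.side_cm,
        )
        rates_out = np.array([c.rate(alt_env, q[0], q[1]) for c in cells]).ravel()
        rates_out_here = np.array([c.rate(alt_env, mx[c_idx], my[c_idx]) for c in cells]).ravel()
        off = mixed_phase_offset_deg if is_mixed else ocpv_phase_offset_deg
        counts_out = _conditioned_counts(
            rng, rates_out, spec_out, d, order_rates=rates_out_here
        )
        if not is_mixed:
            # replace in-context activity entirely
            for j, cid in enumerate(cell_ids):
                removals[cid].append((t0, t1))
        else:
            # keep the original in-context spikes; top up to >= 2 distinct
            # in-context cells at the preferred phase if the cycle is quiet
            n_in_active = 0
            for j, cid in enumerate(cell_ids):
                if spec_in[j]:
                    st = spikes[cid]
                    if np.any((st >= t0) & (st < t1)):
                        n_in_active += 1
            if n_in_active < 2:
                rates_in = np.array(
                    [c.rate(cur_env, mx[c_idx], my[c_idx]) for c in cells]
                ).ravel()
                counts_in = _conditioned_counts(rng, rates_in, spec_in, d)
                for j, cid in enumerate(cell_ids):
                    if counts_in[j] > 0 and spec_in[j]:
                        additions[cid].append(
                            _vonmises_phase_to_time(rng, pop_pref, inject_kappa, t0, t1, counts_in[j])
                        )
        for j, cid in enumerate(cell_ids):
            if counts_out[j] > 0:
                additions[cid].append(
                    _vonmises_phase_to_time(rng, (pop_pref + off) % 360.0, inject_kappa, t0, t1, counts_out[j])
                )
        gt.at[c_idx, "true_map"] = "mixed" if is_mixed else alt_env
        gt.at[c_idx, "injected"] = True
        gt.at[c_idx, "kind"] = "mixed" if is_mixed else "ocpv"

    for cid in cell_ids:
        st = spikes[cid]
        keep = np.ones(st.size, dtype=bool)
        for t0, t1 in removals[cid]:
            keep &= ~((st >= t0) & (st < t1))
        parts = [st[keep]] + additions[cid]
        spikes[cid] = np.sort(np.concatenate(parts))
    return replace(session, spikes=spikes, ground_truth=gt)


def default_protocol(control: bool = False) -> List[SessionSpec]:
    """The study-day protocol with in-vivo-scale flicker rates.

    Baseline out-context events run at ~1.9 events / 1000 TC (~1.3 pure +
    ~0.6 mixed); post-teleportation sessions at ~5.6 / 1000 TC with a ~3x
    within-session decay.  The control variant replaces the teleportation
    session with two short stable-cue sessions and keeps POST rates at
    baseline-like levels.
    """
    pre = dict(flicker_rate_per_1000tc=1.9, mixed_fraction=0.31)
    if control:
        mid = [
            SessionSpec("CTRL1", "CONTROL1", "A", duration=300.0),
            SessionSpec("CTRL2", "CONTROL2", "B", duration=300.0),
        ]
        post = dict(flicker_rate_per_1000tc=3.1, mixed_fraction=0.24)
    else:
        mid = [SessionSpec("TEL", "TELEPORT", "A")]
        post = dict(flicker_rate_per_1000tc=5.6, mixed_fraction=0.36, rate_decay=3.0)
    return [
        SessionSpec("PRE1", "PRE1", "A", **pre),
        SessionSpec("PRE2", "PRE2", "B", **pre),
        *mid,
        SessionSpec("POST1", "POST1", "A", **post),
        SessionSpec("POST2", "POST2", "B", **post),
    ]


def simulate_experiment(
    cells: Sequence[CellSpec],
    protocol: Optional[Sequence[SessionSpec]] = None,
    arena: Arena = Arena(),
    mean_speed: float = 10.0,
    seed: int = 0,
    inject_eligibility: Optional[np.ndarray] = None,
    inject_specificity: Optional[np.ndarray] = None,
) -> Dict[str, SimSession]:
    """Simulate a full experiment: one session per protocol entry.

    Per-session RNG streams are spawned from ``seed``, so the whole
    experiment is reproducible and sessions are independent.
    """
    if protocol is None:
        protocol = default_protocol()
    ss = np.random.SeedSequence(seed)
    out: Dict[str, SimSession] = {}
    for spec, child in zip(protocol, ss.spawn(len(protocol))):
        s_sim, s_inj = child.spawn(2)
        sess = simulate_session(spec, cells, arena, mean_speed, seed=s_sim)
        if spec.flicker_rate_per_1000tc > 0:
            sess = inject_flicker_cycles(
                sess,
                spec.flicker_rate_per_1000tc,
                spec.mixed_fraction,
                seed=s_inj,
                rate_decay=spec.rate_decay,
                eligibility=inject_eligibility,
                specificity=inject_specificity,
            )
        out[spec.name] = sess
    return out
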