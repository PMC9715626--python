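"""Theta-band LFP processing, theta-cycle segmentation and per-cycle
population vectors.

The LFP is band-pass filtered in the theta band (default 6-11 Hz) with a
zero-phase Hamming-window FIR filter and the instantaneous phase is taken
from the analytic signal.  Theta cycles -- the temporal bins of the
momentary population vectors -- are cut at the theta phase with the lowest
mean firing rate across the recorded population, so each cycle spans 360
degrees starting at the population-firing minimum.  Reported spike phases
are relative to that border (0 deg at the cycle border) by linear
interpolation in time between the two borders of the containing cycle.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy import signal

from .arena import Arena
from .preprocess import PositionTrack

__all__ = [
    "LFPSignal",
    "ThetaCycles",
    "PopulationVectors",
    "bandpass_theta",
    "instantaneous_phase_deg",
    "segment_cycles",
    "assign_spike_phases",
    "build_population_vectors",
]


@dataclass
class LFPSignal:
    """A single continuously sampled LFP channel."""

    samples: np.ndarray
    fs: float = 2000.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


def bandpass_theta(
    lfp: LFPSignal,
    low: float = 6.0,
    high: float = 11.0,
    numtaps: int = 2001,
) -> np.ndarray:
    """Zero-phase Hamming-window FIR band-pass of the LFP.

    The symmetric (linear-phase) FIR kernel is applied by centred FFT
    convolution, which is exactly zero-phase.  Passband gain at 8 Hz is
    >= 0.9 and stopband gain at 2 Hz and 25 Hz is <= 0.1 with the default
    1 s kernel at 2 kHz.
    """
    nyq = lfp.fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz outside (0, {nyq}) Hz")
    numtaps = min(numtaps, 2 * (lfp.samples.size // 2) - 1)
    if numtaps % 2 == 0:
        numtaps -= 1
    taps = signal.firwin(numtaps, [low, high], pass_zero=False, window="hamming", fs=lfp.fs)
    return signal.fftconvolve(lfp.samples, taps, mode="same")


def instantaneous_phase_deg(filtered: np.ndarray) -> np.ndarray:
    """Instantaneous phase (deg, [0, 360)) from the analytic signal.

    Phase 0 corresponds to the oscillation peak in this convention; the
    cycle border used downstream is data-derived so the reference is
    immaterial.
    """
    return np.degrees(np.angle(signal.hilbert(filtered))) % 360.0


@dataclass
class ThetaCycles:
    """Segmented theta cycles: non-overlapping [start, end) intervals (s)."""

    start: np.ndarray
    end: np.ndarray
    border_phase_deg: float

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)

    @property
    def n(self) -> int:
        return self.start.size

    @property
    def duration(self) -> np.ndarray:
        return self.end - self.start

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.start + self.end)

    def cycle_of(self, times) -> np.ndarray:
        """Index of the cycle containing each time, -1 if outside all cycles."""
        times = np.asarray(times, dtype=float)
        if self.n == 0:
            return np.full(times.shape, -1, dtype=int)
        idx = np.searchsorted(self.start, times, side="right") - 1
        ok = (idx >= 0) & (times < self.end[np.clip(idx, 0, self.n - 1)])
        return np.where(ok, idx, -1)


def segment_cycles(
    filtered: np.ndarray,
    fs: float,
    t0: float = 0.0,
    spike_times: Optional[np.ndarray] = None,
    n_phase_bins: int = 36,
    min_duration: float = 1.0 / 12.0,
    max_duration: float = 0.2,
) -> ThetaCycles:
    """Cut theta cycles at the population-firing-minimum phase.

    The phase histogram of all spikes (pooled across cells, default 36
    bins) locates the border: the bin with the lowest spike count (ties
    resolved to the earliest bin).  Cycles are the intervals between
    successive crossings of that phase, linearly interpolated in time, and
    cycles with period outside [``min_duration``, ``max_duration``] seconds
    (outside ~5-12 Hz) are discarded as non-theta.

    Without spikes the border falls back to the filtered-LFP trough (phase
    180 deg in the analytic-signal convention) with a warning.
    """
    phase_rad = np.unwrap(np.angle(signal.hilbert(filtered)))
    phase_deg = np.degrees(phase_rad) % 360.0

    if spike_times is not None and np.asarray(spike_times).size > 0:
        st = np.asarray(spike_times, dtype=float)
        idx = np.round((st - t0) * fs).astype(int)
        idx = idx[(idx >= 0) & (idx < filtered.size)]
        hist, edges = np.histogram(phase_deg[idx], bins=n_phase_bins, range=(0.0, 360.0))
        k = int(np.argmin(hist))  # ties -> earliest bin
        border = float(0.5 * (edges[k] + edges[k + 1]))
    else:
        warnings.warn("no spikes available; cutting cycles at the LFP trough")
        border = 180.0

    # crossing times of phase == border (mod 360), ascending
    b = np.radians(border)
    k = np.floor((phase_rad - b) / (2 * np.pi))
    steps = np.nonzero(np.diff(k) >= 1)[0]
    # linear interpolation of the crossing instant within the sample step
    targets = (k[steps + 1]) * 2 * np.pi + b
    denom = phase_rad[steps + 1] - phase_rad[steps]
    frac = np.where(denom > 0, (targets - phase_rad[steps]) / denom, 0.5)
    cross_t = t0 + (steps + np.clip(frac, 0.0, 1.0)) / fs
    cross_t = cross_t[np.argsort(cross_t)]
    if cross_t.size < 2:
        return ThetaCycles(np.empty(0), np.empty(0), border)
    start, end = cross_t[:-1], cross_t[1:]
    dur = end - start
    keep = (dur >= min_duration) & (dur <= max_duration)
    return ThetaCycles(start[keep], end[keep], border)


def assign_spike_phases(cycles: ThetaCycles, spike_times) -> np.ndarray:
    """Per-spike theta phase (deg) relative to the cycle border.

    Phase is linearly interpolated in time within the containing cycle:
    ``360 * (t - t_start) / (t_end - t_start)``.  Spikes outside every
    cycle get NaN.
    """
    st = np.asarray(spike_times, dtype=float)
    idx = cycles.cycle_of(st)
    out = np.full(st.size, np.nan)
    ok = idx >= 0
    i = idx[ok]
    out[ok] = 360.0 * (st[ok] - cycles.start[i]) / (cycles.end[i] - cycles.start[i])
    return out


@dataclass
class PopulationVectors:
    """Per-theta-cycle spike-count vectors with linked behaviour.

    ``counts`` has shape ``(n_cycles, n_cells)``.  ``included`` flags the
    cycles passing the locomotion filter (linked speed above threshold).
    """

    counts: np.ndarray
    cell_ids: list
    t_start: np.ndarray
    t_end: np.ndarray
    bin_flat: np.ndarray
    x: np.ndarray
    y: np.ndarray
    speed: np.ndarray
    included: np.ndarray
    n_dropped_spikes: int = 0

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def duration(self) -> np.ndarray:
        return self.t_end - self.t_start

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.t_start + self.t_end)


def build_population_vectors(
    cycles: ThetaCycles,
    spikes: Mapping[object, np.ndarray],
    track: PositionTrack,
    arena: Arena,
    speed_min: float = 2.0,
) -> PopulationVectors:
    """Assign spikes to theta cycles and link each cycle to behaviour.

    Each spike is counted in the unique cycle containing it (spikes outside
    any cycle are dropped and counted).  The linked position is the
    interpolated track position at the cycle midpoint, converted to an
    arena bin; the linked speed is interpolated the same way and cycles at
    speed <= ``speed_min`` cm/s are flagged as excluded.
    """
    cell_ids = sorted(spikes)
    counts = np.zeros((cycles.n, len(cell_ids)), dtype=np.int64)
    dropped = 0
    for j, cid in enumerate(cell_ids):
        st = np.asarray(spikes[cid], dtype=float)
        idx = cycles.cycle_of(st)
        dropped += int(np.sum(idx < 0))
        good = idx[idx >= 0]
        if good.size:
            counts[:, j] = np.bincount(good, minlength=cycles.n)
    mid = cycles.midpoint
    x, y = track.interp(mid)
    speed = track.interp_speed(mid)
    return PopulationVectors(
        counts=counts,
        cell_ids=cell_ids,
        t_start=cycles.start.copy(),
        t_end=cycles.end.copy(),
        bin_flat=arena.flat_index(x, y),
        x=x,
        y=y,
        speed=speed,
        included=speed > speed_min,
        n_dropped_spikes=dropped,
    )
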