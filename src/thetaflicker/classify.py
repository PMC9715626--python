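"""Context-specificity index, bin eligibility and population-vector labels.

The Position/Environment Specificity Index of cell *i* at position bin *x*
is ``PESI_x = (f_A,x - f_B,x) / (f_A,x + f_B,x)``, computed on the smoothed
template rates; it is +1 where the cell fires only in environment A, -1
where only in B, and undefined where it fires in neither.  A position bin
is *eligible* for classification when at least two cells are +1-specific
and another two are -1-specific there (both context codes are detectable),
and the bin was behaviourally covered in the evaluated session.

A population vector at an eligible bin is labelled from the distinct
context-specific cells active in it (only spikes from cells with |PESI| = 1
at the linked bin count):

* ICPV -- two or more cells specific to the current context, none specific
  to the alternative one;
* OCPV -- two or more cells specific to the alternative context, none
  specific to the current one;
* MPV  -- at least two specific cells active on *each* side;
* unclassified otherwise (including one-sided single-cell activity and the
  conservative 2-vs-1 case).

Incidence is reported per 1000 theta cycles, normalised by the time spent:
the default aggregates counts over eligible bins and divides by the total
number of eligible theta-cycle bins, the per-bin mode averages per-bin
rates as in a per-pixel normalisation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import TemplateSet
from .theta import PopulationVectors

__all__ = [
    "LABELS",
    "Eligibility",
    "compute_pesi",
    "eligible_bins",
    "classify_pvs",
    "incidence_per_1000tc",
    "session_thirds",
    "subsample_cells",
]

LABELS = ("ICPV", "OCPV", "MPV", "unclassified")
_TOL = 1e-12


def compute_pesi(templates: TemplateSet, env_a: str = "A", env_b: str = "B") -> np.ndarray:
    """Specificity index per cell per bin, shape ``(n_cells, n, n)``.

    NaN where both template rates are zero or either is undefined
    (unvisited bin).
    """
    fa = templates.rates[env_a]
    fb = templates.rates[env_b]
    tot = fa + fb
    with np.errstate(invalid="ignore", divide="ignore"):
        pesi = (fa - fb) / tot
    pesi[~np.isfinite(tot)] = np.nan
    pesi[tot == 0] = np.nan
    return pesi


@dataclass
class Eligibility:
    """Which bins support detection of both context codes."""

    eligible: np.ndarray  # (n, n) bool
    n_plus: np.ndarray  # count of +1-specific cells per bin
    n_minus: np.ndarray  # count of -1-specific cells per bin

    @property
    def n_eligible(self) -> int:
        return int(self.eligible.sum())

    def flat(self) -> np.ndarray:
        return self.eligible.ravel()


def eligible_bins(
    pesi: np.ndarray,
    coverage: Optional[np.ndarray] = None,
    min_each: int = 2,
) -> Eligibility:
    """Bins with >= ``min_each`` cells at PESI = +1 and as many at -1.

    ``coverage`` optionally restricts eligibility to behaviourally covered
    bins of the evaluated session (boolean ``(n, n)`` mask).
    """
    plus = np.sum(np.abs(pesi - 1.0) < _TOL, axis=0)
    minus = np.sum(np.abs(pesi + 1.0) < _TOL, axis=0)
    ok = (plus >= min_each) & (minus >= min_each)
    if coverage is not None:
        ok = ok & coverage
    return Eligibility(eligible=ok, n_plus=plus, n_minus=minus)


def classify_pvs(
    pvs: PopulationVectors,
    pesi: np.ndarray,
    eligibility: Eligibility,
    current_env: str,
    min_cells: int = 2,
    mpv_min_per_side: int = 2,
) -> pd.DataFrame:
    """Label every population vector of a session.

    Returns a tidy frame with one row per theta cycle: label, number of
    active current-context-specific (``n_in``) and alternative-context-
    specific (``n_out``) cells at the linked bin, linked bin/speed, and the
    inclusion flags.  Cycles at ineligible bins, or failing the locomotion
    filter, are labelled ``unclassified`` with ``eligible``/``included``
    flags recording why.
    """
    s = 1.0 if current_env == "A" else -1.0
    n_side = pesi.shape[1]
    iy, ix = np.divmod(pvs.bin_flat, n_side)
    # per-cycle per-cell specificity at the linked bin
    pesi_at = pesi[:, iy, ix].T  # (n_cycles, n_cells)
    active = pvs.counts > 0
    n_in = np.sum(active & (np.abs(pesi_at - s) < _TOL), axis=1)
    n_out = np.sum(active & (np.abs(pesi_at + s) < _TOL), axis=1)

    elig = eligibility.flat()[pvs.bin_flat]
    usable = elig & pvs.included

    label = np.full(pvs.n, "unclassified", dtype=object)
    is_ic = (n_in >= min_cells) & (n_out == 0)
    is_oc = (n_out >= min_cells) & (n_in == 0)
    is_mx = (n_in >= mpv_min_per_side) & (n_out >= mpv_min_per_side)
    label[usable & is_ic] = "ICPV"
    label[usable & is_oc] = "OCPV"
    label[usable & is_mx] = "MPV"

    return pd.DataFrame(
        {
            "cycle_index": np.arange(pvs.n),
            "t_start": pvs.t_start,
            "t_end": pvs.t_end,
            "label": label,
            "n_in_specific": n_in,
            "n_out_specific": n_out,
            "bin": pvs.bin_flat,
            "x": pvs.x,
            "y": pvs.y,
            "speed": pvs.speed,
            "included": pvs.included,
            "eligible_bin": elig,
        }
    )


def incidence_per_1000tc(
    labels: pd.DataFrame,
    mode: str = "pooled",
) -> pd.DataFrame:
    """Events per 1000 theta cycles for each label, occupancy-normalised.

    ``pooled`` (default): total counts over eligible, locomotion-passing
    cycles divided by the total number of such cycles.  ``per_bin``:
    per-bin rates (count / theta cycles spent in the bin) averaged over
    the occupied eligible bins, the per-pixel normalisation.
    """
    usable = labels[labels["included"] & labels["eligible_bin"]]
    denom = len(usable)
    rows = []
    for lab in ("ICPV", "OCPV", "MPV"):
        sub = usable[usable["label"] == lab]
        if denom == 0:
            warnings.warn("no eligible theta cycles; incidence undefined")
            rate = np.nan
        elif mode == "pooled":
            rate = 1000.0 * len(sub) / denom
        elif mode == "per_bin":
            per_bin_tc = usable.groupby("bin").size()
            per_bin_ev = sub.groupby("bin").size().reindex(per_bin_tc.index, fill_value=0)
            rate = 1000.0 * float((per_bin_ev / per_bin_tc).mean())
        else:
            raise ValueError(f"unknown incidence mode {mode!r}")
        rows.append({"label": lab, "count": len(sub), "n_eligible_tc": denom, "per_1000tc": rate})
    return pd.DataFrame(rows)


def session_thirds(
    labels: pd.DataFrame,
    mode: str = "equal",
    window_s: float = 150.0,
) -> pd.DataFrame:
    """Within-session incidence trend over three intervals.

    ``equal`` splits the classified span into three equal-duration thirds;
    ``fixed`` uses consecutive ``window_s`` windows from the start (three
    are reported).
    """
    t0 = float(labels["t_start"].min())
    t1 = float(labels["t_end"].max())
    if mode == "equal":
        edges = np.linspace(t0, t1, 4)
    elif mode == "fixed":
        edges = t0 + window_s * np.arange(4)
    else:
        raise ValueError(f"unknown thirds mode {mode!r}")
    mid = 0.5 * (labels["t_start"] + labels["t_end"])
    rows = []
    for k in range(3):
        m = (mid >= edges[k]) & (mid < edges[k + 1] + (1e-9 if k == 2 else 0))
        inc = incidence_per_1000tc(labels[m])
        inc.insert(0, "third", k + 1)
        rows.append(inc)
    return pd.concat(rows, ignore_index=True)


def subsample_cells(
    templates: TemplateSet,
    pvs: PopulationVectors,
    current_env: str,
    coverage: Optional[np.ndarray],
    target_n: int,
    iterations: int = 10,
    seed: int = 0,
    min_cells: int = 2,
    mpv_min_per_side: int = 2,
) -> pd.DataFrame:
    """Incidence averaged over random cell subsamples of size ``target_n``.

    Used to equalise cell-sample sizes across groups: specificity and
    eligibility are re-derived for every subsample and the per-label
    incidence is averaged over iterations.
    """
    if target_n > templates.n_cells:
        raise ValueError("target_n exceeds the available number of cells")
    rng = np.random.default_rng(seed)
    out = []
    for it in range(iterations):
        keep_ids = list(
            np.array(templates.cell_ids, dtype=object)[
                np.sort(rng.choice(templates.n_cells, size=target_n, replace=False))
            ]
        )
        sub_t = templates.subset(keep_ids)
        cols = [pvs.cell_ids.index(c) for c in keep_ids]
        sub_pv = PopulationVectors(
            counts=pvs.counts[:, cols],
            cell_ids=keep_ids,
            t_start=pvs.t_start,
            t_end=pvs.t_end,
            bin_flat=pvs.bin_flat,
            x=pvs.x,
            y=pvs.y,
            speed=pvs.speed,
            included=pvs.included,
        )
        pesi = compute_pesi(sub_t)
        elig = eligible_bins(pesi, coverage, min_each=min_cells)
        labels = classify_pvs(sub_pv, pesi, elig, current_env, min_cells, mpv_min_per_side)
        inc = incidence_per_1000tc(labels)
        inc.insert(0, "iteration", it)
        out.append(inc)
    allit = pd.concat(out, ignore_index=True)
    return (
        allit.groupby("label", as_index=False)
        .agg(per_1000tc=("per_1000tc", "mean"), count=("count", "mean"))
        .assign(iterations=iterations)
    )
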