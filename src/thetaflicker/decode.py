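"""Per-theta-cycle position and context decoding.

Two decoders quantify the quality of the momentary spatial code:

* a correlation decoder -- the cycle's spike-count vector is Pearson-
  correlated with the template rate vector of every position bin of the
  relevant map; the decoded position is the bin with the highest
  correlation and the positional error is the Euclidean distance between
  its centre and the animal's actual position;

* a Bayesian decoder -- assuming independent Poisson spiking at the
  template rates, the posterior ``P(pos, context | spikes)`` is computed
  over all bins of both environments under a uniform prior, and the
  context marginal is the posterior summed over the bins of each
  environment; a context is "detected" when its marginal exceeds 0.95.

Field-geometry covariates of decoding error (distance of active cells'
field centres from the current position, pairwise centre spread, and the
fraction of cells firing at their field periphery) are computed per cycle
from the same templates.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .arena import Arena
from .preprocess import TemplateSet

__all__ = [
    "correlation_decode",
    "bayes_decode",
    "field_metrics",
]


def _template_matrix(templates: TemplateSet, env: str) -> Tuple[np.ndarray, np.ndarray]:
    """Template rates as (n_cells, n_bins_total) plus valid-bin mask."""
    T = templates.rates[env].reshape(templates.n_cells, -1)
    valid = np.all(np.isfinite(T), axis=0)
    return T, valid


def correlation_decode(
    counts: np.ndarray,
    templates: TemplateSet,
    env: str,
    arena: Arena,
    x: np.ndarray,
    y: np.ndarray,
    min_active: int = 2,
) -> pd.DataFrame:
    """Correlation-decode every cycle against the templates of one map.

    ``counts`` has shape ``(n_cycles, n_cells)``.  Cycles with fewer than
    ``min_active`` active cells, or a constant count vector, are not
    decoded (NaN row).  Ties at the maximal correlation resolve to the bin
    nearest the previously decoded one, then to the lowest flat index.

    Returns a frame with ``decoded_bin``, ``r_max`` and ``error_cm``.
    """
    counts = np.asarray(counts, dtype=float)
    T, valid = _template_matrix(templates, env)
    Tv = T[:, valid]
    col_ok = Tv.std(axis=0) > 0
    Tv = Tv[:, col_ok]
    bin_idx = np.nonzero(valid)[0][col_ok]
    centers = arena.bin_centers()

    n_cells = counts.shape[1]
    Tc = Tv - Tv.mean(axis=0, keepdims=True)
    t_norm = np.linalg.norm(Tc, axis=0)

    Cc = counts - counts.mean(axis=1, keepdims=True)
    c_norm = np.linalg.norm(Cc, axis=1)
    active = (counts > 0).sum(axis=1)
    decodable = (active >= min_active) & (c_norm > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Cc @ Tc) / (c_norm[:, None] * t_norm[None, :])

    decoded = np.full(counts.shape[0], -1, dtype=int)
    r_max = np.full(counts.shape[0], np.nan)
    prev = None
    for i in range(counts.shape[0]):
        if not decodable[i]:
            continue
        row = r[i]
        if not np.any(np.isfinite(row)):
            continue
        m = np.nanmax(row)
        cand = np.nonzero(row >= m - 1e-12)[0]
        if cand.size > 1 and prev is not None:
            d = np.linalg.norm(centers[bin_idx[cand]] - centers[prev], axis=1)
            cand = cand[d == d.min()]
        b = int(bin_idx[cand[0]])
        decoded[i] = b
        r_max[i] = m
        prev = b
    err = np.full(counts.shape[0], np.nan)
    ok = decoded >= 0
    err[ok] = np.hypot(
        centers[decoded[ok], 0] - np.asarray(x)[ok], centers[decoded[ok], 1] - np.asarray(y)[ok]
    )
    return pd.DataFrame({"decoded_bin": decoded, "r_max": r_max, "error_cm": err})


def bayes_decode(
    counts: np.ndarray,
    templates: TemplateSet,
    durations: np.ndarray,
    rate_floor: float = 0.01,
    threshold: float = 0.95,
    env_a: str = "A",
    env_b: str = "B",
) -> pd.DataFrame:
    """Poisson-likelihood posterior over (position, context) per cycle.

    ``P(spikes | pos, context)`` is a product of independent Poisson terms
    ``(t f_i)^{n_i}/n_i! exp(-t f_i)`` at the template rates ``f_i``
    (floored at ``rate_floor`` Hz to keep the log-likelihood finite), with
    a uniform prior over all valid bins of both environments.  The context
    marginal sums the posterior over each environment's bins; ``detected``
    is the environment whose marginal exceeds ``threshold``, or '' if none.
    """
    counts = np.asarray(counts, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if np.any(durations <= 0):
        raise ValueError("cycle durations must be positive")
    Ta, va = _template_matrix(templates, env_a)
    Tb, vb = _template_matrix(templates, env_b)
    F = np.concatenate([Ta[:, va], Tb[:, vb]], axis=1)
    F = np.maximum(F, rate_floor)
    n_a = int(va.sum())

    logF = np.log(F)
    sumF = F.sum(axis=0)
    n_tot = counts.sum(axis=1)
    # log L[c, b] = sum_i n_i log f_ib + N_c log t_c - t_c sum_i f_ib  (+ const)
    logL = counts @ logF + n_tot[:, None] * np.log(durations)[:, None] - np.outer(durations, sumF)
    logL -= gammaln(counts + 1.0).sum(axis=1)[:, None]
    log_post = logL - logsumexp(logL, axis=1, keepdims=True)
    post = np.exp(log_post)
    p_a = post[:, :n_a].sum(axis=1)
    p_b = post[:, n_a:].sum(axis=1)
    detected = np.where(p_a > threshold, env_a, np.where(p_b > threshold, env_b, ""))
    return pd.DataFrame({"p_a": p_a, "p_b": p_b, "detected_context": detected})


def field_metrics(
    counts: np.ndarray,
    templates: TemplateSet,
    env: str,
    pesi: np.ndarray,
    specific_sign: float,
    bin_flat: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    arena: Arena,
    periphery_frac: float = 0.1,
) -> pd.DataFrame:
    """Field-geometry covariates per cycle for the relevant map.

    For every active cell that is context-specific at the linked bin
    (``pesi == specific_sign`` there), the place-field centre is the bin of
    maximal template rate in ``env`` (ties to the lowest flat index).  A
    cell fires "at the periphery" when the template rate at the linked bin
    is below ``periphery_frac`` of its peak.  Cells with an all-zero
    template in the relevant map are skipped.

    Returns per-cycle means: centre distance from the current position,
    pairwise centre distance, peripheral fraction, and active-cell count.
    """
    counts = np.asarray(counts)
    T = templates.rates[env].reshape(templates.n_cells, -1)
    Tz = np.nan_to_num(T)
    peaks = Tz.max(axis=1)
    centers_bin = np.argmax(Tz, axis=1)  # ties -> lowest flat index
    centers = arena.bin_centers()[centers_bin]
    n_side = arena.n_bins
    iy, ix = np.divmod(np.asarray(bin_flat), n_side)

    rows = []
    for i in range(counts.shape[0]):
        spec = np.abs(pesi[:, iy[i], ix[i]] - specific_sign) < 1e-12
        act = np.nonzero((counts[i] > 0) & spec & (peaks > 0))[0]
        if act.size == 0:
            rows.append((np.nan, np.nan, np.nan, 0))
            continue
        d_center = np.hypot(centers[act, 0] - x[i], centers[act, 1] - y[i])
        if act.size >= 2:
            pc = centers[act]
            diff = pc[:, None, :] - pc[None, :, :]
            dd = np.hypot(diff[..., 0], diff[..., 1])
            pair = float(dd[np.triu_indices(act.size, 1)].mean())
        else:
            pair = np.nan
        rate_here = Tz[act, np.asarray(bin_flat)[i]]
        peripheral = rate_here < periphery_frac * peaks[act]
        rows.append((float(d_center.mean()), pair, float(peripheral.mean()), int(act.size)))
    return pd.DataFrame(
        rows,
        columns=["mean_center_dist_cm", "mean_pairwise_dist_cm", "frac_peripheral", "n_active"],
    )
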