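"""Two-channel normalization and running-median smoothing of probe tracks.

Raw Cy5 (ChIP) / Cy3 (input DNA) intensities become centered log2 ratios:
``log2(cy5/cy3)`` minus the Tukey biweight mean of the sample's ratios
(the NimbleGen scaling convention), then a position-centered 150-bp
running median (about one nucleosome) suppresses probe-level noise.
"""

from __future__ import annotations

import logging
from typing import Dict

import numpy as np
import pandas as pd

from .containers import ProbeTrack

log = logging.getLogger(__name__)


def tukey_biweight_mean(
    values,
    c: float = 5.0,
    tol: float = 1e-6,
    max_iter: int = 50,
    one_step: bool = False,
) -> float:
    """Tukey's biweight (bisquare) location estimate.

    Iteratively reweighted mean with weights ``(1-u^2)^2`` for ``|u|<1``
    where ``u = (x - t)/(c * MAD)``; the scale is the median absolute
    deviation about the initial median and is held fixed.  ``one_step``
    stops after a single reweighting (the other convention in array
    scaling software; the default iterates to convergence).

    Degenerate inputs (MAD = 0) return the median.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("tukey_biweight_mean requires at least one finite value")
    t = float(np.median(x))
    s = float(np.median(np.abs(x - t)))
    if s == 0.0:
        return t
    for _ in range(1 if one_step else max_iter):
        u = (x - t) / (c * s)
        w = np.square(1.0 - np.square(u))
        w[np.abs(u) >= 1.0] = 0.0
        wsum = w.sum()
        if wsum <= 0:
            break
        t_new = float(np.sum(w * x) / wsum)
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new
    return t


def normalize_log_ratios(
    raw: pd.DataFrame,
    sample_id: str,
    c: float = 5.0,
    one_step: bool = False,
) -> ProbeTrack:
    """Centered log2 ratios from a raw two-channel table.

    ``raw`` columns: ``chrom, pos, cy5, cy3``.  Probes with a non-positive
    channel are rejected (logged); an all-rejected sample is an error.
    The biweight center is computed across the whole sample, so output
    ratios are invariant to scaling both channels by a common constant.
    """
    required = {"chrom", "pos", "cy5", "cy3"}
    if not required.issubset(raw.columns):
        raise ValueError(f"raw table must have columns {sorted(required)}")
    ok = (raw["cy5"] > 0) & (raw["cy3"] > 0)
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("%s: rejecting %d probes with non-positive intensities", sample_id, n_bad)
    kept = raw[ok]
    if not len(kept):
        raise ValueError(f"{sample_id}: no probes with positive intensities in both channels")
    ratios = np.log2(kept["cy5"].to_numpy(float) / kept["cy3"].to_numpy(float))
    center = tukey_biweight_mean(ratios, c=c, one_step=one_step)
    df = pd.DataFrame({"chrom": kept["chrom"], "pos": kept["pos"], "value": ratios - center})
    return ProbeTrack.from_frame(df, sample_id=sample_id)


def smooth_running_median(
    track: ProbeTrack, window_bp: int = 150, min_nonzero: int = 3
) -> ProbeTrack:
    """Position-centered running median over ``window_bp``.

    Each probe's value becomes the median of non-missing values of probes
    within +/- window_bp/2 of its position (endpoints inclusive).  Probes
    whose window holds fewer than ``min_nonzero`` probes with non-missing,
    nonzero value are set missing (NaN) and excluded downstream.
    """
    half = window_bp / 2.0
    chroms: Dict[str, tuple] = {}
    for chrom, (pos, val) in track.chroms.items():
        out = np.full(val.shape, np.nan)
        finite = np.isfinite(val)
        nonzero = finite & (val != 0)
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        for i in range(pos.size):
            sl = slice(lo[i], hi[i])
            if int(nonzero[sl].sum()) < min_nonzero:
                continue
            window_vals = val[sl][finite[sl]]
            if window_vals.size:
                out[i] = np.median(window_vals)
        chroms[chrom] = (pos.copy(), out)
    return ProbeTrack(sample_id=track.sample_id, chroms=chroms)
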