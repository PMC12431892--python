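"""Global field power and peak-topography extraction.

The GFP at a sample is the spatial standard deviation of the
instantaneous topography across electrodes — a reference-free measure
of field strength.  Topographies are sampled at GFP local maxima
(where topographies are most stable), filtered by two criteria
(unusually high peaks above mean + 1 SD are removed, as are peaks in
the lowest 15% of the GFP distribution where topographies are
noise-dominated), and optionally subsampled for tractability.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import EpochedEEG, PeakSet

__all__ = [
    "compute_gfp",
    "find_peaks",
    "filter_peaks",
    "extract_peaks",
    "subsample",
]


def compute_gfp(ep: EpochedEEG) -> np.ndarray:
    """GFP per sample: spatial SD across channels, shape (epochs, samples)."""
    if ep.n_channels < 2:
        raise ValueError("GFP needs at least 2 channels")
    return ep.data.std(axis=1)


def _epoch_peaks(g: np.ndarray, min_distance: int) -> np.ndarray:
    """Strict local maxima of one epoch's GFP, thinned to min_distance.

    A plateau's first sample is its peak.  Thinning keeps the larger of
    two conflicting peaks; equal heights keep the earlier one.
    """
    n = g.size
    candidates = []
    i = 1
    while i < n - 1:
        if g[i] > g[i - 1]:
            j = i
            while j + 1 < n and g[j + 1] == g[i]:
                j += 1
            if j + 1 < n and g[j + 1] < g[i]:
                candidates.append(i)  # first sample of the plateau
            i = j + 1
        else:
            i += 1
    if not candidates or min_distance <= 1:
        return np.asarray(candidates, dtype=int)
    cand = np.asarray(candidates, dtype=int)
    # greedy by height, ties broken toward the earlier index
    order = np.lexsort((cand, -g[cand]))
    kept: list[int] = []
    for idx in cand[order]:
        if all(abs(idx - kpt) >= min_distance for kpt in kept):
            kept.append(int(idx))
    return np.asarray(sorted(kept), dtype=int)


def find_peaks(gfp: np.ndarray, min_distance: int = 2) -> list[np.ndarray]:
    """Per-epoch GFP peak indices; peaks never span epoch boundaries."""
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    gfp = np.atleast_2d(np.asarray(gfp, dtype=float))
    return [_epoch_peaks(row, min_distance) for row in gfp]


def filter_peaks(gfp: np.ndarray, peaks: list[np.ndarray],
                 sd_mult: float | None = 1.0,
                 low_pct: float | None = 15.0
                 ) -> list[np.ndarray]:
    """Drop peaks that are too high or too low relative to the full series.

    Mean, SD and the percentile are computed over the participant's
    entire GFP series (all samples of all epochs), not peaks only.
    Retained peaks satisfy GFP <= mean + sd_mult*SD and GFP strictly
    above the ``low_pct`` percentile.  Either criterion can be disabled
    by passing ``None``.
    """
    gfp = np.atleast_2d(np.asarray(gfp, dtype=float))
    flat = gfp.ravel()
    hi = np.inf if sd_mult is None else flat.mean() + sd_mult * flat.std()
    lo = -np.inf if low_pct is None else np.percentile(flat, low_pct)
    out = []
    for e, idx in enumerate(peaks):
        vals = gfp[e, idx]
        out.append(idx[(vals <= hi) & (vals > lo)])
    if sum(len(i) for i in out) == 0 and sum(len(i) for i in peaks) > 0:
        warnings.warn("all GFP peaks removed by the filtering criteria")
    return out


def extract_peaks(ep: EpochedEEG, min_distance: int = 2,
                  sd_mult: float | None = 1.0,
                  low_pct: float | None = 15.0) -> PeakSet:
    """Detect, filter and collect peak topographies for one participant."""
    gfp = compute_gfp(ep)
    peaks = filter_peaks(gfp, find_peaks(gfp, min_distance), sd_mult, low_pct)
    topos, gvals, src = [], [], []
    for e, idx in enumerate(peaks):
        for s in idx:
            topos.append(ep.data[e, :, s])
            gvals.append(gfp[e, s])
            src.append((e, s))
    if not topos:
        return PeakSet(np.empty((0, ep.n_channels)), np.empty(0),
                       np.empty((0, 2), dtype=int))
    return PeakSet(np.array(topos), np.array(gvals), np.array(src))


def subsample(ps: PeakSet, max_n: int = 100_000, seed: int = 0) -> PeakSet:
    """Uniform random subset of at most ``max_n`` peaks, order-preserving."""
    if ps.n_peaks <= max_n:
        return ps
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(ps.n_peaks, size=max_n, replace=False))
    return PeakSet(ps.topographies[keep], ps.gfp[keep], ps.source[keep])
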