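"""Back-fitting group maps to EEG and smoothing the label sequence.

Every sample (not only GFP peaks) is assigned the map with the lowest
global map dissimilarity (GMD) — equivalently the highest squared
spatial correlation — giving the segmentation from which all dynamic
markers are computed.  A window-smoothing pass then removes
single-sample label intrusions caused by noise, trading per-sample fit
against agreement with neighboring labels.
"""

from __future__ import annotations

import numpy as np

from .cluster import spatial_correlation
from .data import EpochedEEG, MapSet, Segmentation

__all__ = ["gmd", "backfit", "smooth"]

_GFP_EPS = 1e-9


def gmd(u: np.ndarray, v: np.ndarray) -> float:
    """Global map dissimilarity between two topographies.

    Both maps are average-referenced and scaled to unit GFP; the GMD is
    the root-mean-square difference, minimized over polarity.  It is 0
    for identical or polarity-flipped maps and sqrt(2) for orthogonal
    ones, and is invariant to signal strength.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    u = u - u.mean()
    v = v - v.mean()
    gu, gv = u.std(), v.std()
    if gu < _GFP_EPS or gv < _GFP_EPS:
        raise ValueError("GMD undefined for zero-GFP topography")
    u, v = u / gu, v / gv
    d_plus = np.sqrt(np.mean((u - v) ** 2))
    d_minus = np.sqrt(np.mean((u + v) ** 2))
    return float(min(d_plus, d_minus))


def _corr_per_sample(ep: EpochedEEG, ms: MapSet) -> tuple[np.ndarray, np.ndarray]:
    """(corr, gfp): corr is (epochs, samples, k), gfp is (epochs, samples)."""
    if ep.n_channels != ms.n_channels:
        raise ValueError("channel spaces of epochs and maps differ")
    X = ep.stacked()                           # (E*S, C)
    gfp = X.std(axis=1)
    corr = spatial_correlation(ms.maps, X).T   # (E*S, k)
    corr = corr.reshape(ep.n_epochs, ep.n_samples, ms.k)
    return corr, gfp.reshape(ep.n_epochs, ep.n_samples)


def backfit(ep: EpochedEEG, ms: MapSet) -> Segmentation:
    """Label every sample with its minimal-GMD map.

    Minimizing GMD over polarity equals maximizing the squared spatial
    correlation, which is what is computed.  Ties break toward the
    lowest map index.  Samples with near-zero GFP (below 1e-9 uV, where
    GMD is undefined) inherit the previous sample's label; a leading
    run of such samples takes the first defined label of the epoch.
    """
    corr, gfp = _corr_per_sample(ep, ms)
    labels = np.argmax(corr * corr, axis=2)
    defined = gfp >= _GFP_EPS
    for e in range(ep.n_epochs):
        if not defined[e].any():
            labels[e] = 0
            continue
        first = int(np.argmax(defined[e]))
        labels[e, :first] = labels[e, first]
        for s in range(first + 1, ep.n_samples):
            if not defined[e, s]:
                labels[e, s] = labels[e, s - 1]
    return Segmentation(labels, k=ms.k, sfreq=ep.sfreq)


def smooth(seg: Segmentation, ep: EpochedEEG, ms: MapSet,
           half_window: int = 3, penalty: float = 5.0,
           max_passes: int = 1000) -> Segmentation:
    """Window smoothing of a segmentation.

    Iteratively relabels each sample to minimize the unexplained
    variance fraction (1 - corr^2 with the candidate map) minus
    ``penalty`` times the number of same-label neighbors within
    ``+/- half_window`` samples, until no label changes (or
    ``max_passes``).  Epochs are smoothed independently.  With
    ``penalty=0`` the result equals the back-fit labels.  Samples with
    near-zero GFP keep their inherited back-fit label.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    corr, gfp = _corr_per_sample(ep, ms)
    unexplained = 1.0 - corr * corr            # (E, S, k)
    defined = gfp >= _GFP_EPS
    kernel = np.ones(2 * half_window + 1)
    kernel[half_window] = 0.0                  # a sample is not its own neighbor
    labels = seg.labels.copy()
    k = ms.k
    for e in range(seg.n_epochs):
        lab = labels[e]
        for _ in range(max_passes):
            onehot = np.zeros((seg.n_samples, k))
            onehot[np.arange(seg.n_samples), lab] = 1.0
            neighbors = np.column_stack([
                np.convolve(onehot[:, c], kernel, mode="same")
                for c in range(k)
            ])
            score = unexplained[e] - penalty * neighbors
            new = np.argmin(score, axis=1)
            new[~defined[e]] = lab[~defined[e]]
            if np.array_equal(new, lab):
                break
            lab = new
        labels[e] = lab
    return Segmentation(labels, k=seg.k, sfreq=seg.sfreq, map_ref=seg.map_ref)
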