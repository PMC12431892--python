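"""Polarity-invariant modified k-means and three-level group clustering.

Microstate topographies of opposite polarity belong to the same class,
so ordinary k-means (which separates x from -x) does not apply.  The
modified algorithm assigns each topography to the prototype maximizing
the *squared* spatial correlation and updates each prototype as the
dominant eigenvector of the assigned topographies' outer-product sum
(their first principal axis) — both steps are sign-blind.

Group-level maps come from a three-level scheme: per-participant
clustering into k1 maps, bootstrap iterations that resample
participants (with replacement, balanced across groups), pooling and
re-clustering their maps into k2, and a final clustering of all
bootstrap maps into the k2 group maps.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .data import MapSet, PeakSet

__all__ = [
    "ModifiedKMeans",
    "mod_kmeans",
    "multilevel_cluster",
    "order_canonical",
    "spatial_correlation",
]

logger = logging.getLogger(__name__)


def _as_array(X) -> np.ndarray:
    if isinstance(X, PeakSet):
        X = X.topographies
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D array of topographies")
    return X


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=1, keepdims=True)


def _fix_sign(m: np.ndarray) -> np.ndarray:
    """Display-only sign convention: largest-|loading| channel positive."""
    i = int(np.argmax(np.abs(m)))
    return m if m[i] >= 0 else -m


def spatial_correlation(maps: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels, shape (k, n_samples).

    Both inputs are average-referenced and L2-normalized internally, so
    the result is the cosine of the angle between zero-mean topographies.
    """
    M = _center(np.atleast_2d(maps))
    M = M / np.linalg.norm(M, axis=1, keepdims=True)
    V = _center(np.atleast_2d(X))
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return M @ (V / norms).T


class ModifiedKMeans(ClusterMixin, BaseEstimator):
    """Polarity-invariant modified k-means over topographies.

    Parameters
    ----------
    n_clusters : int
        Number of microstate maps (k).
    n_init : int
        Random restarts; the restart with the highest global explained
        variance (GEV) on the training peaks wins.
    max_iter : int
        Iteration cap per restart.
    tol : float
        Convergence threshold on the relative change of the residual
        variance between iterations.
    random_state : int | numpy Generator | None
        Seed for the restarts; a fixed seed makes the fit bit-reproducible.

    Attributes
    ----------
    maps_ : ndarray of shape (n_clusters, n_channels)
        Zero-mean, unit-norm prototype topographies.
    labels_ : ndarray
        Training-peak assignments (polarity-invariant).
    gev_ : float
        GEV of the winning restart on the training peaks.
    n_iter_ : int
        Iterations used by the winning restart.
    """

    def __init__(self, n_clusters: int = 4, n_init: int = 100,
                 max_iter: int = 300, tol: float = 1e-6,
                 random_state=None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _single_run(self, X: np.ndarray, rng: np.random.Generator):
        n, _ = X.shape
        k = self.n_clusters
        idx = rng.choice(n, size=k, replace=False)
        maps = _center(X[idx].copy())
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
        total_ss = float(np.sum(X * X))
        prev_resid = np.inf
        labels = np.zeros(n, dtype=int)
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            act = maps @ X.T                      # (k, n) signed activations
            labels = np.argmax(act * act, axis=0)
            for c in range(k):
                sel = labels == c
                if not np.any(sel):
                    logger.debug("re-seeding empty cluster %d", c)
                    j = rng.integers(n)
                    m = X[j] - X[j].mean()
                    nrm = np.linalg.norm(m)
                    maps[c] = m / nrm if nrm else maps[c]
                    continue
                Xc = X[sel]
                S = Xc.T @ Xc
                vals, vecs = np.linalg.eigh(S)
                maps[c] = vecs[:, -1]
            act = maps @ X.T
            labels = np.argmax(act * act, axis=0)
            chosen = act[labels, np.arange(n)]
            resid = total_ss - float(np.sum(chosen * chosen))
            if prev_resid < np.inf and prev_resid > 0:
                if abs(prev_resid - resid) / prev_resid < self.tol:
                    break
            elif prev_resid == 0:
                break
            prev_resid = resid
        return maps, labels, n_iter

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Cluster peak topographies; X is (n_peaks, n_channels) or a PeakSet."""
        X = _center(_as_array(X))
        n = X.shape[0]
        if n < self.n_clusters:
            raise ValueError(
                f"need at least n_clusters={self.n_clusters} topographies, got {n}")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            maps, labels, n_iter = self._single_run(X, rng)
            g = _gev(X, maps, labels)
            if best is None or g > best[0]:
                best = (g, maps, labels, n_iter)
        g, maps, labels, n_iter = best
        maps = np.array([_fix_sign(m / np.linalg.norm(m)) for m in _center(maps)])
        self.maps_ = maps
        self.labels_ = labels
        self.gev_ = float(g)
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Assign each topography to its best map, sign-blind."""
        check_is_fitted(self, "maps_")
        corr = spatial_correlation(self.maps_, _as_array(X))
        return np.argmax(corr * corr, axis=0)

    def transform(self, X) -> np.ndarray:
        """|spatial correlation| of each topography with each map."""
        check_is_fitted(self, "maps_")
        return np.abs(spatial_correlation(self.maps_, _as_array(X))).T

    def to_mapset(self) -> MapSet:
        check_is_fitted(self, "maps_")
        return MapSet(self.maps_.copy(), gev_train=self.gev_)


def _gev(X: np.ndarray, maps: np.ndarray, labels: np.ndarray) -> float:
    """GEV of assigned maps on zero-mean topographies X."""
    C = X.shape[1]
    gfp2 = X.var(axis=1)                       # spatial variance per sample
    corr = spatial_correlation(maps, X)
    r = corr[labels, np.arange(X.shape[0])]
    denom = gfp2.sum()
    if denom == 0:
        return 0.0
    return float(np.sum(gfp2 * r * r) / denom)


def mod_kmeans(ps: PeakSet | np.ndarray, k: int = 4, n_init: int = 100,
               max_iter: int = 300, tol: float = 1e-6, seed=None) -> MapSet:
    """Functional wrapper over :class:`ModifiedKMeans`."""
    est = ModifiedKMeans(n_clusters=k, n_init=n_init, max_iter=max_iter,
                         tol=tol, random_state=seed)
    return est.fit(ps).to_mapset()


def multilevel_cluster(participant_peaks: list, groups: list | None = None,
                       k1: int = 10, k2: int = 4, n_boot: int = 2000,
                       boot_size: int | None = None, seed=0,
                       n_init_subject: int = 20, n_init_boot: int = 20,
                       n_init_final: int = 100,
                       per_group_sampling: bool = True,
                       return_intermediate: bool = False):
    """Three-level bootstrap clustering to group-level maps.

    Stage 1 clusters each participant's peaks into ``k1`` maps.  Stage 2
    runs ``n_boot`` bootstrap iterations, each drawing ``boot_size``
    participants with replacement from *every* group (balancing uneven
    group sizes), pooling their stage-1 maps and clustering into ``k2``.
    Stage 3 clusters the ``k2 * n_boot`` stage-2 maps into the final
    ``k2`` group maps.

    ``boot_size`` defaults to the smallest group size.  With
    ``per_group_sampling=False`` stage 2 instead draws from the pooled
    cohort.
    """
    n_part = len(participant_peaks)
    if n_part == 0:
        raise ValueError("no participants")
    if groups is None:
        groups = ["all"] * n_part
    if len(groups) != n_part:
        raise ValueError("one group label per participant required")
    group_ids: dict = {}
    for i, g in enumerate(groups):
        group_ids.setdefault(g, []).append(i)
    if any(len(v) == 0 for v in group_ids.values()):
        raise ValueError("empty group")
    if boot_size is None:
        boot_size = min(len(v) for v in group_ids.values())

    ss = np.random.SeedSequence(seed)
    subject_seeds, boot_seed, final_seed = ss.spawn(3)
    subj_rngs = subject_seeds.spawn(n_part)

    stage1 = [
        mod_kmeans(ps, k=k1, n_init=n_init_subject,
                   seed=np.random.default_rng(s)).maps
        for ps, s in zip(participant_peaks, subj_rngs)
    ]

    rng = np.random.default_rng(boot_seed)
    stage2 = []
    for _ in range(n_boot):
        if per_group_sampling:
            chosen = [i for idxs in group_ids.values()
                      for i in rng.choice(idxs, size=boot_size, replace=True)]
        else:
            chosen = list(rng.choice(n_part, size=boot_size, replace=True))
        pooled = np.vstack([stage1[i] for i in chosen])
        ms = mod_kmeans(pooled, k=k2, n_init=n_init_boot, seed=rng)
        stage2.append(ms.maps)
    stage2_arr = np.vstack(stage2)             # (k2 * n_boot, channels)

    final = mod_kmeans(stage2_arr, k=k2, n_init=n_init_final,
                       seed=np.random.default_rng(final_seed))
    if return_intermediate:
        return final, stage2_arr
    return final


def order_canonical(ms: MapSet, templates: MapSet) -> MapSet:
    """Relabel maps onto canonical templates by optimal assignment.

    Solves the one-to-one assignment maximizing the total |spatial
    correlation| (Hungarian method) and reorders the maps so that map i
    carries the i-th template's label.
    """
    if ms.k != templates.k:
        raise ValueError("template count must match map count")
    corr = np.abs(spatial_correlation(templates.maps, ms.maps))  # (k_t, k_m)
    row, col = linear_sum_assignment(-corr)
    order = np.empty(ms.k, dtype=int)
    order[row] = col
    labels = (templates.canonical_labels
              or [str(i) for i in range(templates.k)])
    return MapSet(ms.maps[order], canonical_labels=list(labels),
                  gev_train=ms.gev_train)
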