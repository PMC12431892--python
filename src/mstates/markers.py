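"""Static and dynamic microstate markers.

Static markers are blind to temporal order: the coverage of each map
(fraction of samples it dominates), the Shannon entropy of the
coverage distribution, and the global explained variance (GEV) of the
map set.  Dynamic markers depend on the sequence: mean microstate
duration (MMD) and its variance (MDV), the sample-wise transition
matrix, and the entropy production

    EP = sum_ij P_ij * ln(P_ij / P_ji)

which is zero exactly when the transition probabilities obey detailed
balance (P_ij = P_ji on the support) and grows with the asymmetry of
the microstate flow — a signature of temporally irreversible dynamics.
All entropies are reported in nats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cluster import spatial_correlation
from .data import EpochedEEG, MapSet, Segmentation, TransitionMatrix

__all__ = [
    "coverage",
    "coverage_entropy",
    "gev",
    "run_durations",
    "mmd_mdv",
    "transition_matrix",
    "entropy_production",
    "MarkerRecord",
    "compute_markers",
]


def coverage(seg: Segmentation) -> np.ndarray:
    """Fraction of all labeled samples occupied by each map; sums to 1."""
    if seg.labels.size == 0:
        raise ValueError("empty segmentation")
    counts = np.bincount(seg.labels.ravel(), minlength=seg.k)
    return counts / counts.sum()


def coverage_entropy(cov: np.ndarray) -> float:
    """Shannon entropy (nats) of a coverage distribution; max is ln(k)."""
    cov = np.asarray(cov, dtype=float)
    if np.any(cov < 0):
        raise ValueError("coverage entries must be non-negative")
    if abs(cov.sum() - 1.0) > 1e-9:
        raise ValueError("coverage must sum to 1")
    nz = cov[cov > 0]
    return float(-np.sum(nz * np.log(nz)))


def gev(ep: EpochedEEG, seg: Segmentation, ms: MapSet
        ) -> tuple[np.ndarray, float]:
    """Global explained variance of the assigned maps.

    gev_total = sum_t GFP_t^2 * corr(v_t, map_{L_t})^2 / sum_t GFP_t^2;
    the per-map vector restricts the numerator to that map's samples
    (same denominator), so the per-map values sum to the total.
    """
    if ep.data.shape[:1] + ep.data.shape[2:] != (seg.n_epochs, seg.n_samples):
        raise ValueError("segmentation shape does not match the epochs")
    X = ep.stacked()
    lab = seg.labels.ravel()
    gfp2 = X.var(axis=1)
    denom = gfp2.sum()
    if denom == 0:
        raise ValueError("zero total GFP")
    corr = spatial_correlation(ms.maps, X)     # (k, n)
    r = corr[lab, np.arange(X.shape[0])]
    contrib = gfp2 * r * r
    per_map = np.array([contrib[lab == c].sum() for c in range(ms.k)]) / denom
    return per_map, float(per_map.sum())


def run_durations(seg: Segmentation) -> list[tuple[int, float]]:
    """Maximal constant-label runs as (map, duration_ms).

    Runs never span epoch boundaries; runs truncated by a boundary are
    included.  One sample lasts 1000/sfreq ms.
    """
    ms_per_sample = 1000.0 / seg.sfreq
    out: list[tuple[int, float]] = []
    for row in seg.labels:
        change = np.flatnonzero(np.diff(row) != 0)
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change, [row.size - 1]])
        for s, e in zip(starts, ends):
            out.append((int(row[s]), (e - s + 1) * ms_per_sample))
    return out


def mmd_mdv(durs: list[tuple[int, float]]
            ) -> tuple[float, float, dict[int, float], dict[int, float]]:
    """Pooled mean and population variance of run durations (ms, ms^2).

    Returns ``(mmd, mdv, mmd_per_map, mdv_per_map)``.  With fewer than
    two runs the variance is undefined and reported as NaN.
    """
    if not durs:
        raise ValueError("no runs")
    values = np.array([d for _, d in durs])
    mmd = float(values.mean())
    mdv = float(values.var()) if values.size >= 2 else float("nan")
    if values.size < 2:
        warnings.warn("fewer than 2 runs: duration variance undefined")
    per_mean: dict[int, float] = {}
    per_var: dict[int, float] = {}
    for m in sorted({m for m, _ in durs}):
        v = np.array([d for mm, d in durs if mm == m])
        per_mean[m] = float(v.mean())
        per_var[m] = float(v.var()) if v.size >= 2 else float("nan")
    return mmd, mdv, per_mean, per_var


def transition_matrix(seg: Segmentation, include_self: bool = True
                      ) -> TransitionMatrix:
    """Sample-wise transition probabilities between maps.

    Counts consecutive-sample label pairs within epochs (never across
    epoch boundaries) and normalizes each row.  With
    ``include_self=False`` only label *changes* are counted, i.e. the
    matrix is conditioned on leaving the current map.
    """
    if seg.n_samples < 2:
        raise ValueError("need at least 2 samples per epoch")
    k = seg.k
    counts = np.zeros((k, k), dtype=np.int64)
    for row in seg.labels:
        np.add.at(counts, (row[:-1], row[1:]), 1)
    if not include_self:
        counts = counts.copy()
        np.fill_diagonal(counts, 0)
    P = np.zeros((k, k), dtype=float)
    undefined = []
    for i in range(k):
        s = counts[i].sum()
        if s == 0:
            undefined.append(i)
        else:
            P[i] = counts[i] / s
    return TransitionMatrix(P=P, counts=counts, undefined_rows=undefined)


def entropy_production(tm: TransitionMatrix | np.ndarray,
                       regularize: bool = False) -> float:
    """Entropy production of a transition matrix, in nats.

    EP = sum over ordered pairs (i, j) of P_ij * ln(P_ij / P_ji),
    restricted to pairs where both directions have positive
    probability; diagonal terms contribute zero.  EP >= 0, with
    equality iff P is symmetric on its support.  Pairs with one-sided
    zero probability would make EP infinite under the plug-in estimate
    and are instead excluded with an irreversible-pair warning.

    With ``regularize=True`` (requires count data) every count is
    incremented by 1/total_transitions before normalizing, so no
    estimated probability is exactly zero.
    """
    if isinstance(tm, TransitionMatrix):
        P = tm.P
        counts = np.asarray(tm.counts, dtype=float)
    else:
        P = np.asarray(tm, dtype=float)
        counts = None
        if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("P must be row-stochastic")
    if regularize:
        if counts is None or counts.sum() == 0:
            raise ValueError("regularization requires transition counts")
        c = counts + 1.0 / counts.sum()
        P = c / c.sum(axis=1, keepdims=True)
    k = P.shape[0]
    ep = 0.0
    n_irreversible = 0
    for i in range(k):
        for j in range(k):
            if i == j or P[i, j] <= 0:
                continue
            if P[j, i] <= 0:
                n_irreversible += 1
                continue
            ep += P[i, j] * np.log(P[i, j] / P[j, i])
    if n_irreversible:
        warnings.warn(
            f"{n_irreversible} one-way transition pair(s) excluded from EP")
    return float(ep)


@dataclass
class MarkerRecord:
    """All marker values for one participant, one row of the group table."""

    participant: str
    group: str
    coverage: np.ndarray
    coverage_entropy: float
    gev_per_map: np.ndarray
    gev_total: float
    mmd: float
    mdv: float
    ep: float
    mmd_per_map: dict[int, float] = field(default_factory=dict)
    mdv_per_map: dict[int, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "participant": self.participant,
            "group": self.group,
            "coverage_entropy": self.coverage_entropy,
            "gev_total": self.gev_total,
            "mmd": self.mmd,
            "mdv": self.mdv,
            "ep": self.ep,
        }
        for i, c in enumerate(self.coverage):
            d[f"coverage_{i}"] = float(c)
        for i, g in enumerate(self.gev_per_map):
            d[f"gev_{i}"] = float(g)
        return d


def compute_markers(ep: EpochedEEG, seg: Segmentation, ms: MapSet,
                    participant: str = "", group: str = "",
                    include_self: bool = True) -> MarkerRecord:
    """Evaluate the full marker set for one participant."""
    cov = coverage(seg)
    per_map, total = gev(ep, seg, ms)
    durs = run_durations(seg)
    mmd, mdv, mmd_pm, mdv_pm = mmd_mdv(durs)
    tm = transition_matrix(seg, include_self=include_self)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        e = entropy_production(tm)
    return MarkerRecord(
        participant=participant, group=group, coverage=cov,
        coverage_entropy=coverage_entropy(cov), gev_per_map=per_map,
        gev_total=total, mmd=mmd, mdv=mdv, ep=e,
        mmd_per_map=mmd_pm, mdv_per_map=mdv_pm)
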