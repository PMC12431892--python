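"""Core data containers shared across the pipeline.

The pipeline's common currency is the :class:`EpochedEEG` — an
``epochs x channels x samples`` voltage array with its sampling rate and
2-D sensor layout.  Clustering produces a :class:`MapSet` of unit-norm
microstate topographies; back-fitting produces a :class:`Segmentation`
of per-sample integer labels, from which all dynamic markers derive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SensorLayout",
    "RawEEG",
    "EpochedEEG",
    "PeakSet",
    "MapSet",
    "Segmentation",
    "TransitionMatrix",
    "GroundTruth",
    "grid_layout",
]


@dataclass
class SensorLayout:
    """Sensor names, 2-D head-plane positions and peripheral flags.

    Positions are a unitless projection of the head surface onto the
    plane: x runs left (negative) to right (positive), y runs posterior
    (negative) to anterior (positive).
    """

    ch_names: list[str]
    positions: np.ndarray  # (n_channels, 2)
    edge_flags: np.ndarray  # (n_channels,) bool

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.edge_flags = np.asarray(self.edge_flags, dtype=bool)
        n = len(self.ch_names)
        if n < 8:
            raise ValueError(f"layout needs at least 8 channels, got {n}")
        if self.positions.shape != (n, 2):
            raise ValueError("positions must be (n_channels, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("sensor positions must be finite")
        if self.edge_flags.shape != (n,):
            raise ValueError("edge_flags must be one boolean per channel")

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def subset(self, mask: np.ndarray) -> "SensorLayout":
        """Layout restricted to the channels where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        names = [c for c, m in zip(self.ch_names, mask) if m]
        return SensorLayout(names, self.positions[mask], self.edge_flags[mask])


def grid_layout(n_channels: int = 64, extent: float = 1.0) -> SensorLayout:
    """Regular square grid of sensors on the head plane.

    ``n_channels`` must be a perfect square (the default 64 gives an
    8 x 8 grid).  Channels on the outer ring of the grid are flagged as
    edge channels.
    """
    side = int(round(np.sqrt(n_channels)))
    if side * side != n_channels:
        raise ValueError(f"n_channels must be a perfect square, got {n_channels}")
    coords = np.linspace(-extent, extent, side)
    xx, yy = np.meshgrid(coords, coords)
    positions = np.column_stack([xx.ravel(), yy.ravel()])
    edge = (
        (np.abs(positions[:, 0]) >= extent - 1e-12)
        | (np.abs(positions[:, 1]) >= extent - 1e-12)
    )
    names = [f"E{i + 1:03d}" for i in range(n_channels)]
    return SensorLayout(names, positions, edge)


@dataclass
class RawEEG:
    """A continuous multichannel recording with stimulus events."""

    data: np.ndarray  # (n_channels, n_samples), microvolts
    sfreq: float
    layout: SensorLayout
    events: np.ndarray  # sample indices of stimulus onsets

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.data.ndim != 2:
            raise ValueError("raw data must be (channels, samples)")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError("data/layout channel mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("raw data must be finite")
        if self.events.size and (
            self.events.min() < 0 or self.events.max() >= self.data.shape[1]
        ):
            raise ValueError("events fall outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochedEEG:
    """Epoched voltages: ``(epochs, channels, samples)`` in microvolts."""

    data: np.ndarray
    sfreq: float
    layout: SensorLayout
    tmin: float = 0.0
    channel_mask: np.ndarray | None = None
    epoch_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be (epochs, channels, samples)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")
        if self.tmin > 0:
            raise ValueError("tmin must be <= 0 (pre-stimulus baseline)")
        if self.data.shape[1] != self.layout.n_channels:
            raise ValueError("data/layout channel mismatch")
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.data.shape[1], dtype=bool)
        else:
            self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
            if self.channel_mask.sum() != self.data.shape[1]:
                raise ValueError("channel_mask inconsistent with data shape")
        if self.epoch_mask is None:
            self.epoch_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.epoch_mask = np.asarray(self.epoch_mask, dtype=bool)
            if self.epoch_mask.sum() != self.data.shape[0]:
                raise ValueError("epoch_mask inconsistent with data shape")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy_with(self, **changes) -> "EpochedEEG":
        return replace(self, **changes)

    def stacked(self) -> np.ndarray:
        """All samples pooled over epochs: ``(epochs * samples, channels)``."""
        return self.data.transpose(0, 2, 1).reshape(-1, self.n_channels)


@dataclass
class PeakSet:
    """Topographies extracted at GFP peaks.

    ``topographies`` is ``(n_peaks, n_channels)``; ``source`` holds the
    (epoch, sample) provenance of each peak.
    """

    topographies: np.ndarray
    gfp: np.ndarray
    source: np.ndarray  # (n_peaks, 2) of (epoch, sample)

    def __post_init__(self) -> None:
        self.topographies = np.atleast_2d(np.asarray(self.topographies, dtype=float))
        self.gfp = np.asarray(self.gfp, dtype=float)
        self.source = np.asarray(self.source, dtype=int).reshape(-1, 2)
        if self.topographies.shape[0] != self.gfp.shape[0]:
            raise ValueError("gfp/topography count mismatch")
        if self.source.shape[0] != self.gfp.shape[0]:
            raise ValueError("source/topography count mismatch")

    @property
    def n_peaks(self) -> int:
        return self.topographies.shape[0]


@dataclass
class MapSet:
    """k microstate topographies, each zero-mean and unit-norm."""

    maps: np.ndarray  # (k, n_channels)
    canonical_labels: list[str] | None = None
    gev_train: float | None = None

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        norms = np.linalg.norm(self.maps, axis=1)
        means = self.maps.mean(axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("maps must be unit-norm")
        if not np.allclose(means, 0.0, atol=1e-9):
            raise ValueError("maps must be zero-mean across channels")
        if self.canonical_labels is not None and len(self.canonical_labels) != self.k:
            raise ValueError("one canonical label per map required")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class Segmentation:
    """Per-epoch, per-sample microstate labels in ``[0, k)``."""

    labels: np.ndarray  # (n_epochs, n_samples), int
    k: int
    sfreq: float
    map_ref: str = ""

    def __post_init__(self) -> None:
        self.labels = np.atleast_2d(np.asarray(self.labels, dtype=int))
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.k
        ):
            raise ValueError("labels out of range [0, k)")
        if self.sfreq <= 0:
            raise ValueError("sfreq must be positive")

    @property
    def n_epochs(self) -> int:
        return self.labels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.labels.shape[1]


@dataclass
class TransitionMatrix:
    """Row-stochastic sample-wise transition probabilities.

    ``P[i, j]`` is the probability that map ``i`` at one sample is
    followed by map ``j`` at the next (within the same epoch).  Rows
    whose source map never occurs have zero counts and are listed in
    ``undefined_rows``; their probability rows are left at zero.
    """

    P: np.ndarray
    counts: np.ndarray
    undefined_rows: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.counts = np.asarray(self.counts)
        k = self.P.shape[0]
        if self.P.shape != (k, k) or self.counts.shape != (k, k):
            raise ValueError("P and counts must be square and same shape")
        if np.any(self.P < -1e-15):
            raise ValueError("transition probabilities must be non-negative")
        row_sums = self.P.sum(axis=1)
        for i in range(k):
            if i in self.undefined_rows:
                continue
            if abs(row_sums[i] - 1.0) > 1e-12:
                raise ValueError(f"row {i} of P does not sum to 1")

    @property
    def k(self) -> int:
        return self.P.shape[0]


@dataclass
class GroundTruth:
    """Planted quantities of a synthetic recording (the test oracle)."""

    true_maps: MapSet
    true_labels: np.ndarray  # (n_epochs, n_samples)
    true_transition_matrix: TransitionMatrix | None
    true_mean_duration_ms: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        self.true_labels = np.atleast_2d(np.asarray(self.true_labels, dtype=int))
        k = self.true_maps.k
        if self.true_labels.min() < 0 or self.true_labels.max() >= k:
            raise ValueError("true labels out of range")
        if self.true_mean_duration_ms <= 0:
            raise ValueError("mean duration must be positive")
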