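"""Synthetic EEG with planted microstate structure.

Generates multichannel recordings in which the ground truth — the k
scalp topographies, the sample-level Markov label sequence, and the
noise level — is known exactly, so that every downstream stage
(peak extraction, clustering, back-fitting, markers) can be validated
by parameter recovery.

The signal model is deliberately simple: at each sample one latent map
is active, modulated by a sinusoidal amplitude envelope whose sign
alternates (exercising polarity invariance), plus i.i.d. Gaussian
sensor noise:

    x(t) = A * sin(2*pi*f*t) * m_{s(t)} + noise,   s(t) a Markov chain.

GFP maxima therefore occur at the envelope extrema, where the sample
topography equals the active map up to sign — the regime microstate
clustering assumes.
"""

from __future__ import annotations

import numpy as np

from .data import EpochedEEG, GroundTruth, MapSet, SensorLayout, TransitionMatrix

__all__ = [
    "make_topographies",
    "canonical_templates",
    "sample_state_sequence",
    "stationary_distribution",
    "synthesize_eeg",
    "simulate_participant",
    "amplitude_for_snr",
]

# Canonical map descriptions: A and B are the two diagonal dipolar
# gradients, C is anterior-posterior, D is a frontocentral maximum.
_SQ3 = np.sqrt(3.0) / 2.0
_CANONICAL_DIRECTIONS = {
    # dipole axes 60 degrees apart so the planted maps stay well separated
    "A": (_SQ3, -0.5),    # right-frontal <-> left-posterior diagonal
    "B": (-_SQ3, -0.5),   # left-frontal <-> right-posterior diagonal
    "C": (0.0, -1.0),     # anterior <-> posterior
}


def _normalize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("degenerate (constant) topography")
    return v / n


def _abs_corr(u: np.ndarray, v: np.ndarray) -> float:
    return abs(float(np.dot(_normalize(u), _normalize(v))))


def _smooth_field(layout: SensorLayout, rng: np.random.Generator,
                  scale: float = 0.6) -> np.ndarray:
    """A spatially smooth random field over the sensor positions.

    White noise on the sensors convolved with a Gaussian kernel of
    width ``scale`` (in layout units) — smooth enough to look like a
    plausible scalp potential.
    """
    pos = layout.positions
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    kernel = np.exp(-d2 / (2 * scale**2))
    return kernel @ rng.standard_normal(layout.n_channels)


def canonical_templates(layout: SensorLayout) -> MapSet:
    """The four canonical template maps A-D evaluated on a layout.

    Used both as the deterministic base for planted topographies and as
    the reference for canonical label assignment after clustering.
    """
    pos = layout.positions
    maps = []
    for name in ("A", "B", "C"):
        dx, dy = _CANONICAL_DIRECTIONS[name]
        maps.append(_normalize(pos[:, 0] * dx + pos[:, 1] * dy))
    # D: frontocentral Gaussian bump
    center = np.array([0.0, 0.35])
    d2 = ((pos - center) ** 2).sum(-1)
    maps.append(_normalize(np.exp(-d2 / (2 * 0.35**2))))
    return MapSet(np.array(maps), canonical_labels=["A", "B", "C", "D"])


def make_topographies(layout: SensorLayout, k: int, seed: int,
                      jitter: float = 0.15,
                      max_corr: float = 0.8) -> MapSet:
    """k zero-mean, unit-norm, pairwise non-collinear planted maps.

    The first four maps are seeded perturbations of the canonical A-D
    templates (a smooth random field of relative norm ``jitter`` added
    before renormalization); further maps are smooth random fields
    accepted only if their |spatial correlation| with every previous
    map stays below ``max_corr``.
    """
    if k < 2:
        raise ValueError("need at least k=2 topographies")
    if k > layout.n_channels:
        raise ValueError("k cannot exceed the channel count")
    rng = np.random.default_rng(seed)
    templates = canonical_templates(layout).maps
    maps: list[np.ndarray] = []
    for i in range(min(k, 4)):
        base = templates[i]
        for _ in range(100):
            cand = _normalize(base + jitter * _normalize(_smooth_field(layout, rng)))
            if all(_abs_corr(cand, m) < max_corr for m in maps):
                maps.append(cand)
                break
        else:  # pragma: no cover - jitter small enough in practice
            raise RuntimeError("could not de-correlate canonical topography")
    while len(maps) < k:
        for _ in range(1000):
            cand = _normalize(_smooth_field(layout, rng))
            if all(_abs_corr(cand, m) < max_corr for m in maps):
                maps.append(cand)
                break
        else:
            raise RuntimeError(f"could not draw {k} mutually non-collinear maps")
    labels = ["A", "B", "C", "D"][: min(k, 4)] + [
        f"M{i}" for i in range(4, k)
    ]
    return MapSet(np.array(maps), canonical_labels=labels)


def _validate_stochastic(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition matrix must be row-stochastic")
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi P = pi (left eigenvector)."""
    P = _validate_stochastic(P)
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def sample_state_sequence(P: np.ndarray, n_samples: int, seed) -> np.ndarray:
    """Realize a first-order Markov chain from a row-stochastic P.

    The initial state is drawn from the stationary distribution, so the
    chain is stationary from the first sample.
    """
    P = _validate_stochastic(P)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    k = P.shape[0]
    cdf = np.cumsum(P, axis=1)
    seq = np.empty(n_samples, dtype=int)
    seq[0] = rng.choice(k, p=stationary_distribution(P))
    u = rng.random(n_samples - 1)
    for t in range(1, n_samples):
        seq[t] = np.searchsorted(cdf[seq[t - 1]], u[t - 1], side="right")
    return seq


def amplitude_for_snr(snr: float, n_channels: int, noise_sd: float) -> float:
    """Envelope amplitude giving a peak signal-GFP / noise-GFP ratio of ``snr``.

    A unit-norm zero-mean map over C channels has spatial SD 1/sqrt(C),
    so at an envelope extremum the signal GFP is amplitude/sqrt(C)
    while the expected noise GFP is noise_sd.
    """
    return snr * np.sqrt(n_channels) * noise_sd


def _mean_run_duration_ms(labels: np.ndarray, sfreq: float) -> float:
    durs = []
    for row in np.atleast_2d(labels):
        change = np.flatnonzero(np.diff(row) != 0)
        bounds = np.concatenate([[-1], change, [row.size - 1]])
        durs.extend(np.diff(bounds))
    return float(np.mean(durs) * 1000.0 / sfreq)


def synthesize_eeg(maps: MapSet, labels: np.ndarray, sfreq: float = 250.0,
                   osc_freq: float = 10.0, amplitude: float = 40.0,
                   noise_sd: float = 1.0, epoch_len: int = 375,
                   seed: int = 0,
                   transition_matrix: np.ndarray | None = None,
                   ) -> tuple[EpochedEEG, GroundTruth]:
    """Render a label sequence into epoched multichannel EEG.

    ``labels`` is a flat sample-level sequence whose length must divide
    into epochs of ``epoch_len`` samples.  The active map is modulated
    by ``amplitude * sin(2*pi*osc_freq*t)`` — polarity alternates every
    half-period — with additive Gaussian sensor noise.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 1 or labels.size == 0:
        raise ValueError("labels must be a non-empty 1-D sequence")
    if labels.size % epoch_len != 0:
        raise ValueError("label sequence length must be divisible by epoch_len")
    if not (0 < osc_freq < sfreq / 2):
        raise ValueError("osc_freq must lie below the Nyquist frequency")
    if amplitude == 0 and noise_sd == 0:
        raise ValueError("amplitude and noise_sd cannot both be zero")
    rng = np.random.default_rng(seed)
    n = labels.size
    t = np.arange(n) / sfreq
    envelope = amplitude * np.sin(2 * np.pi * osc_freq * t)
    signal = envelope[:, None] * maps.maps[labels]  # (n, channels)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    n_epochs = n // epoch_len
    data = signal.reshape(n_epochs, epoch_len, -1).transpose(0, 2, 1)
    layout = _layout_for(maps)
    ep = EpochedEEG(data=data, sfreq=sfreq, layout=layout, tmin=0.0)
    tm = None
    if transition_matrix is not None:
        P = _validate_stochastic(transition_matrix)
        tm = TransitionMatrix(P=P, counts=np.zeros_like(P, dtype=int),
                              undefined_rows=list(range(P.shape[0])))
    truth = GroundTruth(
        true_maps=maps,
        true_labels=labels.reshape(n_epochs, epoch_len),
        true_transition_matrix=tm,
        true_mean_duration_ms=_mean_run_duration_ms(
            labels.reshape(n_epochs, epoch_len), sfreq),
        noise_sd=noise_sd,
        seed=seed,
    )
    return ep, truth


def _layout_for(maps: MapSet) -> SensorLayout:
    side = int(round(np.sqrt(maps.n_channels)))
    if side * side == maps.n_channels:
        from .data import grid_layout

        return grid_layout(maps.n_channels)
    # fall back to a circle of sensors when the count is not square
    theta = np.linspace(0, 2 * np.pi, maps.n_channels, endpoint=False)
    pos = np.column_stack([np.cos(theta), np.sin(theta)])
    return SensorLayout([f"E{i + 1:03d}" for i in range(maps.n_channels)],
                        pos, np.zeros(maps.n_channels, dtype=bool))


def simulate_participant(layout: SensorLayout, P: np.ndarray, *,
                         n_epochs: int = 40, epoch_len: int = 375,
                         sfreq: float = 250.0, osc_freq: float = 10.0,
                         snr: float = 5.0, noise_sd: float = 1.0,
                         map_seed: int = 0, seed: int = 0,
                         maps: MapSet | None = None,
                         ) -> tuple[EpochedEEG, GroundTruth]:
    """One synthetic participant: planted maps + Markov dynamics + noise.

    Convenience wrapper: draws the label chain, renders the EEG at the
    requested peak-GFP signal-to-noise ratio, and returns the recording
    with its ground truth.  Pass ``maps`` to share topographies across
    a simulated cohort.
    """
    P = _validate_stochastic(P)
    if maps is None:
        maps = make_topographies(layout, P.shape[0], seed=map_seed)
    labels = sample_state_sequence(P, n_epochs * epoch_len, seed=seed)
    amplitude = (amplitude_for_snr(snr, layout.n_channels, noise_sd)
                 if noise_sd > 0 else amplitude_for_snr(snr, layout.n_channels, 1.0))
    ep, truth = synthesize_eeg(
        maps, labels, sfreq=sfreq, osc_freq=osc_freq, amplitude=amplitude,
        noise_sd=noise_sd, epoch_len=epoch_len, seed=seed + 1,
        transition_matrix=P)
    ep = ep.copy_with(layout=layout)
    return ep, truth
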