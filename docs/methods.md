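# Methods

## The model

EEG microstates are short periods (≈50–100 ms) during which the scalp
potential topography stays semi-stable before switching abruptly to a
different configuration. The package reduces a multichannel recording
to a sequence of discrete map labels and quantifies the *dynamics* of
that sequence — how long states last, how they transition, and whether
the transition flow is time-reversible.

The processing chain is:

1. **Preprocessing** — band-pass filter (0.5–45 Hz), epoching
   (−200 ms to +1344 ms around stimulus onset), bad-channel detection
   and interpolation, bad-epoch rejection, edge-channel removal,
   average reference.
2. **GFP peak extraction** — the global field power
   `GFP(t) = sd_c(x_c(t))` is the spatial standard deviation of the
   instantaneous topography. Topographies are sampled at GFP local
   maxima (minimum peak distance 2 samples), where the field is
   strongest and most stable; peaks above `mean(GFP) + 1·sd(GFP)` and
   peaks in the lowest 15 % of the GFP distribution are discarded, and
   the remainder is randomly subsampled to at most 100 000 maps.
3. **Clustering** — polarity-invariant modified k-means (k = 4,
   100 random restarts, best restart by global explained variance),
   embedded in a three-level group scheme: 10 maps per participant,
   2000 bootstrap iterations that resample participants with
   replacement (balanced across groups, sample size = smallest group),
   each pooling and re-clustering into 4 maps, and a final clustering
   of the 4×2000 bootstrap maps into the 4 group maps.
4. **Segmentation** — every sample is assigned the group map with
   minimal global map dissimilarity (GMD), then the label sequence is
   window-smoothed to suppress single-sample intrusions.
5. **Markers** — per participant: coverage per map and its Shannon
   entropy, GEV (total and per map), mean microstate duration (MMD),
   duration variance (MDV), the sample-wise transition matrix, and the
   entropy production `EP = Σ_ij P_ij ln(P_ij / P_ji)`.
6. **Group statistics** — pairwise Mann-Whitney U tests with
   Bonferroni correction (family = the pairwise comparisons of one
   marker), and a Spearman rank correlation of each marker against the
   ordinal group coding UWS < MCS < EMCS < HC.

### Polarity invariance

Topographies of opposite sign are the same microstate class. The
modified k-means therefore assigns each topography to the prototype
maximizing the *squared* spatial correlation, and updates each
prototype as the dominant eigenvector of `Σ x xᵀ` over its assigned
topographies (the first principal axis) — both steps are blind to
sign. GMD likewise takes the minimum over the two polarities, giving a
range of [0, √2] with 0 for identical-or-flipped maps.

### Entropy production

For the estimated row-stochastic transition matrix `P`,
`EP = Σ_ij P_ij ln(P_ij / P_ji)` (natural log, nats). Grouping the sum
into unordered pairs gives `(P_ij − P_ji)·ln(P_ij/P_ji) ≥ 0`, so EP is
non-negative and zero exactly under detailed balance (`P_ij = P_ji` on
the support). Diagonal terms cancel, so including or excluding
self-transitions in the *counts* only changes the normalization of the
off-diagonal probabilities; both variants are available
(`include_self`, default true — self-transitions dominate at 250 Hz).
Finite-sample pairs with a one-sided zero would make the plug-in
estimate infinite; they are excluded from the sum and reported via a
warning, and an epsilon-regularized variant (every count incremented
by 1/total transitions) is available behind a flag.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| band pass | 0.5–45 Hz | zero-phase 4th-order Butterworth, forward-backward |
| epoch window | −0.200 … +1.344 s | inclusive endpoints: 387 samples at 250 Hz |
| amplitude criterion | 100 µV in >50 % of epochs | bad channel (peak absolute value; a peak-to-peak switch exists) |
| variance criterion | Z > 4, iterated 4× | bad channel, Z-score over currently good channels |
| epoch rejection | 100 µV in >10 % of channels | bad epoch; >50 % bad epochs flags participant exclusion |
| peak distance | 2 samples | minimum spacing of GFP peaks |
| peak filters | 1 SD above mean; lowest 15 % | computed on the full GFP series, not peaks only |
| k1 / k | 10 / 4 | participant-level and group-level cluster counts |
| n_init | 100 (20 at stage 1/2) | k-means restarts; stage-1/2 restarts reduced for tractability |
| n_boot | 2000 | bootstrap iterations of the group clustering |
| tol / max_iter | 1e-6 / 300 | k-means convergence on relative residual-variance change |
| half_window / penalty | 3 samples / 5 | segmentation smoothing (12 ms at 250 Hz) |
| alpha | 0.05 | significance level, Bonferroni-corrected per marker |

Choices the method description leaves open, fixed here and
configurable: the epoch endpoint convention is inclusive (387 samples);
the amplitude criterion uses peak absolute voltage; bad-channel
interpolation is inverse-distance weighting (exponent 2, 6 nearest
good channels) over the 2-D layout rather than a spherical spline —
adequate for smooth fields at desk scale; the GFP-peak filter
statistics use the full series; MDV is the population (divide-by-n)
variance of the pooled run durations (per-map variants are also
emitted); boundary-truncated runs count toward MMD/MDV (exclusion is
flag-selectable); entropies are in nats; the high-GFP peak-removal
rule can be disabled (`sd_mult=None`) since it is atypical relative to
older practice and, on strongly rhythmic data, can remove most
envelope-extremum peaks.

## The synthetic-data generator

The generator plants known structure so every stage is checkable by
parameter recovery:

* **Maps** — seeded perturbations of four canonical templates on a
  2-D head-plane layout: two diagonal dipolar gradients (the classic
  left-posterior↔right-frontal and right-posterior↔left-frontal
  orientations of maps A and B, 60° apart so they are never
  collinear), an anterior-posterior gradient (C), and a frontocentral
  Gaussian (D). All maps are zero-mean, unit-norm, pairwise
  |correlation| < 0.8. Extra maps beyond four are smooth random
  fields.
* **Dynamics** — a sample-level first-order Markov chain started from
  its stationary distribution. A stay-probability of 0.95 at 250 Hz
  gives geometric run lengths with mean 20 samples = 80 ms, inside the
  physiological 50–100 ms range.
* **Signal** — `x(t) = A·sin(2πft)·m_{s(t)} + ε`, ε i.i.d. Gaussian
  per channel. The rectified-sinusoid envelope (default f = 10 Hz)
  creates GFP maxima every half-period with alternating polarity, so
  the polarity-invariance path is always exercised. SNR is defined as
  peak signal GFP over noise GFP: `amplitude / (√C · noise_sd)`.
* **Default montage** — 64 channels on a regular grid (a 256-channel
  geodesic net is emulated only in geometry class, not count), for
  desk-scale speed; the channel count is a parameter.

What the generator does **not** emulate: forward-modeled cortical
sources, spatially correlated noise, artifacts (blinks, muscle), drift,
or gradual map morphing. Passing recovery tests therefore shows the
estimator chain is correct and polarity-robust, not that real EEG
obeys the discrete-map model.

## Numerical choices

* k-means restarts are seeded from a single `SeedSequence`; a fixed
  seed makes every fit bit-reproducible. Empty clusters are re-seeded
  from a random topography.
* Stored maps use a display-only sign convention (largest-|loading|
  channel positive); no marker depends on it.
* Ties in the polarity-invariant argmax/argmin break toward the lowest
  map index; GFP-peak plateaus peak at their first sample; equal-height
  peaks inside the minimum distance keep the earlier one.
* Samples with near-zero GFP (< 1e-9 µV), where GMD is undefined,
  inherit the previous sample's label and are frozen during smoothing.
* Mann-Whitney uses the exact null for combined n ≤ 20 without ties,
  otherwise the normal approximation with continuity and tie
  correction; a constant pooled sample returns p = 1.
* Canonical A–D labels are assigned by Hungarian matching of
  |spatial correlation| against the template maps.

## Validation problem sizes

The recovery studies use sizes chosen for quick desk runs: chain-level
markers (EP, MMD/MDV, coverage entropy) at 100 000 samples; map
recovery with 8 participants × 40 epochs at SNR 5 and 50 bootstrap
iterations; cohort discrimination with 2 × 10 participants × 6 epochs
and 20 repetitions. At these sizes all planted quantities are
recovered within a few percent (see `scripts/acceptance.py`).

## Known limitations

* Group-level statistics from the original clinical cohorts cannot be
  reproduced here: the patient recordings are not public. Validation
  is property- and recovery-based on synthetic data.
* Inverse-distance interpolation is a simplification of spherical
  splines and will be less accurate for sharply curved fields or large
  contiguous bad-channel patches.
* The window smoothing uses synchronous updates with a pass cap; for
  extreme penalty values it behaves like a neighborhood majority vote,
  which shortens reported durations less than it lengthens them.
* The EP plug-in estimator is biased upward at small sample sizes
  (every finite chain looks slightly irreversible); the bias at the
  default validation sizes is below 0.001 nats for symmetric chains.
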