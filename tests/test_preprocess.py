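"""Preprocessing chain: filtering, epoching, artifact rejection rules."""

import numpy as np
import pytest

from mstates import (EpochedEEG, RawEEG, bandpass, detect_bad_channels,
                     epoch, grid_layout, interpolate_channels,
                     preprocess_pipeline, reject_bad_epochs,
                     rereference_and_trim)


def make_raw(layout, n_samples=5000, sfreq=250.0, events=(1000, 2000, 3000),
             fill=0.0, rng=None):
    data = np.full((layout.n_channels, n_samples), fill, dtype=float)
    if rng is not None:
        data += rng.normal(0, 1, data.shape)
    return RawEEG(data, sfreq, layout, np.array(events))


def make_epochs(layout, data):
    return EpochedEEG(np.asarray(data, float), 250.0, layout, tmin=0.0)


class TestBandpass:
    def setup_method(self):
        self.layout = grid_layout(16)
        self.t = np.arange(5000) / 250.0

    def _rms_ratio(self, freq):
        sig = np.tile(np.sin(2 * np.pi * freq * self.t), (16, 1))
        raw = RawEEG(sig, 250.0, self.layout, np.array([2500]))
        out = bandpass(raw, 0.5, 45.0)
        mid = slice(1000, 4000)  # avoid filter edge transients
        return (np.sqrt(np.mean(out.data[:, mid] ** 2))
                / np.sqrt(np.mean(sig[:, mid] ** 2)))

    def test_stopband_attenuates_100hz(self):
        assert self._rms_ratio(100.0) < 0.05

    def test_passband_preserves_10hz(self):
        assert abs(self._rms_ratio(10.0) - 1.0) < 0.05

    def test_dc_removed(self):
        raw = make_raw(self.layout, fill=7.5)
        out = bandpass(raw)
        assert np.abs(out.data[:, 1000:4000]).max() < 1e-6

    def test_invalid_band_rejected(self):
        raw = make_raw(self.layout)
        with pytest.raises(ValueError):
            bandpass(raw, 45.0, 0.5)
        with pytest.raises(ValueError):
            bandpass(raw, 0.5, 200.0)


class TestEpoch:
    def test_default_window_is_387_samples(self):
        raw = make_raw(grid_layout(16))
        ep = epoch(raw)
        assert ep.n_samples == 387  # (1.344 + 0.200) * 250 + 1, inclusive
        assert ep.tmin == -0.200

    def test_one_epoch_per_event(self):
        raw = make_raw(grid_layout(16), events=tuple(range(500, 4500, 400)))
        assert epoch(raw).n_epochs == 10

    def test_out_of_bounds_event_dropped(self):
        raw = make_raw(grid_layout(16), events=(10, 2000))
        ep = epoch(raw, tmin=-0.2, tmax=1.344)
        assert ep.n_epochs == 1  # the event at sample 10 underruns the start


class TestDetectBadChannels:
    def test_amplitude_criterion_hand_count(self):
        layout = grid_layout(16)
        rng = np.random.default_rng(0)
        data = rng.normal(0, 5, (20, 16, 100))
        data[:12, 3, :] = 150.0  # channel 3 exceeds 100 uV in 60% of epochs
        bad = detect_bad_channels(make_epochs(layout, data), z_thresh=1e9)
        assert bad == [layout.ch_names[3]]

    def test_amplitude_below_fraction_not_flagged(self):
        layout = grid_layout(16)
        rng = np.random.default_rng(0)
        data = rng.normal(0, 5, (20, 16, 100))
        data[:8, 3, :50] = 150.0   # only 40% of epochs
        data[:8, 3, 50:] = -150.0  # keep variance comparable? keep modest
        bad = detect_bad_channels(make_epochs(layout, data), z_thresh=1e9)
        assert bad == []

    def test_homogeneous_channels_clean(self):
        layout = grid_layout(16)
        rng = np.random.default_rng(1)
        data = rng.normal(0, 5, (20, 16, 100))
        assert detect_bad_channels(make_epochs(layout, data)) == []

    def test_variance_criterion_iterates(self):
        # one huge outlier masks a second one until it is removed; with
        # 16 channels the z-score ceiling (n-1)/sqrt(n) < 4 would hide both
        layout = grid_layout(64)
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1, (20, 64, 100))
        data[:, 0, :] *= 40.0  # extreme variance outlier
        data[:, 1, :] *= 15.0  # hidden behind channel 0 in the first pass
        bad = detect_bad_channels(make_epochs(layout, data), amp_thresh=1e9)
        assert layout.ch_names[0] in bad and layout.ch_names[1] in bad

    def test_all_channels_bad_is_an_error(self):
        layout = grid_layout(16)
        data = np.full((10, 16, 50), 500.0)
        with pytest.raises(ValueError):
            detect_bad_channels(make_epochs(layout, data))


class TestInterpolate:
    def test_centroid_of_equal_neighbors(self):
        layout = grid_layout(9)  # 3x3; center channel index 4
        data = np.full((2, 9, 10), 3.0)
        data[:, 4, :] = 99.0
        out = interpolate_channels(make_epochs(layout, data),
                                   [layout.ch_names[4]])
        assert np.allclose(out.data[:, 4, :], 3.0)

    def test_empty_bad_list_is_identity(self):
        layout = grid_layout(9)
        ep = make_epochs(layout, np.random.default_rng(0).normal(size=(2, 9, 10)))
        out = interpolate_channels(ep, [])
        assert out is ep

    def test_linear_gradient_recovered(self):
        layout = grid_layout(64)
        field = 10.0 * layout.positions[:, 0] + 50.0  # linear in x
        data = np.tile(field[None, :, None], (3, 1, 20))
        interior = 27  # an interior channel of the 8x8 grid
        assert not layout.edge_flags[interior]
        data_bad = data.copy()
        data_bad[:, interior, :] = -999.0
        out = interpolate_channels(make_epochs(layout, data_bad),
                                   [layout.ch_names[interior]])
        truth = field[interior]
        assert np.abs(out.data[:, interior, :] - truth).max() <= 0.1 * abs(truth)

    def test_too_few_good_channels(self):
        layout = grid_layout(9)
        ep = make_epochs(layout, np.zeros((1, 9, 5)))
        with pytest.raises(ValueError):
            interpolate_channels(ep, layout.ch_names[:7])


class TestRejectBadEpochs:
    def _epochs_with_bad_channels(self, n_loud):
        layout = grid_layout(100)
        data = np.zeros((1, 100, 50))
        data[0, :n_loud, :] = 150.0
        return make_epochs(layout, data)

    def test_eleven_percent_rejected(self):
        out, report = reject_bad_epochs(self._epochs_with_bad_channels(11))
        assert out.n_epochs == 0 and report.n_bad_epochs == 1

    def test_ten_percent_retained(self):
        out, report = reject_bad_epochs(self._epochs_with_bad_channels(10))
        assert out.n_epochs == 1 and report.n_bad_epochs == 0

    def test_participant_exclusion_flag(self):
        layout = grid_layout(100)
        data = np.zeros((20, 100, 50))
        data[:11, :20, :] = 150.0  # 11 of 20 epochs bad (55% > 50%)
        out, report = reject_bad_epochs(make_epochs(layout, data))
        assert report.n_bad_epochs == 11
        assert report.participant_excluded
        # 10 of 20 (exactly 50%) must NOT exclude
        data2 = np.zeros((20, 100, 50))
        data2[:10, :20, :] = 150.0
        _, report2 = reject_bad_epochs(make_epochs(layout, data2))
        assert not report2.participant_excluded


class TestRereference:
    def test_zero_mean_and_edge_trim(self):
        layout = grid_layout(64)
        rng = np.random.default_rng(3)
        ep = make_epochs(layout, rng.normal(size=(4, 64, 30)))
        out = rereference_and_trim(ep)
        assert out.n_channels == 64 - int(layout.edge_flags.sum())
        assert np.abs(out.data.mean(axis=1)).max() < 1e-10

    def test_idempotent(self):
        layout = grid_layout(64)
        rng = np.random.default_rng(4)
        ep = make_epochs(layout, rng.normal(size=(2, 64, 30)))
        once = rereference_and_trim(ep)
        twice = rereference_and_trim(once)
        assert np.allclose(once.data, twice.data)

    def test_constant_input_maps_to_zero(self):
        layout = grid_layout(36)
        ep = make_epochs(layout, np.full((2, 36, 10), 5.0))
        out = rereference_and_trim(ep)
        assert np.allclose(out.data, 0.0)


def test_full_chain_preserves_time_base():
    layout = grid_layout(36)
    rng = np.random.default_rng(5)
    raw = make_raw(layout, n_samples=4000, events=(1000, 2000, 3000), rng=rng)
    ep, report = preprocess_pipeline(raw)
    assert ep.sfreq == raw.sfreq
    assert ep.n_samples == 387
    assert report.n_epochs_in - report.n_bad_epochs == ep.n_epochs
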