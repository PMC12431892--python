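"""Static and dynamic markers: coverage, entropy, GEV, durations,
transition matrices, entropy production."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mstates import (EpochedEEG, coverage, coverage_entropy,
                     entropy_production, gev, grid_layout, mmd_mdv,
                     run_durations, sample_state_sequence,
                     stationary_distribution, transition_matrix)
from mstates.data import MapSet, Segmentation, TransitionMatrix


def seg_from(labels, k=4, sfreq=250.0):
    return Segmentation(np.atleast_2d(np.asarray(labels, int)), k=k, sfreq=sfreq)


class TestCoverage:
    def test_hand_count(self):
        assert np.allclose(coverage(seg_from([0, 0, 1, 1])),
                           [0.5, 0.5, 0.0, 0.0])

    def test_single_map(self):
        assert np.allclose(coverage(seg_from([2, 2, 2])), [0, 0, 1, 0])

    def test_uniform_chain_quarter_each(self):
        P = np.full((4, 4), 0.25)
        seq = sample_state_sequence(P, 100_000, seed=7)
        cov = coverage(seg_from(seq))
        assert np.abs(cov - 0.25).max() <= 0.01

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        cov = coverage(seg_from(rng.integers(0, 4, (5, 100))))
        assert cov.sum() == pytest.approx(1.0, abs=1e-12)


class TestCoverageEntropy:
    def test_uniform_is_ln_k(self):
        assert coverage_entropy([0.25] * 4) == pytest.approx(np.log(4), abs=1e-12)

    def test_degenerate_is_zero(self):
        assert coverage_entropy([1, 0, 0, 0]) == 0.0

    def test_two_point_uniform(self):
        assert coverage_entropy([0.5, 0.5, 0, 0]) == pytest.approx(
            np.log(2), abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            coverage_entropy([1.2, -0.2, 0, 0])


class TestGEV:
    def _maps(self, rng, k=3, n_ch=16):
        X = rng.normal(size=(k, n_ch))
        X -= X.mean(axis=1, keepdims=True)
        return MapSet(X / np.linalg.norm(X, axis=1, keepdims=True))

    def test_proportional_samples_give_one(self):
        layout = grid_layout(16)
        rng = np.random.default_rng(1)
        ms = self._maps(rng)
        lab = rng.integers(0, 3, 40)
        data = (ms.maps[lab] * rng.uniform(0.5, 3, 40)[:, None]).T[None]
        ep = EpochedEEG(data, 250.0, layout)
        per_map, total = gev(ep, seg_from(lab[None], k=3), ms)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_orthogonal_samples_give_zero(self):
        layout = grid_layout(16)
        rng = np.random.default_rng(2)
        ms = self._maps(rng, k=2)
        # samples orthogonal (as zero-mean vectors) to both maps
        basis = np.linalg.svd(np.vstack([ms.maps, np.ones(16)]))[2][3:]
        data = basis[:1].T[None].repeat(10, axis=2).reshape(1, 16, 10)
        ep = EpochedEEG(data, 250.0, layout)
        _, total = gev(ep, seg_from(np.zeros((1, 10)), k=2), ms)
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        layout = grid_layout(16)
        rng = np.random.default_rng(3)
        ms = self._maps(rng, k=4)
        data = rng.normal(size=(2, 16, 25))
        lab = rng.integers(0, 4, (2, 25))
        per_map, total = gev(EpochedEEG(data, 250.0, layout),
                             seg_from(lab, k=4), ms)
        # direct sample-by-sample evaluation of the definition
        num = np.zeros(4)
        den = 0.0
        for e in range(2):
            for s in range(25):
                v = data[e, :, s]
                g2 = v.var()
                r = np.corrcoef(v, ms.maps[lab[e, s]])[0, 1]
                num[lab[e, s]] += g2 * r * r
                den += g2
        assert np.allclose(per_map, num / den, atol=1e-12)
        assert total == pytest.approx(num.sum() / den, abs=1e-12)

    def test_per_map_sums_to_total(self):
        layout = grid_layout(16)
        rng = np.random.default_rng(4)
        ms = self._maps(rng, k=4)
        data = rng.normal(size=(3, 16, 30))
        lab = rng.integers(0, 4, (3, 30))
        per_map, total = gev(EpochedEEG(data, 250.0, layout),
                             seg_from(lab, k=4), ms)
        assert per_map.sum() == pytest.approx(total, abs=1e-12)


class TestRunDurations:
    def test_hand_count_at_250hz(self):
        durs = run_durations(seg_from([0, 0, 0, 1, 1, 2]))
        assert durs == [(0, 12.0), (1, 8.0), (2, 4.0)]

    def test_full_epoch_single_run(self):
        durs = run_durations(seg_from(np.zeros(387, int)))
        assert durs == [(0, 387 * 4.0)]

    def test_no_cross_epoch_merging(self):
        labels = np.zeros((2, 5), dtype=int)
        durs = run_durations(Segmentation(labels, k=4, sfreq=250.0))
        assert durs == [(0, 20.0), (0, 20.0)]


class TestMmdMdv:
    def test_mean_of_hand_durations(self):
        mmd, mdv, _, _ = mmd_mdv([(0, 12.0), (1, 8.0), (2, 4.0)])
        assert mmd == pytest.approx(8.0)
        assert mdv == pytest.approx(np.var([12, 8, 4]))

    def test_equal_runs_zero_variance(self):
        mmd, mdv, _, _ = mmd_mdv([(0, 8.0)] * 5)
        assert mdv == 0.0

    def test_single_run_variance_undefined(self):
        with pytest.warns(UserWarning):
            _, mdv, _, _ = mmd_mdv([(0, 8.0)])
        assert np.isnan(mdv)

    def test_geometric_durations_recovered(self, sticky4):
        seq = sample_state_sequence(sticky4, 100_000, seed=13)
        durs = run_durations(seg_from(seq))
        mmd, mdv, _, _ = mmd_mdv(durs)
        # stay probability 0.95: geometric run length, mean 20 samples
        assert abs(mmd - 80.0) / 80.0 <= 0.05
        geom_var_ms2 = (0.95 / 0.05**2) * 4.0**2
        assert abs(mdv - geom_var_ms2) / geom_var_ms2 <= 0.10


class TestTransitionMatrix:
    def test_hand_count(self):
        tm = transition_matrix(seg_from([0, 0, 1, 1, 0], k=2))
        assert np.array_equal(tm.counts, [[1, 1], [1, 1]])
        assert np.allclose(tm.P[0], [0.5, 0.5])

    def test_constant_labels(self):
        tm = transition_matrix(seg_from([1, 1, 1, 1], k=3))
        assert tm.P[1, 1] == 1.0
        assert set(tm.undefined_rows) == {0, 2}

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 4, (3, 50))
        tm = transition_matrix(Segmentation(labels, k=4, sfreq=250.0))
        counts = np.zeros((4, 4), dtype=int)
        for row in labels:  # independent loop-based count
            for a, b in zip(row[:-1], row[1:]):
                counts[a, b] += 1
        assert np.array_equal(tm.counts, counts)

    def test_planted_chain_recovered(self, sticky4):
        seq = sample_state_sequence(sticky4, 100_000, seed=17)
        tm = transition_matrix(seg_from(seq))
        assert np.abs(tm.P - sticky4).max() <= 0.01

    def test_switch_only_variant(self):
        tm = transition_matrix(seg_from([0, 0, 1, 1, 0], k=2),
                               include_self=False)
        assert tm.counts[0, 0] == 0 and tm.counts[1, 1] == 0
        assert np.allclose(tm.P, [[0, 1], [1, 0]])

    def test_consistency_with_coverage(self, sticky4):
        # long stationary chain: coverage ~ stationary distribution of P-hat
        seq = sample_state_sequence(sticky4, 50_000, seed=19)
        cov = coverage(seg_from(seq))
        pi = stationary_distribution(transition_matrix(seg_from(seq)).P)
        assert np.abs(cov - pi).max() <= 0.01


class TestEntropyProduction:
    def test_symmetric_matrix_zero(self):
        P = np.array([[0.8, 0.1, 0.1], [0.1, 0.7, 0.2], [0.1, 0.2, 0.7]])
        assert entropy_production(P) == 0.0

    def test_two_state_closed_form(self):
        P = np.array([[0.9, 0.1], [0.3, 0.7]])
        assert entropy_production(P) == pytest.approx(0.2 * np.log(3),
                                                      abs=1e-12)

    def test_identity_zero(self):
        assert entropy_production(np.eye(4)) == 0.0

    def test_one_sided_zero_warns(self):
        P = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])
        with pytest.warns(UserWarning):
            assert entropy_production(P) == 0.0  # every pair one-sided

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        P = rng.random((4, 4))
        P /= P.sum(axis=1, keepdims=True)
        perm = [2, 3, 0, 1]
        Q = P[np.ix_(perm, perm)]
        assert entropy_production(Q) == pytest.approx(entropy_production(P),
                                                      abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((4, 4)) + 1e-3
        P /= P.sum(axis=1, keepdims=True)
        assert entropy_production(P) >= 0.0

    def test_regularized_variant_finite(self):
        seq = np.array([0, 1, 1, 2, 2, 0, 0, 1, 2, 0])  # cyclic, one-way pairs
        tm = transition_matrix(seg_from(seq, k=3))
        with pytest.warns(UserWarning):
            plain = entropy_production(tm)
        reg = entropy_production(tm, regularize=True)
        assert np.isfinite(reg) and reg >= 0.0
        assert np.isfinite(plain)

    def test_plugin_estimate_close_to_truth(self):
        P = np.array([[0.9, 0.1], [0.3, 0.7]])
        seq = sample_state_sequence(P, 100_000, seed=23)
        tm = transition_matrix(seg_from(seq, k=2))
        est = entropy_production(tm)
        truth = 0.2 * np.log(3)
        assert abs(est - truth) / truth <= 0.05
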