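"""Information content: analytic values, brute-force oracle, nulls."""

import numpy as np
import pytest

from dgpop.information import (
    cohens_d,
    info_with_null,
    information_content,
    population_info_test,
    shuffle_null,
    InfoResult,
)


def brute_force_info(events, labels, dt, min_occ=0.0):
    """Independent direct evaluation of I = sum p_i (l_i/l) log2(l_i/l)."""
    events = np.asarray(events, float)
    labels = np.asarray(labels)
    bins = [b for b in np.unique(labels) if b >= 0]
    occ = {b: np.sum(labels == b) * dt for b in bins}
    bins = [b for b in bins if occ[b] >= min_occ]
    t_total = sum(occ[b] for b in bins)
    p = {b: occ[b] / t_total for b in bins}
    lam = {b: events[labels == b].sum() / occ[b] for b in bins}
    lam_bar = sum(p[b] * lam[b] for b in bins)
    info = 0.0
    for b in bins:
        if lam[b] > 0:
            info += p[b] * (lam[b] / lam_bar) * np.log2(lam[b] / lam_bar)
    return info


class TestAnalyticValues:
    def test_four_equal_bins_one_active_is_two_bits(self):
        labels = np.tile([0, 1, 2, 3], 25)
        events = (labels == 2).astype(np.uint8)
        res = information_content(events, labels, dt=1.0, min_occupancy_s=0.0)
        assert np.isclose(res.info, 2.0, atol=1e-12)

    def test_uniform_rates_zero_bits(self):
        labels = np.tile([0, 1, 2, 3], 25)
        events = np.ones(100, np.uint8)
        res = information_content(events, labels, dt=1.0, min_occupancy_s=0.0)
        assert np.isclose(res.info, 0.0, atol=1e-12)

    def test_half_occupancy_double_rate_is_one_bit(self):
        # p = (1/2, 1/2), rates (2, 0) x baseline -> 1 bit
        labels = np.array([0] * 50 + [1] * 50)
        events = (labels == 0).astype(np.uint8)
        res = information_content(events, labels, dt=1.0, min_occupancy_s=0.0)
        assert np.isclose(res.info, 1.0, atol=1e-12)

    def test_zero_events_undefined(self):
        labels = np.tile([0, 1], 20)
        res = information_content(np.zeros(40, np.uint8), labels, dt=1.0)
        assert not res.defined

    def test_single_bin_rejected(self):
        with pytest.raises(ValueError):
            information_content(np.ones(10, np.uint8), np.zeros(10, int), dt=1.0)


def test_matches_brute_force_oracle():
    """50 random small instances agree with the directly coded formula."""
    rng = np.random.default_rng(42)
    for _ in range(50):
        n_bins = rng.integers(2, 11)
        n_frames = rng.integers(4 * n_bins, 400)
        labels = rng.integers(0, n_bins, n_frames)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, n_bins, n_frames)
        events = (rng.random(n_frames) < rng.uniform(0.05, 0.3)).astype(np.uint8)
        if events.sum() == 0:
            events[0] = 1
        res = information_content(events, labels, dt=1 / 3, min_occupancy_s=0.0)
        expected = brute_force_info(events, labels, dt=1 / 3)
        assert abs(res.info - expected) < 1e-12


class TestInvariances:
    def test_bin_relabeling_invariant(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 6, 300)
        events = (rng.random(300) < 0.2).astype(np.uint8)
        base = information_content(events, labels, 1.0, 0.0).info
        perm = rng.permutation(6)
        relabeled = information_content(events, perm[labels], 1.0, 0.0).info
        assert np.isclose(base, relabeled, atol=1e-12)

    def test_joint_circular_shift_invariant(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 5, 200)
        events = (rng.random(200) < 0.2).astype(np.uint8)
        base = information_content(events, labels, 1.0, 0.0).info
        shifted = information_content(
            np.roll(events, 37), np.roll(labels, 37), 1.0, 0.0
        ).info
        assert np.isclose(base, shifted, atol=1e-12)

    def test_concentration_never_decreases_info(self):
        # moving all events into a single bin maximizes I for fixed occupancy
        rng = np.random.default_rng(3)
        labels = np.tile(np.arange(4), 50)
        events = (rng.random(200) < 0.2).astype(np.uint8)
        spread = information_content(events, labels, 1.0, 0.0).info
        k = events.sum()
        conc = np.zeros(200, np.uint8)
        conc[np.flatnonzero(labels == 0)[:k]] = 1
        assert k <= 50
        concentrated = information_content(conc, labels, 1.0, 0.0).info
        assert concentrated >= spread - 1e-12

    def test_nonnegative(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            labels = rng.integers(0, 8, 300)
            events = (rng.random(300) < 0.1).astype(np.uint8)
            if events.sum() == 0:
                continue
            assert information_content(events, labels, 1.0, 0.0).info >= -1e-12


class TestShuffleNull:
    def test_null_length_and_determinism(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(0, 4, 600)
        events = (rng.random(600) < 0.05).astype(np.uint8)
        a = shuffle_null(events, labels, 1.0, n_shuffles=1000, seed=7)
        b = shuffle_null(events, labels, 1.0, n_shuffles=1000, seed=7)
        assert len(a) == 1000
        assert np.array_equal(a, b)
        assert np.all(a[np.isfinite(a)] >= -1e-12)

    def test_short_session_rejected(self):
        with pytest.raises(ValueError):
            shuffle_null(np.ones(30, np.uint8), np.zeros(30, int), 1.0, min_shift_s=20.0)

    def test_percentile_fields_populated(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(0, 4, 600)
        events = (rng.random(600) < 0.05).astype(np.uint8)
        res = info_with_null(events, labels, 1.0, n_shuffles=200, seed=0)
        assert np.isfinite(res.null_p95)
        assert 0 <= res.percentile <= 100


class TestPopulationTest:
    def make_result(self, info, null):
        null = np.asarray(null, float)
        return InfoResult(
            info=info,
            p_occ=None,
            rates=None,
            mean_rate=1.0,
            n_events=10,
            null=null,
            null_p95=float(np.percentile(null, 95)),
            exceeds_p95=info > np.percentile(null, 95),
        )

    def test_frac_above_threshold(self):
        rng = np.random.default_rng(0)
        results = []
        for i in range(10):
            null = rng.uniform(0, 1, 200)
            info = 2.0 if i < 2 else 0.1  # 2 of 10 exceed
            results.append(self.make_result(info, null))
        test = population_info_test(results, seed=1)
        assert np.isclose(test.frac_above_p95, 20.0)

    def test_null_like_observations_give_small_d(self):
        rng = np.random.default_rng(1)
        results = []
        for _ in range(40):
            null = rng.normal(1.0, 0.2, 500)
            results.append(self.make_result(float(null.mean()), null))
        test = population_info_test(results, seed=2)
        assert abs(test.cohens_d) < 0.15
        assert test.p_value > 0.05

    def test_p_value_floor(self):
        rng = np.random.default_rng(2)
        results = [
            self.make_result(5.0, rng.uniform(0, 1, 300)) for _ in range(20)
        ]
        test = population_info_test(results, n_replicates=1000, seed=3)
        assert np.isclose(test.p_value, 1.0 / 1001.0)

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError):
            population_info_test([])


def test_cohens_d_pooled_definition():
    a = np.array([2.0, 3.0, 4.0])
    b = np.array([1.0, 2.0, 3.0])
    assert np.isclose(cohens_d(a, b), 1.0)
    assert np.isclose(cohens_d(2 * a, 2 * b), 1.0)  # scale equivariance
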