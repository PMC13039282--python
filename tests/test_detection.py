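import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loophub.detection import (
    Assembly,
    DetectionConfig,
    detect_pairs,
    extend_to_triplets,
    holm_correct,
    pairwise_coincidence_test,
    surrogate_null_p,
)
from loophub.spike_io import BinnedTrain
from loophub.synthetic import PlantSpec, ScenarioConfig, build_scenario


def binary_train(active_idx, n_bins, bin_size=0.01):
    counts = np.zeros(n_bins, dtype=int)
    counts[np.asarray(active_idx, dtype=int)] = 1
    return BinnedTrain(bin_size, 0.0, counts)


class TestConfig:
    def test_grid_lengths_must_match(self):
        with pytest.raises(ValueError, match="same length"):
            DetectionConfig(bin_sizes=(0.01, 0.02), max_lags=(3,))

    def test_default_grid_spans_200ms_delay(self):
        cfg = DetectionConfig()
        assert all(b * l <= 0.2 for b, l in zip(cfg.bin_sizes, cfg.max_lags))


class TestPairwiseTest:
    def test_shifted_copy_recovers_lag(self):
        rng = np.random.default_rng(0)
        idx = rng.choice(5990, size=300, replace=False)
        a = binary_train(idx, 6000)
        b = binary_train(np.clip(idx + 3, 0, 5999), 6000)
        r = pairwise_coincidence_test(a, b, max_lag=10, chunk_bins=100)
        assert r.best_lag == 3
        assert r.p_value < 1e-6
        # surrogate oracle confirms
        p_s = surrogate_null_p(a, b, 3, 100, n_surrogates=499, seed=1)
        assert p_s <= 1 / 100

    def test_empty_train_gives_p_one(self):
        a = binary_train([], 1000)
        b = binary_train([5, 10], 1000)
        r = pairwise_coincidence_test(a, b, 5, 100)
        assert r.joint_count == 0 and r.p_value == 1.0

    def test_symmetry_mirrored_lag_same_p(self):
        rng = np.random.default_rng(1)
        idx = rng.choice(3990, size=200, replace=False)
        a = binary_train(idx, 4000)
        b = binary_train(np.clip(idx + 4, 0, 3999), 4000)
        r_ab = pairwise_coincidence_test(a, b, 8, 100)
        r_ba = pairwise_coincidence_test(b, a, 8, 100)
        assert r_ab.best_lag == -r_ba.best_lag
        assert r_ab.joint_count == r_ba.joint_count
        assert r_ab.p_value == pytest.approx(r_ba.p_value, abs=1e-12)

    def test_tie_prefers_smallest_then_negative_lag(self):
        # constant-activity trains: every lag has the same joint count
        a = binary_train(np.arange(0, 1000, 2), 1000)
        r = pairwise_coincidence_test(a, a, 3, 100)
        assert r.best_lag == 0

    def test_chunk_longer_than_series_falls_back_to_single_chunk(self):
        a = binary_train([1, 5, 9], 20)
        b = binary_train([1, 5, 9], 20)
        r = pairwise_coincidence_test(a, b, 2, chunk_bins=100)
        assert 0.0 <= r.p_value <= 1.0 and r.joint_count == 3

    def test_mismatched_bin_size_rejected(self):
        a = binary_train([1], 100, bin_size=0.01)
        b = binary_train([1], 100, bin_size=0.02)
        with pytest.raises(ValueError):
            pairwise_coincidence_test(a, b, 2, 100)


class TestSurrogate:
    def test_minimum_attainable_p_on_strong_signal(self):
        rng = np.random.default_rng(2)
        idx = rng.choice(2000, size=150, replace=False)
        a = binary_train(idx, 2000)
        r = surrogate_null_p(a, a, 0, 100, n_surrogates=199, seed=0)
        assert r == pytest.approx(1 / 200)

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        a = binary_train(rng.choice(2000, 100, replace=False), 2000)
        b = binary_train(rng.choice(2000, 100, replace=False), 2000)
        p1 = surrogate_null_p(a, b, 2, 100, 199, seed=42)
        p2 = surrogate_null_p(a, b, 2, 100, 199, seed=42)
        assert p1 == p2

    def test_requires_enough_surrogates(self):
        a = binary_train([1], 100)
        with pytest.raises(ValueError):
            surrogate_null_p(a, a, 0, 100, n_surrogates=10)


class TestHolm:
    def test_hand_computed_step_down(self):
        np.testing.assert_allclose(holm_correct([0.01, 0.04, 0.30]), [0.03, 0.08, 0.30])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(holm_correct([1.0]), [1.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_adjustment_dominates_input_and_is_monotone(self, p):
        adj = holm_correct(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


@pytest.fixture(scope="module")
def planted_scenario():
    cfg = ScenarioConfig(
        areas=[("A", 5), ("B", 5)],
        duration=300.0,
        default_rate=5.0,
        planted_pairs=[
            PlantSpec(("A_0", "B_0"), ("A", "B"), 0.02, (0, 3), 250, jitter=0.004),
            PlantSpec(("A_1", "B_1"), ("A", "B"), 0.02, (0, 0), 250, jitter=0.004),
        ],
        seed=21,
    )
    return build_scenario(cfg)


@pytest.fixture(scope="module")
def triplet_scenario():
    cfg = ScenarioConfig(
        areas=[("A", 4), ("B", 4)],
        duration=300.0,
        default_rate=5.0,
        planted_triplets=[
            PlantSpec(
                ("A_0", "B_0", "A_1"), ("A", "B", "A"), 0.02, (0, 2, 5), 250, jitter=0.004
            )
        ],
        seed=33,
    )
    return build_scenario(cfg)


class TestDetectPairs:
    def test_planted_directional_pair_recovered(self, planted_scenario):
        rec, _ = planted_scenario
        found = {
            frozenset(a.members): a for a in detect_pairs(rec, DetectionConfig())
        }
        a = found[frozenset({"A_0", "B_0"})]
        # delay of 3 bins x 20 ms = 60 ms, recovered within one planted bin
        delay = a.lags[1] * a.bin_size
        assert a.members[0] == "A_0"  # A leads
        assert abs(delay - 0.06) <= 0.02
        assert a.p_value < 1e-10
        assert a.activation_bins.size > 100

    def test_planted_synchronous_pair_recovered_at_lag_zero(self, planted_scenario):
        rec, _ = planted_scenario
        found = {frozenset(a.members): a for a in detect_pairs(rec, DetectionConfig())}
        a = found[frozenset({"A_1", "B_1"})]
        assert a.lags == (0, 0)

    def test_single_neuron_recording_yields_nothing(self):
        cfg = ScenarioConfig(areas=[("A", 1)], duration=60.0, default_rate=5.0, seed=0)
        rec, _ = build_scenario(cfg)
        assert detect_pairs(rec, DetectionConfig()) == []


class TestTripletExtension:
    def test_planted_triplet_recovered_with_ordered_lags(self, triplet_scenario):
        rec, _ = triplet_scenario
        cfg = DetectionConfig()
        pairs = detect_pairs(rec, cfg)
        trips = extend_to_triplets(rec, pairs, cfg)
        found = {frozenset(t.members): t for t in trips}
        t = found[frozenset({"A_0", "B_0", "A_1"})]
        delays = {m: l * t.bin_size for m, l in zip(t.members, t.lags)}
        assert abs(delays["B_0"] - delays["A_0"] - 0.04) <= 0.02
        assert abs(delays["A_1"] - delays["A_0"] - 0.10) <= 0.02

    def test_max_size_two_gates_extension(self, triplet_scenario):
        rec, _ = triplet_scenario
        cfg = DetectionConfig(max_size=2)
        pairs = detect_pairs(rec, cfg)
        assert extend_to_triplets(rec, pairs, cfg) == []

    def test_duplicate_member_sets_collapse(self, triplet_scenario):
        # the three pairs inside one planted triplet all extend to the same set
        rec, _ = triplet_scenario
        cfg = DetectionConfig()
        trips = extend_to_triplets(rec, detect_pairs(rec, cfg), cfg)
        sets = [frozenset(t.members) for t in trips]
        assert len(sets) == len(set(sets))


class TestAssemblyModel:
    def test_members_must_be_distinct(self):
        with pytest.raises(ValueError, match="distinct"):
            Assembly(members=("a", "a"), lags=(0, 1), bin_size=0.01, p_value=0.01)

    def test_lags_must_be_sorted_from_zero(self):
        with pytest.raises(ValueError, match="lags"):
            Assembly(members=("a", "b"), lags=(1, 0), bin_size=0.01, p_value=0.01)

    def test_lag_times_scale_with_bin(self):
        a = Assembly(members=("a", "b", "c"), lags=(0, 2, 5), bin_size=0.02, p_value=0.01)
        assert a.lag_times == (0.0, 0.04, 0.1)
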