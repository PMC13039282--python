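import itertools
import math

import numpy as np
import pytest
from loophub.connectivity import (
    UNDEFINED,
    AreaPairCounts,
    aggregate_sessions,
    area_pair_statistics,
    binomial_direction_test,
    binomial_loop_test,
    classify_directional_homogeneity,
    compare_chain_latencies,
    conditional_loop_probability,
    count_possible,
    expected_direct_proportion,
    int_ext_index,
    loop_probabilities,
    pair_probabilities,
    rank_area_pairs,
    ranking_difference,
    tabulate_session,
)
from loophub.detection import Assembly
from loophub.motifs import classify_pair, classify_triplet


def brute_force_possible(n_i: int, n_j: int, kind: str) -> int:
    """Enumerate labelled neuron sets directly."""
    A = [("i", k) for k in range(n_i)]
    B = [("j", k) for k in range(n_j)]
    if kind == "pair_ext":
        return sum(1 for _ in itertools.product(A, B))
    if kind == "pair_int":
        return sum(1 for _ in itertools.combinations(A, 2))
    if kind == "loop_two_area":
        return sum(
            1
            for trip in itertools.combinations(A + B, 3)
            if {sum(1 for t in trip if t[0] == "i")} <= {1, 2}
            and len({t[0] for t in trip}) == 2
        )
    if kind == "loop_fixed_direction":
        return sum(1 for _ in itertools.combinations(A, 2)) * len(B)
    raise ValueError(kind)


class TestCountPossible:
    @pytest.mark.parametrize(
        "n_i, n_j, kind, expected",
        [
            (10, 5, "loop_two_area", 325),
            (4, 3, "loop_fixed_direction", 18),
            (1, 1, "pair_int", 0),
            (10, 20, "pair_ext", 200),
        ],
    )
    def test_worked_examples(self, n_i, n_j, kind, expected):
        assert count_possible(n_i, n_j, kind) == expected

    def test_matches_enumeration_on_small_sizes(self):
        for n_i, n_j in itertools.product(range(2, 7), repeat=2):
            for kind in ("pair_ext", "pair_int", "loop_two_area", "loop_fixed_direction"):
                assert count_possible(n_i, n_j, kind) == brute_force_possible(n_i, n_j, kind)

    def test_negative_sizes_rejected(self):
        with pytest.raises(ValueError):
            count_possible(-1, 3, "pair_ext")


def make_counts(**kw) -> AreaPairCounts:
    base = dict(area_i="A", area_j="B", n_i=10, n_j=20, mouse_ids=("m1", "m2"))
    base.update(kw)
    return AreaPairCounts(**base)


class TestPairProbabilities:
    def test_external_probability_arithmetic(self):
        st_ = pair_probabilities(make_counts(n_pairs_ext_ij=5))
        assert st_.p_pairs_ext_ij == pytest.approx(5 / 200)

    def test_internal_probability_arithmetic(self):
        st_ = pair_probabilities(make_counts(n_pairs_int_i=9))
        assert st_.p_pairs_int_i == pytest.approx(9 / 45)  # C(10,2) = 45

    def test_difference_antisymmetric(self):
        a = pair_probabilities(make_counts(n_pairs_ext_ij=6, n_pairs_ext_ji=2))
        assert a.p_pairs_difference == pytest.approx(0.5)
        b = pair_probabilities(make_counts(n_pairs_ext_ij=2, n_pairs_ext_ji=6))
        assert b.p_pairs_difference == pytest.approx(-0.5)

    def test_difference_undefined_when_both_zero(self):
        st_ = pair_probabilities(make_counts())
        assert st_.p_pairs_difference == UNDEFINED

    def test_zero_denominator_marks_undefined(self):
        st_ = pair_probabilities(make_counts(n_i=1, n_j=0))
        assert st_.p_pairs_ext_ij == UNDEFINED
        assert st_.p_pairs_int_i == UNDEFINED


class TestLoopProbabilities:
    def test_total_loop_probability(self):
        st_ = loop_probabilities(make_counts(n_i=10, n_j=5, n_loop_direct_ij=2, n_loop_direct_ji=1))
        assert st_.p_loop_total == pytest.approx(3 / 325)

    def test_fixed_direction_probability(self):
        st_ = loop_probabilities(make_counts(n_i=4, n_j=3, n_loop_direct_ij=2))
        assert st_.p_loop_direct_ij == pytest.approx(2 / 18)

    def test_direct_reverse_identity_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            ni, nj = rng.integers(2, 30, size=2)
            kij, kji = rng.integers(0, 10, size=2)
            c_ij = make_counts(n_i=int(ni), n_j=int(nj), n_loop_direct_ij=int(kij), n_loop_direct_ji=int(kji))
            c_ji = make_counts(
                area_i="B", area_j="A", n_i=int(nj), n_j=int(ni),
                n_loop_direct_ij=int(kji), n_loop_direct_ji=int(kij),
            )
            assert loop_probabilities(c_ij).p_loop_direct_ij == loop_probabilities(c_ji).p_loop_reverse_ij

    def test_equal_counts_and_sizes_give_zero_difference(self):
        st_ = loop_probabilities(
            make_counts(n_i=10, n_j=10, n_loop_direct_ij=3, n_loop_direct_ji=3)
        )
        assert st_.p_loop_difference == pytest.approx(0.0)

    def test_equal_counts_unequal_sizes_still_differ(self):
        # the fixed-direction denominators scale with (n_i - 1) vs (n_j - 1)
        st_ = loop_probabilities(make_counts(n_loop_direct_ij=3, n_loop_direct_ji=3))
        assert st_.p_loop_difference == pytest.approx((19 - 9) / (19 + 9))


class TestIntExtIndex:
    @pytest.mark.parametrize(
        "p_ext, p_int, expected",
        [(0.02, 0.02, 0.5), (0.03, 0.01, 0.75), (0.0, 0.0, UNDEFINED)],
    )
    def test_worked_examples(self, p_ext, p_int, expected):
        res = int_ext_index(p_ext, p_int)
        if expected == UNDEFINED:
            assert res == UNDEFINED
        else:
            assert res == pytest.approx(expected)

    def test_undefined_inputs_propagate(self):
        assert int_ext_index(UNDEFINED, 0.1) == UNDEFINED


class TestConditionalLoop:
    def test_tiny_subsets_flagged_unreliable(self):
        p, unreliable = conditional_loop_probability(2, 3, 1)
        assert p == pytest.approx(1 / 9)
        assert unreliable  # only nine possible loops

    def test_large_subsets_reliable(self):
        p, unreliable = conditional_loop_probability(10, 10, 0)
        assert p == 0.0 and not unreliable

    def test_zero_denominator_undefined(self):
        p, unreliable = conditional_loop_probability(1, 0, 0)
        assert p == UNDEFINED and unreliable


class TestSessionAggregation:
    def test_pooled_ratio_not_mean_of_ratios(self):
        s1 = make_counts(n_i=10, n_j=10, n_pairs_ext_ij=1)  # possible 100
        s2 = make_counts(n_i=10, n_j=5, n_pairs_ext_ij=2)  # possible 50
        pooled = aggregate_sessions([s1, s2])
        p = pair_probabilities(pooled).p_pairs_ext_ij
        assert p == pytest.approx(3 / 150)
        assert p != pytest.approx((1 / 100 + 2 / 50) / 2)  # mean would be 0.025

    def test_single_session_identity(self):
        s1 = make_counts(n_pairs_ext_ij=4, n_loop_direct_ij=2)
        pooled = aggregate_sessions([s1])
        assert pair_probabilities(pooled).p_pairs_ext_ij == pair_probabilities(s1).p_pairs_ext_ij

    def test_mixed_area_pairs_rejected(self):
        with pytest.raises(ValueError, match="same area pair"):
            aggregate_sessions([make_counts(), make_counts(area_j="C")])

    def test_mouse_count_pools_distinct_mice(self):
        s1 = make_counts(mouse_ids=("m1",))
        s2 = make_counts(mouse_ids=("m1",))
        s3 = make_counts(mouse_ids=("m2",))
        assert aggregate_sessions([s1, s2]).n_mice == 1
        assert aggregate_sessions([s1, s3]).n_mice == 2


class TestExpectedDirect:
    @pytest.mark.parametrize("n_i, n_j, expected", [(4, 3, 0.6), (2, 5, 0.2), (7, 7, 0.5)])
    def test_worked_examples(self, n_i, n_j, expected):
        assert expected_direct_proportion(n_i, n_j) == pytest.approx(expected)

    def test_complementarity(self):
        for n_i, n_j in itertools.product(range(2, 10), repeat=2):
            assert expected_direct_proportion(n_i, n_j) + expected_direct_proportion(
                n_j, n_i
            ) == pytest.approx(1.0)

    def test_matches_count_ratio(self):
        # 18 direct vs 12 reverse possible for sizes (4, 3)
        direct = count_possible(4, 3, "loop_fixed_direction")
        reverse = count_possible(3, 4, "loop_fixed_direction")
        assert expected_direct_proportion(4, 3) == pytest.approx(direct / (direct + reverse))

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ValueError):
            expected_direct_proportion(1, 1)


def exact_binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-sided binomial by full enumeration."""
    pmf = [math.comb(n, x) * p0**x * (1 - p0) ** (n - x) for x in range(n + 1)]
    return sum(q for q in pmf if q <= pmf[k] * (1 + 1e-12))


class TestBinomialTests:
    @pytest.mark.parametrize(
        "k_ij, k_ji, expected",
        [(8, 2, 0.109375), (5, 5, 1.0), (10, 0, 2 / 1024)],
    )
    def test_direction_test_worked_examples(self, k_ij, k_ji, expected):
        assert binomial_direction_test(k_ij, k_ji) == pytest.approx(expected, abs=1e-12)

    def test_direction_test_undefined_for_zero_total(self):
        assert binomial_direction_test(0, 0) == UNDEFINED

    def test_loop_test_equal_sizes_reduces_to_half(self):
        assert binomial_loop_test(9, 1, 6, 6) == pytest.approx(22 / 1024, abs=1e-12)

    def test_loop_test_mode_gives_large_p(self):
        p = binomial_loop_test(5, 5, 7, 7)
        assert p != UNDEFINED and p >= 0.5

    def test_against_enumeration_oracle(self):
        for k, n_total, ni, nj in [(0, 10, 2, 5), (3, 10, 4, 3), (7, 9, 5, 2), (2, 6, 3, 9)]:
            p0 = expected_direct_proportion(ni, nj)
            got = binomial_loop_test(k, n_total - k, ni, nj)
            assert got == pytest.approx(exact_binomial_two_sided(k, n_total, p0), abs=1e-12)


class TestChainLatencies:
    def test_identical_samples_give_t_zero_p_half(self):
        t, p = compare_chain_latencies([0.04, 0.06, 0.08], [0.04, 0.06, 0.08])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_slower_first_half_detected(self):
        a, b = [0.06, 0.08, 0.10], [0.02, 0.02, 0.04]
        t, p = compare_chain_latencies(a, b)
        # hand-computed pooled-variance t
        na, nb = 3, 3
        sp2 = (np.var(a, ddof=1) * (na - 1) + np.var(b, ddof=1) * (nb - 1)) / (na + nb - 2)
        t_hand = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(t_hand)
        assert p < 0.05

    def test_single_element_list_rejected(self):
        with pytest.raises(ValueError):
            compare_chain_latencies([0.1], [0.1, 0.2])


def make_stats(ai, aj, p, possible=1000, n=200, mice=3):
    c = AreaPairCounts(
        area_i=ai, area_j=aj, n_i=n, n_j=n,
        mouse_ids=tuple(f"m{k}" for k in range(mice)),
        n_pairs_ext_ij=int(round(p * count_possible(n, n, "pair_ext"))),
    )
    return area_pair_statistics(c)


class TestRanking:
    def test_filters_exclude_small_or_single_mouse_pairs(self):
        stats = [
            make_stats("A", "B", 0.01),
            make_stats("A", "C", 0.02, n=50),  # too few neurons
            make_stats("B", "C", 0.03, mice=1),  # one mouse
        ]
        full, top, bottom = rank_area_pairs(stats, "pair", min_neurons=100, min_mice=2, k=30)
        assert list(full.area_j) == ["B"]

    def test_descending_with_deterministic_ties(self):
        stats = [make_stats(a, b, 0.01) for a, b in [("C", "D"), ("A", "B"), ("A", "D")]]
        full, _, _ = rank_area_pairs(stats, "pair", min_neurons=10, min_mice=1)
        # equal probability and possible -> lexicographic order
        assert list(zip(full.area_i, full.area_j)) == [("A", "B"), ("A", "D"), ("C", "D")]
        assert list(full["rank"]) == [1, 2, 3]

    def test_rank_difference_across_metrics(self):
        pair_rank = rank_area_pairs(
            [make_stats("A", "B", 0.05), make_stats("A", "C", 0.01)],
            "pair", min_neurons=10, min_mice=1,
        )[0]
        c1 = AreaPairCounts(area_i="A", area_j="B", n_i=200, n_j=200,
                            mouse_ids=("m1", "m2"), n_loop_direct_ij=1)
        c2 = AreaPairCounts(area_i="A", area_j="C", n_i=200, n_j=200,
                            mouse_ids=("m1", "m2"), n_loop_direct_ij=50)
        loop_rank = rank_area_pairs(
            [area_pair_statistics(c1), area_pair_statistics(c2)],
            "loop", min_neurons=10, min_mice=1,
        )[0]
        diff = ranking_difference(pair_rank, loop_rank)
        assert set(diff.rank_difference) == {1}  # both pairs swap positions


class TestHomogeneity:
    def test_consistent_roles_are_homogeneous(self):
        assert classify_directional_homogeneity(["leading", "leading"]) == "homogeneous"

    def test_mixed_roles_are_heterogeneous(self):
        assert classify_directional_homogeneity(["leading", "trailing"]) == "heterogeneous"

    def test_no_significant_partner_is_insufficient(self):
        assert classify_directional_homogeneity([]) == "insufficient"


class TestTabulation:
    def test_counts_from_classified_assemblies(self):
        areas = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        p1 = Assembly(members=("a1", "b1"), lags=(0, 2), bin_size=0.02, p_value=0.01)
        p2 = Assembly(members=("b1", "a2"), lags=(0, 1), bin_size=0.02, p_value=0.01)
        p3 = Assembly(members=("a1", "b2"), lags=(0, 0), bin_size=0.02, p_value=0.01)
        p4 = Assembly(members=("a1", "a2"), lags=(0, 1), bin_size=0.02, p_value=0.01)
        t1 = Assembly(members=("a1", "b1", "a2"), lags=(0, 2, 5), bin_size=0.02, p_value=0.01)
        cpairs = [(a, classify_pair(a, areas)) for a in (p1, p2, p3, p4)]
        ctrips = [(t1, classify_triplet(t1, areas))]
        (c,) = tabulate_session(cpairs, ctrips, areas, {"A": 2, "B": 2})
        assert (c.area_i, c.area_j) == ("A", "B")
        assert c.n_pairs_ext_ij == 1  # a1 -> b1
        assert c.n_pairs_ext_ji == 1  # b1 -> a2
        assert c.n_pairs_sync == 1
        assert c.n_pairs_int_i == 1
        assert c.n_loop_direct_ij == 1 and c.n_loop_direct_ji == 0
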