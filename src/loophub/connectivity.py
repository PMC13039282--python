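"""Area-pair probability formulations, indices and directionality tests.

All "probabilities" here are empirical proportions: the number of detected
assemblies of a given kind between (or within) areas, divided by the number
of possible neuron combinations of that kind.  For an area pair recorded in
several sessions, counts and possible-combination denominators are summed
across sessions *before* dividing (pooled ratio, never a mean of ratios).

Quantities whose denominator is zero are undefined and propagate as the
explicit marker ``UNDEFINED`` (the string ``"X"``) rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detection import Assembly
from .motifs import PairClass, TripletClass

__all__ = [
    "UNDEFINED",
    "AreaPairCounts",
    "AreaPairStats",
    "count_possible",
    "tabulate_session",
    "aggregate_sessions",
    "pair_probabilities",
    "loop_probabilities",
    "area_pair_statistics",
    "int_ext_index",
    "conditional_loop_probability",
    "expected_direct_proportion",
    "binomial_direction_test",
    "binomial_loop_test",
    "compare_chain_latencies",
    "rank_area_pairs",
    "ranking_difference",
    "classify_directional_homogeneity",
]

#: Marker for quantities whose denominator is zero (mirrors the supplementary
#: sheet convention of writing an 'X' instead of an index value).
UNDEFINED = "X"

Value = float | str  # a probability/index or UNDEFINED


def count_possible(n_i: int, n_j: int, kind: str) -> int:
    """Number of possible assemblies of a kind for given area sizes.

    kinds: ``pair_ext`` (one neuron per area), ``pair_int`` (two neurons of
    area *i*), ``loop_two_area`` (any two-area triplet with a repeated area:
    C(n_i,2)*n_j + C(n_j,2)*n_i), ``loop_fixed_direction`` (outer pair in
    area *i*: C(n_i,2)*n_j).  Degenerate sizes give zero.
    """
    if n_i < 0 or n_j < 0:
        raise ValueError("neuron counts must be >= 0")
    if kind == "pair_ext":
        return n_i * n_j
    if kind == "pair_int":
        return math.comb(n_i, 2)
    if kind == "loop_two_area":
        return math.comb(n_i, 2) * n_j + math.comb(n_j, 2) * n_i
    if kind == "loop_fixed_direction":
        return math.comb(n_i, 2) * n_j
    raise ValueError(f"unknown kind {kind!r}")


@dataclass
class AreaPairCounts:
    """Assembly counts for one (unordered) area pair, one or more sessions.

    Directional conventions: ``n_pairs_ext_ij`` counts pairs whose leading
    neuron lies in ``area_i``; ``n_loop_direct_ij`` counts loops with outer
    area ``area_i`` (the same objects are ``n_loop_reverse_ji``).  The
    ``possible_*`` denominators are computed from the per-session sizes at
    construction and are summed by :func:`aggregate_sessions`.
    """

    area_i: str
    area_j: str
    n_i: int
    n_j: int
    session_ids: tuple[str, ...] = ()
    mouse_ids: tuple[str, ...] = ()
    n_pairs_ext_ij: int = 0
    n_pairs_ext_ji: int = 0
    n_pairs_sync: int = 0
    n_pairs_int_i: int = 0
    n_pairs_int_j: int = 0
    n_loop_direct_ij: int = 0
    n_loop_direct_ji: int = 0
    possible_ext: int = field(default=None)  # type: ignore[assignment]
    possible_int_i: int = field(default=None)  # type: ignore[assignment]
    possible_int_j: int = field(default=None)  # type: ignore[assignment]
    possible_loop: int = field(default=None)  # type: ignore[assignment]
    possible_loop_ij: int = field(default=None)  # type: ignore[assignment]
    possible_loop_ji: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.possible_ext is None:
            self.possible_ext = count_possible(self.n_i, self.n_j, "pair_ext")
        if self.possible_int_i is None:
            self.possible_int_i = count_possible(self.n_i, self.n_j, "pair_int")
        if self.possible_int_j is None:
            self.possible_int_j = count_possible(self.n_j, self.n_i, "pair_int")
        if self.possible_loop is None:
            self.possible_loop = count_possible(self.n_i, self.n_j, "loop_two_area")
        if self.possible_loop_ij is None:
            self.possible_loop_ij = count_possible(self.n_i, self.n_j, "loop_fixed_direction")
        if self.possible_loop_ji is None:
            self.possible_loop_ji = count_possible(self.n_j, self.n_i, "loop_fixed_direction")

    @property
    def n_loop_total(self) -> int:
        return self.n_loop_direct_ij + self.n_loop_direct_ji

    @property
    def n_pairs_ext_total(self) -> int:
        return self.n_pairs_ext_ij + self.n_pairs_ext_ji + self.n_pairs_sync

    @property
    def n_mice(self) -> int:
        return len(set(self.mouse_ids))


@dataclass
class AreaPairStats:
    """All probability formulations and indices for one area pair."""

    area_i: str
    area_j: str
    n_i: int = 0
    n_j: int = 0
    n_mice: int = 0
    p_pairs_ext_ij: Value = UNDEFINED
    p_pairs_ext_ji: Value = UNDEFINED
    p_pairs_ext_total: Value = UNDEFINED
    p_pairs_sync: Value = UNDEFINED
    p_pairs_difference: Value = UNDEFINED
    p_pairs_int_i: Value = UNDEFINED
    p_pairs_int_j: Value = UNDEFINED
    p_loop_total: Value = UNDEFINED
    p_loop_direct_ij: Value = UNDEFINED
    p_loop_direct_ji: Value = UNDEFINED
    p_loop_difference: Value = UNDEFINED
    int_ext_i: Value = UNDEFINED
    int_ext_j: Value = UNDEFINED
    p_expected_direct: Value = UNDEFINED
    binomial_direction_p: Value = UNDEFINED
    binomial_loop_p: Value = UNDEFINED
    possible_ext: int = 0
    possible_loop: int = 0

    @property
    def p_loop_reverse_ij(self) -> Value:
        """Reverse-loop probability w.r.t. area_i == direct w.r.t. area_j."""
        return self.p_loop_direct_ji


def _ratio(num: int, den: int) -> Value:
    return num / den if den > 0 else UNDEFINED


def _norm_diff(p_ij: Value, p_ji: Value) -> Value:
    if p_ij == UNDEFINED or p_ji == UNDEFINED:
        return UNDEFINED
    tot = p_ij + p_ji
    if tot == 0:
        return UNDEFINED
    return (p_ij - p_ji) / tot


def tabulate_session(
    pairs: list[tuple[Assembly, PairClass]],
    triplets: list[tuple[Assembly, TripletClass]],
    areas: dict[str, str],
    area_sizes: dict[str, int],
    session_id: str = "s1",
    mouse_id: str = "m1",
) -> list[AreaPairCounts]:
    """Count classified assemblies of one session per unordered area pair.

    ``areas`` maps neuron id -> area label; ``area_sizes`` maps each
    simultaneously recorded area to its neuron count.  Every area pair gets
    an entry even with zero assemblies, so zero-probability pairs keep their
    denominators.  Intra-regional pair counts are attached to every pair
    entry involving that area.
    """
    labels = sorted(area_sizes)
    table = {
        (ai, aj): AreaPairCounts(
            area_i=ai,
            area_j=aj,
            n_i=area_sizes[ai],
            n_j=area_sizes[aj],
            session_ids=(session_id,),
            mouse_ids=(mouse_id,),
        )
        for k, ai in enumerate(labels)
        for aj in labels[k + 1 :]
    }

    def key(a: str, b: str) -> tuple[tuple[str, str], bool]:
        """Canonical unordered key + whether (a, b) matches (area_i, area_j)."""
        return ((a, b), True) if a <= b else ((b, a), False)

    intra: dict[str, int] = {}
    for assembly, cls in pairs:
        a0, a1 = (areas[m] for m in assembly.members)
        if not cls.is_inter_regional:
            intra[a0] = intra.get(a0, 0) + 1
        elif cls.is_directional:
            k, fwd = key(a0, a1)
            c = table[k]
            if fwd:
                c.n_pairs_ext_ij += 1
            else:
                c.n_pairs_ext_ji += 1
        else:
            k, _fwd = key(a0, a1)
            table[k].n_pairs_sync += 1
    for (ai, aj), c in table.items():
        c.n_pairs_int_i = intra.get(ai, 0)
        c.n_pairs_int_j = intra.get(aj, 0)
    for _assembly, cls in triplets:
        if not cls.is_loop:
            continue
        k, fwd = key(cls.outer_area, cls.inner_area)
        c = table[k]
        if fwd:
            c.n_loop_direct_ij += 1
        else:
            c.n_loop_direct_ji += 1
    return list(table.values())


def aggregate_sessions(per_session: list[AreaPairCounts]) -> AreaPairCounts:
    """Pool one area pair across sessions: sum counts *and* denominators.

    The pooled probability is the ratio of summed counts to summed possible
    combinations -- deliberately not the mean of per-session probabilities.
    """
    if not per_session:
        raise ValueError("need at least one session")
    first = per_session[0]
    if any((c.area_i, c.area_j) != (first.area_i, first.area_j) for c in per_session):
        raise ValueError("all entries must describe the same area pair")
    int_fields = [
        "n_i",
        "n_j",
        "n_pairs_ext_ij",
        "n_pairs_ext_ji",
        "n_pairs_sync",
        "n_pairs_int_i",
        "n_pairs_int_j",
        "n_loop_direct_ij",
        "n_loop_direct_ji",
        "possible_ext",
        "possible_int_i",
        "possible_int_j",
        "possible_loop",
        "possible_loop_ij",
        "possible_loop_ji",
    ]
    sums = {f: sum(getattr(c, f) for c in per_session) for f in int_fields}
    return AreaPairCounts(
        area_i=first.area_i,
        area_j=first.area_j,
        session_ids=tuple(s for c in per_session for s in c.session_ids),
        mouse_ids=tuple(m for c in per_session for m in c.mouse_ids),
        **sums,
    )


def pair_probabilities(counts: AreaPairCounts) -> AreaPairStats:
    """Pair-level probabilities and the normalised directional difference."""
    st = AreaPairStats(
        area_i=counts.area_i,
        area_j=counts.area_j,
        n_i=counts.n_i,
        n_j=counts.n_j,
        n_mice=counts.n_mice,
        possible_ext=counts.possible_ext,
        possible_loop=counts.possible_loop,
    )
    st.p_pairs_ext_ij = _ratio(counts.n_pairs_ext_ij, counts.possible_ext)
    st.p_pairs_ext_ji = _ratio(counts.n_pairs_ext_ji, counts.possible_ext)
    st.p_pairs_sync = _ratio(counts.n_pairs_sync, counts.possible_ext)
    st.p_pairs_ext_total = _ratio(counts.n_pairs_ext_total, counts.possible_ext)
    st.p_pairs_int_i = _ratio(counts.n_pairs_int_i, counts.possible_int_i)
    st.p_pairs_int_j = _ratio(counts.n_pairs_int_j, counts.possible_int_j)
    st.p_pairs_difference = _norm_diff(st.p_pairs_ext_ij, st.p_pairs_ext_ji)
    st.int_ext_i = int_ext_index(st.p_pairs_ext_total, st.p_pairs_int_i)
    st.int_ext_j = int_ext_index(st.p_pairs_ext_total, st.p_pairs_int_j)
    return st


def loop_probabilities(counts: AreaPairCounts, stats: AreaPairStats | None = None) -> AreaPairStats:
    """Loop-like probabilities, difference and the directional tests."""
    st = stats or AreaPairStats(
        area_i=counts.area_i,
        area_j=counts.area_j,
        n_i=counts.n_i,
        n_j=counts.n_j,
        n_mice=counts.n_mice,
        possible_ext=counts.possible_ext,
        possible_loop=counts.possible_loop,
    )
    st.p_loop_total = _ratio(counts.n_loop_total, counts.possible_loop)
    st.p_loop_direct_ij = _ratio(counts.n_loop_direct_ij, counts.possible_loop_ij)
    st.p_loop_direct_ji = _ratio(counts.n_loop_direct_ji, counts.possible_loop_ji)
    st.p_loop_difference = _norm_diff(st.p_loop_direct_ij, st.p_loop_direct_ji)
    if counts.n_i + counts.n_j >= 3 and (counts.n_i >= 2 or counts.n_j >= 2):
        st.p_expected_direct = expected_direct_proportion(counts.n_i, counts.n_j)
    st.binomial_direction_p = binomial_direction_test(
        counts.n_pairs_ext_ij, counts.n_pairs_ext_ji
    )
    if st.p_expected_direct != UNDEFINED:
        st.binomial_loop_p = binomial_loop_test(
            counts.n_loop_direct_ij, counts.n_loop_direct_ji, counts.n_i, counts.n_j
        )
    return st


def area_pair_statistics(counts: AreaPairCounts) -> AreaPairStats:
    """Full per-area-pair statistics (pairs + loops + indices + tests)."""
    return loop_probabilities(counts, pair_probabilities(counts))


def int_ext_index(p_ext: Value, p_int: Value) -> Value:
    """Relative propensity for inter- vs intra-regional pairs.

    ``p_ext / (p_ext + p_int)``; 0.5 means equal propensity.  When both
    probabilities are zero (or either is undefined) the index is undefined
    and the 'X' marker is returned.
    """
    if p_ext == UNDEFINED or p_int == UNDEFINED:
        return UNDEFINED
    tot = p_ext + p_int
    if tot == 0:
        return UNDEFINED
    return p_ext / tot


def conditional_loop_probability(
    pair_forming_i,
    pair_forming_j,
    n_loops: int,
    denominator_floor: int = 50,
) -> tuple[Value, bool]:
    """Loop probability restricted to the pair-forming neuron subsets.

    ``pair_forming_i``/``pair_forming_j`` are the subsets of neurons in each
    area that appear in inter-regional pairs (or simply their sizes).
    Evaluates the two-area loop denominator on the subset sizes.  Returns
    ``(probability, unreliable)`` where ``unreliable`` flags denominators
    below ``denominator_floor`` (tiny subsets make the ratio uninformative:
    e.g. subsets of 2 and 3 neurons allow only nine loop-like structures, so
    a single loop already yields 0.11).
    """
    n_i = pair_forming_i if isinstance(pair_forming_i, int) else len(set(pair_forming_i))
    n_j = pair_forming_j if isinstance(pair_forming_j, int) else len(set(pair_forming_j))
    den = count_possible(n_i, n_j, "loop_two_area")
    if den == 0:
        return UNDEFINED, True
    return n_loops / den, den < denominator_floor


def expected_direct_proportion(n_i: int, n_j: int) -> float:
    """Null proportion of direct (outer-area-i) loops among all loops.

    ``(n_i - 1) / (n_i + n_j - 2)``: the fraction of possible two-area
    triplets whose repeated area is *i*.  Complementary in *i* <-> *j*.
    """
    if n_i + n_j < 3:
        raise ValueError("need at least three neurons across the two areas")
    return (n_i - 1) / (n_i + n_j - 2)


def binomial_direction_test(k_ij: int, k_ji: int) -> Value:
    """Exact two-sided binomial test of directional pair asymmetry (p0=0.5).

    Only delayed (directional) pairs enter; synchronous pairs are excluded
    upstream because their expected rate depends on the bin size.  Undefined
    when no directional pair exists.
    """
    n = k_ij + k_ji
    if n == 0:
        return UNDEFINED
    return float(sps.binomtest(k_ij, n, 0.5, alternative="two-sided").pvalue)


def binomial_loop_test(k_direct: int, k_reverse: int, n_i: int, n_j: int) -> Value:
    """Exact two-sided binomial test of loop-chain asymmetry.

    The null is *not* equiprobable: the chance of a direct loop (outer area
    *i*) is :func:`expected_direct_proportion`.  Two-sided by the
    minimum-likelihood method (outcomes no more probable than the observed
    count are summed).
    """
    n = k_direct + k_reverse
    if n == 0:
        return UNDEFINED
    p0 = expected_direct_proportion(n_i, n_j)
    return float(sps.binomtest(k_direct, n, p0, alternative="two-sided").pvalue)


def compare_chain_latencies(
    first_half_latencies, second_half_latencies
) -> tuple[float, float]:
    """One-tailed pooled-variance two-sample t test on chain-link latencies.

    Latency of a link = lag difference x bin size (seconds).  Tests whether
    the first half of the chain is *slower* than the second
    (``mean(first) > mean(second)``); returns ``(t, one-tailed p)``.
    """
    a = np.asarray(first_half_latencies, dtype=float)
    b = np.asarray(second_half_latencies, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each latency list needs at least two values")
    res = sps.ttest_ind(a, b, equal_var=True, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def rank_area_pairs(
    stats: list[AreaPairStats],
    metric: str = "pair",
    min_neurons: int = 100,
    min_mice: int = 2,
    k: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rank area pairs by assembly probability.

    ``metric='pair'`` ranks by total inter-regional pair probability,
    ``'loop'`` by total loop-like probability.  Only pairs whose two areas
    both have at least ``min_neurons`` neurons and that were recorded in at
    least ``min_mice`` mice enter.  Descending by probability (undefined ->
    excluded); ties broken by the larger possible-combination count, then
    lexicographically.  Returns (full ranking, top-k, bottom-k) frames with a
    1-based ``rank`` column.
    """
    if metric == "pair":
        prob_of, poss_of = (lambda s: s.p_pairs_ext_total), (lambda s: s.possible_ext)
    elif metric == "loop":
        prob_of, poss_of = (lambda s: s.p_loop_total), (lambda s: s.possible_loop)
    else:
        raise ValueError("metric must be 'pair' or 'loop'")
    rows = []
    for s in stats:
        if s.n_i < min_neurons or s.n_j < min_neurons or s.n_mice < min_mice:
            continue
        p = prob_of(s)
        if p == UNDEFINED:
            continue
        rows.append(
            {
                "area_i": s.area_i,
                "area_j": s.area_j,
                "probability": float(p),
                "possible": poss_of(s),
                "n_i": s.n_i,
                "n_j": s.n_j,
                "n_mice": s.n_mice,
            }
        )
    df = pd.DataFrame(
        rows, columns=["area_i", "area_j", "probability", "possible", "n_i", "n_j", "n_mice"]
    )
    if len(df):
        df = df.sort_values(
            by=["probability", "possible", "area_i", "area_j"],
            ascending=[False, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df, df.head(k).copy(), df.tail(k).copy()


def ranking_difference(pair_ranking: pd.DataFrame, loop_ranking: pd.DataFrame) -> pd.DataFrame:
    """Absolute rank shift of each area pair between the two rankings."""
    a = pair_ranking[["area_i", "area_j", "rank"]].rename(columns={"rank": "rank_pair"})
    b = loop_ranking[["area_i", "area_j", "rank"]].rename(columns={"rank": "rank_loop"})
    out = a.merge(b, on=["area_i", "area_j"], how="inner")
    out["rank_difference"] = (out["rank_pair"] - out["rank_loop"]).abs()
    return out


def classify_directional_homogeneity(significant_directions: list[str]) -> str:
    """Does an area play one consistent role across its significant partners?

    ``significant_directions`` holds, for each partner area with a
    significant binomial asymmetry, the role this area plays there (e.g.
    'leading'/'trailing' or 'direct'/'reverse').  All equal -> 'homogeneous';
    mixed -> 'heterogeneous'; no significant partner -> 'insufficient'.
    """
    if not significant_directions:
        return "insufficient"
    return "homogeneous" if len(set(significant_directions)) == 1 else "heterogeneous"
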