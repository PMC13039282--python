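"""Motif taxonomy for detected assemblies.

Pairs split along two axes: scope (intra- vs inter-regional) and timing
(synchronous, all lags zero, vs directional).  Triplets spanning exactly two
areas with a strictly delayed chain whose first and last members share an
area are *loop-like* -- the motif that can carry re-entrant (feedback)
coordination between two regions.  A loop that is direct with respect to the
outer area (Area_i -> Area_j -> Area_i) is, by the same token, reverse with
respect to the inner area.  Everything else is non-loop-like, with an
explicit subtype: it contains synchrony, is a unidirectional two-area chain,
stays within one area, or spans three areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .detection import Assembly

__all__ = [
    "PairClass",
    "TripletClass",
    "classify_pair",
    "classify_triplet",
    "partition_neurons",
    "LOOP",
    "NON_LOOP",
]

LOOP = "loop"
NON_LOOP = "non_loop"


@dataclass(frozen=True)
class PairClass:
    """Classification of a two-neuron assembly."""

    scope: str  # "intra_regional" | "inter_regional"
    timing: str  # "synchronous" | "directional"
    leading_area: str | None = None  # directional only
    trailing_area: str | None = None

    @property
    def is_inter_regional(self) -> bool:
        return self.scope == "inter_regional"

    @property
    def is_directional(self) -> bool:
        return self.timing == "directional"


@dataclass(frozen=True)
class TripletClass:
    """Classification of a three-neuron assembly.

    For a loop-like triplet, ``outer_area`` holds the area of the first and
    last chain member and ``inner_area`` the middle member's area; the same
    object is a *direct* loop w.r.t. the outer area and a *reverse* loop
    w.r.t. the inner area (:meth:`kind_for`).
    """

    kind: str  # LOOP | NON_LOOP
    outer_area: str | None = None
    inner_area: str | None = None
    non_loop_subtype: str | None = None
    # subtypes: contains_synchrony | unidirectional_chain | intra_regional | three_area

    @property
    def is_loop(self) -> bool:
        return self.kind == LOOP

    @property
    def spans_two_areas(self) -> bool:
        return self.non_loop_subtype in (None, "contains_synchrony", "unidirectional_chain")

    def kind_for(self, reference_area: str) -> str:
        """'direct_loop' or 'reverse_loop' w.r.t. a reference area."""
        if not self.is_loop:
            return NON_LOOP
        if reference_area == self.outer_area:
            return "direct_loop"
        if reference_area == self.inner_area:
            return "reverse_loop"
        raise ValueError(f"area {reference_area!r} is not part of this loop")


def _member_areas(assembly: Assembly, areas: Mapping[str, str]) -> tuple[str, ...]:
    try:
        return tuple(areas[m] for m in assembly.members)
    except KeyError as err:
        raise KeyError(f"no area label for neuron {err.args[0]!r}") from None


def classify_pair(assembly: Assembly, areas: Mapping[str, str]) -> PairClass:
    """Classify a pair assembly by scope and timing.

    The leading area is the lag-0 member's area (directional pairs only).
    """
    if assembly.size != 2:
        raise ValueError("classify_pair requires a two-member assembly")
    a0, a1 = _member_areas(assembly, areas)
    scope = "intra_regional" if a0 == a1 else "inter_regional"
    if assembly.lags[1] == 0:
        return PairClass(scope=scope, timing="synchronous")
    return PairClass(scope=scope, timing="directional", leading_area=a0, trailing_area=a1)


def classify_triplet(assembly: Assembly, areas: Mapping[str, str]) -> TripletClass:
    """Classify a triplet assembly (members already ordered by lag).

    Loop-like requires *all* consecutive lags strictly positive (any zero-lag
    link is synchrony and disqualifies), exactly two areas, and the first and
    last member sharing an area.
    """
    if assembly.size != 3:
        raise ValueError("classify_triplet requires a three-member assembly")
    a = _member_areas(assembly, areas)
    l0, l1, l2 = assembly.lags
    n_areas = len(set(a))
    if n_areas == 1:
        return TripletClass(kind=NON_LOOP, non_loop_subtype="intra_regional")
    if n_areas == 3:
        return TripletClass(kind=NON_LOOP, non_loop_subtype="three_area")
    if l1 == l0 or l2 == l1:
        return TripletClass(kind=NON_LOOP, non_loop_subtype="contains_synchrony")
    if a[0] == a[2]:
        return TripletClass(kind=LOOP, outer_area=a[0], inner_area=a[1])
    return TripletClass(kind=NON_LOOP, non_loop_subtype="unidirectional_chain")


def partition_neurons(
    triplets: Iterable[tuple[Assembly, TripletClass]],
    all_neurons: Iterable[str],
    include_intra_regional: bool = False,
) -> dict[str, str]:
    """Partition neurons into loop_like / non_loop_like / other populations.

    ``loop_like``: member of at least one loop-like triplet (dominates).
    ``non_loop_like``: member of at least one non-loop inter-regional triplet
    and of no loop-like triplet.  ``other``: neither.  By default only
    two-area non-loop triplets feed the control population; set
    ``include_intra_regional`` to also count one-area triplets.
    """
    loop_members: set[str] = set()
    non_loop_members: set[str] = set()
    for assembly, cls in triplets:
        if cls.is_loop:
            loop_members.update(assembly.members)
        elif cls.spans_two_areas or (
            include_intra_regional and cls.non_loop_subtype == "intra_regional"
        ):
            non_loop_members.update(assembly.members)
    out: dict[str, str] = {}
    for nid in all_neurons:
        if nid in loop_members:
            out[nid] = "loop_like"
        elif nid in non_loop_members:
            out[nid] = "non_loop_like"
        else:
            out[nid] = "other"
    return out
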