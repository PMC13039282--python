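"""Hubness scoring, hub identification and the embedded-hub association test.

A neuron's *external hubness* is the number of distinct external areas with
which it coordinates in at least one inter-regional pair assembly (several
assemblies with the same area count once); *internal hubness* is the number
of distinct same-area partners in intra-regional pairs.  Hubs are identified
two ways: the *percentage* method (score strictly greater than half the
possible connections) and the *percentile* method (score at or above the
nearest-rank 95th percentile of the area's pooled connectivity distribution,
ties at the threshold included, zero scores never hubs).

The association between loop-like membership and hubness is tested per area
with a one-tailed Fisher's exact test on the 2x2 (population x hub) table,
with Benjamini-Hochberg FDR correction across areas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .detection import Assembly
from .motifs import PairClass
from .spike_io import Recording

__all__ = [
    "HubRecord",
    "EmbeddedHubTest",
    "score_hubness",
    "identify_hubs_percentage",
    "identify_hubs_percentile",
    "embedded_hub_test",
    "fdr_correct",
    "run_embedded_hub_tests",
]


@dataclass
class HubRecord:
    """Per-neuron hubness scores, hub flags and population label."""

    neuron_id: str
    area: str
    session_id: str
    mouse_id: str
    external_hubness: int = 0
    internal_hubness: int = 0
    possible_external: int = 0
    possible_internal: int = 0
    population: str = "other"  # loop_like | non_loop_like | other
    hub_flags: dict[str, bool] = field(default_factory=dict)  # keyed (method, scope)

    def score(self, scope: str) -> int:
        if scope == "external":
            return self.external_hubness
        if scope == "internal":
            return self.internal_hubness
        raise ValueError("scope must be 'external' or 'internal'")

    def possible(self, scope: str) -> int:
        return self.possible_external if scope == "external" else self.possible_internal


@dataclass
class EmbeddedHubTest:
    """One Fisher test of hub enrichment in the loop-like population."""

    area: str
    method: str  # percentage | percentile
    scope: str  # external | internal
    control: str  # non_loop | all_remaining
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: loop, control; cols: hub, non-hub
    p_value: float
    p_fdr: float | None = None
    n_loop: int = 0
    n_control: int = 0
    excluded: str | None = None  # reason when the area fails inclusion


def score_hubness(
    pairs: list[tuple[Assembly, PairClass]],
    recording: Recording,
    populations: dict[str, str] | None = None,
) -> list[HubRecord]:
    """Score every neuron of a recording from its classified pair assemblies.

    ``possible_external`` is the number of *other* areas recorded in the
    session; ``possible_internal`` is the neuron's area size minus one.
    ``populations`` optionally attaches loop-like / non-loop-like / other
    labels (from :func:`loophub.motifs.partition_neurons`).
    """
    area_of = recording.area_map()
    all_areas = recording.areas()
    area_sizes: dict[str, int] = {}
    for tr in recording.neurons:
        area_sizes[tr.area] = area_sizes.get(tr.area, 0) + 1
    mouse_of = getattr(recording, "neuron_mouse", {})

    ext_partners: dict[str, set[str]] = {nid: set() for nid in recording.neuron_ids}
    int_partners: dict[str, set[str]] = {nid: set() for nid in recording.neuron_ids}
    for assembly, cls in pairs:
        m0, m1 = assembly.members
        if cls.is_inter_regional:
            ext_partners[m0].add(area_of[m1])
            ext_partners[m1].add(area_of[m0])
        else:
            int_partners[m0].add(m1)
            int_partners[m1].add(m0)

    records = []
    for tr in recording.neurons:
        nid = tr.neuron_id
        records.append(
            HubRecord(
                neuron_id=nid,
                area=tr.area,
                session_id=recording.session_id,
                mouse_id=mouse_of.get(nid, recording.mouse_id),
                external_hubness=len(ext_partners[nid]),
                internal_hubness=len(int_partners[nid]),
                possible_external=len(all_areas) - 1,
                possible_internal=area_sizes[tr.area] - 1,
                population=(populations or {}).get(nid, "other"),
            )
        )
    return records


def identify_hubs_percentage(
    records: list[HubRecord], scope: str
) -> tuple[dict[str, bool], set[str]]:
    """Hub = score strictly greater than half the possible connections.

    Returns the flags plus the set of *untestable* areas: areas where no
    neuron passes the threshold (hypoconnectivity) or where every neuron
    does (hyperconnectivity makes hub identification impossible), including
    areas with zero possible connections.  Flags are also stored on each
    record under the key ``("percentage", scope)``.
    """
    flags: dict[str, bool] = {}
    by_area: dict[str, list[bool]] = {}
    for r in records:
        if r.possible(scope) <= 0:
            is_hub = False
            by_area.setdefault(r.area, [])  # area present but untestable neuron
        else:
            is_hub = r.score(scope) > r.possible(scope) / 2
            by_area.setdefault(r.area, []).append(is_hub)
        flags[r.neuron_id] = is_hub
        r.hub_flags[("percentage", scope)] = is_hub
    untestable = {
        area
        for area, hub_list in by_area.items()
        if not hub_list or all(hub_list) or not any(hub_list)
    }
    return flags, untestable


def _nearest_rank_percentile(scores: np.ndarray, q: float) -> float:
    """Nearest-rank q-th percentile: value at index ceil(q/100 * n), 1-based."""
    s = np.sort(np.asarray(scores))
    rank = max(1, math.ceil(q / 100.0 * s.size))
    return float(s[rank - 1])


def identify_hubs_percentile(
    records: list[HubRecord], scope: str, q: float = 95.0
) -> dict[str, bool]:
    """Hub = score at or above the area's nearest-rank q-th percentile.

    The reference distribution pools the scores of all records passed for
    each area (callers restrict the list to the populations under
    comparison).  Ties at the threshold are hubs; a zero score is never a
    hub.  Flags are stored under ``("percentile", scope)``.
    """
    flags: dict[str, bool] = {}
    by_area: dict[str, list[HubRecord]] = {}
    for r in records:
        by_area.setdefault(r.area, []).append(r)
    for area, rs in by_area.items():
        thr = _nearest_rank_percentile(np.array([r.score(scope) for r in rs]), q)
        for r in rs:
            is_hub = r.score(scope) >= thr and r.score(scope) > 0
            flags[r.neuron_id] = is_hub
            r.hub_flags[("percentile", scope)] = is_hub
    return flags


def fdr_correct(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p, np.zeros(0, dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def embedded_hub_test(
    records: list[HubRecord],
    area: str,
    method: str = "percentile",
    scope: str = "external",
    control: str = "non_loop",
    min_group: int = 35,
    min_mice: int = 2,
    percentile_q: float = 95.0,
) -> EmbeddedHubTest:
    """Is the loop-like population of an area enriched in hub neurons?

    Builds the 2x2 table (loop-like vs control population) x (hub vs
    non-hub) and computes the one-tailed Fisher's exact p (hypergeometric
    upper tail: loop-like enriched).  Hub flags are recomputed within the
    pooled comparison group using the requested method.  Areas with fewer
    than ``min_group`` neurons in either population, or recorded in fewer
    than ``min_mice`` mice, are excluded with a reason.
    """
    if control not in ("non_loop", "all_remaining"):
        raise ValueError("control must be 'non_loop' or 'all_remaining'")
    loop = [r for r in records if r.area == area and r.population == "loop_like"]
    if control == "non_loop":
        ctrl = [r for r in records if r.area == area and r.population == "non_loop_like"]
    else:
        ctrl = [r for r in records if r.area == area and r.population != "loop_like"]

    def excluded(reason: str) -> EmbeddedHubTest:
        return EmbeddedHubTest(
            area=area,
            method=method,
            scope=scope,
            control=control,
            table=((0, 0), (0, 0)),
            p_value=float("nan"),
            n_loop=len(loop),
            n_control=len(ctrl),
            excluded=reason,
        )

    if len(loop) < min_group or len(ctrl) < min_group:
        return excluded(
            f"needs >= {min_group} neurons per population "
            f"(loop={len(loop)}, control={len(ctrl)})"
        )
    mice = {r.mouse_id for r in loop + ctrl}
    if len(mice) < min_mice:
        return excluded(f"recorded in {len(mice)} mouse/mice, needs >= {min_mice}")

    pooled = loop + ctrl
    if method == "percentage":
        flags, _ = identify_hubs_percentage(pooled, scope)
    elif method == "percentile":
        flags = identify_hubs_percentile(pooled, scope, q=percentile_q)
    else:
        raise ValueError("method must be 'percentage' or 'percentile'")

    a = sum(flags[r.neuron_id] for r in loop)
    b = len(loop) - a
    c = sum(flags[r.neuron_id] for r in ctrl)
    d = len(ctrl) - c
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="greater")
    return EmbeddedHubTest(
        area=area,
        method=method,
        scope=scope,
        control=control,
        table=((a, b), (c, d)),
        p_value=float(p),
        n_loop=len(loop),
        n_control=len(ctrl),
    )


def run_embedded_hub_tests(
    records: list[HubRecord],
    method: str = "percentile",
    scope: str = "external",
    control: str = "non_loop",
    min_group: int = 35,
    min_mice: int = 2,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Run the embedded-hub test for every area and FDR-correct across areas.

    The FDR family is the set of areas tested within one (method, scope,
    control) combination.  Excluded areas appear in the output with their
    reason and no p-values.
    """
    areas = sorted({r.area for r in records})
    tests = [
        embedded_hub_test(records, area, method, scope, control, min_group, min_mice)
        for area in areas
    ]
    kept = [t for t in tests if t.excluded is None]
    if kept:
        p_adj, reject = fdr_correct([t.p_value for t in kept], q=fdr_q)
        for t, pa in zip(kept, p_adj):
            t.p_fdr = float(pa)
    rows = [
        {
            "area": t.area,
            "method": t.method,
            "scope": t.scope,
            "control": t.control,
            "n_loop": t.n_loop,
            "n_control": t.n_control,
            "loop_hubs": t.table[0][0],
            "control_hubs": t.table[1][0],
            "p_value": t.p_value,
            "p_fdr": t.p_fdr if t.p_fdr is not None else float("nan"),
            "significant": (t.p_fdr is not None and t.p_fdr < fdr_q),
            "excluded": t.excluded or "",
        }
        for t in tests
    ]
    return pd.DataFrame(rows)
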