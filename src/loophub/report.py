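"""Heatmap matrices, rankings and the area-centred hub graph.

The hub graph mirrors the study's graph-based representation: a centre area's
loop-like and non-loop-like neurons (node size proportional to external
hubness), fixed-size nodes for the external areas, one red neuron->area edge
per distinct partner area regardless of assembly multiplicity, and dashed
intra-area neuron<->neuron edges (one per intra-regional pair).  Layout is a
seeded force-directed placement (networkx ``spring_layout``).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import UNDEFINED, AreaPairStats
from .detection import Assembly
from .hubs import HubRecord
from .motifs import PairClass

__all__ = [
    "build_area_graph",
    "export_graph",
    "directional_probability_matrix",
    "composite_matrix",
    "render_heatmap",
]

#: Sentinel written for area pairs never recorded simultaneously.
NOT_RECORDED = "not_recorded"


def build_area_graph(
    records: list[HubRecord],
    pairs: list[tuple[Assembly, PairClass]],
    center_area: str,
    seed: int = 0,
    include_other: bool = False,
) -> nx.Graph:
    """Undirected graph centred on one area.

    Nodes: external areas (``kind='area'``, fixed size), centre-area neurons
    of the loop-like and non-loop-like populations (``kind='neuron'``,
    ``size`` proportional to external hubness; 'other' neurons included on
    request).  Edges: ``kind='external'`` neuron->area (one per distinct
    partner area) and ``kind='internal'`` neuron<->neuron (one per
    intra-regional pair).  Node positions (``pos``) come from a seeded
    force-directed layout, deterministic for a given seed.
    """
    by_id = {r.neuron_id: r for r in records}
    center = [
        r
        for r in records
        if r.area == center_area
        and (r.population in ("loop_like", "non_loop_like") or include_other)
    ]
    if not any(r.area == center_area for r in records):
        raise ValueError(f"unknown center area {center_area!r}")

    g = nx.Graph()
    keep = {r.neuron_id for r in center}
    for r in center:
        g.add_node(
            r.neuron_id,
            kind="neuron",
            population=r.population,
            size=1.0 + float(r.external_hubness),
        )
    for assembly, cls in pairs:
        m0, m1 = assembly.members
        r0, r1 = by_id.get(m0), by_id.get(m1)
        if r0 is None or r1 is None:
            continue
        if cls.is_inter_regional:
            for here, there in ((r0, r1), (r1, r0)):
                if here.neuron_id in keep and there.area != center_area:
                    if not g.has_node(there.area):
                        g.add_node(there.area, kind="area", size=3.0)
                    g.add_edge(here.neuron_id, there.area, kind="external")
        elif r0.area == center_area and m0 in keep and m1 in keep:
            g.add_edge(m0, m1, kind="internal")
    pos = nx.spring_layout(g, seed=seed)
    nx.set_node_attributes(g, {n: (float(x), float(y)) for n, (x, y) in pos.items()}, "pos")
    return g


def export_graph(g: nx.Graph, graphml_path: str | Path, edgelist_path: str | Path) -> None:
    """Write the graph as GraphML plus a plain edge-list CSV."""
    h = g.copy()
    for n, data in h.nodes(data=True):
        if "pos" in data:
            data["x"], data["y"] = data.pop("pos")
    nx.write_graphml(h, graphml_path)
    rows = [
        {"source": u, "target": v, "kind": d.get("kind", "")} for u, v, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "kind"]).to_csv(edgelist_path, index=False)


def render_heatmap(
    matrix: pd.DataFrame, path: str | Path, log_scale: bool = True, title: str = ""
) -> None:
    """Render a probability/difference matrix as a heatmap figure.

    Probabilities use a logarithmic colour scale, normalised differences a
    linear symmetric one (pass ``log_scale=False``); undefined entries and
    never-co-recorded pairs render light grey.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    vals = matrix.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(matrix)),) * 2)
    masked = np.ma.masked_invalid(vals)
    cmap = plt.get_cmap("viridis" if log_scale else "coolwarm").copy()
    cmap.set_bad("#d9d9d9")
    if log_scale:
        positive = masked[masked > 0]
        norm = (
            LogNorm(vmin=float(positive.min()), vmax=float(positive.max()))
            if positive.size
            else None
        )
        im = ax.imshow(np.ma.masked_less_equal(masked, 0), cmap=cmap, norm=norm)
    else:
        lim = float(np.abs(masked).max()) if masked.count() else 1.0
        im = ax.imshow(masked, cmap=cmap, vmin=-lim, vmax=lim)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _fmt(v) -> object:
    return v if v != UNDEFINED else UNDEFINED


def directional_probability_matrix(
    stats: list[AreaPairStats], metric: str = "pair"
) -> pd.DataFrame:
    """Square matrix of directional probabilities; entry (i, j) is the
    probability of a directional pair from area i to area j (``metric='pair'``)
    or of a direct loop with outer area i (``'loop'``).  The diagonal and
    never-co-recorded pairs carry sentinels."""
    areas = sorted({s.area_i for s in stats} | {s.area_j for s in stats})
    m = pd.DataFrame(NOT_RECORDED, index=areas, columns=areas, dtype=object)
    np.fill_diagonal(m.values, UNDEFINED)
    for s in stats:
        if metric == "pair":
            fwd, rev = s.p_pairs_ext_ij, s.p_pairs_ext_ji
        else:
            fwd, rev = s.p_loop_direct_ij, s.p_loop_direct_ji
        m.loc[s.area_i, s.area_j] = _fmt(fwd)
        m.loc[s.area_j, s.area_i] = _fmt(rev)
    return m


def composite_matrix(stats: list[AreaPairStats], metric: str = "pair") -> pd.DataFrame:
    """Lower triangle: total probability; upper triangle: normalised
    directional difference (the two-panel heatmap composition)."""
    areas = sorted({s.area_i for s in stats} | {s.area_j for s in stats})
    pos = {a: k for k, a in enumerate(areas)}
    m = pd.DataFrame(NOT_RECORDED, index=areas, columns=areas, dtype=object)
    np.fill_diagonal(m.values, UNDEFINED)
    for s in stats:
        if metric == "pair":
            total, diff = s.p_pairs_ext_total, s.p_pairs_difference
        else:
            total, diff = s.p_loop_total, s.p_loop_difference
        lo, hi = sorted((s.area_i, s.area_j), key=pos.get)
        m.loc[hi, lo] = _fmt(total)  # lower triangle (row below column)
        m.loc[lo, hi] = _fmt(diff)  # upper triangle
    return m
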