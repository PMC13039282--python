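"""End-to-end orchestration: simulate -> filter -> detect -> classify ->
stats -> hubs -> report, with every stage's output persisted as CSV/JSON."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (
    aggregate_sessions,
    area_pair_statistics,
    rank_area_pairs,
    ranking_difference,
    tabulate_session,
)
from .detection import Assembly, DetectionConfig, detect_pairs, extend_to_triplets
from .hubs import run_embedded_hub_tests, score_hubness
from .motifs import classify_pair, classify_triplet, partition_neurons
from .report import (
    build_area_graph,
    composite_matrix,
    directional_probability_matrix,
    export_graph,
    render_heatmap,
)
from .spike_io import Recording, filter_min_spikes, read_recording, write_recording
from .synthetic import ScenarioConfig, build_scenario

__all__ = ["PipelineConfig", "run_pipeline", "assemblies_to_frame"]


@dataclass
class PipelineConfig:
    """Thresholds and paths for a full pipeline run (study defaults)."""

    out_dir: str = "results"
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    min_spikes: int = 100
    ranking_min_neurons: int = 100
    ranking_min_mice: int = 2
    ranking_k: int = 30
    hub_min_group: int = 35
    hub_min_mice: int = 2
    fdr_q: float = 0.05
    center_area: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_spikes",
            "ranking_min_neurons",
            "ranking_min_mice",
            "ranking_k",
            "hub_min_group",
            "hub_min_mice",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        det = data.pop("detection", None)
        cfg = cls(**data)
        if det:
            cfg.detection = DetectionConfig(**det)
        return cfg


def assemblies_to_frame(assemblies: list[Assembly], areas: dict[str, str]) -> pd.DataFrame:
    rows = [
        {
            "assembly_id": k,
            "members": "|".join(a.members),
            "areas": "|".join(areas.get(m, "?") for m in a.members),
            "lags": "|".join(str(l) for l in a.lags),
            "bin_size": a.bin_size,
            "p_value": a.p_value,
            "n_activations": int(a.activation_bins.size),
        }
        for k, a in enumerate(assemblies)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "assembly_id",
            "members",
            "areas",
            "lags",
            "bin_size",
            "p_value",
            "n_activations",
        ],
    )


def _activations_frame(assemblies: list[Assembly]) -> pd.DataFrame:
    rows = [
        {"assembly_id": k, "bin_index": int(b), "time_s": float(b) * a.bin_size}
        for k, a in enumerate(assemblies)
        for b in a.activation_bins
    ]
    return pd.DataFrame(rows, columns=["assembly_id", "bin_index", "time_s"])


def run_pipeline(
    config: PipelineConfig,
    recording: Recording | None = None,
    scenario: ScenarioConfig | None = None,
) -> dict:
    """Run the full analysis on a recording (or a simulated scenario).

    Stages: (optional) simulate, >min_spikes filter, pair detection, triplet
    extension, motif classification, area-pair statistics and rankings, hub
    scoring and embedded-hub tests, graph/report outputs.  Every stage
    writes its tables under ``config.out_dir``; a run log records versions,
    seeds and parameters.  Returns the in-memory result bundle.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        if recording is None:
            stage = "simulate"
            if scenario is None:
                raise ValueError("provide a recording or a scenario")
            recording, manifest = build_scenario(scenario)
            manifest.to_json(out / "ground_truth.json")
            write_recording(recording, out / "spikes.csv", out / "neurons.csv")

        stage = "filter"
        filtered = filter_min_spikes(recording, config.min_spikes)
        areas = filtered.area_map()
        area_sizes: dict[str, int] = {}
        for tr in filtered.neurons:
            area_sizes[tr.area] = area_sizes.get(tr.area, 0) + 1

        stage = "detect-pairs"
        pairs = detect_pairs(filtered, config.detection)
        stage = "detect-triplets"
        triplets = (
            extend_to_triplets(filtered, pairs, config.detection)
            if config.detection.max_size >= 3
            else []
        )
        assemblies_to_frame(pairs, areas).to_csv(out / "pairs.csv", index=False)
        assemblies_to_frame(triplets, areas).to_csv(out / "triplets.csv", index=False)
        _activations_frame(pairs).to_csv(out / "pair_activations.csv", index=False)

        stage = "classify"
        cpairs = [(a, classify_pair(a, areas)) for a in pairs]
        ctrips = [(a, classify_triplet(a, areas)) for a in triplets]
        motif_rows = [
            {
                "assembly_id": k,
                "members": "|".join(a.members),
                "size": a.size,
                "label": (
                    f"{c.scope}_{c.timing}"
                    if a.size == 2
                    else (c.kind if c.is_loop else f"non_loop:{c.non_loop_subtype}")
                ),
                "outer_area": getattr(c, "outer_area", None) or "",
                "inner_area": getattr(c, "inner_area", None) or "",
            }
            for k, (a, c) in enumerate(cpairs + ctrips)
        ]
        pd.DataFrame(motif_rows).to_csv(out / "motifs.csv", index=False)
        populations = partition_neurons(ctrips, filtered.neuron_ids)
        pd.DataFrame(
            [{"neuron_id": n, "population": p} for n, p in populations.items()]
        ).to_csv(out / "populations.csv", index=False)

        stage = "stats"
        counts = tabulate_session(
            cpairs, ctrips, areas, area_sizes, filtered.session_id, filtered.mouse_id
        )
        pooled = [aggregate_sessions([c]) for c in counts]
        stats = [area_pair_statistics(c) for c in pooled]
        stats_df = pd.DataFrame([vars(s) for s in stats])
        stats_df.to_csv(out / "area_pair_statistics.csv", index=False)
        for metric in ("pair", "loop"):
            directional = directional_probability_matrix(stats, metric)
            directional.to_csv(out / f"heatmap_directional_{metric}.csv")
            composite_matrix(stats, metric).to_csv(out / f"heatmap_composite_{metric}.csv")
            render_heatmap(
                directional,
                out / f"heatmap_directional_{metric}.png",
                log_scale=True,
                title=f"directional {metric} probability",
            )
        rank_pair, top_p, bot_p = rank_area_pairs(
            stats, "pair", config.ranking_min_neurons, config.ranking_min_mice, config.ranking_k
        )
        rank_loop, top_l, bot_l = rank_area_pairs(
            stats, "loop", config.ranking_min_neurons, config.ranking_min_mice, config.ranking_k
        )
        rank_pair.to_csv(out / "ranking_pairs.csv", index=False)
        rank_loop.to_csv(out / "ranking_loops.csv", index=False)
        ranking_difference(rank_pair, rank_loop).to_csv(
            out / "ranking_comparison.csv", index=False
        )

        stage = "hubs"
        records = score_hubness(cpairs, filtered, populations)
        hub_tables = []
        for method in ("percentage", "percentile"):
            for scope in ("external", "internal"):
                df = run_embedded_hub_tests(
                    records,
                    method=method,
                    scope=scope,
                    control="non_loop",
                    min_group=config.hub_min_group,
                    min_mice=config.hub_min_mice,
                    fdr_q=config.fdr_q,
                )
                hub_tables.append(df)
        hub_stats = pd.concat(hub_tables, ignore_index=True)
        hub_stats.to_csv(out / "hub_statistics.csv", index=False)

        stage = "report"
        notices = []
        if config.detection.max_size < 3:
            notices.append("max_size=2: triplet-dependent outputs skipped")
        center = config.center_area
        if center is None and area_sizes:
            center = max(area_sizes, key=area_sizes.get)
        graph = None
        if center is not None and config.detection.max_size >= 3:
            graph = build_area_graph(records, cpairs, center, seed=config.seed)
            export_graph(graph, out / "area_graph.graphml", out / "area_graph_edges.csv")

        log = {
            "loophub_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "seed": config.seed,
            "min_spikes": config.min_spikes,
            "bin_sizes": list(config.detection.bin_sizes),
            "max_lags": list(config.detection.max_lags),
            "alpha": config.detection.alpha,
            "chunk_bins": config.detection.chunk_bins,
            "max_size": config.detection.max_size,
            "n_neurons_analysed": filtered.n_neurons,
            "n_pairs": len(pairs),
            "n_triplets": len(triplets),
            "notices": notices,
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=1))
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return {
        "recording": filtered,
        "pairs": cpairs,
        "triplets": ctrips,
        "populations": populations,
        "stats": stats,
        "rankings": {"pair": rank_pair, "loop": rank_loop},
        "hub_records": records,
        "hub_statistics": hub_stats,
        "graph": graph,
        "notices": notices,
    }
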