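"""Scoring detected assemblies against planted ground truth, plus the
calibration / oracle-agreement / hub-power simulations used to validate the
pipeline on synthetic data."""

from __future__ import annotations

import numpy as np

from .detection import (
    Assembly,
    DetectionConfig,
    _lag_sweep,
    detect_pairs,
    surrogate_null_p,
)
from .hubs import run_embedded_hub_tests, score_hubness
from .motifs import classify_pair, classify_triplet
from .spike_io import BinnedTrain
from .synthetic import (
    GroundTruthManifest,
    ManifestEntry,
    ScenarioConfig,
    build_scenario,
    hub_association_structure,
)

__all__ = [
    "pair_recovery",
    "triplet_recovery",
    "pair_false_positive_fraction",
    "surrogate_agreement",
    "embedded_hub_rejections",
]


def _delays(members, lags, bin_size) -> dict[str, float]:
    """Member activation delay (s) relative to the first member."""
    return {m: (l - lags[0]) * bin_size for m, l in zip(members, lags)}


def _entry_matches(entry: ManifestEntry, detected: Assembly, areas: dict[str, str]) -> bool:
    """Same member set, every delay within one planted bin, same motif class.

    The detector may settle on a neighbouring grid resolution, so delays are
    compared in seconds, with a one-planted-bin tolerance per member.
    """
    if frozenset(entry.members) != frozenset(detected.members):
        return False
    planted = _delays(entry.members, entry.lags, entry.bin_size)
    got = _delays(detected.members, detected.lags, detected.bin_size)
    ref = entry.members[0]
    offset = got[ref]  # re-reference detected delays to the planted first member
    if any(abs((got[m] - offset) - planted[m]) > entry.bin_size + 1e-9 for m in entry.members):
        return False
    if entry.size == 2:
        want = classify_pair(entry.as_assembly(), areas)
        have = classify_pair(detected, areas)
        if (want.scope, want.timing) != (have.scope, have.timing):
            return False
        if want.is_directional and want.leading_area != have.leading_area:
            return False
    else:
        want = classify_triplet(entry.as_assembly(), areas)
        have = classify_triplet(detected, areas)
        if want.kind != have.kind:
            return False
        if want.is_loop and (want.outer_area, want.inner_area) != (
            have.outer_area,
            have.inner_area,
        ):
            return False
    return True


def pair_recovery(
    manifest: GroundTruthManifest, detected: list[Assembly], areas: dict[str, str]
) -> tuple[int, int]:
    """(number of planted pairs recovered, number planted)."""
    by_set = {frozenset(a.members): a for a in detected}
    hits = sum(
        1
        for e in manifest.pairs
        if frozenset(e.members) in by_set and _entry_matches(e, by_set[frozenset(e.members)], areas)
    )
    return hits, len(manifest.pairs)


def triplet_recovery(
    manifest: GroundTruthManifest, detected: list[Assembly], areas: dict[str, str]
) -> tuple[int, int]:
    """(number of planted triplets recovered, number planted)."""
    by_set = {frozenset(a.members): a for a in detected}
    hits = sum(
        1
        for e in manifest.triplets
        if frozenset(e.members) in by_set and _entry_matches(e, by_set[frozenset(e.members)], areas)
    )
    return hits, len(manifest.triplets)


def pair_false_positive_fraction(
    seeds,
    n_neurons: int = 30,
    duration: float = 600.0,
    rate_hz: float = 5.0,
    config: DetectionConfig | None = None,
) -> tuple[float, int]:
    """Fraction of neuron pairs called significant on independent Poisson
    recordings (every call is a false positive).  Returns (fraction, total
    pairs tested)."""
    config = config or DetectionConfig()
    n_sig = total = 0
    half = n_neurons // 2
    for seed in seeds:
        cfg = ScenarioConfig(
            areas=[("A", half), ("B", n_neurons - half)],
            duration=duration,
            default_rate=rate_hz,
            seed=int(seed),
        )
        rec, _ = build_scenario(cfg)
        n_sig += len(detect_pairs(rec, config))
        total += n_neurons * (n_neurons - 1) // 2
    return n_sig / total, total


def surrogate_agreement(
    n_cases: int = 200,
    n_bins: int = 2000,
    chunk_bins: int = 100,
    n_surrogates: int = 999,
    seed: int = 0,
) -> float:
    """Median |parametric p - permutation p| over random moderate-signal
    pairs, both computed at lag zero on the same trains."""
    rng = np.random.default_rng(seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=n_cases)
    diffs = []
    for cs in case_seeds:
        crng = np.random.default_rng(int(cs))
        p_act = crng.uniform(0.05, 0.3)
        x = (crng.random(n_bins) < p_act).astype(int)
        y = (crng.random(n_bins) < p_act).astype(int)
        shared = crng.choice(n_bins, size=int(crng.integers(0, 12)), replace=False)
        x[shared] = 1
        y[shared] = 1
        _, _, _, _, P = _lag_sweep(
            x[None].astype(float), y[None].astype(float), 0, chunk_bins, lags=np.array([0])
        )
        p_par = float(P[0, 0, 0])
        p_sur = surrogate_null_p(
            BinnedTrain(0.01, 0.0, x),
            BinnedTrain(0.01, 0.0, y),
            0,
            chunk_bins,
            n_surrogates,
            seed=int(cs) ^ 0x5EED,
        )
        diffs.append(abs(p_par - p_sur))
    return float(np.median(diffs))


def embedded_hub_rejections(
    seeds, enrichment: float, method: str = "percentile", scope: str = "external"
) -> int:
    """Number of seeds whose embedded-hub test is FDR-significant.

    ``enrichment=1`` gives the null scenario (hubness independent of the
    loop-like label), larger values couple loop membership to external
    partner count.
    """
    hits = 0
    for seed in seeds:
        rec, pairs, labels = hub_association_structure(int(seed), enrichment=enrichment)
        areas = rec.area_map()
        cpairs = [(a, classify_pair(a, areas)) for a in pairs]
        records = [r for r in score_hubness(cpairs, rec, labels) if r.area == "CTX"]
        df = run_embedded_hub_tests(records, method=method, scope=scope)
        row = df[df.area == "CTX"].iloc[0]
        hits += bool(row.significant)
    return hits
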