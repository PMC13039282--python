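"""Synthetic spike recordings with planted assemblies and hub structure.

Background activity is modelled as independent (piecewise-)homogeneous
Poisson point processes per neuron.  Assemblies are planted on top: each
planted assembly fires ``n_activations`` times at occurrence times drawn
uniformly over the recording, and member *m* contributes a spike at
``occurrence + lags[m] * bin_size + U(0, jitter)``.  Because the jitter is
smaller than the bin size, the planted coordination is detectable at the
planted resolution.  A machine-readable manifest records every planted
structure so that downstream stages can be scored against ground truth.

The module also generates assembly-level hub scenarios (planted inter-area
pair structures with a configurable external-partner enrichment of the
loop-like population) used to exercise the embedded-hub statistics without
simulating spikes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .detection import Assembly
from .spike_io import NeuronTrain, Recording

__all__ = [
    "PlantSpec",
    "ScenarioConfig",
    "GroundTruthManifest",
    "generate_background",
    "plant_assembly",
    "build_scenario",
    "reference_scenario",
    "hub_association_structure",
]

#: Piecewise-constant rate: list of (t_from, t_to, rate_hz) segments.
RateProfile = float | list[tuple[float, float, float]]


@dataclass
class PlantSpec:
    """One assembly to plant: members, temporal structure and strength."""

    members: tuple[str, ...]
    member_areas: tuple[str, ...]
    bin_size: float
    lags: tuple[int, ...]
    n_activations: int
    jitter: float = 0.0

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        self.member_areas = tuple(self.member_areas)
        self.lags = tuple(int(l) for l in self.lags)
        if len(self.members) != len(self.lags) or len(self.members) != len(self.member_areas):
            raise ValueError("members, member_areas and lags must have equal length")
        if self.lags[0] != 0 or any(np.diff(self.lags) < 0):
            raise ValueError("lags must start at 0 and be non-decreasing")
        if not self.jitter < self.bin_size:
            raise ValueError("jitter must be smaller than bin_size")
        if self.n_activations < 1:
            raise ValueError("n_activations must be >= 1")

    @property
    def lag_span(self) -> float:
        return self.lags[-1] * self.bin_size


@dataclass
class ScenarioConfig:
    """Full description of a synthetic recording.

    ``background_rates`` maps an area label (or a neuron id, which takes
    precedence) to a rate in Hz or to a piecewise-constant profile; areas
    without an entry use ``default_rate``.
    """

    areas: list[tuple[str, int]]
    duration: float
    default_rate: float = 5.0
    background_rates: dict[str, RateProfile] = field(default_factory=dict)
    planted_pairs: list[PlantSpec] = field(default_factory=list)
    planted_triplets: list[PlantSpec] = field(default_factory=list)
    hub_min_partner_areas: int = 3
    seed: int = 0
    session_id: str = "synthetic-1"
    mouse_id: str = "mouse-1"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for area, count in self.areas:
            if count < 0:
                raise ValueError(f"area {area!r}: neuron count must be >= 0")
        declared = set(self.neuron_ids())
        for spec in list(self.planted_pairs) + list(self.planted_triplets):
            missing = set(spec.members) - declared
            if missing:
                raise ValueError(f"planted members not in declared areas: {sorted(missing)}")

    def neuron_ids(self) -> list[str]:
        return [f"{area}_{k}" for area, count in self.areas for k in range(count)]

    def area_of(self, neuron_id: str) -> str:
        return neuron_id.rsplit("_", 1)[0]

    def rate_profile(self, neuron_id: str) -> list[tuple[float, float, float]]:
        prof = self.background_rates.get(
            neuron_id, self.background_rates.get(self.area_of(neuron_id), self.default_rate)
        )
        if isinstance(prof, (int, float)):
            prof = [(0.0, self.duration, float(prof))]
        for t0, t1, r in prof:
            if r < 0:
                raise ValueError("rates must be >= 0")
            if t1 <= t0:
                raise ValueError("rate segments must have positive length")
        return [(float(t0), float(t1), float(r)) for t0, t1, r in prof]


@dataclass
class ManifestEntry:
    """Ground truth for one planted assembly."""

    members: tuple[str, ...]
    member_areas: tuple[str, ...]
    bin_size: float
    lags: tuple[int, ...]
    activation_times: np.ndarray

    @property
    def size(self) -> int:
        return len(self.members)

    def as_assembly(self) -> Assembly:
        """Planted structure as an :class:`~loophub.detection.Assembly`."""
        return Assembly(
            members=self.members,
            lags=self.lags,
            bin_size=self.bin_size,
            p_value=0.0,
            activation_bins=np.floor(self.activation_times / self.bin_size).astype(np.int64),
        )


@dataclass
class GroundTruthManifest:
    """Everything planted into a scenario, for downstream scoring."""

    assemblies: list[ManifestEntry] = field(default_factory=list)
    designated_hubs: list[str] = field(default_factory=list)

    @property
    def pairs(self) -> list[ManifestEntry]:
        return [e for e in self.assemblies if e.size == 2]

    @property
    def triplets(self) -> list[ManifestEntry]:
        return [e for e in self.assemblies if e.size == 3]

    def to_json(self, path: str | Path) -> None:
        data = {
            "assemblies": [
                {**asdict(e), "activation_times": e.activation_times.tolist()}
                for e in self.assemblies
            ],
            "designated_hubs": list(self.designated_hubs),
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        data = json.loads(Path(path).read_text())
        entries = [
            ManifestEntry(
                members=tuple(e["members"]),
                member_areas=tuple(e["member_areas"]),
                bin_size=e["bin_size"],
                lags=tuple(e["lags"]),
                activation_times=np.asarray(e["activation_times"], dtype=float),
            )
            for e in data["assemblies"]
        ]
        return cls(assemblies=entries, designated_hubs=list(data["designated_hubs"]))


def _poisson_train(
    rng: np.random.Generator, profile: list[tuple[float, float, float]]
) -> np.ndarray:
    pieces = []
    for t0, t1, rate in profile:
        n = rng.poisson(rate * (t1 - t0))
        pieces.append(rng.uniform(t0, t1, size=n))
    times = np.concatenate(pieces) if pieces else np.empty(0)
    return np.sort(times)


def generate_background(config: ScenarioConfig) -> Recording:
    """Independent Poisson background for every declared neuron.

    Bit-reproducible for a fixed ``config.seed`` (one child stream per
    neuron, spawned in declaration order).
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(config.neuron_ids()))
    neurons = []
    for nid, ss in zip(config.neuron_ids(), streams):
        rng = np.random.default_rng(ss)
        times = _poisson_train(rng, config.rate_profile(nid))
        neurons.append(NeuronTrain(neuron_id=nid, area=config.area_of(nid), spike_times=times))
    return Recording(
        session_id=config.session_id,
        mouse_id=config.mouse_id,
        t_start=0.0,
        t_end=config.duration,
        neurons=neurons,
    )


def plant_assembly(
    recording: Recording, spec: PlantSpec, seed: int
) -> tuple[Recording, ManifestEntry]:
    """Plant one assembly into a recording, returning the new recording.

    Occurrence times are uniform over ``[t_start, t_end - lag_span - jitter]``
    so that every member spike stays in bounds; member spikes are merged into
    the background trains, kept sorted.
    """
    span = spec.lag_span + spec.jitter
    if span >= recording.duration:
        raise ValueError("lag span exceeds recording duration")
    rng = np.random.default_rng(seed)
    occ = np.sort(
        rng.uniform(recording.t_start, recording.t_end - span, size=spec.n_activations)
    )
    new_neurons = []
    for tr in recording.neurons:
        if tr.neuron_id in spec.members:
            m = spec.members.index(tr.neuron_id)
            jit = rng.uniform(0.0, spec.jitter, size=occ.size) if spec.jitter > 0 else 0.0
            extra = occ + spec.lags[m] * spec.bin_size + jit
            merged = np.sort(np.concatenate([tr.spike_times, extra]))
            new_neurons.append(NeuronTrain(tr.neuron_id, tr.area, merged))
        else:
            new_neurons.append(tr)
    rec = Recording(
        session_id=recording.session_id,
        mouse_id=recording.mouse_id,
        t_start=recording.t_start,
        t_end=recording.t_end,
        neurons=new_neurons,
    )
    entry = ManifestEntry(
        members=spec.members,
        member_areas=spec.member_areas,
        bin_size=spec.bin_size,
        lags=spec.lags,
        activation_times=occ,
    )
    return rec, entry


def build_scenario(config: ScenarioConfig) -> tuple[Recording, GroundTruthManifest]:
    """Background plus all planted assemblies, with a complete manifest.

    Designated hubs are the neurons that appear in planted *inter-area* pair
    assemblies with at least ``config.hub_min_partner_areas`` distinct
    partner areas.
    """
    rec = generate_background(config)
    manifest = GroundTruthManifest()
    plant_seeds = np.random.SeedSequence(config.seed).spawn(1)[0].generate_state(
        len(config.planted_pairs) + len(config.planted_triplets)
    ) >> 1  # keep below 2**31
    for spec, s in zip(
        list(config.planted_pairs) + list(config.planted_triplets), plant_seeds
    ):
        rec, entry = plant_assembly(rec, spec, int(s))
        manifest.assemblies.append(entry)

    partner_areas: dict[str, set[str]] = {}
    for entry in manifest.pairs:
        (m0, m1), (a0, a1) = entry.members, entry.member_areas
        if a0 != a1:
            partner_areas.setdefault(m0, set()).add(a1)
            partner_areas.setdefault(m1, set()).add(a0)
    manifest.designated_hubs = sorted(
        nid
        for nid, parts in partner_areas.items()
        if len(parts) >= config.hub_min_partner_areas
    )
    return rec, manifest


# ---------------------------------------------------------------------------
# study scenarios


def reference_scenario(
    seed: int = 0,
    n_per_area: int = 40,
    duration: float = 600.0,
    rate_hz: float = 5.0,
    n_pairs: int = 20,
    n_triplets: int = 10,
    n_activations: int = 400,
    bin_size: float = 0.02,
    jitter: float = 0.004,
) -> ScenarioConfig:
    """The strong-signal two-area reference scenario.

    Two areas A and B of ``n_per_area`` neurons each at a 5 Hz Poisson
    background for 600 s.  Twenty planted pairs (mixing intra/inter-regional
    and synchronous/directional structures) occupy neurons A_0..A_19 and
    B_0..B_19; ten planted loop-like triplets (alternating direct A-B-A and
    reverse B-A-B chains) occupy A_20..A_34 and B_20..B_34, so every planted
    member set is disjoint from the others and recovery can be scored
    per-plant.  400 activations against a 3000-spike background give each
    plant a coincidence excess tens of null standard deviations above chance.
    """
    if n_pairs > n_per_area or 3 * n_triplets > 2 * (n_per_area - n_pairs):
        raise ValueError("not enough neurons to plant disjoint assemblies")
    pair_structures = [  # (areas pattern, lags)
        (("A", "B"), (0, 3)),
        (("B", "A"), (0, 2)),
        (("A", "B"), (0, 0)),  # synchronous inter-regional
        (("A", "A"), (0, 2)),  # directional intra-regional
        (("B", "B"), (0, 0)),  # synchronous intra-regional
    ]
    counters = {"A": 0, "B": 0}

    def take(area: str) -> str:
        nid = f"{area}_{counters[area]}"
        counters[area] += 1
        return nid

    pairs = []
    for k in range(n_pairs):
        areas, lags = pair_structures[k % len(pair_structures)]
        pairs.append(
            PlantSpec(
                members=tuple(take(a) for a in areas),
                member_areas=areas,
                bin_size=bin_size,
                lags=lags,
                n_activations=n_activations,
                jitter=jitter,
            )
        )
    counters = {"A": n_pairs, "B": n_pairs}
    triplet_structures = [
        (("A", "B", "A"), (0, 2, 5)),  # direct loop w.r.t. A
        (("B", "A", "B"), (0, 3, 6)),  # reverse loop w.r.t. A
    ]
    triplets = []
    for k in range(n_triplets):
        areas, lags = triplet_structures[k % len(triplet_structures)]
        triplets.append(
            PlantSpec(
                members=tuple(take(a) for a in areas),
                member_areas=areas,
                bin_size=bin_size,
                lags=lags,
                n_activations=n_activations,
                jitter=jitter,
            )
        )
    return ScenarioConfig(
        areas=[("A", n_per_area), ("B", n_per_area)],
        duration=duration,
        default_rate=rate_hz,
        planted_pairs=pairs,
        planted_triplets=triplets,
        seed=seed,
    )


def hub_association_structure(
    seed: int,
    enrichment: float = 3.0,
    n_loop: int = 100,
    n_control: int = 100,
    n_external_areas: int = 8,
    base_partner_prob: float = 0.15,
    center_area: str = "CTX",
) -> tuple[Recording, list[Assembly], dict[str, str]]:
    """Assembly-level scenario coupling loop-like membership to hubness.

    Generates a center area split into a loop-like and a control population
    (half of each population in each of two mice/sessions is emulated by a
    two-mouse metadata split), plus ``n_external_areas`` external areas.
    Each center neuron forms an inter-regional pair with each external area
    independently with probability ``base_partner_prob`` (control) or
    ``enrichment * base_partner_prob`` (loop-like).  ``enrichment=1`` gives
    the null scenario in which hubness is independent of population.

    Returns the (spike-free) recording, the planted pair assemblies and the
    neuron -> population-label map.
    """
    rng = np.random.default_rng(seed)
    p_loop = min(1.0, enrichment * base_partner_prob)
    ext_areas = [f"EXT{k}" for k in range(n_external_areas)]

    neurons = []
    labels: dict[str, str] = {}
    for k in range(n_loop + n_control):
        nid = f"{center_area}_{k}"
        neurons.append(NeuronTrain(nid, center_area, np.empty(0)))
        labels[nid] = "loop_like" if k < n_loop else "non_loop_like"
    for area in ext_areas:
        for k in range(4):
            neurons.append(NeuronTrain(f"{area}_{k}", area, np.empty(0)))

    mouse_of = {
        f"{center_area}_{k}": ("m1" if k % 2 == 0 else "m2")
        for k in range(n_loop + n_control)
    }
    rec = Recording(
        session_id="hub-scenario", mouse_id="m1+m2", t_start=0.0, t_end=1.0, neurons=neurons
    )
    rec.neuron_mouse = mouse_of  # per-neuron mouse split for inclusion filters

    pairs: list[Assembly] = []
    for k in range(n_loop + n_control):
        nid = f"{center_area}_{k}"
        p = p_loop if labels[nid] == "loop_like" else base_partner_prob
        hit = rng.random(n_external_areas) < p
        for a_idx in np.nonzero(hit)[0]:
            partner = f"{ext_areas[a_idx]}_{int(rng.integers(0, 4))}"
            pairs.append(
                Assembly(members=(nid, partner), lags=(0, 1), bin_size=0.02, p_value=0.01)
            )
    return rec, pairs, labels
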