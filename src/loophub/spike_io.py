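"""Data model and tabular I/O for parallel spike-train recordings.

A :class:`Recording` holds the simultaneously recorded spike trains of one
session together with area / session / mouse metadata.  Spike tables are plain
CSV/TSV files with columns ``neuron_id,time_s``; metadata tables have columns
``neuron_id,area,session_id,mouse_id`` and optional ``t_start,t_end`` columns.
All times are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NeuronTrain",
    "Recording",
    "BinnedTrain",
    "read_recording",
    "write_recording",
    "filter_min_spikes",
    "bin_spikes",
]


@dataclass
class NeuronTrain:
    """Spike train of a single neuron.

    Parameters
    ----------
    neuron_id
        Unique identifier within the session.
    area
        Brain-area acronym (non-empty).
    spike_times
        Spike times in seconds, sorted ascending.
    """

    neuron_id: str
    area: str
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not self.area:
            raise ValueError(f"neuron {self.neuron_id!r}: area label must be non-empty")
        times = np.asarray(self.spike_times, dtype=float)
        if times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if times.size and np.any(np.diff(times) < 0):
            times = np.sort(times)
        self.spike_times = times

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class Recording:
    """One recording session: parallel spike trains plus metadata.

    Invariants: neuron ids are unique, every spike time lies inside
    ``[t_start, t_end]``.
    """

    session_id: str
    mouse_id: str
    t_start: float
    t_end: float
    neurons: list[NeuronTrain] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must be greater than t_start")
        seen: set[str] = set()
        for tr in self.neurons:
            if tr.neuron_id in seen:
                raise ValueError(f"duplicate neuron id {tr.neuron_id!r}")
            seen.add(tr.neuron_id)
            if tr.spike_times.size:
                lo, hi = tr.spike_times[0], tr.spike_times[-1]
                if lo < self.t_start or hi > self.t_end:
                    raise ValueError(
                        f"neuron {tr.neuron_id!r}: spike times [{lo}, {hi}] outside "
                        f"recording bounds [{self.t_start}, {self.t_end}]"
                    )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def neuron_ids(self) -> list[str]:
        return [tr.neuron_id for tr in self.neurons]

    def area_map(self) -> dict[str, str]:
        """Mapping neuron id -> area acronym."""
        return {tr.neuron_id: tr.area for tr in self.neurons}

    def areas(self) -> list[str]:
        """Distinct area labels, in first-appearance order."""
        out: list[str] = []
        for tr in self.neurons:
            if tr.area not in out:
                out.append(tr.area)
        return out

    def __getitem__(self, neuron_id: str) -> NeuronTrain:
        for tr in self.neurons:
            if tr.neuron_id == neuron_id:
                return tr
        raise KeyError(neuron_id)


@dataclass
class BinnedTrain:
    """Spike counts on a regular grid of half-open bins.

    Bin ``k`` covers ``[origin + k*bin_size, origin + (k+1)*bin_size)``.
    """

    bin_size: float
    origin: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def read_recording(spike_table_path: str | Path, metadata_path: str | Path) -> Recording:
    """Read a recording from a spike table and a neuron metadata table.

    The spike table must have columns ``neuron_id,time_s``; the metadata table
    ``neuron_id,area,session_id,mouse_id`` (one row per neuron) and optionally
    ``t_start,t_end``.  Neurons listed in the metadata but absent from the
    spike table become zero-spike trains; spikes from neurons missing from the
    metadata raise.  When no bounds are given they default to the min/max
    spike time.
    """
    spikes = _read_table(spike_table_path)
    meta = _read_table(metadata_path)

    for col in ("neuron_id", "time_s"):
        if col not in spikes.columns:
            raise ValueError(f"spike table missing column {col!r}")
    for col in ("neuron_id", "area", "session_id", "mouse_id"):
        if col not in meta.columns:
            raise ValueError(f"metadata table missing column {col!r}")

    times = pd.to_numeric(spikes["time_s"], errors="coerce")
    if times.isna().any():
        raise ValueError("spike table contains non-numeric times")

    meta = meta.copy()
    meta["neuron_id"] = meta["neuron_id"].astype(str)
    spike_ids = spikes["neuron_id"].astype(str)
    known = set(meta["neuron_id"])
    unknown = sorted(set(spike_ids) - known)
    if unknown:
        raise ValueError(f"spike table references neurons absent from metadata: {unknown[:5]}")

    sessions = meta["session_id"].astype(str).unique()
    mice = meta["mouse_id"].astype(str).unique()
    if len(sessions) != 1 or len(mice) != 1:
        raise ValueError("metadata must describe exactly one session of one mouse")

    if "t_start" in meta.columns and meta["t_start"].notna().all():
        t_start = float(meta["t_start"].iloc[0])
    else:
        t_start = float(times.min()) if len(times) else 0.0
    if "t_end" in meta.columns and meta["t_end"].notna().all():
        t_end = float(meta["t_end"].iloc[0])
    else:
        t_end = float(times.max()) if len(times) else t_start + 1.0

    by_neuron: dict[str, np.ndarray] = {
        str(nid): np.sort(np.asarray(grp, dtype=float))
        for nid, grp in times.groupby(spike_ids)
    }
    neurons = [
        NeuronTrain(
            neuron_id=str(row.neuron_id),
            area=str(row.area),
            spike_times=by_neuron.get(str(row.neuron_id), np.empty(0)),
        )
        for row in meta.itertuples()
    ]
    return Recording(
        session_id=str(sessions[0]),
        mouse_id=str(mice[0]),
        t_start=t_start,
        t_end=t_end,
        neurons=neurons,
    )


def write_recording(
    recording: Recording, spike_table_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a recording back to the CSV/TSV pair accepted by :func:`read_recording`."""
    rows = [
        (tr.neuron_id, t) for tr in recording.neurons for t in tr.spike_times
    ]
    spikes = pd.DataFrame(rows, columns=["neuron_id", "time_s"])
    meta = pd.DataFrame(
        {
            "neuron_id": [tr.neuron_id for tr in recording.neurons],
            "area": [tr.area for tr in recording.neurons],
            "session_id": recording.session_id,
            "mouse_id": recording.mouse_id,
            "t_start": recording.t_start,
            "t_end": recording.t_end,
        }
    )
    sep_s = "\t" if str(spike_table_path).endswith((".tsv", ".tab")) else ","
    sep_m = "\t" if str(metadata_path).endswith((".tsv", ".tab")) else ","
    spikes.to_csv(spike_table_path, index=False, sep=sep_s)
    meta.to_csv(metadata_path, index=False, sep=sep_m)


def filter_min_spikes(recording: Recording, min_spikes: int = 100) -> Recording:
    """Keep neurons firing strictly more than ``min_spikes`` spikes.

    The strict inequality matters: a neuron with exactly ``min_spikes`` spikes
    is removed.  Neuron order is preserved and the operation is idempotent.
    """
    if min_spikes < 0:
        raise ValueError("min_spikes must be >= 0")
    kept = [tr for tr in recording.neurons if tr.n_spikes > min_spikes]
    return replace(recording, neurons=kept)


def bin_spikes(
    train: NeuronTrain, bin_size: float, t_start: float, t_end: float
) -> BinnedTrain:
    """Bin a spike train onto half-open bins of width ``bin_size``.

    A trailing span shorter than one bin is dropped; a spike exactly on a bin
    edge belongs to the bin starting there.  A span shorter than one bin
    yields an empty count vector.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if not t_end > t_start:
        raise ValueError("t_end must be greater than t_start")
    n_bins = int(np.floor((t_end - t_start) / bin_size + 1e-12))
    if n_bins == 0:
        return BinnedTrain(bin_size=bin_size, origin=t_start, counts=np.zeros(0, dtype=np.int64))
    idx = np.floor((np.asarray(train.spike_times, dtype=float) - t_start) / bin_size).astype(
        np.int64
    )
    idx = idx[(idx >= 0) & (idx < n_bins)]
    counts = np.bincount(idx, minlength=n_bins)
    return BinnedTrain(bin_size=bin_size, origin=t_start, counts=counts)
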