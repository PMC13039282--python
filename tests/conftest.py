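import numpy as np
import pytest

from loophub.spike_io import NeuronTrain, Recording


@pytest.fixture
def toy_recording() -> Recording:
    """Two areas, four neurons, 10 s; deterministic spike times."""
    rng = np.random.default_rng(7)
    neurons = [
        NeuronTrain(f"{area}_{k}", area, np.sort(rng.uniform(0, 10, size=50)))
        for area in ("V1", "HPC")
        for k in range(2)
    ]
    return Recording(session_id="s1", mouse_id="m1", t_start=0.0, t_end=10.0, neurons=neurons)


def make_recording(spike_map: dict[str, tuple[str, list[float]]], t_end: float = 10.0) -> Recording:
    """Recording from {neuron_id: (area, spike_times)}."""
    neurons = [
        NeuronTrain(nid, area, np.asarray(times, dtype=float))
        for nid, (area, times) in spike_map.items()
    ]
    return Recording(session_id="s1", mouse_id="m1", t_start=0.0, t_end=t_end, neurons=neurons)
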