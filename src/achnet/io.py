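"""File interchange: spike-event files, weight matrices, topologies.

Spike data travel as two-column text (neuron index, time in ms) with a
header carrying the recording window; dense matrices go to HDF5 (dataset
``weights``, rows = postsynaptic) or delimited text depending on the file
suffix.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .measures import PairwiseMatrix, SpikeData
from .network import NetworkTopology

__all__ = [
    "save_spikes", "load_spikes",
    "save_matrix", "load_matrix",
    "save_topology", "load_topology",
]


def save_spikes(path, spike_data: SpikeData) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# t_start_ms={spike_data.t_start} "
                 f"t_end_ms={spike_data.t_end} n_neurons={spike_data.n}\n")
        fh.write("# neuron_index\tspike_time_ms\n")
        for i, train in enumerate(spike_data.trains):
            for t in train:
                fh.write(f"{i}\t{t:.4f}\n")


def load_spikes(path) -> SpikeData:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
    meta = dict(kv.split("=") for kv in header)
    n = int(meta["n_neurons"])
    raw = np.loadtxt(path, comments="#", ndmin=2)
    trains = [np.empty(0)] * n
    if raw.size:
        idx = raw[:, 0].astype(int)
        trains = [np.sort(raw[idx == i, 1]) for i in range(n)]
    return SpikeData(trains, float(meta["t_start_ms"]), float(meta["t_end_ms"]))


def save_matrix(path, values: np.ndarray | PairwiseMatrix,
                kind: str | None = None) -> None:
    path = Path(path)
    if isinstance(values, PairwiseMatrix):
        kind = kind or values.kind
        values = np.where(values.mask, values.values, np.nan)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            d = f.create_dataset("weights", data=values)
            if kind:
                d.attrs["kind"] = kind
    else:
        np.savetxt(path, values, delimiter="\t",
                   header=f"kind={kind or 'weights'}")


def load_matrix(path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return f["weights"][()]
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def save_topology(path, topo: NetworkTopology) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=topo.weights)
        f.create_dataset("is_inhibitory", data=topo.is_inhibitory)
        f.create_dataset("hub", data=topo.hub)
        f.create_dataset("degree_rank", data=topo.degree_rank)
        f.attrs["w0_exc"] = topo.w0_exc


def load_topology(path) -> NetworkTopology:
    with h5py.File(path, "r") as f:
        return NetworkTopology(
            weights=f["weights"][()],
            is_inhibitory=f["is_inhibitory"][()].astype(bool),
            hub=f["hub"][()].astype(np.int64),
            degree_rank=f["degree_rank"][()].astype(np.int64),
            w0_exc=float(f.attrs["w0_exc"]))
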