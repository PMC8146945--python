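"""HDF5 checkpoints for reservoir models (initial and trained)."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .plasticity import STDPParams, TrainedModel
from .reservoir import LIFParams, NeuronGrid, ReservoirModel, SpikeActivity, SWCParams


def _model_to_group(g: h5py.Group, model: ReservoirModel) -> None:
    g.create_dataset("coords", data=model.grid.coords)
    g.create_dataset("excitatory", data=model.grid.excitatory)
    i, j = np.nonzero(model.connections)
    g.create_dataset("conn_i", data=i.astype(np.int64))
    g.create_dataset("conn_j", data=j.astype(np.int64))
    g.create_dataset("w", data=model.weights[i, j])
    g.attrs["grid_source"] = model.grid.source
    g.attrs["seed"] = model.seed
    g.attrs["lif"] = json.dumps(vars(model.lif))
    g.attrs["swc"] = json.dumps(vars(model.swc))
    if model.input_map is not None:
        g.attrs["input_map"] = json.dumps(model.input_map)


def _model_from_group(g: h5py.Group) -> ReservoirModel:
    coords = g["coords"][...]
    grid = NeuronGrid(coords, g["excitatory"][...].astype(bool), g.attrs["grid_source"])
    n = grid.n_neurons
    i, j, w = g["conn_i"][...], g["conn_j"][...], g["w"][...]
    conn = np.zeros((n, n), dtype=bool)
    conn[i, j] = True
    weights = np.zeros((n, n))
    weights[i, j] = w
    input_map = (
        json.loads(g.attrs["input_map"]) if "input_map" in g.attrs else None
    )
    return ReservoirModel(
        grid=grid,
        weights=weights,
        connections=conn,
        lif=LIFParams(**json.loads(g.attrs["lif"])),
        swc=SWCParams(**json.loads(g.attrs["swc"])),
        seed=int(g.attrs["seed"]),
        input_map=input_map,
    )


def save_model(path, model: ReservoirModel | TrainedModel) -> None:
    with h5py.File(path, "w") as fh:
        if isinstance(model, TrainedModel):
            fh.attrs["kind"] = "trained"
            fh.attrs["trained_on"] = model.trained_on
            fh.attrs["stdp"] = json.dumps(vars(model.params))
            _model_to_group(fh.create_group("model"), model.model)
            i, j = np.nonzero(model.model.connections)
            fh.create_dataset("initial_w", data=model.initial_weights[i, j])
            fh.create_dataset("fired_t", data=model.activity.times)
            fh.create_dataset("fired_i", data=model.activity.neurons)
            fh.attrs["n_steps"] = model.activity.n_steps
        else:
            fh.attrs["kind"] = "reservoir"
            _model_to_group(fh.create_group("model"), model)


def load_model(path) -> ReservoirModel | TrainedModel:
    with h5py.File(path, "r") as fh:
        model = _model_from_group(fh["model"])
        if fh.attrs["kind"] == "reservoir":
            return model
        i, j = np.nonzero(model.connections)
        initial = np.zeros_like(model.weights)
        initial[i, j] = fh["initial_w"][...]
        activity = SpikeActivity(
            fh["fired_t"][...], fh["fired_i"][...], int(fh.attrs["n_steps"])
        )
        return TrainedModel(
            model=model,
            trained_on=str(fh.attrs["trained_on"]),
            activity=activity,
            params=STDPParams(**json.loads(fh.attrs["stdp"])),
            initial_weights=initial,
        )
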