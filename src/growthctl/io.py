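"""Readers and writers for solved objects and simulation output.

Control maps and tensors go to HDF5 (compact int8 mode grids plus float
gain tables, with the configuration stored as a JSON attribute); vectors,
matrices and trajectory tables go to CSV with explicit state headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .control import ControlMap
from .biculture import ControlTensor
from .kernel import PopulationDistribution
from .model import ModelConfig, config_from_dict, config_to_dict


def _write_config_attr(obj, config: ModelConfig):
    obj.attrs["config_json"] = json.dumps(config_to_dict(config))
    obj.attrs["growthctl_version"] = __version__


def _read_config_attr(obj) -> ModelConfig:
    cfg, _ = config_from_dict(json.loads(obj.attrs["config_json"]))
    return cfg


def save_control_map(cmap: ControlMap, path):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("modes", data=cmap.modes, dtype="i1")
        fh.create_dataset("gains", data=cmap.gains)
        fh.create_dataset("gain_margin", data=cmap.gain_margin)
        fh.create_dataset("states", data=np.arange(cmap.modes.shape[1]))
        fh.create_dataset("times", data=np.arange(cmap.modes.shape[0]))
        _write_config_attr(fh, cmap.config)


def load_control_map(path) -> ControlMap:
    with h5py.File(path, "r") as fh:
        return ControlMap(
            config=_read_config_attr(fh),
            modes=fh["modes"][...],
            gains=fh["gains"][...],
            gain_margin=fh["gain_margin"][...],
        )


def save_tensor(tensor: ControlTensor, path):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("modes", data=tensor.modes, dtype="i1")
        if tensor.gains is not None:
            fh.create_dataset("gains", data=tensor.gains)
        fh.create_dataset("states", data=np.arange(tensor.modes.shape[1]))
        fh.create_dataset("times", data=np.arange(tensor.modes.shape[0]))
        fh.attrs["provenance"] = tensor.provenance
        _write_config_attr(fh, tensor.config)


def load_tensor(path) -> ControlTensor:
    with h5py.File(path, "r") as fh:
        return ControlTensor(
            config=_read_config_attr(fh),
            modes=fh["modes"][...],
            provenance=str(fh.attrs["provenance"]),
            gains=fh["gains"][...] if "gains" in fh else None,
        )


def save_distribution_h5(dist: PopulationDistribution, path):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("states", data=np.arange(dist.probs.size))
        fh.create_dataset("probs", data=dist.probs)
        fh.create_dataset("t", data=dist.t)


def distribution_to_csv(dist: PopulationDistribution, path):
    pd.DataFrame(
        {"N": np.arange(dist.probs.size), "prob": dist.probs}
    ).to_csv(path, index=False)


def control_map_slice_to_csv(cmap: ControlMap, path, t: int):
    """One time slice of a control map as a tidy CSV."""
    pd.DataFrame(
        {
            "N": np.arange(cmap.modes.shape[1]),
            "mode": cmap.modes[t],
            "gain": cmap.gains[t],
            "gain_margin": cmap.gain_margin[t],
        }
    ).to_csv(path, index=False)


def matrix_to_csv(W: np.ndarray, path):
    """Dense transition matrix with a header row of destination states."""
    pd.DataFrame(W, columns=[str(i) for i in range(W.shape[1])]).to_csv(
        path, index_label="source"
    )


def trajectories_to_dataframe(cycles, run_id: int = 0) -> pd.DataFrame:
    """Flatten serial-transfer trajectories into the tidy CSV dialect
    (columns: run_id, cycle, t, phenotype, size, mode)."""
    frames = []
    for cycle in cycles:
        for pheno, traj in enumerate(cycle):
            frames.append(
                pd.DataFrame(
                    {
                        "run_id": run_id,
                        "cycle": traj.cycle_index,
                        "t": traj.times,
                        "phenotype": pheno,
                        "size": traj.sizes,
                        "mode": traj.modes,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def write_manifest(manifest: dict, path):
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
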