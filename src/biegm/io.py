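"""File I/O: OFF meshes, attribute tables, HDF5 results, trace text files."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .forward import EgmTrace
from .mesh import TissueModel, lumped_areas
from .tissue import SimulationResult


def write_mesh_off(tissue: TissueModel, path) -> None:
    """Triangle mesh in OFF format (plain text)."""
    p = Path(path)
    with p.open("w") as f:
        f.write("OFF\n")
        f.write(f"{tissue.n_nodes} {tissue.triangles.shape[0]} 0\n")
        for v in tissue.nodes:
            f.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for t in tissue.triangles:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_mesh_off(path, **tissue_kwargs) -> TissueModel:
    lines = Path(path).read_text().split("\n")
    assert lines[0].strip() == "OFF", "not an OFF file"
    nv, nf, _ = (int(x) for x in lines[1].split())
    nodes = np.array([[float(x) for x in lines[2 + i].split()]
                      for i in range(nv)])
    tris = np.array([[int(x) for x in lines[2 + nv + i].split()[1:4]]
                     for i in range(nf)], dtype=np.int64)
    return TissueModel(nodes=nodes, triangles=tris,
                       node_area=lumped_areas(nodes, tris), **tissue_kwargs)


def write_attributes(tissue: TissueModel, path) -> None:
    """Per-node scar/fibrosis flags as a delimited table."""
    with Path(path).open("w") as f:
        f.write("node_id\tscar\tfibrosis\n")
        for i in range(tissue.n_nodes):
            f.write(f"{i}\t{int(tissue.scar_mask[i])}\t"
                    f"{int(tissue.fibrosis_mask[i])}\n")


def read_attributes(tissue: TissueModel, path) -> TissueModel:
    data = np.loadtxt(path, skiprows=1, dtype=int)
    return tissue.with_masks(scar_mask=data[:, 1].astype(bool),
                             fibrosis_mask=data[:, 2].astype(bool))


def write_voltage_table(values: np.ndarray, path) -> None:
    with Path(path).open("w") as f:
        f.write("node_id\tx_mV\n")
        for i, v in enumerate(values):
            f.write(f"{i}\t{v:.6f}\n")


def save_result(result: SimulationResult, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=result.times)
        f.create_dataset("vm_field", data=result.vm_field,
                         compression="gzip", compression_opts=4)
        f.create_dataset("source_field", data=result.source_field,
                         compression="gzip", compression_opts=4)
        f.create_dataset("activation_times", data=result.activation_times)
        meta = {k: v for k, v in result.meta.items()}
        for k, v in meta.items():
            if isinstance(v, np.ndarray):
                f.create_dataset(f"meta/{k}", data=v)
            else:
                f.attrs[k] = v


def load_result(path) -> SimulationResult:
    with h5py.File(path, "r") as f:
        meta = dict(f.attrs)
        if "meta" in f:
            for k in f["meta"]:
                meta[k] = f[f"meta/{k}"][()]
        return SimulationResult(
            times=f["times"][()],
            vm_field=f["vm_field"][()],
            source_field=f["source_field"][()],
            activation_times=f["activation_times"][()],
            meta=meta)


def write_trace(trace: EgmTrace, path) -> None:
    """Trace as delimited text with a metadata header."""
    with Path(path).open("w") as f:
        meta = trace.meta or {}
        f.write(f"# filter={trace.filter_applied}\n")
        for k, v in meta.items():
            f.write(f"# {k}={v}\n")
        f.write("time_ms\tv_dist_mV\tv_prox_mV\tv_bi_mV\n")
        for i in range(trace.times.size):
            f.write(f"{trace.times[i]:.3f}\t{trace.v_distal[i]:.9g}\t"
                    f"{trace.v_proximal[i]:.9g}\t{trace.v_bipolar[i]:.9g}\n")


def read_trace(path) -> EgmTrace:
    meta = {}
    filt = "none"
    with Path(path).open() as f:
        rows = []
        for line in f:
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition("=")
                if k.strip() == "filter":
                    filt = v
                else:
                    meta[k.strip()] = v
            elif not line.startswith("time_ms"):
                rows.append([float(x) for x in line.split()])
    a = np.array(rows)
    return EgmTrace(times=a[:, 0], v_distal=a[:, 1], v_proximal=a[:, 2],
                    v_bipolar=a[:, 3], filter_applied=filt, meta=meta)


def write_manifest(path, config: dict, seed: int) -> None:
    """JSON run manifest capturing config + seed + package version."""
    from . import __version__

    payload = {"config": config, "seed": seed, "biegm_version": __version__}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=str) + "\n")
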