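"""Plain-text readers and writers for package artifacts.

Everything round-trips through delimited text or JSON: spike rasters as
(cell_id, time_ms) tables, calcium rasters as 0/1 matrices with a JSON
sidecar, feature tables as TSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import CaRaster
from .network import SpikeRaster


def write_spike_raster(path, raster: SpikeRaster, params: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        meta = {"n_cells": raster.n_cells, "duration_ms": raster.duration_ms}
        if params:
            meta.update(params)
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("cell_id\ttime_ms\n")
        for c, t in zip(raster.cells, raster.times_ms):
            fh.write(f"{c}\t{t:.3f}\n")


def read_spike_raster(path) -> SpikeRaster:
    path = Path(path)
    with open(path) as fh:
        meta = json.loads(fh.readline().lstrip("# "))
    df = pd.read_csv(path, sep="\t", comment="#")
    return SpikeRaster(
        cells=df["cell_id"].to_numpy(np.int64),
        times_ms=df["time_ms"].to_numpy(float),
        n_cells=int(meta["n_cells"]),
        duration_ms=float(meta["duration_ms"]),
    )


def write_ca_raster(path, raster: CaRaster) -> None:
    """0/1 matrix (rows = cells, no delimiter) plus a .json sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        for row in raster.matrix:
            fh.write("".join("1" if v else "0" for v in row) + "\n")
    sidecar = {
        "bin_ms": raster.bin_ms,
        "cell_indices": raster.cell_indices.tolist(),
        "n_cells_total": raster.n_cells_total,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_ca_raster(path) -> CaRaster:
    path = Path(path)
    rows = [list(line.strip()) for line in open(path) if line.strip()]
    mat = np.array(rows, dtype=np.uint8)
    side = path.with_suffix(path.suffix + ".json")
    if side.exists():
        meta = json.load(open(side))
        return CaRaster(
            matrix=mat,
            cell_indices=np.array(meta["cell_indices"], dtype=np.int64),
            bin_ms=float(meta["bin_ms"]),
            n_cells_total=meta.get("n_cells_total"),
        )
    return CaRaster(matrix=mat, cell_indices=np.arange(mat.shape[0]))


def write_features_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_features_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_voltage_trace(path, t_ms: np.ndarray, v_mv: np.ndarray) -> None:
    np.savetxt(path, np.column_stack([t_ms, v_mv]), fmt="%.6g",
               delimiter="\t", header="time_ms\tv_mv", comments="")


def read_voltage_trace(path) -> tuple[np.ndarray, np.ndarray]:
    arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    return arr[:, 0], arr[:, 1]


_CELL_SCALARS = ("g_na", "g_k", "g_kir", "g_af", "g_as", "g_krp", "g_nap",
                 "g_nas", "g_leak", "e_na", "e_k", "e_leak", "cm",
                 "temperature", "drive_scale")


def write_cell_params(path, params) -> None:
    """Cell parameter set as key = value text (scalars only; kinetics by tag)."""
    with open(path, "w") as fh:
        for k in _CELL_SCALARS:
            fh.write(f"{k} = {getattr(params, k)!r}\n")
        fh.write(f"kinetics_tag = {params.kinetics_tag!r}\n")


def read_cell_params(path):
    from .cell import CellParams

    kv = {}
    for line in open(path):
        if "=" in line:
            k, v = line.split("=", 1)
            kv[k.strip()] = eval(v.strip(), {}, {})  # noqa: S307 - trusted config
    tag = kv.pop("kinetics_tag", None)
    p = CellParams(**kv)
    if tag is not None and tag != p.kinetics_tag:
        raise ValueError(f"unknown kinetics tag {tag!r}")
    return p
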