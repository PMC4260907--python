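"""Persistence: Vm movies, electrogram tables, entropy maps, VTK export.

VmField is stored as a ``.npy`` array container plus a JSON sidecar with
the grid metadata (nx, ny, dx, dt_sample, t0).  Electrogram sets are
delimited text (one column per electrode, header row with positions) plus
JSON metadata.  Map frames can be exported as VTK-legacy structured
points for visualization in ParaView-like tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rotormap.egm_forward import ElectrodeArray
from rotormap.tissue_sim import AlievPanfilovParams, TissueGrid, VmField

__all__ = [
    "save_vm",
    "load_vm",
    "save_egm_set",
    "load_egm_set",
    "write_vtk_frame",
    "entropy_series_frame",
]


def save_vm(vm: VmField, path: str | Path) -> None:
    """Write ``path``.npy (frames) and ``path``.json (grid metadata)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), vm.values)
    g = vm.grid
    meta = {
        "nx": g.nx,
        "ny": g.ny,
        "dx": g.dx,
        "diffusion": g.diffusion,
        "dt_sample_ms": vm.dt_sample_ms,
        "t0_ms": vm.t0_ms,
        "kinetics": vars(g.kinetics),
        "masked_cells": int((~g.conduction_mask).sum()),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    if meta["masked_cells"]:
        np.save(path.with_suffix(".mask.npy"), g.conduction_mask)


def load_vm(path: str | Path) -> VmField:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    mask_file = path.with_suffix(".mask.npy")
    mask = np.load(mask_file) if mask_file.exists() else None
    grid = TissueGrid(
        nx=meta["nx"],
        ny=meta["ny"],
        dx=meta["dx"],
        diffusion=meta["diffusion"],
        kinetics=AlievPanfilovParams(**meta["kinetics"]),
        conduction_mask=mask,
    )
    return VmField(
        values=np.load(path.with_suffix(".npy")),
        dt_sample_ms=meta["dt_sample_ms"],
        t0_ms=meta["t0_ms"],
        grid=grid,
    )


def save_egm_set(
    egms: np.ndarray,
    array: ElectrodeArray,
    fs: float,
    path: str | Path,
) -> None:
    """One delimited-text file per array: columns = electrodes (header
    ``x{X}_y{Y}``), plus a JSON metadata sidecar."""
    path = Path(path)
    cols = [f"x{p[0]:g}_y{p[1]:g}" for p in array.positions]
    pd.DataFrame(np.asarray(egms).T, columns=cols).to_csv(path, index=False)
    meta = {
        "fs": fs,
        "n_electrodes": array.n_electrodes,
        "grid_shape": list(array.grid_shape) if array.grid_shape else None,
        "positions": array.positions.tolist(),
        "ratio_sigma": array.ratio_sigma,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_egm_set(path: str | Path) -> tuple[np.ndarray, ElectrodeArray, float]:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    array = ElectrodeArray(
        positions=np.asarray(meta["positions"]),
        ratio_sigma=meta.get("ratio_sigma", 0.4),
        grid_shape=tuple(meta["grid_shape"]) if meta.get("grid_shape") else None,
    )
    return df.to_numpy().T, array, float(meta["fs"])


def write_vtk_frame(
    field: np.ndarray,
    spacing_mm: float,
    path: str | Path,
    name: str = "value",
) -> None:
    """Minimal VTK-legacy STRUCTURED_POINTS ASCII export of one 2D frame."""
    field = np.asarray(field, dtype=float)
    ny, nx = field.shape
    lines = [
        "# vtk DataFile Version 3.0",
        name,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        "ORIGIN 0 0 0",
        f"SPACING {spacing_mm:g} {spacing_mm:g} 1",
        f"POINT_DATA {nx * ny}",
        f"SCALARS {name} float 1",
        "LOOKUP_TABLE default",
    ]
    vals = np.where(np.isfinite(field), field, 0.0).ravel()
    lines.extend(" ".join(f"{v:.6g}" for v in vals[i : i + 9]) for i in range(0, len(vals), 9))
    Path(path).write_text("\n".join(lines) + "\n")


def entropy_series_frame(values_by_site: dict, window: int) -> pd.DataFrame:
    """Long-format table (electrode id, window index, t_start, value)."""
    rows = []
    for site, series in values_by_site.items():
        for w, (t, v) in enumerate(zip(series.t_start_ms, series.values)):
            rows.append({"electrode": site, "window": w, "t_start_ms": t, "value": v})
    return pd.DataFrame(rows)
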