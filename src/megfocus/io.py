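"""Serialization: HDF5 model/recording files, events TSV, NIfTI exports."""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .cds import EventCatalog
from .head_model import SensorArray, SourceGrid, SphereModel
from .sloreta import CurrentMap, InverseKernel


def save_model_h5(
    path: str | Path,
    sensors: SensorArray,
    grid: SourceGrid,
    sphere: SphereModel,
) -> None:
    """Write sensors + source grid (+ sphere) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        s = f.create_group("sensors")
        s.create_dataset("pos_inner", data=sensors.positions_inner)
        s.create_dataset("pos_outer", data=sensors.positions_outer)
        s.create_dataset("axes", data=sensors.axes)
        s.attrs["units"] = "m"
        s.attrs["baseline"] = sensors.baseline
        g = f.create_group("grid")
        g.create_dataset("pos", data=grid.voxel_positions)
        g.create_dataset("labels", data=grid.region_labels)
        g.attrs["units"] = "m"
        g.attrs["spacing"] = grid.spacing
        sp = f.create_group("sphere")
        sp.create_dataset("center", data=sphere.center)
        sp.attrs["radius"] = sphere.radius
        if sphere.per_channel_centers is not None:
            sp.create_dataset("per_channel_centers", data=sphere.per_channel_centers)


def load_model_h5(path: str | Path) -> tuple[SensorArray, SourceGrid, SphereModel]:
    with h5py.File(path, "r") as f:
        sensors = SensorArray(
            positions_inner=f["sensors/pos_inner"][()],
            positions_outer=f["sensors/pos_outer"][()],
            axes=f["sensors/axes"][()],
            baseline=float(f["sensors"].attrs["baseline"]),
        )
        sphere = SphereModel(
            center=f["sphere/center"][()],
            radius=float(f["sphere"].attrs["radius"]),
            per_channel_centers=(
                f["sphere/per_channel_centers"][()]
                if "per_channel_centers" in f["sphere"]
                else None
            ),
        )
        pos = f["grid/pos"][()]
        grid = SourceGrid(
            voxel_positions=pos,
            spacing=float(f["grid"].attrs["spacing"]),
            region_labels=f["grid/labels"][()],
            eccentricities=np.linalg.norm(pos - sphere.center, axis=1),
        )
    return sensors, grid, sphere


def save_kernel_h5(path: str | Path, kernel: InverseKernel, snr: float) -> None:
    with h5py.File(path, "a") as f:
        if "inverse" in f:
            del f["inverse"]
        g = f.create_group("inverse")
        g.create_dataset("kernel", data=kernel.kernel)
        g.create_dataset("resolution_blocks", data=kernel.resolution_blocks)
        g.create_dataset("whitener", data=kernel.whitener)
        g.attrs["lambda"] = kernel.lam
        g.attrs["snr"] = snr


def save_recording_h5(path: str | Path, raw: np.ndarray, sr: float) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("raw")
        g.create_dataset("session0", data=raw)
        g.attrs["sr"] = sr
        g.attrs["units"] = "tesla"


def load_recording_h5(path: str | Path) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as f:
        return f["raw/session0"][()], float(f["raw"].attrs["sr"])


def save_events_tsv(path: str | Path, events: EventCatalog) -> None:
    rows = [
        {"onset_s": a, "offset_s": b, "kind": "IED"} for a, b in events.ied_windows
    ] + [{"onset_s": a, "offset_s": b, "kind": "BL"} for a, b in events.bl_windows]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_events_tsv(path: str | Path, guard_s: float = 1.0) -> EventCatalog:
    df = pd.read_csv(path, sep="\t")
    ied = [
        (float(r.onset_s), float(r.offset_s))
        for r in df.itertuples()
        if r.kind == "IED"
    ]
    bl = [
        (float(r.onset_s), float(r.offset_s))
        for r in df.itertuples()
        if r.kind == "BL"
    ]
    return EventCatalog(tuple(ied), tuple(bl), guard_s=guard_s)


def _lattice_volume(grid: SourceGrid, values: np.ndarray, background: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Scatter per-voxel values onto the lattice bounding box; mm affine."""
    pos = grid.voxel_positions
    origin = pos.min(axis=0)
    idx = np.round((pos - origin) / grid.spacing).astype(int)
    shape = idx.max(axis=0) + 1
    vol = np.full(shape, background, dtype=float)
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = values
    affine = np.eye(4)
    affine[:3, :3] *= grid.spacing * 1000.0  # meters -> millimeters
    affine[:3, 3] = origin * 1000.0
    return vol, affine


def export_labels_nifti(path: str | Path, grid: SourceGrid) -> None:
    """Region label map on the grid lattice (background 0), mm coordinates."""
    vol, affine = _lattice_volume(grid, grid.region_labels.astype(float))
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def export_map_nifti(path: str | Path, grid: SourceGrid, current_map: CurrentMap) -> None:
    """Window-averaged standardized-power map as NIfTI on the grid lattice."""
    values = current_map.values
    if values.ndim != 1:
        raise ValueError("export a time-averaged map, not a time series")
    vol, affine = _lattice_volume(grid, values)
    nib.save(nib.Nifti1Image(vol, affine), str(path))
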