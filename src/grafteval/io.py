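"""Readers and writers for the package's plain-text interchange formats.

Tables are UTF-8 CSV with a header and "." decimals; raster masks are TIFF
with a JSON sidecar carrying the voxel size; ground truth and geometry
travel as JSON. Formats:

* spike table: unit_id, intensity, trial, t_spike_s
* point pattern: x_um, y_um (+ JSON sidecar: field_radius, disc_center,
  disc_diameter)
* puncta table: id, x_um, y_um, z_um (one file per channel)
* skeleton table: cell_id, polyline, vertex_index, x_um, y_um, z_um
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .hc import PointPattern
from .mea import SpikeDataset, StimulusProtocol
from .synapse import DendriteSkeleton, PunctaScene

__all__ = [
    "write_spike_table", "read_spike_table",
    "write_point_pattern", "read_point_pattern",
    "write_puncta", "read_puncta",
    "write_skeletons", "read_skeletons",
    "write_mask", "read_mask",
    "write_json", "read_json",
]


def write_spike_table(ds: SpikeDataset, path: str | Path) -> int:
    frame = ds.to_frame()
    frame.to_csv(path, index=False)
    return len(frame)


def read_spike_table(
    path: str | Path,
    protocol: StimulusProtocol,
    electrodes: Mapping[str, str] | None = None,
) -> SpikeDataset:
    frame = pd.read_csv(path)
    required = {"unit_id", "intensity", "trial", "t_spike_s"}
    if not required.issubset(frame.columns):
        raise ValueError(f"spike table must have columns {sorted(required)}")
    return SpikeDataset.from_frame(frame, protocol, electrodes)


def write_point_pattern(pattern: PointPattern, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(pattern.points, columns=["x_um", "y_um"]).to_csv(path, index=False)
    sidecar = {
        "field_radius": pattern.field_radius,
        "disc_center": list(pattern.disc_center),
        "disc_diameter": pattern.disc_diameter,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_point_pattern(path: str | Path) -> PointPattern:
    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return PointPattern(
        points=frame[["x_um", "y_um"]].to_numpy(float),
        field_radius=float(meta["field_radius"]),
        disc_center=tuple(meta["disc_center"]),
        disc_diameter=float(meta["disc_diameter"]),
    )


def write_puncta(spots: pd.DataFrame, path: str | Path) -> None:
    spots[["id", "x_um", "y_um", "z_um"]].to_csv(path, index=False)


def read_puncta(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"id", "x_um", "y_um", "z_um"}
    if not required.issubset(frame.columns):
        raise ValueError(f"puncta table must have columns {sorted(required)}")
    return frame


def write_skeletons(dendrites: Sequence[DendriteSkeleton], path: str | Path) -> None:
    rows = []
    for skel in dendrites:
        for pi, poly in enumerate(skel.polylines):
            for vi, (x, y, z) in enumerate(poly):
                rows.append((skel.cell_id, pi, vi, x, y, z))
    pd.DataFrame(
        rows, columns=["cell_id", "polyline", "vertex_index", "x_um", "y_um", "z_um"]
    ).to_csv(path, index=False)


def read_skeletons(path: str | Path) -> list[DendriteSkeleton]:
    frame = pd.read_csv(path)
    out = []
    for cid, cgrp in frame.groupby("cell_id", sort=True):
        polys = []
        for _, pgrp in cgrp.groupby("polyline", sort=True):
            pgrp = pgrp.sort_values("vertex_index")
            polys.append(pgrp[["x_um", "y_um", "z_um"]].to_numpy(float))
        out.append(DendriteSkeleton(cell_id=str(cid), polylines=polys))
    return out


def write_mask(mask: np.ndarray, voxel_size: Sequence[float], path: str | Path) -> None:
    """Write a binary raster as TIFF plus a JSON voxel-size sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint8),
                     photometric="minisblack")
    path.with_suffix(".json").write_text(
        json.dumps({"voxel_size": list(map(float, voxel_size))})
    )


def read_mask(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    path = Path(path)
    mask = tifffile.imread(path).astype(bool)
    meta = json.loads(path.with_suffix(".json").read_text())
    return mask, tuple(meta["voxel_size"])


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def scene_from_tables(
    ctbp2_path: str | Path,
    mglur6_path: str | Path,
    skeleton_path: str | Path | None = None,
) -> PunctaScene:
    dendrites = read_skeletons(skeleton_path) if skeleton_path else []
    return PunctaScene(
        ctbp2=read_puncta(ctbp2_path),
        mglur6=read_puncta(mglur6_path),
        dendrites=dendrites,
    )
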