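"""Reading and writing of volumes, renders and vessel graphs.

Volumes go to multi-page TIFF (one file per channel) with a JSON sidecar
carrying spacing, channel and generation parameters; vessel graphs to a CSV
edge list plus JSON metadata; projections to PNG.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .types import EllipsoidBoundary, ProjectionImage, VesselTree, VolumeImage

__all__ = [
    "save_volume",
    "load_volume",
    "save_projection",
    "load_image",
    "save_tree",
    "load_tree",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, tuple, list)):
        return [_jsonable(v) for v in obj]
    return obj


def save_volume(volume: VolumeImage, path: str | Path, params=None) -> Path:
    """Write a volume as multi-page TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.voxels)
    sidecar = {
        "spacing_zyx_um": list(volume.spacing),
        "channel": volume.channel,
        "bit_depth": volume.bit_depth,
    }
    if params is not None:
        sidecar["synth_params"] = _jsonable(params)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_volume(path: str | Path, spacing=None) -> VolumeImage:
    """Read a TIFF stack; spacing comes from the sidecar unless given."""
    path = Path(path)
    voxels = tifffile.imread(path)
    channel, bit_depth = "EC", 16 if voxels.dtype.itemsize > 1 else 8
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        spacing = spacing or tuple(meta["spacing_zyx_um"])
        channel = meta.get("channel", channel)
        bit_depth = meta.get("bit_depth", bit_depth)
    if spacing is None:
        raise ValueError(f"no spacing sidecar next to {path}; pass spacing explicitly")
    return VolumeImage(voxels=voxels, spacing=tuple(spacing), channel=channel, bit_depth=bit_depth)


def save_projection(projection: ProjectionImage, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, projection.pixels)
    return path


def load_image(path: str | Path) -> np.ndarray:
    """Read a 2D PNG/TIFF image as an array (possibly multi-channel)."""
    return np.asarray(iio.imread(Path(path)))


def save_tree(tree: VesselTree, csv_path: str | Path) -> Path:
    """Edge list CSV (node ids, um coordinates, radii, label, length) plus a
    JSON metadata sidecar with boundary, hilum and ground-truth totals."""
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for u, v, data in tree.graph.edges(data=True):
        pu, pv = tree.pos(u), tree.pos(v)
        rows.append(
            {
                "node_a": u, "node_b": v,
                "az_um": pu[0], "ay_um": pu[1], "ax_um": pu[2],
                "bz_um": pv[0], "by_um": pv[1], "bx_um": pv[2],
                "radius_a_um": tree.radius(u), "radius_b_um": tree.radius(v),
                "edge_radius_um": data["radius"],
                "label": data["label"],
                "length_um": data["length"],
            }
        )
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    meta = {
        "roots": tree.roots,
        "hilum_um": None if tree.hilum is None else tree.hilum.tolist(),
        "boundary": None if tree.boundary is None else tree.boundary.to_dict(),
        "total_baseline_length_um": tree.total_baseline_length,
        "total_neovessel_length_um": tree.total_neovessel_length,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return csv_path


def load_tree(csv_path: str | Path) -> VesselTree:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta_path = csv_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    boundary = meta.get("boundary")
    tree = VesselTree(
        boundary=None if boundary is None else EllipsoidBoundary.from_dict(boundary),
        hilum=None if meta.get("hilum_um") is None else np.asarray(meta["hilum_um"]),
        roots=meta.get("roots", []),
    )
    for _, r in df.iterrows():
        u, v = int(r.node_a), int(r.node_b)
        if u not in tree.graph:
            tree.add_node(u, np.array([r.az_um, r.ay_um, r.ax_um]), float(r.radius_a_um))
        if v not in tree.graph:
            tree.add_node(v, np.array([r.bz_um, r.by_um, r.bx_um]), float(r.radius_b_um))
        tree.add_edge(
            u, v, label=str(r.label), radius=float(r.edge_radius_um), length=float(r.length_um)
        )
    tree.total_baseline_length = float(meta.get("total_baseline_length_um", tree.total_length("baseline")))
    tree.total_neovessel_length = float(meta.get("total_neovessel_length_um", tree.total_length("neovessel")))
    return tree
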