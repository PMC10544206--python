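"""Core data containers shared across the pipeline.

All 3D coordinates are physical micrometres in ``(z, y, x)`` order; voxel
``(i, j, k)`` has its centre at ``((i + 0.5) dz, (j + 0.5) dy, (k + 0.5) dx)``.
Lengths are therefore meaningful under anisotropic spacing (multiphoton stacks
have z-steps several times the in-plane pixel size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import networkx as nx
import numpy as np

__all__ = [
    "VolumeImage",
    "ProjectionImage",
    "EllipsoidBoundary",
    "VesselTree",
    "BASELINE",
    "NEOVESSEL",
]

BASELINE = "baseline"
NEOVESSEL = "neovessel"


@dataclass
class VolumeImage:
    """An anisotropic 3D intensity grid: the stand-in for a cleared-lung stack.

    Parameters
    ----------
    voxels : ndarray, shape (Z, Y, X)
        Non-negative intensities.
    spacing : tuple of float
        Micrometres per voxel along (z, y, x).
    channel : str
        Stain label: ``"SMA"`` (smooth-muscle wall), ``"EC"`` (endothelium /
        lineage label) or ``"nuclei"``.
    bit_depth : int
        8 or 16; intensities must not exceed ``2**bit_depth - 1``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel: str = "EC"
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.voxels.size and (self.voxels.min() < 0 or self.voxels.max() > self.max_value):
            raise ValueError("intensities must lie in [0, bit-depth maximum]")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in um^3."""
        return float(np.prod(self.spacing))

    @property
    def physical_extent(self) -> np.ndarray:
        """Physical size of the grid (z, y, x) in um."""
        return np.asarray(self.shape) * np.asarray(self.spacing)


@dataclass
class ProjectionImage:
    """A 2D 8-bit render of a volume (the '2.5D' representation).

    ``provenance`` records the projection axis and mode
    (``maximum-intensity`` or ``depth-shaded``).
    """

    pixels: np.ndarray
    pixel_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2D")
        if self.pixels.dtype != np.uint8:
            if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 255):
                raise ValueError("projection values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)


@dataclass
class EllipsoidBoundary:
    """Axis-aligned ellipsoidal lung boundary with a hilum on its surface.

    The hilum (where vessels enter the lung) sits on the -y surface of the
    ellipsoid; radial extent measures ("elongation toward the periphery") are
    taken from it.
    """

    center: np.ndarray  # (z, y, x) um
    semi_axes: np.ndarray  # (z, y, x) um

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.semi_axes = np.asarray(self.semi_axes, dtype=float)
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi-axes must be positive")

    @property
    def hilum(self) -> np.ndarray:
        h = self.center.copy()
        h[1] -= self.semi_axes[1]
        return h

    def contains(self, point: np.ndarray, tol: float = 1e-9) -> bool:
        q = (np.asarray(point, dtype=float) - self.center) / self.semi_axes
        return bool(np.dot(q, q) <= 1.0 + tol)

    def ray_exit_distance(self, origin: np.ndarray, direction: np.ndarray) -> float:
        """Distance from ``origin`` (inside or on the surface) to the boundary
        along unit vector ``direction``.

        Solves the quadratic for ``|((o + t d) - c) / a| = 1`` and returns the
        largest non-negative root.
        """
        o = (np.asarray(origin, dtype=float) - self.center) / self.semi_axes
        d = np.asarray(direction, dtype=float) / self.semi_axes
        a = np.dot(d, d)
        b = 2.0 * np.dot(o, d)
        c = np.dot(o, o) - 1.0
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise ValueError("ray does not intersect the boundary (origin outside?)")
        t = (-b + np.sqrt(disc)) / (2.0 * a)
        if t < 0:
            raise ValueError("ray exits behind the origin (origin outside boundary)")
        return float(t)

    def mid_axial_semi_axes(self) -> tuple[float, float]:
        """(y, x) semi-axes of the mid-axial (z = center) cross-section."""
        return float(self.semi_axes[1]), float(self.semi_axes[2])

    def mid_axial_mask(self, pixel_size: float, pad: int = 4) -> np.ndarray:
        """Boolean raster of the mid-axial cross-section at ``pixel_size`` um/px."""
        by, bx = self.mid_axial_semi_axes()
        ny = int(np.ceil(2 * by / pixel_size)) + 2 * pad
        nx_ = int(np.ceil(2 * bx / pixel_size)) + 2 * pad
        yy = (np.arange(ny) + 0.5) * pixel_size - (ny * pixel_size) / 2
        xx = (np.arange(nx_) + 0.5) * pixel_size - (nx_ * pixel_size) / 2
        return (yy[:, None] / by) ** 2 + (xx[None, :] / bx) ** 2 <= 1.0

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "semi_axes": self.semi_axes.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "EllipsoidBoundary":
        return cls(np.asarray(d["center"]), np.asarray(d["semi_axes"]))


class VesselTree:
    """Geometric vessel graph: nodes carry 3D um coordinates and radii, edges
    carry polyline lengths and a ``baseline`` / ``neovessel`` label.

    Serves both as generator ground truth and as skeletonization output
    (where edges additionally carry their centerline voxel indices).
    """

    def __init__(
        self,
        graph: nx.Graph | None = None,
        boundary: EllipsoidBoundary | None = None,
        hilum: np.ndarray | None = None,
        roots: list[int] | None = None,
    ) -> None:
        self.graph = graph if graph is not None else nx.Graph()
        self.boundary = boundary
        self.hilum = None if hilum is None else np.asarray(hilum, dtype=float)
        self.roots = roots or []
        self.total_baseline_length: float = 0.0
        self.total_neovessel_length: float = 0.0

    # -- construction -----------------------------------------------------
    def add_node(self, node_id: int, pos: np.ndarray, radius: float) -> int:
        self.graph.add_node(node_id, pos=np.asarray(pos, dtype=float), radius=float(radius))
        return node_id

    def add_edge(
        self,
        u: int,
        v: int,
        label: str = BASELINE,
        radius: float | None = None,
        length: float | None = None,
        **extra,
    ) -> None:
        if length is None:
            length = float(np.linalg.norm(self.pos(u) - self.pos(v)))
        if radius is None:
            radius = min(self.graph.nodes[u]["radius"], self.graph.nodes[v]["radius"])
        self.graph.add_edge(u, v, label=label, radius=float(radius), length=float(length), **extra)

    def record_totals(self) -> None:
        """Refresh the ground-truth length bookkeeping from the edge list."""
        self.total_baseline_length = self.total_length(BASELINE)
        self.total_neovessel_length = self.total_length(NEOVESSEL)

    # -- queries ----------------------------------------------------------
    def pos(self, node_id: int) -> np.ndarray:
        return self.graph.nodes[node_id]["pos"]

    def radius(self, node_id: int) -> float:
        return self.graph.nodes[node_id]["radius"]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self, label: str | None = None) -> Iterator[tuple[int, int, dict]]:
        for u, v, data in self.graph.edges(data=True):
            if label is None or data.get("label") == label:
                yield u, v, data

    def total_length(self, label: str | None = None) -> float:
        return float(sum(d["length"] for _, _, d in self.edges(label)))

    def terminal_nodes(self, exclude: set[int] | None = None) -> list[int]:
        """Degree-1 nodes (vessel tips), excluding roots by default."""
        exclude = set(self.roots) if exclude is None else exclude
        return [n for n in self.graph.nodes if self.graph.degree[n] == 1 and n not in exclude]

    def recompute_edge_lengths(self) -> None:
        """Set every straight edge's length to the endpoint Euclidean distance."""
        for u, v, data in self.graph.edges(data=True):
            data["length"] = float(np.linalg.norm(self.pos(u) - self.pos(v)))
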