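"""Ground-truthed synthetic 3D vascular volumes and measurement tables.

Emulates anisotropic multiphoton stacks of a cleared mouse lung: a branching,
tapering arterial tree grown from the hilum inside an ellipsoidal lung
boundary, with

* an endothelial (``EC``) channel painting every vessel as a solid tube,
* a smooth-muscle (``SMA``) channel painting an annular wall around baseline
  vessels only (hypoxia-style neovessel sprouts are unmuscularized),
* optional peripheral sprouts appended to terminal branches (the angiogenic
  response of chronic hypoxia) and radial elongation of terminal tips toward
  the pleural boundary,
* Gaussian background plus Poisson shot noise.

Every output is bit-identical under identical parameters and seed, and the
tree records its ground-truth baseline/neovessel length totals so downstream
estimators can be scored against truth.

Default voxel geometry is the x20-objective multiphoton setting
(1.13 um in-plane, 2.2 um z-step); the x10 and x5 settings are available via
:data:`VOXEL_GEOMETRIES`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm

from .types import BASELINE, NEOVESSEL, EllipsoidBoundary, ProjectionImage, VesselTree, VolumeImage

__all__ = [
    "SynthParams",
    "VOXEL_GEOMETRIES",
    "PRESETS",
    "preset_params",
    "generate_vessel_tree",
    "rasterize_tree",
    "render_projection",
    "perturb_projection",
    "simulate_group_table",
    "make_cylinder_volume",
    "make_annulus_image",
]

#: The microscope's three voxel geometries, keyed by objective magnification:
#: (z, y, x) um per voxel.
VOXEL_GEOMETRIES: dict[str, tuple[float, float, float]] = {
    "5x": (13.2, 4.54, 4.54),
    "10x": (6.6, 2.27, 2.27),
    "20x": (2.2, 1.13, 1.13),
}


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic lung-vasculature generator.

    All lengths in micrometres; ``volume_shape``/``spacing`` in (z, y, x).
    """

    seed: int = 0
    volume_shape: tuple[int, int, int] = (80, 160, 160)
    spacing: tuple[float, float, float] = VOXEL_GEOMETRIES["20x"]
    n_root_vessels: int = 2
    branch_generations: int = 4
    branch_angle_spread: float = 40.0  # degrees
    taper_ratio: float = 0.8  # child radius / parent radius, in (0, 1]
    root_radius: float = 8.0
    wall_thickness_fraction: float = 0.3  # SMC layer thickness / lumen radius
    n_sprouts: int = 0
    sprout_length_mean: float = 45.0
    sprout_length_sd: float = 10.0
    sprout_radius: float = 3.5
    elongation_factor: float = 1.0  # radial scaling of terminal tips from hilum
    background_level: float = 10.0
    shot_noise_scale: float = 1.0  # 0 disables Poisson shot noise
    gaussian_noise_sd: float = 3.0
    foreground_intensity: float = 200.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if len(self.volume_shape) != 3 or any(int(s) <= 0 for s in self.volume_shape):
            raise ValueError(f"volume_shape must be 3 positive integers, got {self.volume_shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if self.n_root_vessels < 1 or self.branch_generations < 1:
            raise ValueError("n_root_vessels and branch_generations must be >= 1")
        if not 0 < self.taper_ratio <= 1:
            raise ValueError("taper_ratio must lie in (0, 1]")
        if not 0 < self.wall_thickness_fraction < 1:
            raise ValueError("wall_thickness_fraction must lie in (0, 1)")
        if self.n_sprouts < 0:
            raise ValueError("n_sprouts must be >= 0")
        if self.elongation_factor < 1:
            raise ValueError("elongation_factor must be >= 1")

    @property
    def physical_extent(self) -> np.ndarray:
        return np.asarray(self.volume_shape) * np.asarray(self.spacing)


#: Experimental-arm presets: normoxia (no remodeling), chronic hypoxia (strong
#: sprouting + peripheral elongation) and Sugen+hypoxia (blunted angiogenic
#: response). Magnitudes are free choices that preserve the qualitative
#: ordering Nx < SuHx < Hx in sprout burden.
PRESETS: dict[str, dict] = {
    "normoxia": {"n_sprouts": 0, "elongation_factor": 1.0},
    "hx": {"n_sprouts": 20, "elongation_factor": 1.35},
    "suhx": {"n_sprouts": 4, "elongation_factor": 1.05},
}


def preset_params(name: str, **overrides) -> SynthParams:
    """SynthParams for one of the ``normoxia`` / ``hx`` / ``suhx`` presets."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SynthParams(**{**PRESETS[name], **overrides})


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------


def _ellip_norm(boundary: EllipsoidBoundary, point: np.ndarray) -> float:
    q = (point - boundary.center) / boundary.semi_axes
    return float(np.linalg.norm(q))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about unit ``axis`` by ``angle`` radians."""
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * np.dot(axis, v) * (1 - math.cos(angle))
    )


def _perpendicular(direction: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, direction) * direction
        n = np.linalg.norm(p)
        if n > 1e-8:
            return p / n


def _segment_segment_distance(
    p1: np.ndarray, q1: np.ndarray, p2: np.ndarray, q2: np.ndarray
) -> float:
    """Minimum distance between 3D segments p1-q1 and p2-q2."""
    d1, d2, r = q1 - p1, q2 - p2, p1 - p2
    a, e, f = np.dot(d1, d1), np.dot(d2, d2), np.dot(d2, r)
    if a < 1e-12 and e < 1e-12:
        return float(np.linalg.norm(r))
    if a < 1e-12:
        s, t = 0.0, np.clip(f / e, 0.0, 1.0)
    else:
        c = np.dot(d1, r)
        if e < 1e-12:
            t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
        else:
            b = np.dot(d1, d2)
            denom = a * e - b * b
            s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t, s = 0.0, np.clip(-c / a, 0.0, 1.0)
            elif t > 1.0:
                t, s = 1.0, np.clip((b - c) / a, 0.0, 1.0)
    return float(np.linalg.norm(p1 + s * d1 - (p2 + t * d2)))


def _sprout_clearance(
    tree: VesselTree, tip_id: int, start: np.ndarray, end: np.ndarray, radius: float
) -> float:
    """Surface-to-surface clearance (um) between a candidate sprout and every
    vessel not incident to its attachment tip; the first fifth of the sprout
    is exempt (it legitimately leaves the parent tube)."""
    probe_start = start + 0.2 * (end - start)
    clearance = np.inf
    for u, v, data in tree.graph.edges(data=True):
        if tip_id in (u, v):
            continue
        d = _segment_segment_distance(probe_start, end, tree.pos(u), tree.pos(v))
        clearance = min(clearance, d - radius - data["radius"])
    return float(clearance)


def generate_vessel_tree(params: SynthParams) -> VesselTree:
    """Grow a branching, tapering vascular tree inside the lung boundary.

    The tree starts at the hilum (on the -y surface of the ellipsoid), each
    branch splits into two children rotated by ~``branch_angle_spread`` about
    the parent direction, radii shrink by ``taper_ratio`` per generation, and
    segments that would leave the boundary are shortened to stay inside.
    Afterwards terminal tips are radially scaled from the hilum by
    ``elongation_factor`` (an error is raised, naming the node, if that would
    leave the boundary), and ``n_sprouts`` unmuscularized neovessels with
    truncated-normal lengths are attached to terminal baseline tips.

    Ground-truth baseline/neovessel length totals are recorded on the tree.
    """
    rng = np.random.default_rng(params.seed)
    extent = params.physical_extent
    center = extent / 2.0
    boundary = EllipsoidBoundary(center=center, semi_axes=0.42 * extent)
    hilum = boundary.hilum

    tree = VesselTree(boundary=boundary, hilum=hilum, roots=[0])
    tree.add_node(0, hilum, params.root_radius)
    next_id = [1]

    root_length = 0.4 * float(min(boundary.semi_axes[1], boundary.semi_axes[2]))
    # baseline arteries stop short of the pleura; peripheral elongation and
    # sprouts are what reach toward it
    envelope = EllipsoidBoundary(center=center, semi_axes=0.7 * boundary.semi_axes)

    # growth reserves room for peripheral elongation up to a factor of 1.5;
    # larger factors are geometrically infeasible for this lung model and
    # surface as the per-tip boundary error below
    f_reserved = min(params.elongation_factor, 1.5)

    def elongation_headroom_ok(point: np.ndarray) -> bool:
        q = hilum + f_reserved * (point - hilum)
        return boundary.contains(q, tol=0.0) and _ellip_norm(boundary, q) <= 0.96

    def grow(parent: int, direction: np.ndarray, length: float, radius: float, gen: int) -> None:
        p = tree.pos(parent)
        # stay inside the growth envelope: shorten toward it if needed
        try:
            t_exit = envelope.ray_exit_distance(p, direction)
        except ValueError:  # ray misses the envelope entirely: prune
            return
        seg_len = min(length, 0.9 * t_exit)
        # reserve headroom so later peripheral elongation stays inside the lung
        for _ in range(8):
            if seg_len < 1e-6 or elongation_headroom_ok(p + seg_len * direction):
                break
            seg_len *= 0.7
        if seg_len < 1e-6 or not elongation_headroom_ok(p + seg_len * direction):
            return
        tip = p + seg_len * direction
        node = tree.add_node(next_id[0], tip, radius)
        next_id[0] += 1
        tree.add_edge(parent, node, label=BASELINE, radius=radius)
        if gen >= params.branch_generations:
            return
        half = math.radians(params.branch_angle_spread) / 2.0
        axis = _perpendicular(direction, rng)
        for sign in (1.0, -1.0):
            jitter = 0.7 + 0.6 * rng.random()
            child_dir = _unit(_rotate(direction, axis, sign * half * jitter))
            grow(node, child_dir, 0.72 * seg_len, radius * params.taper_ratio, gen + 1)

    for _ in range(params.n_root_vessels):
        d = _unit(np.array([0.25 * rng.normal(), 1.0, 0.35 * rng.normal()]))
        grow(0, d, root_length, params.root_radius, 1)

    # peripheral elongation of terminal baseline tips
    if params.elongation_factor > 1.0:
        for tip_id in tree.terminal_nodes():
            p_new = hilum + params.elongation_factor * (tree.pos(tip_id) - hilum)
            if not boundary.contains(p_new, tol=1e-6):
                raise ValueError(
                    f"elongation_factor {params.elongation_factor} pushes node "
                    f"{tip_id} outside the lung boundary"
                )
            tree.graph.nodes[tip_id]["pos"] = p_new
        tree.recompute_edge_lengths()

    # hypoxia-style sprouts on terminal baseline tips: spread over the tips
    # with directions chosen for clearance from the existing tree, so sprout
    # tubes do not fuse with it and ground-truth lengths stay meaningful
    tips = tree.terminal_nodes()
    tip_order = list(rng.permutation(tips))
    for s in range(params.n_sprouts):
        if params.sprout_length_sd > 0:
            a = -params.sprout_length_mean / params.sprout_length_sd
            length = float(
                truncnorm.ppf(
                    rng.random(), a, np.inf,
                    loc=params.sprout_length_mean, scale=params.sprout_length_sd,
                )
            )
        else:
            length = params.sprout_length_mean
        best: tuple[int, np.ndarray] | None = None
        best_clear = -np.inf
        for k in range(len(tip_order)):
            tip_id = int(tip_order[(s + k) % len(tip_order)])
            p = tree.pos(tip_id)
            outward = _unit(p - hilum)
            # prefer outward, then tangential candidates (sprouts stay
            # peripheral rather than burrowing back along the tree)
            for weight in (1.0, 0.8, 0.6, 0.4, 0.2, 0.0):
                g = rng.normal(size=3)
                tangential = g - np.dot(g, outward) * outward
                cand = _unit(weight * outward + 0.9 * tangential)
                end_c = p + length * cand
                if not boundary.contains(end_c):
                    continue
                clearance = _sprout_clearance(tree, tip_id, p, end_c, params.sprout_radius)
                if clearance > best_clear:
                    best, best_clear = (tip_id, end_c), clearance
            if best_clear > 2.0:
                break
        if best is None:  # no in-bounds candidate anywhere: aim inward
            tip_id = int(tip_order[s % len(tip_order)])
            p = tree.pos(tip_id)
            target = center + 0.3 * boundary.semi_axes * rng.uniform(-1, 1, size=3)
            best = (tip_id, p + length * _unit(target - p))
        tip_id, end = best
        node = tree.add_node(next_id[0], end, params.sprout_radius)
        next_id[0] += 1
        tree.add_edge(tip_id, node, label=NEOVESSEL, radius=params.sprout_radius)

    tree.record_totals()
    return tree


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _segment_distance_grid(
    p0: np.ndarray, p1: np.ndarray, lo: np.ndarray, hi: np.ndarray,
    spacing: np.ndarray,
) -> tuple[tuple[slice, ...], np.ndarray]:
    """Physical distance from every voxel centre in index box [lo, hi) to the
    segment p0-p1 (a capsule test). Returns (slices, distance array)."""
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    axes = [
        (np.arange(a, b) + 0.5) * s for (a, b), s in zip(zip(lo, hi), spacing)
    ]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([zz, yy, xx], axis=-1)
    d = p1 - p0
    len2 = float(np.dot(d, d))
    if len2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / len2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    return sl, dist


def _paint_tube(
    canvas: np.ndarray, p0: np.ndarray, p1: np.ndarray,
    r_in: float, r_out: float, spacing: np.ndarray, value: float,
) -> None:
    """Set voxels whose centre lies within (r_in, r_out] um of segment p0-p1."""
    shape = np.asarray(canvas.shape)
    pad = r_out + np.max(spacing)
    lo = np.floor((np.minimum(p0, p1) - pad) / spacing).astype(int)
    hi = np.ceil((np.maximum(p0, p1) + pad) / spacing).astype(int) + 1
    lo = np.clip(lo, 0, shape)
    hi = np.clip(hi, 0, shape)
    if np.any(lo >= hi):
        return
    sl, dist = _segment_distance_grid(p0, p1, lo, hi, spacing)
    sel = (dist <= r_out) if r_in <= 0 else ((dist > r_in) & (dist <= r_out))
    region = canvas[sl]
    region[sel] = np.maximum(region[sel], value)


def rasterize_tree(tree: VesselTree, params: SynthParams, channel: str = "EC") -> VolumeImage:
    """Voxelize a vessel tree into an intensity volume for one stain channel.

    ``EC`` paints every edge as a solid tube of its radius; ``SMA`` paints an
    annular smooth-muscle shell of thickness ``wall_thickness_fraction x
    radius`` around baseline edges only (neovessels are unmuscularized);
    ``nuclei`` scatters small puncta along vessel walls and in the
    parenchyma. Distances are evaluated in physical um so anisotropic voxels
    yield correct tube cross-sections. Noise (Poisson shot noise on signal,
    then Gaussian background) is applied after geometry.
    """
    if channel not in ("EC", "SMA", "nuclei"):
        raise ValueError(f"unknown channel {channel!r}")
    spacing = np.asarray(params.spacing, dtype=float)
    shape = np.asarray(params.volume_shape, dtype=int)
    extent = shape * spacing

    # the whole painted geometry must fit in the grid
    for n, data in tree.graph.nodes(data=True):
        margin = data["radius"] * (1.0 + params.wall_thickness_fraction)
        p = data["pos"]
        if np.any(p - margin < 0) or np.any(p + margin > extent):
            raise ValueError(
                f"tree does not fit in the volume: node {n} at {np.round(p, 2)} um "
                f"(radius {data['radius']:.2f} um) exceeds extent {np.round(extent, 2)}"
            )

    canvas = np.zeros(tuple(shape), dtype=float)
    fg = params.foreground_intensity
    for u, v, data in tree.graph.edges(data=True):
        p0, p1, r = tree.pos(u), tree.pos(v), data["radius"]
        if channel == "EC":
            _paint_tube(canvas, p0, p1, 0.0, r, spacing, fg)
        elif channel == "SMA" and data["label"] == BASELINE:
            _paint_tube(canvas, p0, p1, r, r * (1.0 + params.wall_thickness_fraction), spacing, fg)

    rng = np.random.default_rng([params.seed, {"EC": 1, "SMA": 2, "nuclei": 3}[channel]])
    if channel == "nuclei":
        n_puncta = max(tree.n_nodes * 6, 60)
        centers = rng.uniform(0, 1, size=(n_puncta, 3)) * (extent - 8.0) + 4.0
        for c in centers:
            _paint_tube(canvas, c, c, 0.0, 2.5, spacing, fg)

    if params.shot_noise_scale > 0:
        signal = canvas > 0
        canvas[signal] = (
            rng.poisson(canvas[signal] / params.shot_noise_scale) * params.shot_noise_scale
        )
    canvas += params.background_level
    if params.gaussian_noise_sd > 0:
        canvas += rng.normal(0.0, params.gaussian_noise_sd, size=canvas.shape)

    max_val = (1 << params.bit_depth) - 1
    canvas = np.clip(canvas, 0, max_val)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    return VolumeImage(
        voxels=canvas.round().astype(dtype),
        spacing=tuple(spacing),
        channel=channel,
        bit_depth=params.bit_depth,
    )


# ---------------------------------------------------------------------------
# rendering and perturbation
# ---------------------------------------------------------------------------


def render_projection(volume: VolumeImage, axis: int = 0, mode: str = "maximum-intensity") -> ProjectionImage:
    """2D 8-bit render of a volume along ``axis``.

    ``maximum-intensity``: per-pixel maxima, rescaled to the full 8-bit
    range. ``depth-shaded``: maxima attenuated by the depth of the brightest
    voxel, giving renders a weak 3D cue.
    """
    if volume.voxels.size == 0:
        raise ValueError("empty volume")
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    if mode not in ("maximum-intensity", "depth-shaded"):
        raise ValueError(f"unknown mode {mode!r}")

    vox = volume.voxels.astype(float)
    mip = vox.max(axis=axis)
    if mode == "depth-shaded":
        depth = np.argmax(vox, axis=axis) / max(vox.shape[axis] - 1, 1)
        mip = mip * (1.0 - 0.5 * depth)
    peak = mip.max()
    pixels = np.zeros_like(mip, dtype=np.uint8) if peak == 0 else (
        (mip / peak) * 255.0
    ).round().astype(np.uint8)
    in_plane = [s for i, s in enumerate(volume.spacing) if i != axis]
    return ProjectionImage(
        pixels=pixels,
        pixel_size=float(np.mean(in_plane)),
        provenance={"axis": axis, "mode": mode, "in_plane_spacing": in_plane},
    )


def perturb_projection(image: ProjectionImage, level: int, seed: int = 0) -> ProjectionImage:
    """Graded degradation of a render: rotation + elastic warp + extra tube
    segments, all of magnitude increasing strictly with ``level``.

    ``level`` 0 is the identity. Deterministic given ``(seed, level)``. Used
    as the harness for the similarity score's monotone-degradation behavior.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    if level == 0:
        return ProjectionImage(
            pixels=image.pixels.copy(),
            pixel_size=image.pixel_size,
            provenance={**image.provenance, "perturb_level": 0},
        )
    from skimage.draw import line as draw_line
    from skimage.transform import rotate as sk_rotate

    rng = np.random.default_rng([seed, level])
    img = image.pixels.astype(float)

    img = sk_rotate(img, angle=1.5 * level, preserve_range=True, mode="constant")

    # smooth random displacement field, amplitude growing with level
    amp = 1.0 * level
    dy = ndimage.gaussian_filter(rng.normal(size=img.shape), 12.0) * amp * 12.0
    dx = ndimage.gaussian_filter(rng.normal(size=img.shape), 12.0) * amp * 12.0
    yy, xx = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]), indexing="ij")
    img = ndimage.map_coordinates(img, [yy + dy, xx + dx], order=1, mode="constant")

    # spurious tube segments
    h, w = img.shape
    for _ in range(2 * level):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(0.1, 0.3) * min(h, w)
        r1 = int(np.clip(r0 + length * np.sin(ang), 0, h - 1))
        c1 = int(np.clip(c0 + length * np.cos(ang), 0, w - 1))
        rr, cc = draw_line(int(r0), int(c0), r1, c1)
        tube = np.zeros_like(img, dtype=bool)
        tube[rr, cc] = True
        img[ndimage.binary_dilation(tube, iterations=1)] = 190.0

    return ProjectionImage(
        pixels=np.clip(img, 0, 255).round().astype(np.uint8),
        pixel_size=image.pixel_size,
        provenance={**image.provenance, "perturb_level": level, "perturb_seed": seed},
    )


# ---------------------------------------------------------------------------
# measurement tables and analytic phantoms
# ---------------------------------------------------------------------------


def simulate_group_table(
    group_means: list[float],
    group_sds: list[float],
    n_per_group: int = 7,
    seed: int = 0,
    group_labels: list[str] | None = None,
    units: str = "a.u.",
) -> pd.DataFrame:
    """Independent normal per-animal measurements for each experimental group.

    Default ``n_per_group`` of 7 mirrors a typical small-animal study arm.
    Columns: ``group``, ``animal_id``, ``value``, ``units``.
    """
    if len(group_means) != len(group_sds):
        raise ValueError("group_means and group_sds must have equal length")
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    if any(sd < 0 for sd in group_sds):
        raise ValueError("group sds must be non-negative")
    labels = group_labels or [f"group{i + 1}" for i in range(len(group_means))]
    rng = np.random.default_rng(seed)
    rows = []
    for g, (mu, sd) in zip(labels, zip(group_means, group_sds)):
        values = mu + sd * rng.standard_normal(n_per_group)
        for i, v in enumerate(values):
            rows.append({"group": g, "animal_id": f"{g}_{i + 1}", "value": float(v), "units": units})
    return pd.DataFrame(rows)


def make_cylinder_volume(
    radius_um: float,
    length_um: float,
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int],
    axis: int = 0,
    intensity: int = 200,
) -> VolumeImage:
    """Single straight axis-aligned tube phantom, centred in the grid."""
    sp = np.asarray(spacing, dtype=float)
    # centre on a voxel centre so the cross-section is odd-symmetric (a
    # perfectly even-width block has no centre voxel for thinning to keep)
    center = (np.asarray(shape) // 2 + 0.5) * sp
    axes = [(np.arange(n) + 0.5) * s - c for n, s, c in zip(shape, sp, center)]
    grids = np.meshgrid(*axes, indexing="ij")
    radial = np.sqrt(sum(g ** 2 for i, g in enumerate(grids) if i != axis))
    axial = np.abs(grids[axis])
    # true flat-capped cylinder (no spherical end caps) so the analytic
    # volume pi r^2 L and the centerline length L hold exactly
    canvas = np.where(
        (radial <= radius_um) & (axial <= length_um / 2.0), float(intensity), 0.0
    )
    return VolumeImage(canvas.astype(np.uint8), tuple(sp), channel="EC")


def make_annulus_image(
    outer_radius_um: float,
    inner_radius_um: float,
    pixel_size_um: float,
    pad_px: int = 8,
    intensity: int = 220,
) -> np.ndarray:
    """2D phantom of one vessel cross-section: a bright annular SMC wall."""
    if not 0 <= inner_radius_um < outer_radius_um:
        raise ValueError("need 0 <= inner radius < outer radius")
    n = int(np.ceil(2 * outer_radius_um / pixel_size_um)) + 2 * pad_px
    c = (n * pixel_size_um) / 2.0
    coords = (np.arange(n) + 0.5) * pixel_size_um - c
    rr = np.hypot(coords[:, None], coords[None, :])
    img = np.zeros((n, n), dtype=np.uint8)
    img[(rr <= outer_radius_um) & (rr > inner_radius_um)] = intensity
    return img
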