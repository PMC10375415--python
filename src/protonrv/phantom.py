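"""Voxel phantoms: homogeneous water blocks, blocks with an air gap, and
body-like cylinders with random dense inclusions.

Axes convention: x is the beam direction, y horizontal, z vertical. Grids
are indexed ``[ix, iy, iz]``; all lengths below are mm unless a name says cm.
The density grid is derived from the material-id grid through the registry,
so the two can never disagree.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .materials import MaterialRegistry, default_registry

__all__ = [
    "VoxelPhantom",
    "StructureSpec",
    "AirLayerRecord",
    "build_rect_phantom",
    "insert_air_layer",
    "build_cylinder_phantom",
    "substitute_region",
    "export_ct",
    "flip_phantom",
]

STRUCTURE_SHAPES = ("ellipsoid", "rectangle", "cylinder")
STRUCTURE_MATERIALS = ("hydroxyapatite", "glass")


@dataclasses.dataclass
class VoxelPhantom:
    origin: np.ndarray  # mm, (3,)
    voxel_size: np.ndarray  # mm, (3,)
    material_id: np.ndarray  # int16 grid [ix, iy, iz]
    registry: MaterialRegistry

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be > 0")

    @property
    def shape(self):
        return self.material_id.shape

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * self.voxel_size

    @property
    def density(self) -> np.ndarray:
        """Density grid in g/cm^3, derived from the material ids."""
        rho, _, _, _ = self.registry.arrays()
        return rho[self.material_id]

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size[axis]

    def center_grids(self):
        """Broadcastable voxel-center coordinate arrays (cx, cy, cz) in mm."""
        cx = self.axis_centers(0)[:, None, None]
        cy = self.axis_centers(1)[None, :, None]
        cz = self.axis_centers(2)[None, None, :]
        return cx, cy, cz

    def copy(self) -> "VoxelPhantom":
        return VoxelPhantom(
            self.origin.copy(), self.voxel_size.copy(), self.material_id.copy(), self.registry
        )


@dataclasses.dataclass(frozen=True)
class StructureSpec:
    """One internal inclusion of the cylinder phantom."""

    shape: str  # one of STRUCTURE_SHAPES
    material: str  # hydroxyapatite or glass
    extent_cm: tuple  # per-axis size, cm
    center_mm: tuple

    def __post_init__(self) -> None:
        if self.shape not in STRUCTURE_SHAPES:
            raise ValueError(f"shape must be one of {STRUCTURE_SHAPES}")
        if self.material not in STRUCTURE_MATERIALS:
            raise ValueError(f"material must be one of {STRUCTURE_MATERIALS}")


@dataclasses.dataclass(frozen=True)
class AirLayerRecord:
    x_start_mm: float
    thickness_mm: float


def build_rect_phantom(dims_cm, voxel_mm, registry: MaterialRegistry | None = None) -> VoxelPhantom:
    """All-water rectangular phantom of the given outer dimensions.

    ``dims_cm`` is the (x, y, z) size in cm; ``voxel_mm`` a scalar or per-axis
    voxel size. Grid shape is ceil(dims / voxel) per axis.
    """
    registry = registry or default_registry()
    dims_mm = np.asarray(dims_cm, dtype=float) * 10.0
    voxel = np.broadcast_to(np.asarray(voxel_mm, dtype=float), (3,)).copy()
    if np.any(dims_mm <= 0) or np.any(voxel <= 0):
        raise ValueError("dims and voxel size must be > 0")
    if np.any(voxel > dims_mm):
        raise ValueError("voxel size exceeds a phantom dimension")
    shape = tuple(int(math.ceil(d / v)) for d, v in zip(dims_mm, voxel))
    mid = np.full(shape, registry.id_of("water"), dtype=np.int16)
    return VoxelPhantom(np.zeros(3), voxel, mid, registry)


def insert_air_layer(
    p: VoxelPhantom,
    rng,
    *,
    thickness_range_cm=(1.0, 5.0),
    position_frac=(0.1, 0.9),
    max_retries: int = 16,
):
    """Replace an axis-aligned slab (full y-z cross-section) with air.

    Slab thickness is uniform in ``thickness_range_cm``; the slab center is
    uniform over the ``position_frac`` window of the x extent. Returns the
    modified copy plus a ground-truth :class:`AirLayerRecord`.
    """
    air = p.registry.id_of("air")
    X = p.extent_mm[0]
    for _ in range(max_retries):
        thickness = rng.uniform(*thickness_range_cm) * 10.0
        center = rng.uniform(position_frac[0] * X, position_frac[1] * X)
        x0, x1 = center - thickness / 2.0, center + thickness / 2.0
        x0c, x1c = max(x0, 0.0), min(x1, X)
        if x1c > x0c:
            out = p.copy()
            cx = out.axis_centers(0) - out.origin[0]
            sel = (cx >= x0c) & (cx < x1c)
            out.material_id[sel, :, :] = air
            return out, AirLayerRecord(x_start_mm=float(x0c), thickness_mm=float(x1c - x0c))
    raise RuntimeError("could not place air layer inside the phantom")


def _structure_mask(p: VoxelPhantom, spec: StructureSpec) -> np.ndarray:
    cx, cy, cz = p.center_grids()
    ext = np.asarray(spec.extent_cm) * 10.0
    c = np.asarray(spec.center_mm)
    if spec.shape == "ellipsoid":
        a = ext / 2.0
        return ((cx - c[0]) / a[0]) ** 2 + ((cy - c[1]) / a[1]) ** 2 + (
            (cz - c[2]) / a[2]
        ) ** 2 <= 1.0
    if spec.shape == "rectangle":
        h = ext / 2.0
        return (
            (np.abs(cx - c[0]) <= h[0])
            & (np.abs(cy - c[1]) <= h[1])
            & (np.abs(cz - c[2]) <= h[2])
        )
    # cylinder: axis along z, extent[0] as diameter, extent[2] as height
    r = ext[0] / 2.0
    return ((cx - c[0]) ** 2 + (cy - c[1]) ** 2 <= r * r) & (np.abs(cz - c[2]) <= ext[2] / 2.0)


def build_cylinder_phantom(
    radius_cm: float,
    height_cm: float,
    voxel_mm,
    rng,
    *,
    registry: MaterialRegistry | None = None,
    n_structures_range=(3, 6),
    size_range_cm=(5.0, 20.0),
):
    """Water cylinder (axis along z) with 3-6 random dense inclusions.

    Inclusions are hydroxyapatite or glass, shaped as ellipsoids, boxes or
    cylinders with per-axis sizes drawn uniformly from ``size_range_cm``;
    whatever protrudes is clipped to the cylinder. Voxels outside the
    cylinder are air. Returns the phantom and the list of
    :class:`StructureSpec` ground truths.
    """
    if radius_cm <= 0 or height_cm <= 0:
        raise ValueError("radius and height must be > 0")
    registry = registry or default_registry()
    dims_cm = (2 * radius_cm, 2 * radius_cm, height_cm)
    p = build_rect_phantom(dims_cm, voxel_mm, registry)
    cx, cy, cz = p.center_grids()
    R = radius_cm * 10.0
    center_xy = (p.extent_mm[0] / 2.0, p.extent_mm[1] / 2.0)
    inside = (cx - center_xy[0]) ** 2 + (cy - center_xy[1]) ** 2 <= R * R
    inside = np.broadcast_to(inside, p.shape)
    p.material_id[~inside] = registry.id_of("air")

    n = int(rng.integers(n_structures_range[0], n_structures_range[1] + 1))
    specs = []
    for _ in range(n):
        shape = STRUCTURE_SHAPES[rng.integers(len(STRUCTURE_SHAPES))]
        material = STRUCTURE_MATERIALS[rng.integers(len(STRUCTURE_MATERIALS))]
        ext = tuple(float(rng.uniform(*size_range_cm)) for _ in range(3))
        # center anywhere inside the cylinder footprint and height
        phi = rng.uniform(0, 2 * math.pi)
        rad = R * math.sqrt(rng.uniform())
        center = (
            center_xy[0] + rad * math.cos(phi),
            center_xy[1] + rad * math.sin(phi),
            float(rng.uniform(0, p.extent_mm[2])),
        )
        spec = StructureSpec(shape=shape, material=material, extent_cm=ext, center_mm=center)
        mask = _structure_mask(p, spec) & inside  # clip to the cylinder
        p.material_id[mask] = registry.id_of(material)
        specs.append(spec)
    return p, specs


def substitute_region(p: VoxelPhantom, box_mm, material: str) -> VoxelPhantom:
    """Reassign voxels whose centers fall inside an axis-aligned box.

    ``box_mm`` is ((x0, x1), (y0, y1), (z0, z1)). Returns a modified copy;
    the input phantom is untouched.
    """
    mid = p.registry.id_of(material)  # raises for unknown material
    box = np.asarray(box_mm, dtype=float)
    lo, hi = box[:, 0], box[:, 1]
    if np.any(hi <= p.origin) or np.any(lo >= p.origin + p.extent_mm):
        raise ValueError("substitution box does not intersect the phantom")
    out = p.copy()
    cx, cy, cz = out.center_grids()
    mask = (
        (cx >= lo[0]) & (cx < hi[0]) & (cy >= lo[1]) & (cy < hi[1]) & (cz >= lo[2]) & (cz < hi[2])
    )
    out.material_id[np.broadcast_to(mask, out.shape)] = mid
    return out


def export_ct(p: VoxelPhantom) -> np.ndarray:
    """The phantom's density grid (g/cm^3) — the study's stand-in for CT."""
    return p.density.copy()


def flip_phantom(p: VoxelPhantom, axis: int) -> VoxelPhantom:
    """Mirror the phantom along a grid axis (1 = y, 2 = z)."""
    out = p.copy()
    out.material_id = np.flip(out.material_id, axis=axis).copy()
    return out
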