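"""Beam source definition and sampling (pencil and wobbler modes), and the
scintillation-detector arrays that surround the phantom.

Detectors are 10 mm x 10 mm x 3 mm plastic scintillator tiles whose centers
sit 10 mm outside the phantom surface, face parallel to the surface with the
normal pointing inward. Readouts are total deposited energy per detector
(MeV) — an integrated-current stand-in.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .phantom import VoxelPhantom

__all__ = [
    "BeamSpec",
    "ProtonState",
    "Detector",
    "DetectorArray",
    "CurrentReadout",
    "sample_initial_proton",
    "sample_initial_protons",
    "place_detectors_rect",
    "place_detectors_cyl",
    "select_subset",
]

DETECTOR_FACE_MM = 10.0
DETECTOR_THICKNESS_MM = 3.0
STANDOFF_MM = 10.0


@dataclasses.dataclass(frozen=True)
class BeamSpec:
    """Proton source: energy (MeV), transverse center shift (y, z) in cm,
    beam diameter in cm, mode 'pencil' or 'wobbler', and proton count."""

    energy: float
    center_shift_cm: tuple = (0.0, 0.0)
    width_cm: float = 1.0
    mode: str = "pencil"
    n_protons: int = 100_000
    wobble_radius_factor: float = 1.5  # wobble circle radius / beam radius

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError("energy must be > 0")
        if self.width_cm <= 0:
            raise ValueError("beam width must be > 0")
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")
        if self.mode not in ("pencil", "wobbler"):
            raise ValueError("mode must be 'pencil' or 'wobbler'")


@dataclasses.dataclass
class ProtonState:
    position: np.ndarray  # mm
    direction: np.ndarray  # unit vector
    energy: float  # MeV


def _beam_center_mm(b: BeamSpec, p: VoxelPhantom) -> np.ndarray:
    cy = p.origin[1] + p.extent_mm[1] / 2.0 + b.center_shift_cm[0] * 10.0
    cz = p.origin[2] + p.extent_mm[2] / 2.0 + b.center_shift_cm[1] * 10.0
    return np.array([p.origin[0], cy, cz])


def sample_initial_protons(b: BeamSpec, p: VoxelPhantom, rng, n: int | None = None):
    """Vectorized source sampling: (positions (n,3), directions (n,3), E (n,)).

    Entry points lie on the upstream (x = origin) face, uniform on a disc of
    the configured diameter; in wobbler mode the disc center is additionally
    displaced along a circle of radius ``wobble_radius_factor`` times the
    beam radius, with uniform phase per proton. Direction is +x.
    """
    n = b.n_protons if n is None else n
    center = _beam_center_mm(b, p)
    radius = b.width_cm * 10.0 / 2.0
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    r = radius * np.sqrt(rng.random(n))
    dy, dz = r * np.cos(phi), r * np.sin(phi)
    if b.mode == "wobbler":
        wr = b.wobble_radius_factor * radius
        wphi = rng.uniform(0.0, 2.0 * math.pi, n)
        dy = dy + wr * np.cos(wphi)
        dz = dz + wr * np.sin(wphi)
    pos = np.empty((n, 3))
    pos[:, 0] = center[0]
    pos[:, 1] = center[1] + dy
    pos[:, 2] = center[2] + dz
    dirs = np.zeros((n, 3))
    dirs[:, 0] = 1.0
    E = np.full(n, float(b.energy))
    return pos, dirs, E


def sample_initial_proton(b: BeamSpec, p: VoxelPhantom, rng) -> ProtonState:
    pos, dirs, E = sample_initial_protons(b, p, rng, 1)
    return ProtonState(position=pos[0], direction=dirs[0], energy=float(E[0]))


@dataclasses.dataclass(frozen=True)
class Detector:
    center: np.ndarray  # mm
    normal: np.ndarray  # inward unit vector
    u_axis: np.ndarray  # in-face unit vector
    v_axis: np.ndarray  # in-face unit vector
    id: tuple  # (column, row)


class DetectorArray:
    """Ordered detector collection with vectorized geometry arrays."""

    def __init__(self, detectors, *, n_columns: int, n_rows: int, layout: str):
        ids = [d.id for d in detectors]
        if len(set(ids)) != len(ids):
            raise ValueError("detector ids must be unique")
        self.detectors = list(detectors)
        self.n_columns = n_columns
        self.n_rows = n_rows
        self.layout = layout
        self.centers = np.array([d.center for d in self.detectors]).reshape(-1, 3)
        self.normals = np.array([d.normal for d in self.detectors]).reshape(-1, 3)
        self.u_axes = np.array([d.u_axis for d in self.detectors]).reshape(-1, 3)
        self.v_axes = np.array([d.v_axis for d in self.detectors]).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.detectors)

    @property
    def ids(self):
        return [d.id for d in self.detectors]

    def mirror_permutation(self, axis: int, about_mm: float, tol: float = 1e-6):
        """Index permutation mapping each detector to its mirror twin across
        the plane ``coordinate[axis] = about_mm``. Raises if the layout has
        no exact mirror symmetry."""
        mirrored = self.centers.copy()
        mirrored[:, axis] = 2.0 * about_mm - mirrored[:, axis]
        perm = np.empty(len(self), dtype=int)
        for i, c in enumerate(mirrored):
            d2 = np.sum((self.centers - c) ** 2, axis=1)
            j = int(np.argmin(d2))
            if d2[j] > tol:
                raise ValueError("detector layout is not mirror-symmetric about this plane")
            perm[i] = j
        return perm

    def to_json_obj(self):
        return [
            {"id": list(d.id), "center": d.center.tolist(), "normal": d.normal.tolist()}
            for d in self.detectors
        ]


@dataclasses.dataclass
class CurrentReadout:
    """Per-detector accumulated deposited energy (MeV), ordered by detector."""

    ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("readout length must match detector count")
        if np.any(self.values < 0):
            raise ValueError("currents must be >= 0")

    def to_full_vector(self, n_columns: int, n_rows: int) -> np.ndarray:
        """Embed into a dense (n_columns, n_rows) grid; absent ids stay 0."""
        out = np.zeros((n_columns, n_rows))
        for (c, r), v in zip(self.ids, self.values):
            out[c, r] = v
        return out


_SIDES = {"+y": (1, +1), "-y": (1, -1), "+z": (2, +1), "-z": (2, -1)}


def place_detectors_rect(
    p: VoxelPhantom, n_per_side: int = 24, sides=("+y", "-y")
) -> DetectorArray:
    """Detector rows along x on the requested faces of a rectangular phantom.

    Each side carries ``n_per_side`` tiles evenly spanning the x extent, at
    the standard 10 mm standoff, centered in the side's transverse
    coordinate. Side order and x order fix the readout ordering.
    """
    if n_per_side < 1:
        raise ValueError("n_per_side must be >= 1")
    if not sides:
        raise ValueError("at least one side is required")
    X = p.extent_mm[0]
    pitch = X / n_per_side
    xs = p.origin[0] + (np.arange(n_per_side) + 0.5) * pitch
    dets = []
    for row, side in enumerate(sides):
        if side not in _SIDES:
            raise ValueError(f"unknown side {side!r}")
        axis, sign = _SIDES[side]
        coord = p.origin[axis] + (p.extent_mm[axis] if sign > 0 else 0.0) + sign * STANDOFF_MM
        other = 2 if axis == 1 else 1
        mid_other = p.origin[other] + p.extent_mm[other] / 2.0
        normal = np.zeros(3)
        normal[axis] = -sign
        u = np.array([1.0, 0.0, 0.0])
        v = np.cross(normal, u)
        for col, x in enumerate(xs):
            c = np.zeros(3)
            c[0] = x
            c[axis] = coord
            c[other] = mid_other
            dets.append(Detector(center=c, normal=normal, u_axis=u, v_axis=v, id=(col, row)))
    return DetectorArray(dets, n_columns=n_per_side, n_rows=len(sides), layout="rect")


def place_detectors_cyl(
    p: VoxelPhantom,
    beam: BeamSpec,
    *,
    angular_step_deg: float = 10.0,
    n_rows: int = 12,
    exclusion_cm: float = 2.0,
    radius_mm: float | None = None,
) -> DetectorArray:
    """Detector columns around a cylindrical phantom (axis along z).

    Columns sit at ``angular_step_deg`` intervals on a circle 10 mm outside
    the cylinder surface; ``n_rows`` rows are stacked gap-free (10 mm pitch)
    along z, centered on the beam plane. Detectors whose center lies within
    ``exclusion_cm`` of the beam envelope (the cylinder of radius
    width/2 around the beam axis) are removed so they do not intercept the
    beam; their ids are recorded on the returned array as ``removed_ids``.
    """
    if 360.0 % angular_step_deg != 0:
        raise ValueError("360 must be divisible by the angular step")
    n_cols = int(round(360.0 / angular_step_deg))
    cx = p.origin[0] + p.extent_mm[0] / 2.0
    cy = p.origin[1] + p.extent_mm[1] / 2.0
    R = (min(p.extent_mm[0], p.extent_mm[1]) / 2.0 if radius_mm is None else radius_mm)
    R_det = R + STANDOFF_MM
    beam_y = cy + beam.center_shift_cm[0] * 10.0
    beam_z = p.origin[2] + p.extent_mm[2] / 2.0 + beam.center_shift_cm[1] * 10.0
    z0 = beam_z - (n_rows - 1) / 2.0 * DETECTOR_FACE_MM
    envelope = beam.width_cm * 10.0 / 2.0
    dets, removed = [], []
    for col in range(n_cols):
        phi = math.radians(col * angular_step_deg)
        nx, ny = math.cos(phi), math.sin(phi)
        center_xy = np.array([cx + R_det * nx, cy + R_det * ny])
        normal = np.array([-nx, -ny, 0.0])
        u = np.array([-ny, nx, 0.0])  # tangential
        v = np.array([0.0, 0.0, 1.0])
        for row in range(n_rows):
            c = np.array([center_xy[0], center_xy[1], z0 + row * DETECTOR_FACE_MM])
            # distance from the detector center to the beam axis (line along x)
            d_axis = math.hypot(c[1] - beam_y, c[2] - beam_z)
            det = Detector(center=c, normal=normal, u_axis=u, v_axis=v, id=(col, row))
            if d_axis - envelope < exclusion_cm * 10.0:
                removed.append((col, row))
            else:
                dets.append(det)
    arr = DetectorArray(dets, n_columns=n_cols, n_rows=n_rows, layout="cylinder")
    arr.removed_ids = removed
    return arr


def select_subset(a: DetectorArray, columns=None, rows=None) -> DetectorArray:
    """Restrict an array to the given column/row ids, preserving order."""
    columns = set(range(a.n_columns)) if columns is None else set(columns)
    rows = set(range(a.n_rows)) if rows is None else set(rows)
    if not columns.issubset(range(a.n_columns)) or not rows.issubset(range(a.n_rows)):
        raise ValueError("unknown detector column/row id in subset")
    dets = [d for d in a.detectors if d.id[0] in columns and d.id[1] in rows]
    if not dets:
        raise ValueError("subset selects no detectors")
    out = DetectorArray(dets, n_columns=a.n_columns, n_rows=a.n_rows, layout=a.layout)
    if hasattr(a, "removed_ids"):
        out.removed_ids = [i for i in a.removed_ids if i[0] in columns and i[1] in rows]
    return out
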