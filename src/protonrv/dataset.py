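"""Dataset generation for the three simulation families, with the 64/16/20
split and mirror-flip augmentation.

Families:

``A``
    homogeneous rectangular water phantom, pencil beam, lateral detector
    rows on the two y faces; target is the central x-y dose slab (2D).
``B``
    rectangular phantom with a randomly sized and positioned air layer,
    detectors on all four lateral faces; same 2D slab target.
``C``
    cylindrical phantom with 3-6 random hydroxyapatite/glass inclusions,
    wobbler beam, 36 x 12 detector barrel with the beam-exclusion rule;
    target is the full 3D dose grid and the density grid is stored as CT.

Augmentation mirrors a sample about the y (or z) midplane: dose/CT grids
are flipped, the current vector is permuted by the detector layout's mirror
map, and the recorded beam shift changes sign. Flips are applied after
splitting, to the train and validation sets only.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .beam import BeamSpec, place_detectors_cyl, place_detectors_rect
from .phantom import build_cylinder_phantom, build_rect_phantom, insert_air_layer
from .transport import TransportConfig, simulate

__all__ = [
    "FamilyConfig",
    "FAMILY_DEFAULTS",
    "SplitSpec",
    "split_dataset",
    "generate_dataset",
    "load_dataset",
    "augment_flips",
]


@dataclasses.dataclass
class FamilyConfig:
    """Study conditions of one simulation family."""

    family: str
    energy_range: tuple  # MeV
    shift_y_cm: float  # uniform in [-shift, +shift]
    shift_z_cm: float
    width_range_cm: tuple  # (lo, hi) beam diameter; degenerate for pencil families
    mode: str
    n_protons: int
    voxel_mm: tuple
    phantom_dims_cm: tuple  # rect (x, y, z); for C: (radius, height)
    detector_layout: str  # "rect2", "rect4", "cyl"
    target: str  # "slab2d" or "grid3d"
    with_ct: bool
    flip_axes: tuple  # augmentation flips, subset of ("y", "z")
    air_layer: bool = False
    slab_halfwidth_vox: int = 1  # slab target: +-voxels around the z midplane
    slab_y_downsample: int = 2  # transverse rebinning of the slab target
    normalize_target_total: float = 100.0  # stored dose normalized to this total (0 = off)


# Desk-scale study conditions. Beam parameter ranges follow the study design
# (energies, shifts and widths per family); grid resolutions are 1.875 mm in
# depth for the rectangular families (5 mm transverse, 2-voxel central slab
# target) and 10 mm isotropic for the cylindrical family.
FAMILY_DEFAULTS = {
    "A": FamilyConfig(
        family="A",
        energy_range=(180.0, 220.0),
        shift_y_cm=4.0,
        shift_z_cm=0.0,
        width_range_cm=(1.0, 1.0),
        mode="pencil",
        n_protons=20_000,
        voxel_mm=(1.875, 5.0, 5.0),
        phantom_dims_cm=(36.0, 20.0, 20.0),
        detector_layout="rect2",
        target="slab2d",
        with_ct=False,
        flip_axes=("y",),
    ),
    "B": FamilyConfig(
        family="B",
        energy_range=(180.0, 220.0),
        shift_y_cm=4.0,
        shift_z_cm=0.0,
        width_range_cm=(1.0, 1.0),
        mode="pencil",
        n_protons=20_000,
        voxel_mm=(1.875, 5.0, 5.0),
        phantom_dims_cm=(36.0, 20.0, 20.0),
        detector_layout="rect4",
        target="slab2d",
        with_ct=False,
        flip_axes=("y",),
        air_layer=True,
    ),
    "C": FamilyConfig(
        family="C",
        energy_range=(120.0, 180.0),
        shift_y_cm=16.0,
        shift_z_cm=16.0,
        width_range_cm=(1.0, 4.0),
        mode="wobbler",
        n_protons=20_000,
        voxel_mm=(10.0, 10.0, 10.0),
        phantom_dims_cm=(20.0, 40.0),  # radius, height
        detector_layout="cyl",
        target="grid3d",
        with_ct=True,
        flip_axes=("z",),
    ),
}


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    fractions: tuple = (0.64, 0.16, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_dataset(n: int, spec: SplitSpec):
    """Disjoint, exhaustive (train, val, test) index arrays.

    Counts are round(f * n) for train and validation; the remainder is the
    test set (n = 10 -> 6/2/2).
    """
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    n_train = round(spec.fractions[0] * n)
    n_val = round(spec.fractions[1] * n)
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def _build_sample(cfg: FamilyConfig, rng):
    """One phantom + beam + detector realization. Returns
    (phantom, beam, detectors, ct or None, metadata dict)."""
    meta = {}
    if cfg.family in ("A", "B"):
        p = build_rect_phantom(cfg.phantom_dims_cm, cfg.voxel_mm)
        if cfg.air_layer:
            p, rec = insert_air_layer(p, rng)
            meta["air_x_start_mm"] = rec.x_start_mm
            meta["air_thickness_mm"] = rec.thickness_mm
    else:
        p, specs = build_cylinder_phantom(
            cfg.phantom_dims_cm[0], cfg.phantom_dims_cm[1], cfg.voxel_mm, rng
        )
        meta["n_structures"] = len(specs)
    energy = float(rng.uniform(*cfg.energy_range))
    shift_y = float(rng.uniform(-cfg.shift_y_cm, cfg.shift_y_cm)) if cfg.shift_y_cm else 0.0
    shift_z = float(rng.uniform(-cfg.shift_z_cm, cfg.shift_z_cm)) if cfg.shift_z_cm else 0.0
    width = float(rng.uniform(*cfg.width_range_cm))
    beam = BeamSpec(
        energy=energy,
        center_shift_cm=(shift_y, shift_z),
        width_cm=width,
        mode=cfg.mode,
        n_protons=cfg.n_protons,
    )
    if cfg.detector_layout == "rect2":
        det = place_detectors_rect(p, 24, ("+y", "-y"))
    elif cfg.detector_layout == "rect4":
        det = place_detectors_rect(p, 24, ("+y", "-y", "+z", "-z"))
    elif cfg.detector_layout == "cyl":
        det = place_detectors_cyl(p, beam)
    else:
        raise ValueError(cfg.detector_layout)
    ct = p.density.astype(np.float32) if cfg.with_ct else None
    meta.update(energy=energy, shift_y_cm=shift_y, shift_z_cm=shift_z, width_cm=width)
    return p, beam, det, ct, meta


def _extract_target(cfg: FamilyConfig, dose_grid):
    """Target grid in the normalized-dose convention (total = 100 Gy).

    For the 2D families this is the central x-y slab (2 z-voxels summed),
    rebinned transversely by ``slab_y_downsample``; for the 3D family the
    full grid."""
    if cfg.target == "slab2d":
        nz = dose_grid.shape[2]
        lo = nz // 2 - cfg.slab_halfwidth_vox
        out = dose_grid[:, :, lo : nz // 2 + cfg.slab_halfwidth_vox].sum(axis=2)
        d = cfg.slab_y_downsample
        if d > 1:
            ny = out.shape[1] // d * d
            out = out[:, :ny].reshape(out.shape[0], ny // d, d).sum(axis=2)
    else:
        out = dose_grid
    if cfg.normalize_target_total and out.sum() > 0:
        out = out * (cfg.normalize_target_total / out.sum())
    return out


def _current_vector(cfg: FamilyConfig, det, readout):
    if cfg.detector_layout == "cyl":
        return readout.to_full_vector(det.n_columns, det.n_rows)
    return readout.values.copy()  # fixed rect layout, no removals


def generate_dataset(
    path,
    cfg: FamilyConfig,
    n_samples: int,
    seed: int,
    transport: TransportConfig | None = None,
    progress=None,
):
    """Simulate ``n_samples`` independent samples and write them to HDF5.

    Fully reproducible: sample i uses a child of SeedSequence(seed).
    """
    transport = transport or TransportConfig()
    children = np.random.SeedSequence(seed).spawn(n_samples)
    X_cur, Y, CT, metas = [], [], [], []
    for i in range(n_samples):
        rng = np.random.default_rng(children[i])
        p, beam, det, ct, meta = _build_sample(cfg, rng)
        res = simulate(p, beam, det, transport, rng)
        X_cur.append(_current_vector(cfg, det, res.currents).astype(np.float32))
        Y.append(_extract_target(cfg, res.dose.grid).astype(np.float32))
        if ct is not None:
            CT.append(ct)
        metas.append(meta)
        if progress is not None:
            progress(i + 1, n_samples)
    with h5py.File(path, "w") as f:
        f.create_dataset("currents", data=np.stack(X_cur))
        f.create_dataset("dose", data=np.stack(Y))
        if CT:
            f.create_dataset("ct", data=np.stack(CT))
        g = f.create_group("metadata")
        for key in metas[0]:
            g.create_dataset(key, data=np.array([m.get(key, np.nan) for m in metas]))
        f.attrs["family"] = cfg.family
        f.attrs["seed"] = seed
        f.attrs["config"] = json.dumps(dataclasses.asdict(cfg))
        f.attrs["voxel_mm"] = cfg.voxel_mm


def load_dataset(path):
    """Read a dataset file back into arrays: dict with currents/dose[/ct],
    metadata dict of arrays, and the FamilyConfig."""
    with h5py.File(path, "r") as f:
        out = {"currents": f["currents"][...], "dose": f["dose"][...]}
        if "ct" in f:
            out["ct"] = f["ct"][...]
        out["metadata"] = {k: f["metadata"][k][...] for k in f["metadata"]}
        cfg = FamilyConfig(**json.loads(f.attrs["config"]))
        for key in ("energy_range", "width_range_cm", "voxel_mm", "phantom_dims_cm", "flip_axes"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
    return out, cfg


# -- flip augmentation -----------------------------------------------------

_REcT_SIDES = {"rect2": ("+y", "-y"), "rect4": ("+y", "-y", "+z", "-z")}


def _flip_currents(cfg: FamilyConfig, cur, axis: str):
    """Mirror the current vector/map under a y- or z-flip of the scene."""
    if cfg.detector_layout == "cyl":
        out = cur.copy()  # (columns, rows)
        if axis == "y":
            out = out[(np.arange(out.shape[0]) * -1) % out.shape[0], :]
        else:
            out = out[:, ::-1]
        return out
    sides = _REcT_SIDES[cfg.detector_layout]
    n = 24
    out = cur.copy().reshape(len(sides), n)
    swap = {"y": ("+y", "-y"), "z": ("+z", "-z")}[axis]
    if swap[0] in sides:
        i, j = sides.index(swap[0]), sides.index(swap[1])
        out[[i, j]] = out[[j, i]]
    return out.reshape(cur.shape)


def _flip_target(cfg: FamilyConfig, y, axis: str):
    if cfg.target == "slab2d":
        if axis == "z":
            raise ValueError("slab targets have no z axis to flip")
        return y[:, ::-1].copy()
    ax = {"y": 1, "z": 2}[axis]
    return np.flip(y, axis=ax).copy()


def augment_flips(data: dict, cfg: FamilyConfig, train_idx, val_idx, axes=None):
    """Append mirrored copies of the train/val samples; test is untouched.

    Returns (new data dict, new train_idx, new val_idx). Each requested axis
    doubles the train and validation sets; the flipped twin of a sample
    keeps its split membership, so no augmented leakage into test is
    possible.
    """
    axes = cfg.flip_axes if axes is None else axes
    X, Y = [data["currents"]], [data["dose"]]
    CT = [data["ct"]] if "ct" in data else None
    tr, va = [np.asarray(train_idx, dtype=int)], [np.asarray(val_idx, dtype=int)]
    n = data["currents"].shape[0]
    meta = {k: [v] for k, v in data["metadata"].items()}
    for axis in axes:
        src = np.concatenate([tr[0], va[0]])
        Xf = np.stack([_flip_currents(cfg, c, axis) for c in data["currents"][src]])
        Yf = np.stack([_flip_target(cfg, y, axis) for y in data["dose"][src]])
        X.append(Xf)
        Y.append(Yf)
        if CT is not None:
            ax = {"y": 1, "z": 2}[axis]
            CT.append(np.flip(data["ct"][src], axis=ax + 1).copy())
        for k, v in data["metadata"].items():
            vf = v[src].copy()
            if (axis == "y" and k == "shift_y_cm") or (axis == "z" and k == "shift_z_cm"):
                vf = -vf
            meta[k].append(vf)
        pos = np.arange(len(src)) + n
        tr.append(pos[: len(tr[0])])
        va.append(pos[len(tr[0]) :])
        n += len(src)
    out = {
        "currents": np.concatenate(X),
        "dose": np.concatenate(Y),
        "metadata": {k: np.concatenate(v) for k, v in meta.items()},
    }
    if CT is not None:
        out["ct"] = np.concatenate(CT)
    return out, np.concatenate(tr), np.concatenate(va)
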