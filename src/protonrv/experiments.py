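"""The three headline experiments around the trained pipeline:

* material substitution — replace a box of the phantom with air or Pb
  either upstream of ("front") or at/behind ("around-peak") the Bragg peak
  and test, over repeated simulations, whether the detector currents change
  significantly. The front substitution changes the currents; the
  around-peak substitution does not, because protons near the peak are too
  slow to escape — the observation that motivates feeding the density grid
  (CT) to the reconstruction model.
* detector reduction — retrain the (FC-encoder) model on decimated
  detector subsets and track how the peak errors degrade.
* CT ablation — train with and without the density-grid input on identical
  splits and compare peak errors pairwise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .beam import BeamSpec, DetectorArray, select_subset
from .dataset import augment_flips, split_dataset, SplitSpec
from .evaluation import evaluate_testset
from .models import ModelConfig, build_model, train
from .phantom import VoxelPhantom, substitute_region
from .physics import csda_range
from .transport import TransportConfig, simulate

__all__ = [
    "SubstitutionReport",
    "run_substitution_experiment",
    "run_detector_reduction",
    "run_ct_ablation",
]


@dataclasses.dataclass
class SubstitutionReport:
    material: str
    region_class: str  # "front" or "around-peak"
    base_mean: np.ndarray
    base_std: np.ndarray
    sub_mean: np.ndarray
    sub_std: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray  # Benjamini-Hochberg at 5%
    n_repeats: int

    @property
    def any_significant(self) -> bool:
        return bool(self.significant.any())


def _bh_reject(p, alpha=0.05):
    """Benjamini-Hochberg step-up procedure."""
    p = np.asarray(p)
    order = np.argsort(p)
    m = len(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    k = np.flatnonzero(passed)
    out = np.zeros(m, dtype=bool)
    if len(k):
        out[order[: k.max() + 1]] = True
    return out


def classify_region(p: VoxelPhantom, beam: BeamSpec, box_mm) -> str:
    """'front' if the substituted box lies upstream of the unperturbed Bragg
    depth along the beam axis, else 'around-peak'."""
    water = p.registry["water"]
    depth_mm = csda_range(beam.energy, water) * 10.0
    x0, x1 = box_mm[0]
    entry = p.origin[0]
    if x1 - entry <= depth_mm * 0.9:
        return "front"
    return "around-peak"


def run_substitution_experiment(
    p: VoxelPhantom,
    beam: BeamSpec,
    det: DetectorArray,
    box_mm,
    material: str,
    cfg: TransportConfig,
    *,
    n_repeats: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> SubstitutionReport:
    """Repeated-seed two-sample comparison of currents with and without the
    substitution; per-detector Welch t-tests with Benjamini-Hochberg
    control across detectors."""
    if np.all(np.asarray(box_mm)[:, 1] <= p.origin) or np.all(
        np.asarray(box_mm)[:, 0] >= p.origin + p.extent_mm
    ):
        raise ValueError("substitution region is outside the phantom")
    p_sub = substitute_region(p, box_mm, material)
    base, sub = [], []
    ss = np.random.SeedSequence(seed).spawn(2 * n_repeats)
    for i in range(n_repeats):
        base.append(simulate(p, beam, det, cfg, np.random.default_rng(ss[2 * i])).currents.values)
        sub.append(
            simulate(p_sub, beam, det, cfg, np.random.default_rng(ss[2 * i + 1])).currents.values
        )
    base, sub = np.array(base), np.array(sub)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pvals = stats.ttest_ind(base, sub, equal_var=False)
    pvals = np.nan_to_num(pvals, nan=1.0)  # zero-variance (all-zero) detectors
    return SubstitutionReport(
        material=material,
        region_class=classify_region(p, beam, box_mm),
        base_mean=base.mean(0),
        base_std=base.std(0, ddof=1),
        sub_mean=sub.mean(0),
        sub_std=sub.std(0, ddof=1),
        p_values=pvals,
        significant=_bh_reject(pvals, alpha),
        n_repeats=n_repeats,
    )


def _train_eval_once(data, fam_cfg, tr, va, te, voxel, *, with_ct, encoder, epochs, lr, seed,
                     current_cols=None, current_rows=None):
    """Shared train+evaluate step on a fixed split (one seed)."""
    work = {k: (v.copy() if hasattr(v, "copy") else v) for k, v in data.items()}
    if current_cols is not None or current_rows is not None:
        cur = work["currents"]
        if cur.ndim != 3:
            raise ValueError("detector subsetting expects (n, columns, rows) currents")
        cols = np.asarray(current_cols if current_cols is not None else range(cur.shape[1]))
        rows = np.asarray(current_rows if current_rows is not None else range(cur.shape[2]))
        work["currents"] = cur[:, cols][:, :, rows]
    aug, tr_a, va_a = augment_flips(work, fam_cfg, tr, va)
    flat = (int(np.prod(aug["currents"].shape[1:])),)
    if encoder == "fc":
        aug["currents"] = aug["currents"].reshape(len(aug["currents"]), -1)
        work["currents"] = work["currents"].reshape(len(work["currents"]), -1)
        current_shape = flat
    else:
        current_shape = aug["currents"].shape[1:]
    mcfg = ModelConfig(seed=seed, epochs=epochs, lr=lr)
    model = build_model(
        mcfg,
        with_ct=with_ct,
        current_shape=current_shape,
        target_shape=aug["dose"].shape[1:],
        encoder=encoder,
    )
    train(model, aug["currents"], aug["dose"], tr_a, va_a,
          X_ct=aug.get("ct") if with_ct else None)
    eval_data = dict(work)
    if not with_ct:
        eval_data.pop("ct", None)
    return model, evaluate_testset(model, eval_data, te, voxel)


def run_detector_reduction(
    data: dict,
    fam_cfg,
    voxel,
    schedule,
    *,
    n_repeats: int = 10,
    epochs: int = 20,
    lr: float = 1e-3,
    seed: int = 0,
    split_seed: int = 1,
):
    """Error-vs-detector-count curves for family C.

    ``schedule`` is a list of (columns, rows) id lists (None = all). Per the
    reduced-detector protocol the current encoder is the FC variant. Each
    point is trained ``n_repeats`` times with different weight seeds; the
    mean and std of the test-split depth peak error are reported.
    """
    n = data["currents"].shape[0]
    tr, va, te = split_dataset(n, SplitSpec(seed=split_seed))
    out = []
    for cols, rows in schedule:
        if cols is not None and len(cols) == 0 or rows is not None and len(rows) == 0:
            raise ValueError("empty detector subset")
        errs = []
        for r in range(n_repeats):
            _, rep = _train_eval_once(
                data, fam_cfg, tr, va, te, voxel,
                with_ct=False, encoder="fc", epochs=epochs, lr=lr,
                seed=seed + 1000 * r, current_cols=cols, current_rows=rows,
            )
            errs.append(rep.per_sample["dx_peak_mm"].mean())
        out.append(
            {
                "n_columns": len(cols) if cols is not None else data["currents"].shape[1],
                "n_rows": len(rows) if rows is not None else data["currents"].shape[2],
                "dx_peak_mean_mm": float(np.mean(errs)),
                "dx_peak_std_mm": float(np.std(errs, ddof=1)) if len(errs) > 1 else 0.0,
                "repeats": list(map(float, errs)),
            }
        )
    return out


def alternating_decimation(n: int, keep: int):
    """Evenly decimated id subset (36 -> 18 keeps every other column)."""
    if keep < 1 or keep > n:
        raise ValueError("keep must be in [1, n]")
    return list(np.round(np.linspace(0, n, keep, endpoint=False)).astype(int))


def run_ct_ablation(
    data: dict,
    fam_cfg,
    voxel,
    *,
    seeds=(0, 1, 2),
    epochs: int = 20,
    lr: float = 1e-3,
    split_seed: int = 1,
):
    """Paired with/without-CT comparison on identical splits and seeds.

    Returns {"with_ct": [...], "without_ct": [...]} of EvalReports, one per
    seed, all evaluated on the same test indices.
    """
    n = data["currents"].shape[0]
    tr, va, te = split_dataset(n, SplitSpec(seed=split_seed))
    out = {"with_ct": [], "without_ct": []}
    for s in seeds:
        for arm, flag in (("with_ct", True), ("without_ct", False)):
            _, rep = _train_eval_once(
                data, fam_cfg, tr, va, te, voxel,
                with_ct=flag, encoder="conv", epochs=epochs, lr=lr, seed=s,
            )
            out[arm].append(rep)
    return out
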