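"""End-to-end study pipelines: dataset -> split -> augmentation -> training
-> held-out evaluation, for each simulation family.

``run_study`` is the single entry point the acceptance script and the CLI
share. Study sizes default to the desk-scale conditions described in
docs/methods.md (a few hundred samples, 3 x 10^4 protons per sample);
everything is reproducible from one integer seed.
"""

from __future__ import annotations

import dataclasses
import tempfile
from pathlib import Path

import numpy as np

from .dataset import (
    FAMILY_DEFAULTS,
    SplitSpec,
    augment_flips,
    generate_dataset,
    load_dataset,
    split_dataset,
)
from .evaluation import EvalReport, GammaCriteria, evaluate_testset
from .models import ModelConfig, build_model, train
from .transport import TransportConfig

__all__ = ["StudyConfig", "StudyResult", "run_study", "target_voxel_mm"]

DEFAULT_N_SAMPLES = {"A": 200, "B": 180, "C": 180}
DEFAULT_EPOCHS = {"A": 95, "B": 28, "C": 40}

import math as _math


def default_transport(family: str) -> TransportConfig:
    """Per-family transport settings: family A biases virtual-proton
    azimuths toward its two instrumented faces; the four-sided and barrel
    layouts see all azimuths, so they raise the spawn rate instead."""
    if family == "A":
        return TransportConfig(
            spawn_rate_per_step=0.045,
            phi_bias_mix=0.8,
            phi_arcs=((0.0, _math.pi / 4), (_math.pi, _math.pi / 4)),
        )
    return TransportConfig(spawn_rate_per_step=0.06)


@dataclasses.dataclass
class StudyConfig:
    family: str
    n_samples: int | None = None
    epochs: int | None = None
    with_ct: bool | None = None  # default: family C -> True
    encoder: str | None = None  # default: conv for C, fc for A/B
    seed: int = 0
    n_protons: int | None = None
    lr: float = 1e-3

    def resolve(self):
        fam = FAMILY_DEFAULTS[self.family]
        cfg = dataclasses.replace(fam)
        if self.n_protons is not None:
            cfg.n_protons = self.n_protons
        n = self.n_samples or DEFAULT_N_SAMPLES[self.family]
        epochs = self.epochs or DEFAULT_EPOCHS[self.family]
        with_ct = cfg.with_ct if self.with_ct is None else self.with_ct
        encoder = self.encoder or ("conv" if self.family == "C" else "fc")
        return cfg, n, epochs, with_ct, encoder


@dataclasses.dataclass
class StudyResult:
    report: EvalReport
    model: object
    history: dict
    data: dict
    splits: tuple
    voxel_mm: tuple
    family_cfg: object


def target_voxel_mm(fam_cfg):
    """Voxel size of the target lattice (2D slab or 3D grid)."""
    v = fam_cfg.voxel_mm
    if fam_cfg.target == "slab2d":
        return (v[0], v[1] * getattr(fam_cfg, "slab_y_downsample", 1))
    return tuple(v)


def run_study(
    study: StudyConfig,
    dataset_path=None,
    criteria: GammaCriteria | None = None,
    progress=None,
) -> StudyResult:
    """Generate (or reuse) the dataset, train the estimator and evaluate it
    on the held-out test split."""
    fam_cfg, n_samples, epochs, with_ct, encoder = study.resolve()
    if dataset_path is not None and Path(dataset_path).exists():
        data, fam_cfg = load_dataset(dataset_path)
    else:
        if dataset_path is None:
            tmp = tempfile.NamedTemporaryFile(suffix=".h5", delete=False)
            dataset_path = tmp.name
            tmp.close()
        generate_dataset(
            dataset_path, fam_cfg, n_samples, study.seed,
            default_transport(study.family), progress=progress,
        )
        data, fam_cfg = load_dataset(dataset_path)

    n = data["currents"].shape[0]
    tr, va, te = split_dataset(n, SplitSpec(seed=study.seed + 1))
    aug, tr_a, va_a = augment_flips(data, fam_cfg, tr, va)

    target_shape = aug["dose"].shape[1:]
    if encoder == "conv" and fam_cfg.detector_layout == "cyl":
        current_shape = aug["currents"].shape[1:]
    else:
        current_shape = (int(np.prod(aug["currents"].shape[1:])),)
        aug["currents"] = aug["currents"].reshape(len(aug["currents"]), -1)
        data["currents"] = data["currents"].reshape(len(data["currents"]), -1)
    latent = 128 if study.family == "C" else 256  # 3D decoder cost dominates C
    mcfg = ModelConfig(seed=study.seed + 2, epochs=epochs, lr=study.lr,
                       base_filters_2d=24, latent=latent, ct_feat=64)
    model = build_model(
        mcfg,
        with_ct=with_ct,
        current_shape=current_shape,
        target_shape=target_shape,
        encoder=encoder,
    )
    hist = train(
        model,
        aug["currents"],
        aug["dose"],
        tr_a,
        va_a,
        X_ct=aug.get("ct") if with_ct else None,
    )
    voxel = target_voxel_mm(fam_cfg)
    eval_data = dict(data)
    if not with_ct:
        eval_data.pop("ct", None)
    report = evaluate_testset(
        model, eval_data, te, voxel, criteria, label=f"({fam_cfg.family})" + (" with CT" if with_ct else "")
    )
    return StudyResult(
        report=report,
        model=model,
        history=hist,
        data=data,
        splits=(tr, va, te),
        voxel_mm=voxel,
        family_cfg=fam_cfg,
    )
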