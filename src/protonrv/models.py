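"""Encoder–decoder models mapping detector currents to dose grids.

Architecture family (following the generative-decoder pattern): a current
encoder (fully connected for the rectangular-phantom layouts, convolutional
over the column x row current map for the cylindrical layout), an optional
convolutional encoder for the density grid ("CT") whose features are fused
with the current latent, and a decoder that upsamples with halving filter
counts, batch norm + LeakyReLU(0.2) between stages and tanh after the last
convolution. Loss is MSE, optimizer Adam, batch size 4.

Targets are affinely mapped into (-1, 1) using the training-split dose
maximum — to the sub-range [-0.9, 0.9], so the (large) zero-dose background
sits where tanh still has gradient instead of at its saturated endpoint —
and currents are scaled by the training-split 99th percentile. Both
statistics are stored on the model and serialized with it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn

__all__ = ["ModelConfig", "DoseEstimator", "build_model", "train", "predict"]

TANH_HEADROOM = 0.9  # targets use [-0.9, 0.9] so the background keeps gradient


@dataclasses.dataclass
class ModelConfig:
    latent: int = 256
    leaky_alpha: float = 0.2
    lr: float = 2e-4
    lr_decay: str = "cosine"  # "cosine" anneals to lr/20 over the run; "none" holds lr
    current_transform: str = "linear"  # optional "sqrt" compresses counting noise
    epochs: int = 200
    batch_size: int = 4
    seed: int = 0
    base_filters_2d: int = 16
    base_filters_3d: int = 8
    ct_filters: int = 4
    ct_feat: int = 128

    def to_dict(self):
        return dataclasses.asdict(self)


def _fc_encoder(d_in, cfg: ModelConfig, rng):
    a = cfg.leaky_alpha
    return nn.Sequential(
        [
            nn.Dense(d_in, 128, rng),
            nn.LeakyReLU(a),
            nn.Dense(128, cfg.latent, rng),
            nn.LeakyReLU(a),
        ]
    )


def _conv_current_encoder(map_shape, cfg: ModelConfig, rng):
    """2D conv encoder over the (columns, rows) current map."""
    a = cfg.leaky_alpha
    h, w = map_shape
    h2, w2 = (h + 1) // 2, (w + 1) // 2
    h4, w4 = (h2 + 1) // 2, (w2 + 1) // 2
    return nn.Sequential(
        [
            nn.Reshape((1, h, w)),
            nn.Conv2D(1, 8, rng, stride=2),
            nn.BatchNorm(8),
            nn.LeakyReLU(a),
            nn.Conv2D(8, 16, rng, stride=2),
            nn.BatchNorm(16),
            nn.LeakyReLU(a),
            nn.Reshape((16 * h4 * w4,)),
            nn.Dense(16 * h4 * w4, cfg.latent, rng),
            nn.LeakyReLU(a),
        ]
    )


def _decoder_2d(latent_in, target_shape, cfg: ModelConfig, rng):
    a = cfg.leaky_alpha
    H, W = target_shape
    if H % 4 or W % 4:
        raise ValueError("2D target shape must be divisible by 4")
    f = cfg.base_filters_2d
    h0, w0 = H // 4, W // 4
    return nn.Sequential(
        [
            nn.Dense(latent_in, f * h0 * w0, rng),
            nn.Reshape((f, h0, w0)),
            nn.BatchNorm(f),
            nn.LeakyReLU(a),
            nn.Upsample(),
            nn.Conv2D(f, f // 2, rng),
            nn.BatchNorm(f // 2),
            nn.LeakyReLU(a),
            nn.Upsample(),
            nn.Conv2D(f // 2, f // 4, rng),
            nn.BatchNorm(f // 4),
            nn.LeakyReLU(a),
            nn.Conv2D(f // 4, 1, rng),
            nn.Tanh(),
        ]
    )


def _decoder_3d(latent_in, target_shape, cfg: ModelConfig, rng):
    # filter counts halve along the two conv stages at half resolution; the
    # last (full-resolution) convolution is kept at 2 input channels to
    # bound the im2col working set of the largest grid
    a = cfg.leaky_alpha
    D, H, W = target_shape
    if D % 4 or H % 4 or W % 4:
        raise ValueError("3D target shape must be divisible by 4")
    f = cfg.base_filters_3d
    d0, h0, w0 = D // 4, H // 4, W // 4
    return nn.Sequential(
        [
            nn.Dense(latent_in, f * d0 * h0 * w0, rng),
            nn.Reshape((f, d0, h0, w0)),
            nn.BatchNorm(f),
            nn.LeakyReLU(a),
            nn.Upsample(),
            nn.Conv3D(f, f // 2, rng),
            nn.BatchNorm(f // 2),
            nn.LeakyReLU(a),
            nn.Conv3D(f // 2, f // 4, rng),
            nn.BatchNorm(f // 4),
            nn.LeakyReLU(a),
            nn.Upsample(),
            nn.Conv3D(f // 4, 1, rng),
            nn.Tanh(),
        ]
    )


def _ct_encoder(ct_shape, cfg: ModelConfig, rng):
    a = cfg.leaky_alpha
    D, H, W = ct_shape
    f = cfg.ct_filters
    half = lambda n: (n + 1) // 2
    d4, h4, w4 = half(half(D)), half(half(H)), half(half(W))
    flat = 2 * f * d4 * h4 * w4
    first = nn.Conv3D(1, f, rng, stride=2)
    first.input_grad = False  # CT is data; no gradient needed past it
    return nn.Sequential(
        [
            nn.Reshape((1, D, H, W)),
            first,
            nn.BatchNorm(f),
            nn.LeakyReLU(a),
            nn.Conv3D(f, 2 * f, rng, stride=2),
            nn.BatchNorm(2 * f),
            nn.LeakyReLU(a),
            nn.Reshape((flat,)),
            nn.Dense(flat, cfg.ct_feat, rng),
            nn.LeakyReLU(a),
        ]
    )


class DoseEstimator:
    """Currents (+ optional CT) -> normalized dose grid in (-1, 1)."""

    def __init__(self, current_encoder, ct_encoder, decoder, cfg: ModelConfig, meta: dict):
        self.current_encoder = current_encoder
        self.ct_encoder = ct_encoder
        self.decoder = decoder
        self.cfg = cfg
        self.meta = dict(meta)  # builder kwargs + normalization constants

    # -- plumbing ---------------------------------------------------------
    def forward(self, currents, ct=None, train: bool = False):
        z = self.current_encoder.forward(currents, train)
        if self.ct_encoder is not None:
            if ct is None:
                raise ValueError("model was built with CT conditioning; ct is required")
            zc = self.ct_encoder.forward(ct, train)
            self._zdim = z.shape[1]
            z = np.concatenate([z, zc], axis=1)
        return self.decoder.forward(z, train)

    def backward(self, grad):
        gz = self.decoder.backward(grad)
        if self.ct_encoder is not None:
            self.ct_encoder.backward(gz[:, self._zdim :])
            gz = gz[:, : self._zdim]
        self.current_encoder.backward(gz)

    def params(self):
        out = self.current_encoder.params() + self.decoder.params()
        if self.ct_encoder is not None:
            out = out + self.ct_encoder.params()
        return out

    def _bn_layers(self):
        seqs = [self.current_encoder, self.decoder] + (
            [self.ct_encoder] if self.ct_encoder is not None else []
        )
        return [l for s in seqs for l in s.layers if isinstance(l, nn.BatchNorm)]

    def snapshot(self):
        return (
            [p.copy() for p, _ in self.params()],
            [(l.run_mean.copy(), l.run_var.copy()) for l in self._bn_layers()],
        )

    def restore(self, snap):
        arrays, bn = snap
        for (p, _), a in zip(self.params(), arrays):
            p[...] = a
        for l, (m, v) in zip(self._bn_layers(), bn):
            l.run_mean[...] = m
            l.run_var[...] = v

    # -- persistence ------------------------------------------------------
    def save(self, path):
        path = Path(path)
        arrays, bn = self.snapshot()
        blobs = {f"p{i}": a for i, a in enumerate(arrays)}
        for i, (m, v) in enumerate(bn):
            blobs[f"bnm{i}"] = m
            blobs[f"bnv{i}"] = v
        np.savez(path.with_suffix(".npz"), **blobs)
        path.with_suffix(".json").write_text(
            json.dumps({"config": self.cfg.to_dict(), "meta": self.meta}, indent=2)
        )

    @classmethod
    def load(cls, path):
        path = Path(path)
        info = json.loads(path.with_suffix(".json").read_text())
        cfg = ModelConfig(**info["config"])
        meta = info["meta"]
        model = build_model(
            cfg,
            with_ct=meta["with_ct"],
            current_shape=tuple(meta["current_shape"]),
            target_shape=tuple(meta["target_shape"]),
            encoder=meta["encoder"],
        )
        model.meta = meta
        blobs = np.load(path.with_suffix(".npz"))
        arrays = [blobs[f"p{i}"] for i in range(len(model.params()))]
        bn = [
            (blobs[f"bnm{i}"], blobs[f"bnv{i}"]) for i in range(len(model._bn_layers()))
        ]
        model.restore((arrays, bn))
        return model


def build_model(
    cfg: ModelConfig,
    *,
    with_ct: bool,
    current_shape,
    target_shape,
    encoder: str = "fc",
) -> DoseEstimator:
    """Assemble an estimator.

    ``current_shape``: (n,) for a flat readout with an FC encoder, or
    (columns, rows) for the convolutional current-map encoder.
    ``target_shape``: (H, W) for 2D slab targets, (D, H, W) for 3D.
    """
    rng = np.random.default_rng(cfg.seed)
    if encoder == "fc":
        d_in = int(np.prod(current_shape))
        cur_enc = _fc_encoder(d_in, cfg, rng)
    elif encoder == "conv":
        if len(current_shape) != 2:
            raise ValueError("conv current encoder needs a (columns, rows) map")
        cur_enc = _conv_current_encoder(current_shape, cfg, rng)
    else:
        raise ValueError(f"unknown encoder {encoder!r}")
    ct_enc = None
    latent_in = cfg.latent
    if with_ct:
        if len(target_shape) != 3:
            raise ValueError("CT conditioning is defined for 3D targets")
        ct_enc = _ct_encoder(tuple(target_shape), cfg, rng)
        latent_in += cfg.ct_feat
    if len(target_shape) == 2:
        dec = _decoder_2d(latent_in, target_shape, cfg, rng)
    elif len(target_shape) == 3:
        dec = _decoder_3d(latent_in, target_shape, cfg, rng)
    else:
        raise ValueError("target must be 2D or 3D")
    meta = {
        "with_ct": with_ct,
        "current_shape": list(current_shape),
        "target_shape": list(target_shape),
        "encoder": encoder,
    }
    return DoseEstimator(cur_enc, ct_enc, dec, cfg, meta)


def _normalize_currents(X, scale, transform):
    Xn = X / scale
    if transform == "sqrt":
        return np.sqrt(np.maximum(Xn, 0.0))
    return Xn


def _normalize_ct(ct):
    return ct / 2.0 - 1.0  # densities 0..~11 g/cm^3; water -> -0.5


def train(
    model: DoseEstimator,
    X_cur,
    Y,
    train_idx,
    val_idx,
    *,
    X_ct=None,
    epochs: int | None = None,
    verbose: bool = False,
):
    """Fit the estimator; returns {train_loss, val_loss} per-epoch history.

    Normalization statistics (current 99th percentile, dose maximum) are
    computed on the training split only and stored on the model. The
    parameters achieving the best validation loss are restored at the end.
    """
    if len(train_idx) == 0:
        raise ValueError("empty training split")
    cfg = model.cfg
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed + 1)

    cur_scale = float(np.percentile(X_cur[train_idx], 99.0))
    if cur_scale <= 0:
        cur_scale = 1.0
    dose_max = float(Y[train_idx].max())
    if dose_max <= 0:
        raise ValueError("training targets are identically zero")
    model.meta["current_scale"] = cur_scale
    model.meta["dose_max"] = dose_max

    Xn = _normalize_currents(X_cur, cur_scale, cfg.current_transform).astype(nn.DTYPE)
    Yn = (TANH_HEADROOM * (2.0 * Y / dose_max - 1.0))[:, None].astype(nn.DTYPE)
    Ct = _normalize_ct(X_ct).astype(nn.DTYPE) if X_ct is not None else None

    opt = nn.Adam(model.params(), lr=cfg.lr)
    hist = {"train_loss": [], "val_loss": []}
    best = (np.inf, None)
    tr = np.asarray(train_idx)
    for epoch in range(epochs):
        if cfg.lr_decay == "cosine" and epochs > 1:
            frac = epoch / (epochs - 1)
            opt.lr = cfg.lr / 20.0 + (cfg.lr - cfg.lr / 20.0) * 0.5 * (
                1.0 + np.cos(np.pi * frac)
            )
        order = rng.permutation(len(tr))
        losses = []
        for k in range(0, len(order), cfg.batch_size):
            idx = tr[order[k : k + cfg.batch_size]]
            pred = model.forward(
                Xn[idx], Ct[idx] if Ct is not None else None, train=True
            )
            loss, g = nn.mse_loss(pred, Yn[idx])
            model.backward(g)
            opt.step()
            losses.append(loss)
        if not np.isfinite(losses).any() or not np.isfinite(losses[-1]):
            raise RuntimeError(f"training diverged at epoch {epoch} (loss={losses[-1]})")
        vl = _eval_loss(model, Xn, Yn, Ct, val_idx) if len(val_idx) else float("nan")
        hist["train_loss"].append(float(np.mean(losses)))
        hist["val_loss"].append(vl)
        if len(val_idx) and vl < best[0]:
            best = (vl, model.snapshot())
        if verbose:
            print(f"epoch {epoch + 1}/{epochs} train {hist['train_loss'][-1]:.5f} val {vl:.5f}")
    if best[1] is not None:
        model.restore(best[1])
    return hist


def _eval_loss(model, Xn, Yn, Ct, idx, batch: int = 16):
    idx = np.asarray(idx)
    total = 0.0
    for k in range(0, len(idx), batch):
        b = idx[k : k + batch]
        pred = model.forward(Xn[b], Ct[b] if Ct is not None else None, train=False)
        total += float(((pred - Yn[b]) ** 2).sum())
    return total / (len(idx) * np.prod(Yn.shape[1:]))


def predict(model: DoseEstimator, currents, ct=None, *, mask_air: bool = True):
    """DL dose on the target lattice (dose units of the training targets,
    clipped at zero).

    When a density grid is supplied, voxels with density below 0.1 g/cm^3
    (air) are zeroed: air deposits no appreciable dose, and the prior
    removes convolution edge artifacts in the never-dosed exterior."""
    currents = np.atleast_2d(np.asarray(currents, dtype=float))
    if "current_scale" not in model.meta:
        raise RuntimeError("model has not been trained (no normalization stats)")
    Xn = _normalize_currents(
        currents, model.meta["current_scale"], model.meta.get("current_transform", "linear")
    ).astype(nn.DTYPE)
    Ct = _normalize_ct(np.asarray(ct, dtype=float)).astype(nn.DTYPE) if ct is not None else None
    if Ct is not None and Ct.ndim == len(model.meta["target_shape"]):
        Ct = Ct[None]
    out = model.forward(Xn, Ct, train=False)[:, 0]
    dose = (out / TANH_HEADROOM + 1.0) / 2.0 * model.meta["dose_max"]
    dose = np.clip(dose, 0.0, None)
    if mask_air and ct is not None:
        dose = dose * (np.asarray(ct, dtype=float).reshape(dose.shape) > 0.1)
    return dose
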