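"""Three-stage patch network converting normalized MRI to pseudo-CT.

The converter is an image regression network operating on 32x32 MRI patches:
three convolutional stages with no padding anywhere (valid convolution), so
the spatial extent shrinks by (kernel - 1) per stage and the default kernels
(7, 5, 5) take 32x32 down to exactly 18x18.  Hidden stages use a rectifier;
the output stage is linear and single-channel (HU).  Deep supervision
attaches a 1x1 auxiliary regression head after each hidden stage; each head's
center-cropped MSE joins the total loss with a small weight, which keeps
intermediate features predictive and speeds convergence on small datasets.

Training is plain stochastic gradient descent with momentum (mini-batch 128,
learning rate 0.01, momentum 0.9) minimizing mean squared error.  Inputs and
labels are affinely standardized from training statistics; predictions are
mapped back to raw HU.  The implementation is pure NumPy — convolutions are
im2col matrix products — which is fully adequate at this network size and
keeps training deterministic for a fixed seed on a fixed platform.

Whole-volume inference reflect-pads each axial slice by 7 px, tiles 32x32
windows at a configurable stride, and averages overlapping 18x18 outputs, so
the pseudo-CT grid matches the input grid.

A transparent monotone-lookup baseline (piecewise-linear interpolation
through the extracted intensity pairs) ships alongside the network: the
pairs define a pointwise MRI->HU map, and the lookup makes that map
inspectable and cheap to evaluate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .pairs import PATCH_IN, PATCH_OUT, IntensityPairSet, PairedPatchSet
from .volume import Modality, Volume


@dataclass
class ModelSpec:
    kernel_sizes: tuple[int, int, int] = (7, 5, 5)
    channels: tuple[int, int, int] = (32, 32, 1)
    dsn_weights: tuple[float, float] = (0.3, 0.3)
    #: weights start at this fraction of the He scale; small-gain init keeps
    #: the first SGD steps inside the stable region at the fixed lr/momentum
    #: for every initialization seed
    init_gain: float = 0.3
    #: slope of the hidden rectifier for negative inputs (0 = standard ReLU)
    leak: float = 0.0
    input_size: int = PATCH_IN
    output_size: int = PATCH_OUT

    def __post_init__(self) -> None:
        self.kernel_sizes = tuple(int(k) for k in self.kernel_sizes)
        self.channels = tuple(int(c) for c in self.channels)
        if len(self.kernel_sizes) != 3 or len(self.channels) != 3:
            raise ValueError("exactly three stages")
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernels must be odd")
        reduction = sum(k - 1 for k in self.kernel_sizes)
        if reduction != self.input_size - self.output_size:
            raise ValueError(
                f"kernel sizes {self.kernel_sizes} reduce a {self.input_size} "
                f"input by {reduction}, not {self.input_size - self.output_size}")
        if self.channels[-1] != 1:
            raise ValueError("final stage must have one output channel")
        if any(w < 0 for w in self.dsn_weights):
            raise ValueError("dsn weights must be non-negative")


@dataclass
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 50
    patience: int = 10          # early stop on validation loss; 0 disables
    #: global gradient-norm ceiling (standardized units); keeps the first
    #: momentum steps from overshooting along the top curvature direction,
    #: which otherwise diverges or kills rectifier units on some seeds.
    #: 0 disables clipping.
    clip_norm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs + 1, self.learning_rate,
               self.momentum + 1) <= 0:
            raise ValueError("hyperparameters must be positive (epochs >= 0)")


# ---------------------------------------------------------------------------
# Convolution primitives.  Activations live in channels-last (N, H, W, C)
# layout; a valid convolution is one im2col reshape plus one BLAS matrix
# product, and the backward pass reuses the cached column matrix, which is
# what makes CPU training cheap at this patch size.


_SCRATCH: dict[tuple, np.ndarray] = {}


def _scratch(key: str, shape: tuple, dtype=np.float32) -> np.ndarray:
    """Reusable work buffer; avoids re-faulting large pages every batch."""
    buf = _SCRATCH.get((key, shape))
    if buf is None:
        buf = np.empty(shape, dtype=dtype)
        _SCRATCH[(key, shape)] = buf
    return buf


def _im2col(x: np.ndarray, k: int, key: str = "im2col") -> np.ndarray:
    """(N,H,W,C) -> (N*oh*ow, k*k*C) sliding-window column matrix.

    Built by k*k slab assignments (flat order (k, k, C) matching the weight
    layout), which beats one big transposed gather.
    """
    n, h, w, c = x.shape
    oh, ow = h - k + 1, w - k + 1
    cols = _scratch(key, (n, oh, ow, k, k, c), x.dtype)
    for di in range(k):
        for dj in range(k):
            cols[:, :, :, di, dj, :] = x[:, di:di + oh, dj:dj + ow, :]
    return cols.reshape(n * oh * ow, k * k * c)


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray,
                  return_cols: bool = False, key: str = "im2col"):
    """Valid convolution. x (N,H,W,C), w (k,k,C,O) -> (N,oh,ow,O)."""
    n, h, wd, c = x.shape
    k, _, _, o = w.shape
    oh, ow = h - k + 1, wd - k + 1
    cols = _im2col(x, k, key=key)
    out = (cols @ w.reshape(-1, o) + b).reshape(n, oh, ow, o)
    return (out, cols) if return_cols else out


def _conv_backward(dout: np.ndarray, cols: np.ndarray, x_shape, w: np.ndarray,
                   need_dx: bool = True):
    """Gradients of valid convolution from cached columns. -> (dx, dw, db)."""
    n, h, wd, c = x_shape
    k, _, _, o = w.shape
    oh, ow = h - k + 1, wd - k + 1
    dflat = dout.reshape(-1, o)
    dw = (cols.T @ dflat).reshape(w.shape)
    db = dflat.sum(axis=0)
    if not need_dx:
        return None, dw, db
    dcols = _scratch("dcols", (n * oh * ow, k * k * c))
    np.matmul(dflat, w.reshape(-1, o).T, out=dcols)
    dcols = dcols.reshape(n, oh, ow, k, k, c)
    dx = np.zeros(x_shape, dtype=np.float32)
    for di in range(k):
        for dj in range(k):
            dx[:, di:di + oh, dj:dj + ow, :] += dcols[:, :, :, di, dj, :]
    return dx, dw, db


def _center_crop(x: np.ndarray, size: int) -> np.ndarray:
    """Crop the spatial axes (1, 2 for NHWC; trailing two for (N, H, W))."""
    if x.ndim == 4:
        off = (x.shape[1] - size) // 2
        return x[:, off:off + size, off:off + size, :]
    off = (x.shape[-1] - size) // 2
    return x[..., off:off + size, off:off + size]


@dataclass
class TrainedModel:
    """Network weights plus the affine input/label scalings fit at training."""

    spec: ModelSpec
    params: dict[str, np.ndarray]
    input_mean: float = 0.0
    input_sd: float = 1.0
    label_mean: float = 0.0
    label_sd: float = 1.0
    trained: bool = False
    loss_history: list[dict] = field(default_factory=list)

    # -- construction -------------------------------------------------------

    @classmethod
    def build(cls, spec: ModelSpec | None = None, seed: int = 0) -> "TrainedModel":
        """Seeded He-normal initialization of all stages and DSN heads."""
        spec = spec or ModelSpec()
        rng = np.random.default_rng(seed)
        params: dict[str, np.ndarray] = {}
        in_ch = 1
        for i, (k, out_ch) in enumerate(zip(spec.kernel_sizes, spec.channels)):
            fan_in = in_ch * k * k
            params[f"w{i}"] = rng.normal(
                0.0, spec.init_gain * np.sqrt(2.0 / fan_in),
                (k, k, in_ch, out_ch)).astype(np.float32)
            params[f"b{i}"] = np.zeros(out_ch, dtype=np.float32)
            in_ch = out_ch
        for i, ch in enumerate(spec.channels[:2]):
            params[f"aux_w{i}"] = rng.normal(
                0.0, spec.init_gain * np.sqrt(2.0 / ch), (ch,)).astype(np.float32)
            params[f"aux_b{i}"] = np.zeros(1, dtype=np.float32)
        model = cls(spec=spec, params=params)
        # sanity: receptive-field arithmetic
        probe = np.zeros((1, spec.input_size, spec.input_size, 1), np.float32)
        out = model._forward(probe)
        assert out.shape[-2:] == (spec.output_size, spec.output_size)
        return model

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray) -> np.ndarray:
        """Backbone forward pass on standardized input x (N,32,32,1)."""
        act = x
        for i in range(3):
            act = _conv_forward(act, self.params[f"w{i}"], self.params[f"b{i}"])
            if i < 2:
                np.multiply(act, np.where(act > 0, 1.0, self.spec.leak).astype(
                    np.float32), out=act)
        return act[..., 0]   # (N, 18, 18)

    def _aux_predict(self, hidden: np.ndarray, i: int) -> np.ndarray:
        pred = hidden @ self.params[f"aux_w{i}"] + self.params[f"aux_b{i}"][0]
        return _center_crop(pred, self.spec.output_size)

    # -- training -----------------------------------------------------------

    def _loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Total (main + weighted auxiliary) MSE and parameter gradients."""
        spec = self.spec
        acts = [x]
        colss = []
        masks = [None, None]
        act = x
        for i in range(3):
            act, cols = _conv_forward(act, self.params[f"w{i}"],
                                      self.params[f"b{i}"], return_cols=True,
                                      key=f"cols{i}")
            colss.append(cols)
            if i < 2:
                masks[i] = np.where(act > 0, 1.0, self.spec.leak).astype(np.float32)
                act = act * masks[i]
            acts.append(act)

        main = acts[-1][..., 0]
        diff = main - y
        loss = float((diff**2).mean())
        grads: dict[str, np.ndarray] = {}
        d_act = ((2.0 / diff.size) * diff)[..., None].astype(np.float32)

        d_hidden_extra = [None, None]
        for i, wgt in enumerate(spec.dsn_weights):
            hidden = acts[i + 1]
            adiff = self._aux_predict(hidden, i) - y
            loss += wgt * float((adiff**2).mean())
            if wgt == 0:
                grads[f"aux_w{i}"] = np.zeros_like(self.params[f"aux_w{i}"])
                grads[f"aux_b{i}"] = np.zeros_like(self.params[f"aux_b{i}"])
                continue
            dpred = (wgt * (2.0 / adiff.size) * adiff).astype(np.float32)
            off = (hidden.shape[1] - spec.output_size) // 2
            dh = np.zeros_like(hidden)
            dh[:, off:off + spec.output_size, off:off + spec.output_size, :] = (
                dpred[..., None] * self.params[f"aux_w{i}"])
            d_hidden_extra[i] = dh
            cropped = _center_crop(hidden, spec.output_size)
            grads[f"aux_w{i}"] = np.tensordot(
                dpred, cropped, axes=([0, 1, 2], [0, 1, 2])).astype(np.float32)
            grads[f"aux_b{i}"] = np.array([dpred.sum()], dtype=np.float32)

        for i in range(2, -1, -1):
            if i < 2:
                d_act = d_act * masks[i]
                if d_hidden_extra[i] is not None:
                    # aux-head gradient enters after the rectifier
                    d_act = d_act + d_hidden_extra[i] * masks[i]
            dx, dw, db = _conv_backward(d_act.astype(np.float32), colss[i],
                                        acts[i].shape, self.params[f"w{i}"],
                                        need_dx=i > 0)
            grads[f"w{i}"] = dw
            grads[f"b{i}"] = db
            d_act = dx
        return loss, grads

    def _standardize_in(self, x: np.ndarray) -> np.ndarray:
        return ((x - self.input_mean) / self.input_sd).astype(np.float32)

    def train(self, train: PairedPatchSet, val: PairedPatchSet | None,
              cfg: TrainConfig | None = None) -> "TrainedModel":
        """SGD with momentum on the DSN-weighted MSE; records loss history.

        Loss history entries hold per-epoch mean training loss and
        validation RMSE, both on the raw HU scale.
        """
        cfg = cfg or TrainConfig()
        if train is None or len(train) == 0:
            raise ValueError("empty training set")
        self.input_mean = float(train.inputs.mean())
        self.input_sd = float(train.inputs.std()) or 1.0
        self.label_mean = float(train.labels.mean())
        self.label_sd = float(train.labels.std()) or 1.0

        x = self._standardize_in(train.inputs)[..., None]
        y = ((train.labels - self.label_mean) / self.label_sd).astype(np.float32)

        rng = np.random.default_rng(cfg.seed)
        velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
        best_val = np.inf
        best_params = None
        stall = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(x))
            batch_losses = []
            for start in range(0, len(x), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                loss, grads = self._loss_and_grads(x[idx], y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}")
                batch_losses.append(loss)
                if cfg.clip_norm:
                    gnorm = np.sqrt(sum(float((g**2).sum())
                                        for g in grads.values()))
                    if gnorm > cfg.clip_norm:
                        scale = cfg.clip_norm / gnorm
                        for g in grads.values():
                            g *= scale
                for k in self.params:
                    velocity[k] = (cfg.momentum * velocity[k]
                                   - cfg.learning_rate * grads[k])
                    self.params[k] += velocity[k]
            entry = {"epoch": epoch,
                     "train_loss_hu2": float(np.mean(batch_losses)) * self.label_sd**2}
            if val is not None and len(val):
                entry["val_rmse_hu"] = self.validation_rmse(val)
            self.loss_history.append(entry)
            if cfg.patience and "val_rmse_hu" in entry:
                if entry["val_rmse_hu"] < best_val - 1e-9:
                    best_val = entry["val_rmse_hu"]
                    best_params = {k: v.copy() for k, v in self.params.items()}
                    stall = 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        break
        if best_params is not None:
            self.params = best_params
        self.trained = self.trained or cfg.epochs > 0
        return self

    def predict_patches(self, inputs: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Raw-HU predictions for (N, 32, 32) input patches."""
        x = self._standardize_in(np.asarray(inputs))[..., None]
        outs = []
        for start in range(0, len(x), chunk):
            outs.append(self._forward(x[start:start + chunk]))
        pred = np.concatenate(outs) if outs else np.empty((0, 18, 18))
        return pred * self.label_sd + self.label_mean

    def validation_rmse(self, patches: PairedPatchSet) -> float:
        pred = self.predict_patches(patches.inputs)
        return float(np.sqrt(np.mean((pred - patches.labels) ** 2)))

    # -- persistence --------------------------------------------------------

    def save(self, model_dir: str | Path) -> None:
        """Model directory: JSON spec/scalings + NPZ weight blob."""
        d = Path(model_dir)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "spec": {"kernel_sizes": list(self.spec.kernel_sizes),
                     "channels": list(self.spec.channels),
                     "dsn_weights": list(self.spec.dsn_weights),
                     "init_gain": self.spec.init_gain,
                     "leak": self.spec.leak},
            "input_mean": self.input_mean, "input_sd": self.input_sd,
            "label_mean": self.label_mean, "label_sd": self.label_sd,
            "trained": self.trained,
            "loss_history": self.loss_history,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))
        np.savez(d / "weights.npz", **self.params)

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedModel":
        d = Path(model_dir)
        meta = json.loads((d / "model.json").read_text())
        spec = ModelSpec(kernel_sizes=tuple(meta["spec"]["kernel_sizes"]),
                         channels=tuple(meta["spec"]["channels"]),
                         dsn_weights=tuple(meta["spec"]["dsn_weights"]),
                         init_gain=meta["spec"].get("init_gain", 0.3),
                         leak=meta["spec"].get("leak", 0.0))
        with np.load(d / "weights.npz") as z:
            params = {k: z[k].copy() for k in z.files}
        return cls(spec=spec, params=params,
                   input_mean=meta["input_mean"], input_sd=meta["input_sd"],
                   label_mean=meta["label_mean"], label_sd=meta["label_sd"],
                   trained=meta["trained"], loss_history=meta["loss_history"])


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> TrainedModel:
    return TrainedModel.build(spec, seed)


def train_model(model: TrainedModel, train: PairedPatchSet,
                val: PairedPatchSet | None = None,
                cfg: TrainConfig | None = None) -> TrainedModel:
    return model.train(train, val, cfg)


def predict_volume(model: TrainedModel, mri_corrected: Volume,
                   stride: int = PATCH_OUT) -> Volume:
    """Sliding-window pseudo-CT synthesis; output grid matches input grid.

    Each axial slice is reflect-padded by 7 px so 18x18 output tiles cover
    the full slice; overlapping tiles (stride < 18) are averaged.
    """
    if not model.trained:
        raise ValueError("model has not been trained")
    if not 1 <= stride <= PATCH_OUT:
        raise ValueError("stride must be in 1..18")
    pad = (PATCH_IN - PATCH_OUT) // 2
    out = np.zeros(mri_corrected.shape)
    for s in range(mri_corrected.n_slices):
        img = mri_corrected.data[s]
        h, w = img.shape
        padded = np.pad(img, pad, mode="reflect")
        rows = sorted({*range(0, h - PATCH_OUT + 1, stride), h - PATCH_OUT})
        cols = sorted({*range(0, w - PATCH_OUT + 1, stride), w - PATCH_OUT})
        windows = [padded[r:r + PATCH_IN, c:c + PATCH_IN]
                   for r in rows for c in cols]
        preds = model.predict_patches(np.stack(windows))
        acc = np.zeros((h, w))
        cnt = np.zeros((h, w))
        i = 0
        for r in rows:
            for c in cols:
                acc[r:r + PATCH_OUT, c:c + PATCH_OUT] += preds[i]
                cnt[r:r + PATCH_OUT, c:c + PATCH_OUT] += 1
                i += 1
        out[s] = acc / cnt
    return Volume(out, spacing=mri_corrected.spacing,
                  modality=Modality.PSEUDO_CT, units="HU")


def compose_bone(pseudo_ct: Volume, real_ct_registered: Volume,
                 bone_mask: np.ndarray) -> Volume:
    """Paste registered real-CT values inside a bone mask into the pseudo-CT.

    Bone is outside the scope of the intensity conversion; clinical practice
    fills it from the registered planning CT (or an atlas), and this utility
    performs that compositing step.
    """
    if pseudo_ct.shape != real_ct_registered.shape:
        raise ValueError("grids must match")
    mask = np.asarray(bone_mask, dtype=bool)
    if mask.shape != pseudo_ct.shape:
        raise ValueError("mask shape must match the volumes")
    data = np.where(mask, real_ct_registered.data, pseudo_ct.data)
    return pseudo_ct.copy_with(data, modality=Modality.PSEUDO_CT, units="HU")


class LookupConverter:
    """Monotone piecewise-linear MRI->HU map through the intensity pairs.

    Duplicate MRI intensities are averaged; the map is held flat beyond the
    extracted intensity range.  A transparent baseline against which the
    network can be checked.
    """

    def __init__(self, pairs: IntensityPairSet):
        df = pairs.pairs.groupby("mri_au", as_index=False).ct_hu.mean()
        df = df.sort_values("mri_au")
        if df.empty:
            raise ValueError("no pairs")
        self.x = df.mri_au.to_numpy()
        self.y = df.ct_hu.to_numpy()

    def __call__(self, values: np.ndarray) -> np.ndarray:
        return np.interp(values, self.x, self.y)

    def predict_volume(self, mri_corrected: Volume) -> Volume:
        return Volume(self(mri_corrected.data), spacing=mri_corrected.spacing,
                      modality=Modality.PSEUDO_CT, units="HU")
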