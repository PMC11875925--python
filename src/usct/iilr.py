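"""Image-to-image learned reconstruction (IILR) of high-resolution SOS maps.

A dual-channel U-Net maps (water-offset low-resolution SOS from traveltime
tomography, max-abs-normalized reflectivity from DAS) to the water-offset
high-resolution SOS map; adding the known water SOS back yields the estimate.
Subtracting the per-sample water-bath SOS from input and target removes the
nuisance variability of the bath temperature from the learning problem.

Architecture: a contracting path of ``n_blocks`` blocks (two 3×3 convolutions
then 2×2 average pooling; output channels double per block from
``base_channels``), a mirrored expanding path (2×2 stride-2 transposed
convolution, skip concatenation with the matching contracting level, two 3×3
convolutions), batch normalization before every convolution, leaky ReLU
(slope 0.2) everywhere except the linear 1×1 output convolution.  With six
blocks and base 32 (2-channel input) this totals ≈31.1 million trainable
parameters.

Training minimizes the mean-squared error L(θ) = (1/2I)·Σᵢ‖𝒜_θ(xᵢ) − yᵢ‖²_F
with Adam under a triangular cyclic learning rate, on-the-fly augmentation by
right-angle rotations and flips, and best-model selection on validation loss.
Tumor-weighted fine-tuning continues from the MSE optimum with the weighted
loss (1/2I)·Σᵢ‖W ⊙ (𝒜_θ(xᵢ) − yᵢ)‖²_F, where W is 0 in water, w > 1 inside
tumor regions of interest and 1 elsewhere.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .nn import (Adam, AvgPool2d, BatchNorm2d, Conv2d, ConvTranspose2d, LeakyReLU,
                 cyclic_lr, param_count)

__all__ = ["NetworkConfig", "TrainConfig", "TrainState", "UNet", "build_unet",
           "water_offset", "loss_mse", "loss_wmse", "make_weight_mask",
           "prepare_inputs", "train_model", "finetune_model", "reconstruct_sos"]


@dataclass
class NetworkConfig:
    n_blocks: int = 6
    base_channels: int = 32
    in_channels: int = 2
    leaky_slope: float = 0.2
    use_batchnorm: bool = True
    seed: int = 0


class UNet:
    """U-Net with average-pool downsampling and transposed-conv upsampling.

    Skip connections concatenate the post-pool contracting features of each
    level with the matching expanding features; the shallowest expanding block
    has no skip (it upsamples back to the input resolution) and a final 1×1
    convolution produces the single output channel.
    """

    def __init__(self, cfg: NetworkConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        B, C0 = cfg.n_blocks, cfg.base_channels
        bn = cfg.use_batchnorm
        sl = cfg.leaky_slope

        def conv_unit(cin, cout, k=3):
            layers = []
            if bn:
                layers.append(BatchNorm2d(cin))
            layers.append(Conv2d(cin, cout, k, rng))
            return layers

        self.enc_blocks = []
        self.pools = []
        cin = cfg.in_channels
        for i in range(B):
            cout = C0 * 2 ** i
            blk = conv_unit(cin, cout) + [LeakyReLU(sl)] + conv_unit(cout, cout) + [LeakyReLU(sl)]
            self.enc_blocks.append(blk)
            self.pools.append(AvgPool2d())
            cin = cout
        self.tconvs = []
        self.dec_blocks = []
        c = C0 * 2 ** (B - 1)
        for j in range(B):
            has_skip = j <= B - 2
            c_up = c // 2 if has_skip else c
            self.tconvs.append(ConvTranspose2d(c, c_up, rng))
            c_cat = 2 * c_up if has_skip else c_up
            c_out = c_cat // 2 if has_skip else c_cat
            blk = (conv_unit(c_cat, c_out) + [LeakyReLU(sl)]
                   + conv_unit(c_out, c_out) + [LeakyReLU(sl)])
            self.dec_blocks.append(blk)
            c = c_out
        self.head = conv_unit(c, 1, k=1)  # linear output: no activation

    def layers(self):
        for blk in self.enc_blocks + self.dec_blocks + [self.head]:
            yield from blk
        yield from self.tconvs

    def parameters(self):
        params, grads = [], []
        for lay in self.layers():
            params.extend(lay.params)
            grads.extend(lay.grads)
        return params, grads

    def n_parameters(self) -> int:
        return param_count(self.layers())

    def get_state(self):
        return [p.copy() for p in self.parameters()[0]] + \
            [lay.running_mean.copy() for lay in self.layers() if isinstance(lay, BatchNorm2d)] + \
            [lay.running_var.copy() for lay in self.layers() if isinstance(lay, BatchNorm2d)]

    def set_state(self, state):
        params = self.parameters()[0]
        n = len(params)
        for p, s in zip(params, state[:n]):
            p[...] = s
        bns = [lay for lay in self.layers() if isinstance(lay, BatchNorm2d)]
        for bnl, s in zip(bns, state[n:n + len(bns)]):
            bnl.running_mean[...] = s
        for bnl, s in zip(bns, state[n + len(bns):]):
            bnl.running_var[...] = s

    def forward(self, x, train=True):
        B = self.cfg.n_blocks
        if x.shape[2] % 2 ** B or x.shape[3] % 2 ** B:
            raise ValueError(f"spatial size {x.shape[2:]} not divisible by 2^{B}")
        h = x
        skips = []
        for i in range(B):
            for lay in self.enc_blocks[i]:
                h = lay.forward(h, train)
            h = self.pools[i].forward(h, train)
            if i < B - 1:
                skips.append(h)
        self._split = []
        for j in range(B):
            h = self.tconvs[j].forward(h, train)
            if j <= B - 2:
                skip = skips[B - 2 - j]
                self._split.append(h.shape[1])
                h = np.concatenate([h, skip], axis=1)
            for lay in self.dec_blocks[j]:
                h = lay.forward(h, train)
        for lay in self.head:
            h = lay.forward(h, train)
        return h

    def backward(self, dout):
        B = self.cfg.n_blocks
        d = dout
        for lay in reversed(self.head):
            d = lay.backward(d)
        skip_grads = [None] * (B - 1)
        for j in range(B - 1, -1, -1):
            for lay in reversed(self.dec_blocks[j]):
                d = lay.backward(d)
            if j <= B - 2:
                c_up = self._split[j]
                skip_grads[B - 2 - j] = d[:, c_up:]
                d = d[:, :c_up]
            d = self.tconvs[j].backward(d)
        for i in range(B - 1, -1, -1):
            if i < B - 1:
                d = d + skip_grads[i]
            d = self.pools[i].backward(d)
            for lay in reversed(self.enc_blocks[i]):
                d = lay.backward(d)
        return d


def build_unet(cfg: NetworkConfig):
    """Instantiate the network; returns (model, trainable parameter count)."""
    model = UNet(cfg)
    return model, model.n_parameters()


# ------------------------------------------------------------------ data plumbing

def water_offset(img: np.ndarray, water_sos: float, direction: str = "subtract") -> np.ndarray:
    """Add or subtract the constant water-bath SOS; subtract∘add is identity."""
    if direction == "subtract":
        return img - water_sos
    if direction == "add":
        return img + water_sos
    raise ValueError("direction must be 'subtract' or 'add'")


def prepare_inputs(c_low: np.ndarray, refl: np.ndarray, water_sos: float,
                   channels: str = "rt") -> np.ndarray:
    """Stack the network input channels: water-offset low-res SOS ('t') and/or
    max-abs-normalized reflectivity ('r'), in (T, R) order for 'rt'."""
    chans = []
    if "t" in channels:
        chans.append(water_offset(c_low, water_sos))
    if "r" in channels:
        m = np.max(np.abs(refl))
        chans.append(refl / m if m > 0 else refl)
    if not chans:
        raise ValueError(f"no channels selected by {channels!r}")
    return np.stack(chans).astype(np.float32)


def loss_mse(pred: np.ndarray, target: np.ndarray) -> float:
    """(1/2I)·Σᵢ‖predᵢ − targetᵢ‖²_F over the leading (batch) axis."""
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    I = pred.shape[0]
    r = (np.asarray(pred, np.float64) - target).reshape(I, -1)
    return float(0.5 / I * np.sum(r * r))


def loss_wmse(pred: np.ndarray, target: np.ndarray, W: np.ndarray) -> float:
    """(1/2I)·Σᵢ‖W ⊙ (predᵢ − targetᵢ)‖²_F; W broadcast over the batch."""
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    I = pred.shape[0]
    r = (np.asarray(pred, np.float64) - target) * W
    return float(0.5 / I * np.sum(r * r))


def make_weight_mask(labels: np.ndarray, tumor_rois, w: float) -> np.ndarray:
    """Loss weight map: 0 in the water bath, ``w`` inside tumor ROIs, 1 elsewhere."""
    if w <= 1:
        raise ValueError("tumor weight w must be > 1")
    W = np.ones(labels.shape, np.float32)
    W[labels == 0] = 0.0
    if tumor_rois is not None:
        if isinstance(tumor_rois, np.ndarray):
            tumor_rois = [tumor_rois]
        for m in tumor_rois:
            W[m & (labels != 0)] = w
    return W


# ------------------------------------------------------------------ training

@dataclass
class TrainConfig:
    channels: str = "rt"              # 'rt', 'r' or 't'
    epochs: int = 100
    batch_size: int = 8
    lr_max: float = 1e-2
    lr_min: float = 1e-5
    lr_period: int = 2000             # iterations per cyclic-LR period
    augment_ratio: int = 3            # augmented : non-augmented presentations
    seed: int = 0
    loss: str = "mse"                 # 'mse' or 'wmse'
    tumor_weight: float = 5.0         # w of the WMSE loss (ignored for 'mse')


@dataclass
class TrainState:
    model: UNet
    cfg: TrainConfig
    best_state: list
    best_val: float
    best_epoch: int
    iteration: int = 0
    history: dict = field(default_factory=dict)

    def use_best(self):
        self.model.set_state(self.best_state)


def _augment(arrs, rng, ratio):
    """Apply one shared random right-angle rotation/flip to [C?,H,W] arrays.

    With augmentation ratio r, a sample is transformed with probability
    r/(1+r) (identity otherwise), so presentations are non-augmented :
    augmented ≈ 1 : r in expectation.
    """
    if rng.random() >= ratio / (1.0 + ratio):
        return arrs
    k = int(rng.integers(4))
    fx = bool(rng.integers(2))
    fy = bool(rng.integers(2))
    out = []
    for a in arrs:
        b = np.rot90(a, k, axes=(-2, -1))
        if fx:
            b = np.flip(b, axis=-1)
        if fy:
            b = np.flip(b, axis=-2)
        out.append(np.ascontiguousarray(b))
    return out


def _select_channels(X, channels):
    # X stacked as (T, R); single-channel ablations slice accordingly
    if channels == "rt":
        return X
    if channels == "t":
        return X[:, :1]
    if channels == "r":
        return X[:, 1:2]
    raise ValueError(f"unknown channel selection {channels!r}")


def _eval_loss(model, X, Y, Wm, cfg, batch=8):
    tot, n = 0.0, X.shape[0]
    for s in range(0, n, batch):
        pred = model.forward(X[s:s + batch], train=False)
        if cfg.loss == "wmse":
            tot += loss_wmse(pred, Y[s:s + batch], Wm[s:s + batch]) * pred.shape[0]
        else:
            tot += loss_mse(pred, Y[s:s + batch]) * pred.shape[0]
    return tot / n


def train_model(X, Y, train_idx, val_idx, cfg: TrainConfig,
                weight_masks: np.ndarray | None = None,
                model: UNet | None = None, net_cfg: NetworkConfig | None = None) -> TrainState:
    """Train (or continue training) the U-Net on stacked inputs X [N,C,H,W]
    and water-offset targets Y [N,1,H,W].

    Adam with a triangular cyclic learning rate, seeded shuffling and
    augmentation (shared transform across channels, target and weight mask),
    best-checkpoint selection by validation loss (computed without
    augmentation).  Raises on empty splits or divergent (non-finite) loss.
    """
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("empty train or validation split")
    X = _select_channels(np.asarray(X, np.float32), cfg.channels)
    Y = np.asarray(Y, np.float32)
    if cfg.loss == "wmse":
        if weight_masks is None:
            raise ValueError("WMSE training requires weight masks (tumor ROIs)")
        Wm = np.asarray(weight_masks, np.float32)
        if Wm.ndim == 3:
            Wm = Wm[:, None]
    else:
        Wm = np.ones_like(Y)
    if model is None:
        net_cfg = net_cfg or NetworkConfig(in_channels=X.shape[1], seed=cfg.seed)
        model = UNet(net_cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    params, grads = model.parameters()
    opt = Adam(params, grads)
    Xtr, Ytr, Wtr = X[train_idx], Y[train_idx], Wm[train_idx]
    state = TrainState(model=model, cfg=cfg, best_state=model.get_state(),
                       best_val=np.inf, best_epoch=-1,
                       history={"train": [], "val": []})
    n_tr = len(train_idx)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n_tr)
        ep_loss = 0.0
        for s in range(0, n_tr, cfg.batch_size):
            sel = order[s:s + cfg.batch_size]
            xb, yb, wb = [], [], []
            for i in sel:
                x, y, w_ = _augment([Xtr[i], Ytr[i], Wtr[i]], rng, cfg.augment_ratio)
                xb.append(x)
                yb.append(y)
                wb.append(w_)
            xb = np.stack(xb)
            yb = np.stack(yb)
            wb = np.stack(wb)
            pred = model.forward(xb, train=True)
            I = pred.shape[0]
            resid = (pred - yb) * wb
            loss = float(0.5 / I * np.sum(resid.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"divergent loss at epoch {epoch}: {loss} "
                    f"(iteration {state.iteration}, lr schedule position "
                    f"{state.iteration % cfg.lr_period})")
            dpred = (resid * wb / I).astype(np.float32)
            model.backward(dpred)
            lr = cyclic_lr(state.iteration, cfg.lr_max, cfg.lr_min, cfg.lr_period)
            opt.step(lr)
            state.iteration += 1
            ep_loss += loss * I
        state.history["train"].append(ep_loss / n_tr)
        val = _eval_loss(model, X[val_idx], Y[val_idx], Wm[val_idx], cfg)
        state.history["val"].append(val)
        if val < state.best_val:
            state.best_val = val
            state.best_epoch = epoch
            state.best_state = model.get_state()
    return state


def finetune_model(state: TrainState, w: float, labels: np.ndarray, tumor_roi_masks,
                   train_idx, val_idx, epochs: int = 50, lr_max: float = 1e-3,
                   X=None, Y=None) -> TrainState:
    """Tumor-weighted fine-tuning from an MSE-trained checkpoint.

    Continues from the best pre-trained parameters, optimizing the WMSE loss
    with weight masks built from the tumor ROIs; selection by lowest
    validation WMSE.  ``w=1 + ε`` reduces to continued (water-masked) MSE.
    """
    masks = np.stack([make_weight_mask(labels[i], tumor_roi_masks[i], w)
                      for i in range(labels.shape[0])])
    cfg = dataclasses.replace(state.cfg, loss="wmse", tumor_weight=w,
                              epochs=epochs, lr_max=lr_max)
    model = copy.deepcopy(state.model)
    model.set_state(state.best_state)
    return train_model(X, Y, train_idx, val_idx, cfg, weight_masks=masks, model=model)


def reconstruct_sos(state: TrainState, c_low: np.ndarray, refl: np.ndarray,
                    water_sos: float) -> np.ndarray:
    """High-resolution SOS estimate: network output plus the water constant.

    Inputs are preprocessed exactly as in training (water offset, max-abs
    reflectivity scaling, channel selection); inference is deterministic
    (batch-norm running statistics, no augmentation).
    """
    x = prepare_inputs(c_low, refl, water_sos, "rt")[None]
    x = _select_channels(x, state.cfg.channels)
    out = state.model.forward(x, train=False)[0, 0]
    return water_offset(out.astype(np.float64), water_sos, "add")
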