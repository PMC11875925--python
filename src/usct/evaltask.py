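"""Image-quality evaluation: traditional metrics and a task-based observer study.

Traditional metrics compare a reconstructed SOS map C̄ with the target C:
NRMSE = ‖C − C̄‖_F / ‖C − C_w‖_F (normalized by the object-minus-water norm),
SSIM with the standard defaults, and PSNR after linearly rescaling the
[1.4, 1.6] mm/μs dynamic range to [0, 1].  Ensembles are compared with the
two-sided non-parametric Mann–Whitney U-test.

Task-based assessment uses a patch-based signal-known-stochastically /
background-known-stochastically binary detection task: square patches are
drawn from reconstructions, labeled signal-present (≥1 tumor pixel) or
signal-absent, and scored by a small CNN numerical observer (three blocks of
convolution, batch normalization, leaky ReLU and 2×2 average pooling,
followed by a fully connected layer with sigmoid output).  Performance is
summarized by the empirical ROC curve and its area (AUC) with the
Hanley–McNeil standard error; a two-parameter binormal fit is available as a
secondary estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.metrics import structural_similarity

from .nn import (Adam, AvgPool2d, BatchNorm2d, Conv2d, LeakyReLU, Linear,
                 cyclic_lr, param_count, sigmoid)
from .phantom import TUMOR, LabelMap

__all__ = ["metric_nrmse", "metric_psnr", "metric_ssim", "metric_report",
           "test_mannwhitney", "TumorROI", "tumor_roi_masks", "ObserverPatch",
           "sample_patches", "ObserverConfig", "ObserverNet", "build_observer",
           "train_observer", "ROCResult", "fit_roc_auc"]


# ------------------------------------------------------------------ traditional IQ

def metric_nrmse(pred: np.ndarray, target: np.ndarray, water_sos: float,
                 mask: np.ndarray | None = None) -> float:
    """‖C − C̄‖_F / ‖C − C_w‖_F, optionally restricted to a region mask
    (both numerator and denominator masked)."""
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    if mask is not None:
        pred = pred[mask]
        target = target[mask]
    denom = np.linalg.norm(target - water_sos)
    if denom == 0:
        raise ValueError("target is identically water: NRMSE undefined")
    return float(np.linalg.norm(target - pred) / denom)


def _rescale(img, drange):
    lo, hi = drange
    return (np.asarray(img, np.float64) - lo) / (hi - lo)


def metric_psnr(pred: np.ndarray, target: np.ndarray,
                drange: tuple[float, float] = (1.4, 1.6)) -> float:
    """PSNR (dB) after rescaling the SOS dynamic range to [0, 1] (unit peak).
    Identical images return +inf."""
    if pred.shape != target.shape:
        raise ValueError("shape mismatch")
    mse = float(np.mean((_rescale(pred, drange) - _rescale(target, drange)) ** 2))
    if mse == 0:
        return np.inf
    return float(10.0 * np.log10(1.0 / mse))


def metric_ssim(pred: np.ndarray, target: np.ndarray,
                drange: tuple[float, float] = (1.4, 1.6)) -> float:
    """SSIM with the standard constants (K1=0.01, K2=0.03, 11-pixel Gaussian
    window with σ=1.5) on images rescaled to unit dynamic range."""
    return float(structural_similarity(
        _rescale(target, drange), _rescale(pred, drange), data_range=1.0,
        gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
        K1=0.01, K2=0.03))


def metric_report(preds, targets, water_sos) -> pd.DataFrame:
    """Per-sample NRMSE/SSIM/PSNR table; means and SDs in ``df.attrs['summary']``."""
    ws = np.broadcast_to(np.asarray(water_sos, float), (len(preds),))
    rows = [{"sample": i,
             "nrmse": metric_nrmse(p, t, w),
             "ssim": metric_ssim(p, t),
             "psnr": metric_psnr(p, t)}
            for i, (p, t, w) in enumerate(zip(preds, targets, ws))]
    df = pd.DataFrame(rows)
    df.attrs["summary"] = df[["nrmse", "ssim", "psnr"]].agg(["mean", "std"])
    return df


def test_mannwhitney(a, b) -> float:
    """Two-sided Mann–Whitney U-test p-value (exact for small samples)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    method = "exact" if (a.size <= 8 and b.size <= 8
                         and np.unique(np.concatenate([a, b])).size == a.size + b.size) \
        else "auto"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


# ------------------------------------------------------------------ tumor ROIs

@dataclass
class TumorROI:
    center: tuple[int, int]
    side: int
    mask: np.ndarray           # boolean square ROI
    clipped: bool = False      # ROI ran into the image edge


def tumor_roi_masks(labels: LabelMap):
    """One square ROI per connected tumor component plus the normal-tissue mask.

    The ROI side is the larger of the component's width and height plus a
    4-pixel expansion on each side, centered on the component; ROIs clipped by
    the image edge are flagged.  The normal mask is breast tissue minus all
    tumor ROIs.
    """
    lab = labels.labels
    tumor = lab == TUMOR
    comp, n = ndimage.label(tumor)
    rois = []
    for c in range(1, n + 1):
        m = comp == c
        rr, cc = np.nonzero(m)
        height = rr.max() - rr.min() + 1
        width = cc.max() - cc.min() + 1
        side = int(max(height, width)) + 8
        ci = int(round((rr.min() + rr.max()) / 2.0))
        cj = int(round((cc.min() + cc.max()) / 2.0))
        i0, j0 = ci - side // 2, cj - side // 2
        i1, j1 = i0 + side, j0 + side
        clipped = i0 < 0 or j0 < 0 or i1 > lab.shape[0] or j1 > lab.shape[1]
        sq = np.zeros(lab.shape, bool)
        sq[max(i0, 0):i1, max(j0, 0):j1] = True
        rois.append(TumorROI((ci, cj), side, sq, clipped))
    normal = lab > 0
    for r in rois:
        normal = normal & ~r.mask
    return rois, normal


# ------------------------------------------------------------------ detection task

@dataclass
class ObserverPatch:
    patch: np.ndarray
    label: int                 # 1 signal-present, 0 signal-absent
    corner: tuple[int, int]
    source_id: int = -1


def sample_patches(image: np.ndarray, labels: np.ndarray, n_sp: int, n_sa: int,
                   seed: int, patch_size: int = 96, source_id: int = -1,
                   max_attempts: int = 2000):
    """Randomly extract signal-present / signal-absent patches.

    SP patches are constructed around a randomly chosen tumor pixel (so they
    contain ≥1 tumor pixel by construction, possibly more than one signal);
    SA corners are rejection-sampled until tumor-free.  Seeded and
    reproducible.
    """
    H, W = image.shape
    ps = patch_size
    if H < ps or W < ps:
        raise ValueError(f"image {image.shape} smaller than patch size {ps}")
    rng = np.random.default_rng(seed)
    tumor = labels == TUMOR
    ti, tj = np.nonzero(tumor)
    out = []
    if n_sp > 0 and ti.size == 0:
        raise ValueError("no tumor pixels: signal-present patches unobtainable")
    for _ in range(n_sp):
        k = rng.integers(ti.size)
        i0 = int(np.clip(ti[k] - rng.integers(ps), 0, H - ps))
        j0 = int(np.clip(tj[k] - rng.integers(ps), 0, W - ps))
        # clipping can shift the window off the tumor pixel; nudge back on
        i0 = int(np.clip(i0, ti[k] - ps + 1, ti[k]))
        j0 = int(np.clip(j0, tj[k] - ps + 1, tj[k]))
        i0 = int(np.clip(i0, 0, H - ps))
        j0 = int(np.clip(j0, 0, W - ps))
        out.append(ObserverPatch(image[i0:i0 + ps, j0:j0 + ps].copy(), 1, (i0, j0), source_id))
    csum = np.pad(np.cumsum(np.cumsum(tumor, 0), 1), ((1, 0), (1, 0)))

    def n_tumor(i0, j0):
        return csum[i0 + ps, j0 + ps] - csum[i0, j0 + ps] - csum[i0 + ps, j0] + csum[i0, j0]

    for _ in range(n_sa):
        ok = False
        for _a in range(max_attempts):
            i0 = int(rng.integers(H - ps + 1))
            j0 = int(rng.integers(W - ps + 1))
            if n_tumor(i0, j0) == 0:
                out.append(ObserverPatch(image[i0:i0 + ps, j0:j0 + ps].copy(), 0,
                                         (i0, j0), source_id))
                ok = True
                break
        if not ok:
            raise ValueError("no valid signal-absent patch location exists")
    return out


@dataclass
class ObserverConfig:
    n_blocks: int = 3
    channels: int = 64
    kernel: int = 5
    patch_size: int = 96
    leaky_slope: float = 0.2
    seed: int = 0


class ObserverNet:
    """CNN numerical observer scoring the posterior probability of a signal."""

    def __init__(self, cfg: ObserverConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.layers = []
        cin = 1
        for _ in range(cfg.n_blocks):
            self.layers += [Conv2d(cin, cfg.channels, cfg.kernel, rng),
                            BatchNorm2d(cfg.channels),
                            LeakyReLU(cfg.leaky_slope),
                            AvgPool2d()]
            cin = cfg.channels
        side = cfg.patch_size // 2 ** cfg.n_blocks
        self.fc = Linear(cfg.channels * side * side, 1, rng)

    def parameters(self):
        params, grads = [], []
        for lay in self.layers + [self.fc]:
            params.extend(lay.params)
            grads.extend(lay.grads)
        return params, grads

    def n_parameters(self):
        return param_count(self.layers + [self.fc])

    def get_state(self):
        bns = [l for l in self.layers if isinstance(l, BatchNorm2d)]
        return [p.copy() for p in self.parameters()[0]] + \
            [l.running_mean.copy() for l in bns] + [l.running_var.copy() for l in bns]

    def set_state(self, state):
        params = self.parameters()[0]
        n = len(params)
        for p, s in zip(params, state[:n]):
            p[...] = s
        bns = [l for l in self.layers if isinstance(l, BatchNorm2d)]
        for l, s in zip(bns, state[n:n + len(bns)]):
            l.running_mean[...] = s
        for l, s in zip(bns, state[n + len(bns):]):
            l.running_var[...] = s

    def logits(self, x, train=True):
        h = x
        for lay in self.layers:
            h = lay.forward(h, train)
        self._fc_in_shape = h.shape
        return self.fc.forward(h.reshape(h.shape[0], -1), train)[:, 0]

    def backward(self, dlogit):
        d = self.fc.backward(dlogit[:, None]).reshape(self._fc_in_shape)
        for lay in reversed(self.layers):
            d = lay.backward(d)
        return d

    def predict(self, patches) -> np.ndarray:
        """Posterior probability of signal presence, in (0, 1)."""
        x = np.asarray(patches, np.float32)
        if x.ndim == 3:
            x = x[:, None]
        return sigmoid(self.logits(x, train=False))


def build_observer(cfg: ObserverConfig | None = None):
    cfg = cfg or ObserverConfig()
    net = ObserverNet(cfg)
    return net, net.n_parameters()


def _patch_batch(images, label_maps, ids, rng, cfg, batch):
    xs, ys = [], []
    for _ in range(batch):
        i = int(ids[rng.integers(len(ids))])
        has_tumor = np.any(label_maps[i] == TUMOR)
        want_sp = has_tumor and rng.random() < 0.5
        p = sample_patches(images[i], label_maps[i], int(want_sp), int(not want_sp),
                           seed=int(rng.integers(2 ** 31)), patch_size=cfg.patch_size,
                           source_id=i)[0]
        xs.append(p.patch)
        ys.append(p.label)
    x = np.asarray(xs, np.float32)[:, None]
    return x, np.asarray(ys, np.float64)


def train_observer(images, label_maps, train_ids, val_ids, cfg: ObserverConfig | None = None,
                   net: ObserverNet | None = None, epochs: int = 100, batch: int = 16,
                   batches_per_epoch: int = 4, lr_max: float = 1e-3, lr_min: float = 1e-5,
                   lr_period: int = 400, seed: int = 0) -> ObserverNet:
    """Train (or fine-tune, passing ``net``) the observer with on-the-fly patch
    sampling and binary cross-entropy; best checkpoint by validation loss.

    Raises if the training images can supply only one class of patches.
    """
    cfg = cfg or (net.cfg if net is not None else ObserverConfig())
    if net is None:
        net = ObserverNet(cfg)
    if not any(np.any(label_maps[i] == TUMOR) for i in train_ids):
        raise ValueError("training set has no tumors: single-class detection task")
    rng = np.random.default_rng(seed)
    params, grads = net.parameters()
    opt = Adam(params, grads)
    vrng = np.random.default_rng(seed + 7919)
    xv, yv = _patch_batch(images, label_maps, val_ids, vrng, cfg, batch=4 * batch)
    best, best_state = np.inf, net.get_state()
    it = 0
    for _ep in range(epochs):
        for _b in range(batches_per_epoch):
            x, yb = _patch_batch(images, label_maps, train_ids, rng, cfg, batch)
            z = net.logits(x, train=True)
            p = sigmoid(z)
            loss = -np.mean(yb * np.log(p + 1e-12) + (1 - yb) * np.log(1 - p + 1e-12))
            if not np.isfinite(loss):
                raise FloatingPointError("divergent observer loss")
            net.backward(((p - yb) / len(yb)).astype(np.float32))
            opt.step(cyclic_lr(it, lr_max, lr_min, lr_period))
            it += 1
        pv = sigmoid(net.logits(xv, train=False))
        vloss = -np.mean(yv * np.log(pv + 1e-12) + (1 - yv) * np.log(1 - pv + 1e-12))
        if vloss < best:
            best = vloss
            best_state = net.get_state()
    net.set_state(best_state)
    return net


# ------------------------------------------------------------------ ROC analysis

@dataclass
class ROCResult:
    scores: np.ndarray
    truth: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    auc_se: float
    binormal: dict = field(default_factory=dict)


def fit_roc_auc(scores, truth, binormal: bool = False) -> ROCResult:
    """Empirical ROC curve, trapezoidal AUC and the Hanley–McNeil standard
    error; optionally a two-parameter binormal estimate as secondary output.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, float)
    truth = np.asarray(truth, int)
    n1 = int(truth.sum())
    n0 = int(truth.size - n1)
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(truth, scores)
    auc = float(np.trapezoid(tpr, fpr))
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    se = float(np.sqrt((auc * (1 - auc) + (n1 - 1) * (q1 - auc ** 2)
                        + (n0 - 1) * (q2 - auc ** 2)) / (n0 * n1)))
    res = ROCResult(scores=scores, truth=truth, fpr=fpr, tpr=tpr, auc=auc, auc_se=se)
    if binormal:
        s0, s1 = scores[truth == 0], scores[truth == 1]
        mu0, sd0 = float(s0.mean()), float(s0.std(ddof=1) + 1e-12)
        mu1, sd1 = float(s1.mean()), float(s1.std(ddof=1) + 1e-12)
        a = (mu1 - mu0) / sd1
        b = sd0 / sd1
        res.binormal = {"a": a, "b": b,
                        "auc": float(stats.norm.cdf(a / np.sqrt(1 + b ** 2)))}
    return res
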