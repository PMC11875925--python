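"""Desk-scale virtual imaging studies.

These studies replicate, at a scale that runs on one CPU in minutes, the two
ensemble experiments the testbed is built for:

* Study 1 — input-modality comparison: train the dual-channel network and the
  two single-channel ablations (traveltime-only, reflectivity-only) on the
  same phantom ensemble and compare test NRMSE.
* Study 3 — tumor-weighted fine-tuning: fine-tune the dual-channel model with
  the weighted loss at several tumor weights w and compare tumor-region vs
  normal-region NRMSE.

To make an ensemble of ≥100 phantoms tractable, the study's forward models
are ray-based rather than full-wave: first-arrival TOF data are computed with
the package's bent-ray predictor (eikonal solves + ray tracing on the true
slowness, plus additive Gaussian picking noise), and backscatter echoes are
synthesized with a single-scattering (Born-type) model — impulses at the
two-way water delays of acoustic-impedance-gradient scatterers, convolved
with the source pulse.  Both data streams are then pushed through the *real*
reconstruction chain (proximal Gauss–Newton BRTT; Wiener deconvolution and
modified-Akima DAS beamforming), so the learned models consume inputs with
the same information structure as wave-simulated data: a quantitative but
low-resolution SOS channel and a high-resolution boundary channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import brtt, dasrt, evaltask, iilr, phantom, wavesim
from .gridops import resample_for_network

__all__ = ["DeskStudyConfig", "StudyData", "born_reflection_traces",
           "generate_study_data", "train_variants", "evaluate_variant",
           "finetune_variant", "region_nrmse_table"]


@dataclass
class DeskStudyConfig:
    n_phantoms: int = 130
    split: tuple[int, int, int] = (100, 10, 20)
    # object grid: 64² at 1.25 mm (80 mm extent)
    phantom_cfg: phantom.PhantomConfig = field(default_factory=lambda: phantom.PhantomConfig(
        grid_shape=(64, 64), grid_spacing=1.25,
        breast_radius_frac=(0.55, 0.75), skin_thickness=2.0, gland_scale=7.0,
        tumor_count_probs=(0.10, 0.45, 0.30, 0.15), tumor_axes_mm=(2.5, 5.0),
        texture_corr_length=4.0, texture_rel_amplitude=0.006))
    n_elements: int = 32
    ring_radius: float = 36.0          # mm
    brtt_grid: int = 32
    brtt_spacing: float = 2.5          # mm
    brtt_max_iter: int = 6
    tof_noise_us: float = 0.02         # picking-error standard deviation
    das_grid: int = 64
    das_spacing: float = 1.25          # mm
    net_size: int = 48                 # center crop fed to the network
    dt: float = 0.1                    # μs, Born trace sampling
    pulse_mhz: float = 1.0
    k_side: int = 7                    # near-emitter apodization half-width (15 receivers)
    trace_noise_rel: float = 0.01


@dataclass
class StudyData:
    X: np.ndarray                 # [N, 2, H, W] inputs (water-offset low-res SOS, refl.)
    Y: np.ndarray                 # [N, 1, H, W] water-offset targets
    labels: np.ndarray            # [N, H, W] cropped tissue labels
    water_sos: np.ndarray         # [N]
    tumor_rois: list              # per-sample combined tumor-ROI mask (or None)
    splits: dict                  # {'train','val','test'} index lists
    spacing: float = 1.25


def born_reflection_traces(medium: phantom.AcousticMedium, array: wavesim.RingArray,
                           pulse: wavesim.SourcePulse, apod: np.ndarray, dt: float,
                           T: float, seed: int = 0,
                           noise_rel: float = 0.0) -> wavesim.MeasurementSet:
    """Single-scattering echo synthesis for the desk-scale studies.

    Scatterers are pixels with a significant acoustic-impedance gradient
    (Z = ρ·c); each contributes an impulse at its two-way straight-ray water
    delay with amplitude |∇Z|, and traces are convolved with the source pulse.
    This keeps boundary geometry (the information DAS recovers) while skipping
    the full wave solve.
    """
    z = medium.density * medium.sos
    gy, gx = np.gradient(z, medium.grid_spacing)
    r = np.hypot(gx, gy)
    thr = 0.02 * r.max() if r.max() > 0 else 0.0
    sel = r > thr
    ys, xs = np.nonzero(sel)
    h = medium.grid_spacing
    ny, nx = medium.sos.shape
    px = (xs - (nx - 1) / 2.0) * h
    py = (ys - (ny - 1) / 2.0) * h
    amp = r[sel]
    pos = array.positions()
    L = int(round(T / dt))
    n = array.n_elements
    g = np.zeros((n, n, L), np.float64)
    dist = np.hypot(pos[:, 0][:, None] - px[None, :], pos[:, 1][:, None] - py[None, :])
    c_w = medium.water_sos
    for m in range(n):
        for rec in np.nonzero(apod[m])[0]:
            t = (dist[m] + dist[rec]) / c_w
            idx = np.rint(t / dt).astype(int)
            ok = idx < L
            np.add.at(g[m, rec], idx[ok], amp[ok])
    # band-limit with the pulse
    s = np.zeros(L)
    w = pulse.waveform[:L]
    s[:len(w)] = w
    g = np.fft.irfft(np.fft.rfft(g, axis=-1) * np.fft.rfft(s), n=L, axis=-1)
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        scale = np.sqrt(np.mean(g[apod.astype(bool)] ** 2))
        g = g + rng.normal(0.0, noise_rel * scale, g.shape) * apod[:, :, None]
    return wavesim.MeasurementSet(g=g, dt=dt, T=L * dt, water_sos=c_w, array=array)


def generate_study_data(cfg: DeskStudyConfig, seed: int) -> StudyData:
    """Generate the full study ensemble: phantoms, BRTT and DAS reconstructions,
    network-ready tensors and tumor ROI masks."""
    rng = np.random.default_rng(seed)
    array = wavesim.make_ring_array(cfg.n_elements, cfg.ring_radius)
    pulse = wavesim.make_source_pulse(cfg.pulse_mhz, cfg.dt)
    apod = dasrt.apodization_weights(array, dasrt.ApodizationRule(k_side=cfg.k_side))
    # acquisition long enough for the farthest two-way backscatter path
    T = 2.4 * (cfg.ring_radius + cfg.das_grid * cfg.das_spacing / 2) / 1.4
    box = brtt.DEFAULT_BOX
    n = cfg.n_phantoms
    size = cfg.net_size
    X = np.zeros((n, 2, size, size), np.float32)
    Y = np.zeros((n, 1, size, size), np.float32)
    labels_out = np.zeros((n, size, size), np.int16)
    water = np.zeros(n)
    roi_masks: list = []
    for i in range(n):
        lab, med, _tumors = phantom.make_phantom(int(rng.integers(2 ** 31)), cfg.phantom_cfg)
        water[i] = med.water_sos
        # --- traveltime channel: bent-ray TOF data -> proximal GN inversion
        b_true = brtt.sos_to_slowness(
            resample_for_network(med.sos, med.grid_spacing,
                                 (cfg.brtt_grid, cfg.brtt_grid), cfg.brtt_spacing),
            cfg.brtt_spacing, box)
        tof = brtt.predict_tof(b_true, array)
        tof.t_obs = tof.t_obs + rng.normal(0.0, cfg.tof_noise_us, tof.t_obs.shape) \
            * tof.valid_mask
        b0 = brtt.SlownessImage(np.full(b_true.shape, 1.0 / med.water_sos),
                                cfg.brtt_spacing, box)
        res = brtt.reconstruct_brtt(tof, b0, array, max_iter=cfg.brtt_max_iter)
        c_low = brtt.slowness_to_sos(res.slowness)
        c_low_net = resample_for_network(c_low, cfg.brtt_spacing,
                                         (cfg.das_grid, cfg.das_grid), cfg.das_spacing,
                                         (size, size))
        # --- reflectivity channel: Born echoes -> deconvolution -> DAS
        ms = born_reflection_traces(med, array, pulse, apod, cfg.dt, T,
                                    seed=int(rng.integers(2 ** 31)),
                                    noise_rel=cfg.trace_noise_rel)
        ms = dasrt.deconvolve_source(ms, pulse)
        Tf = dasrt.traveltime_fields(res.slowness, array,
                                     (cfg.das_grid, cfg.das_grid), cfg.das_spacing)
        refl = dasrt.reconstruct_das(ms, Tf, apod, cfg.das_spacing)
        refl_net = resample_for_network(refl.f, cfg.das_spacing,
                                        (cfg.das_grid, cfg.das_grid), cfg.das_spacing,
                                        (size, size))
        # --- target and labels on the network grid
        tgt = resample_for_network(med.sos, med.grid_spacing,
                                   (cfg.das_grid, cfg.das_grid), cfg.das_spacing,
                                   (size, size))
        lab_net = resample_for_network(lab.labels.astype(float), med.grid_spacing,
                                       (cfg.das_grid, cfg.das_grid), cfg.das_spacing,
                                       (size, size)).astype(np.int16)
        X[i] = iilr.prepare_inputs(c_low_net, refl_net, med.water_sos)
        Y[i, 0] = tgt - med.water_sos
        labels_out[i] = lab_net
        rois, _ = evaltask.tumor_roi_masks(phantom.LabelMap(lab_net, cfg.das_spacing))
        roi_masks.append(np.any([r.mask for r in rois], axis=0) if rois else None)
    order = rng.permutation(n)
    a, b = cfg.split[0], cfg.split[0] + cfg.split[1]
    splits = {"train": np.sort(order[:a]).tolist(),
              "val": np.sort(order[a:b]).tolist(),
              "test": np.sort(order[b:]).tolist()}
    return StudyData(X=X, Y=Y, labels=labels_out, water_sos=water,
                     tumor_rois=roi_masks, splits=splits, spacing=cfg.das_spacing)


def train_variants(data: StudyData, channels=("rt", "r", "t"), epochs: int = 60,
                   batch_size: int = 10, seed: int = 0,
                   net_cfg: iilr.NetworkConfig | None = None) -> dict:
    """Train one model per channel configuration on identical splits/seeds."""
    out = {}
    for ch in channels:
        cfg = iilr.TrainConfig(channels=ch, epochs=epochs, batch_size=batch_size,
                               lr_max=1e-2, lr_min=1e-5,
                               lr_period=2 * max(1, len(data.splits["train"]) // batch_size)
                               * max(1, epochs // 4),
                               seed=seed)
        ncfg = net_cfg or iilr.NetworkConfig(n_blocks=3, base_channels=8,
                                             in_channels=len(ch), seed=seed)
        ncfg = iilr.NetworkConfig(**{**ncfg.__dict__, "in_channels": len(ch)})
        state = iilr.train_model(data.X, data.Y, data.splits["train"], data.splits["val"],
                                 cfg, net_cfg=ncfg)
        state.use_best()
        out[ch] = state
    return out


def evaluate_variant(state: iilr.TrainState, data: StudyData, idx=None) -> pd.DataFrame:
    """Per-sample NRMSE/SSIM/PSNR of a trained model on the given indices."""
    idx = data.splits["test"] if idx is None else idx
    preds, targets = [], []
    for i in idx:
        x = iilr._select_channels(data.X[i:i + 1], state.cfg.channels)
        pred = state.model.forward(x, train=False)[0, 0].astype(np.float64) + data.water_sos[i]
        preds.append(pred)
        targets.append(data.Y[i, 0].astype(np.float64) + data.water_sos[i])
    return evaltask.metric_report(preds, targets, data.water_sos[idx])


def finetune_variant(state: iilr.TrainState, data: StudyData, w: float,
                     epochs: int = 25) -> iilr.TrainState:
    ft = iilr.finetune_model(state, w, data.labels, data.tumor_rois,
                             data.splits["train"], data.splits["val"],
                             epochs=epochs, lr_max=1e-3, X=data.X, Y=data.Y)
    ft.use_best()
    return ft


def region_nrmse_table(states: dict, data: StudyData, idx=None) -> pd.DataFrame:
    """Tumor-region vs normal-region NRMSE per model, on tumor-bearing samples."""
    idx = data.splits["test"] if idx is None else idx
    rows = []
    for name, state in states.items():
        for i in idx:
            roi = data.tumor_rois[i]
            if roi is None:
                continue
            x = iilr._select_channels(data.X[i:i + 1], state.cfg.channels)
            pred = state.model.forward(x, train=False)[0, 0].astype(np.float64) \
                + data.water_sos[i]
            tgt = data.Y[i, 0].astype(np.float64) + data.water_sos[i]
            normal = (data.labels[i] > 0) & ~roi
            rows.append({
                "model": name, "sample": i,
                "nrmse_tumor": evaltask.metric_nrmse(pred, tgt, data.water_sos[i], mask=roi),
                "nrmse_normal": evaltask.metric_nrmse(pred, tgt, data.water_sos[i], mask=normal),
            })
    return pd.DataFrame(rows)
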