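"""Stochastic 2-D breast-like acoustic phantoms for virtual ring-array USCT.

Each phantom is a tissue label map plus co-registered maps of speed of sound
(SOS, mm/μs), ambient density (g/cm³) and acoustic attenuation
(dB·MHz⁻ʸ·cm⁻¹) immersed in a water bath.  The generator emulates the
statistical structure of numerical breast phantoms used in virtual imaging
trials: a smooth star-convex breast outline, a thin skin layer, glandular
structures embedded in fat with thin ligament-like interfaces, within-tissue
texture from a spatially correlated Gaussian random field (GRF), four breast
density classes (A–D, increasingly dense; D smaller with stronger
heterogeneity), and rare elliptical tumor inclusions with probabilistic size
and location.  It is a deliberately simplified 2-D stand-in: no anatomic
realism is claimed, only controllable ensemble statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import ndimage

from .gridops import pixel_coords, resample_for_network

__all__ = [
    "WATER", "FAT", "GLANDULAR", "LIGAMENT", "SKIN", "TUMOR", "CLASS_TABLE",
    "LabelMap", "AcousticMedium", "TumorSpec", "PhantomConfig",
    "make_phantom", "add_grf_texture", "make_dataset", "load_dataset",
    "desk_config", "full_config", "tumor_axes_for_fraction",
]

# tissue class codes (0 = connected water exterior, by construction)
WATER, FAT, GLANDULAR, LIGAMENT, SKIN, TUMOR = 0, 1, 2, 3, 4, 5
CLASS_TABLE = {WATER: "water", FAT: "fat", GLANDULAR: "glandular",
               LIGAMENT: "ligament", SKIN: "skin", TUMOR: "tumor"}

SOS_FLOOR, SOS_CEIL = 1.3, 1.7  # hard physical bounds, mm/μs


@dataclass
class LabelMap:
    labels: np.ndarray           # integer tissue class per pixel
    grid_spacing: float          # mm per pixel
    class_table: dict = field(default_factory=lambda: dict(CLASS_TABLE))

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class AcousticMedium:
    """Co-registered acoustic property maps of the object being imaged."""
    sos: np.ndarray              # mm/μs
    density: np.ndarray          # g/cm³
    attenuation: np.ndarray      # dB·MHz⁻ʸ·cm⁻¹
    power_law_exponent: float    # y of the attenuation power law
    water_sos: float             # mm/μs
    grid_spacing: float          # mm

    def validate(self) -> None:
        if not (self.sos.shape == self.density.shape == self.attenuation.shape):
            raise ValueError("property grids must share one shape")
        if np.any(self.sos < SOS_FLOOR) or np.any(self.sos > SOS_CEIL):
            raise ValueError("SOS outside physical bounds [1.3, 1.7] mm/μs")
        if np.any(self.density <= 0) or np.any(self.attenuation < 0):
            raise ValueError("density must be positive, attenuation non-negative")


@dataclass
class TumorSpec:
    center: tuple[int, int]      # (row, col) pixel coordinates
    axes: tuple[float, float]    # half-lengths, mm
    orientation: float           # radians
    sos_value: float             # mm/μs


# per-tissue (sos mean mm/μs, density g/cm³, attenuation dB·MHz⁻ʸ·cm⁻¹)
_DEFAULT_TISSUES = {
    FAT:       (1.445, 0.94, 0.40),
    GLANDULAR: (1.540, 1.02, 0.75),
    LIGAMENT:  (1.570, 1.06, 1.20),
    SKIN:      (1.580, 1.10, 1.60),
    TUMOR:     (1.572, 1.05, 1.00),
}

# (glandular area fraction, breast size factor, heterogeneity factor)
_DENSITY_CLASSES = {
    "A": (0.06, 1.00, 1.0),
    "B": (0.20, 1.00, 1.0),
    "C": (0.40, 0.95, 1.0),
    "D": (0.60, 0.78, 1.6),
}


@dataclass
class PhantomConfig:
    grid_shape: tuple[int, int] = (256, 256)
    grid_spacing: float = 1.0                      # mm
    density_class: str = "B"
    breast_radius_frac: tuple[float, float] = (0.55, 0.75)  # of usable half-extent
    outline_wobble: float = 0.07                   # relative Fourier perturbation
    skin_thickness: float = 1.5                    # mm
    gland_scale: float = 8.0                       # mm, blob correlation scale
    water_sos_range: tuple[float, float] = (1.48, 1.52)     # mm/μs
    sos_jitter: float = 0.008                      # per-phantom tissue-mean jitter, mm/μs
    tumor_count_probs: tuple[float, ...] = (0.2, 0.5, 0.2, 0.1)  # P(0..3 tumors)
    tumor_axes_mm: tuple[float, float] = (2.0, 6.0)         # half-axis range
    tumor_sos_delta: tuple[float, float] = (0.02, 0.045)    # above glandular mean
    texture_corr_length: float = 4.0               # mm (e-folding of autocorrelation)
    texture_rel_amplitude: float = 0.006           # fractional SOS/density perturbation
    power_law_exponent: float = 1.5
    tissues: dict = field(default_factory=lambda: dict(_DEFAULT_TISSUES))
    max_tumor_attempts: int = 200
    # dataset target grid (network target map after NN upscale + crop)
    target_shape: tuple[int, int] | None = None
    target_spacing: float | None = None
    target_crop: tuple[int, int] | None = None


def desk_config(**overrides) -> PhantomConfig:
    """Desk-scale preset: 96² at 1 mm with 64² cropped targets at 1 mm."""
    cfg = PhantomConfig(grid_shape=(96, 96), grid_spacing=1.0,
                        target_shape=(96, 96), target_spacing=1.0,
                        target_crop=(64, 64))
    return replace(cfg, **overrides) if overrides else cfg


def full_config(**overrides) -> PhantomConfig:
    """Full-scale preset: 256² at 1 mm with 592² targets at 0.25 mm."""
    cfg = PhantomConfig(grid_shape=(256, 256), grid_spacing=1.0,
                        target_shape=(1024, 1024), target_spacing=0.25,
                        target_crop=(592, 592))
    return replace(cfg, **overrides) if overrides else cfg


def _breast_mask(shape, spacing, radius, wobble, rng):
    """Smooth star-convex closed region: low-order random Fourier perturbation
    of a circle, rasterized on the pixel grid."""
    y, x = pixel_coords(shape, spacing)
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    r_of_theta = np.ones_like(theta)
    for k in range(1, 5):
        a_k = wobble / k * rng.standard_normal()
        phi_k = rng.uniform(0, 2 * np.pi)
        r_of_theta = r_of_theta + a_k * np.cos(k * theta + phi_k)
    return rho <= radius * r_of_theta


def _smooth_field(shape, sigma_px, rng):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_px, mode="wrap")
    return (f - f.mean()) / (f.std() + 1e-30)


def _ellipse_mask(shape, spacing, center_px, axes_mm, orientation):
    y, x = pixel_coords(shape, spacing)
    ny, nx = shape
    cy = (center_px[0] - (ny - 1) / 2.0) * spacing
    cx = (center_px[1] - (nx - 1) / 2.0) * spacing
    ct, st = np.cos(orientation), np.sin(orientation)
    u = (x - cx) * ct + (y - cy) * st
    v = -(x - cx) * st + (y - cy) * ct
    return (u / axes_mm[0]) ** 2 + (v / axes_mm[1]) ** 2 <= 1.0


def make_phantom(seed: int, cfg: PhantomConfig | None = None):
    """Generate one phantom: (LabelMap, AcousticMedium, list[TumorSpec]).

    Deterministic for a fixed (seed, cfg).  Raises on an invalid density class
    and reports (rather than silently dropping) tumors that cannot be placed
    after ``cfg.max_tumor_attempts`` rejection-sampling attempts.
    """
    cfg = cfg or PhantomConfig()
    if cfg.density_class not in _DENSITY_CLASSES:
        raise ValueError(f"invalid density class {cfg.density_class!r}, expected one of A-D")
    gland_frac, size_factor, hetero = _DENSITY_CLASSES[cfg.density_class]
    rng = np.random.default_rng(seed)
    shape, h = tuple(cfg.grid_shape), cfg.grid_spacing
    half_extent = min(shape) / 2.0 * h

    radius = rng.uniform(*cfg.breast_radius_frac) * half_extent * size_factor
    breast = _breast_mask(shape, h, radius, cfg.outline_wobble, rng)
    # keep the water exterior connected: retain the largest component only
    lab, n = ndimage.label(breast)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        breast = lab == (1 + int(np.argmax(sizes)))
    ndimage.binary_fill_holes(breast, output=breast)

    skin_px = max(1, int(round(cfg.skin_thickness / h)))
    interior = ndimage.binary_erosion(breast, iterations=skin_px)
    labels = np.zeros(shape, dtype=np.int16)
    labels[breast] = SKIN
    labels[interior] = FAT

    # glandular blobs: thresholded smooth field, restricted off the skin
    gland_field = _smooth_field(shape, cfg.gland_scale / h, rng)
    core = ndimage.binary_erosion(interior, iterations=max(1, skin_px))
    if core.any() and gland_frac > 0:
        thr = np.quantile(gland_field[core], 1.0 - gland_frac)
        gland = core & (gland_field >= thr)
        labels[gland] = GLANDULAR
        # thin ligament-like rim around glandular structures
        rim = ndimage.binary_dilation(gland) & ~gland & core
        labels[rim] = LIGAMENT

    # tumors
    n_tumors = int(rng.choice(len(cfg.tumor_count_probs), p=np.asarray(cfg.tumor_count_probs)
                              / np.sum(cfg.tumor_count_probs)))
    tumors: list[TumorSpec] = []
    placeable = ndimage.binary_erosion(interior, iterations=1)
    rows, cols = np.nonzero(placeable)
    gmean = cfg.tissues[GLANDULAR][0]
    for _ in range(n_tumors):
        if rows.size == 0:
            raise RuntimeError("no interior tissue available for tumor placement")
        placed = False
        for _attempt in range(cfg.max_tumor_attempts):
            k = rng.integers(rows.size)
            a = rng.uniform(*cfg.tumor_axes_mm)
            b = a * rng.uniform(0.6, 1.0)
            ang = rng.uniform(0, np.pi)
            mask = _ellipse_mask(shape, h, (rows[k], cols[k]), (a, b), ang)
            if mask.any() and np.all(interior[mask]) and not np.any(labels[mask] == TUMOR):
                sos_val = gmean + rng.uniform(*cfg.tumor_sos_delta)
                labels[mask] = TUMOR
                tumors.append(TumorSpec((int(rows[k]), int(cols[k])), (a, b), ang, sos_val))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"tumor placement failed after {cfg.max_tumor_attempts} attempts "
                f"(axes up to {cfg.tumor_axes_mm[1]} mm may not fit this breast)")

    # acoustic properties
    water_sos = rng.uniform(*cfg.water_sos_range)
    sos = np.full(shape, water_sos)
    density = np.ones(shape)
    atten = np.zeros(shape)
    for cls, (smean, dmean, amean) in cfg.tissues.items():
        m = labels == cls
        if not m.any():
            continue
        if cls == TUMOR:
            continue  # per-tumor SOS below
        sos[m] = smean + rng.normal(0.0, cfg.sos_jitter)
        density[m] = dmean
        atten[m] = amean
    for spec in tumors:
        m = _ellipse_mask(shape, h, spec.center, spec.axes, spec.orientation) & (labels == TUMOR)
        sos[m] = spec.sos_value
        density[m] = cfg.tissues[TUMOR][1]
        atten[m] = cfg.tissues[TUMOR][2]

    medium = AcousticMedium(sos, density, atten, cfg.power_law_exponent, water_sos, h)
    label_map = LabelMap(labels, h)
    if cfg.texture_rel_amplitude > 0:
        medium = add_grf_texture(medium, label_map, cfg.texture_corr_length,
                                 cfg.texture_rel_amplitude * hetero,
                                 seed=int(rng.integers(2 ** 31)))
    # tissue SOS stays inside the nominal soft-tissue dynamic range
    tissue = labels > 0
    medium.sos[tissue] = np.clip(medium.sos[tissue], 1.4, 1.6)
    medium.validate()
    return label_map, medium, tumors


def add_grf_texture(medium: AcousticMedium, labels: LabelMap, corr_length: float,
                    rel_amplitude: float, seed: int) -> AcousticMedium:
    """Add zero-mean spatially correlated texture to SOS and density in tissue.

    The field is white noise spectrally shaped by a Gaussian kernel with
    σ = corr_length/2, which gives the autocorrelation exp(-r²/corr_length²),
    i.e. an e-folding length of ``corr_length``.  The perturbation is
    re-centered per tissue class so tissue-mean properties are preserved, and
    water pixels are untouched.  Values that would leave [1.3, 1.7] mm/μs are
    clipped with a warning.
    """
    if corr_length <= 0:
        raise ValueError("corr_length must be positive")
    if rel_amplitude < 0:
        raise ValueError("rel_amplitude must be non-negative")
    if rel_amplitude == 0:
        return medium
    rng = np.random.default_rng(seed)
    f = _smooth_field(medium.sos.shape, corr_length / (2.0 * medium.grid_spacing), rng)
    tissue = labels.labels > 0
    pert = np.zeros_like(medium.sos)
    for cls in np.unique(labels.labels[tissue]):
        m = labels.labels == cls
        g = f[m] - f[m].mean()
        s = g.std()
        if s > 0:
            g = g / s
        pert[m] = g
    sos = medium.sos + rel_amplitude * medium.sos * pert
    density = medium.density + rel_amplitude * medium.density * pert
    if np.any(sos < SOS_FLOOR) or np.any(sos > SOS_CEIL):
        warnings.warn("texture amplitude clipped at the [1.3, 1.7] mm/μs bounds")
        sos = np.clip(sos, SOS_FLOOR, SOS_CEIL)
    return AcousticMedium(sos, density, medium.attenuation, medium.power_law_exponent,
                          medium.water_sos, medium.grid_spacing)


def tumor_axes_for_fraction(cfg: PhantomConfig, target_fraction: float) -> tuple[float, float]:
    """Half-axis range making the expected tumor pixel fraction of breast
    tissue equal ``target_fraction`` (first-moment calculation).

    Uses E[area] = E[n]·π·E[a·b] with b = a·U(0.6, 1), against the mean breast
    area implied by the configured radius fraction and density class.
    """
    probs = np.asarray(cfg.tumor_count_probs, float)
    probs = probs / probs.sum()
    mean_n = float(np.sum(np.arange(probs.size) * probs))
    if mean_n <= 0:
        raise ValueError("tumor count distribution has zero mean")
    _, size_factor, _ = _DENSITY_CLASSES[cfg.density_class]
    half_extent = min(cfg.grid_shape) / 2.0 * cfg.grid_spacing
    lo, hi = cfg.breast_radius_frac
    mean_r2 = (lo ** 2 + lo * hi + hi ** 2) / 3.0 * (half_extent * size_factor) ** 2
    breast_area = np.pi * mean_r2
    # E[a·b] = E[a²]·E[ratio]; with a ~ U(lo_a, hi_a) of ratio hi/lo = 1.5
    mean_ratio = 0.8
    # solve for a uniform range [a0, 1.5 a0]: E[a²] = a0²·(1+1.5+1.5²)/3
    target_ab = target_fraction * breast_area / (mean_n * np.pi * mean_ratio)
    a0 = np.sqrt(target_ab / ((1 + 1.5 + 1.5 ** 2) / 3.0))
    return (a0, 1.5 * a0)


def make_dataset(n: int, cfg: PhantomConfig, seed: int, path: str,
                 split: tuple[int, int, int] | None = None, overwrite: bool = False) -> str:
    """Generate ``n`` phantoms and write them (plus disjoint train/val/test
    splits and cropped target SOS maps) to an HDF5 file.

    Layout: ``/samples/<id>/{labels, sos, density, attenuation, water_sos,
    tumors, target_sos}`` and ``/splits/{train, val, test}``.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to form train/val/test splits")
    if split is None:
        n_val = max(1, n // 10)
        n_test = max(1, n // 10)
        split = (n - n_val - n_test, n_val, n_test)
    if sum(split) != n:
        raise ValueError(f"split {split} does not sum to n={n}")
    mode = "w" if overwrite else "w-"
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2 ** 31, size=n)
    with h5py.File(path, mode) as f:
        f.attrs["grid_spacing"] = cfg.grid_spacing
        f.attrs["density_class"] = cfg.density_class
        f.attrs["power_law_exponent"] = cfg.power_law_exponent
        grp = f.create_group("samples")
        for i in range(n):
            labels, medium, tumors = make_phantom(int(seeds[i]), cfg)
            g = grp.create_group(str(i))
            g.create_dataset("labels", data=labels.labels, dtype=np.int16)
            g.create_dataset("sos", data=medium.sos.astype(np.float32))
            g.create_dataset("density", data=medium.density.astype(np.float32))
            g.create_dataset("attenuation", data=medium.attenuation.astype(np.float32))
            g.attrs["water_sos"] = medium.water_sos
            tum = np.array([(t.center[0], t.center[1], t.axes[0], t.axes[1],
                             t.orientation, t.sos_value) for t in tumors], dtype=np.float64)
            g.create_dataset("tumors", data=tum.reshape(-1, 6))
            if cfg.target_shape is not None:
                tgt = resample_for_network(medium.sos, cfg.grid_spacing, cfg.target_shape,
                                           cfg.target_spacing, cfg.target_crop)
                g.create_dataset("target_sos", data=tgt.astype(np.float32))
                tgt_lab = resample_for_network(labels.labels.astype(float), cfg.grid_spacing,
                                               cfg.target_shape, cfg.target_spacing,
                                               cfg.target_crop).astype(np.int16)
                g.create_dataset("target_labels", data=tgt_lab)
        perm = rng.permutation(n)
        sp = f.create_group("splits")
        sp.create_dataset("train", data=np.sort(perm[:split[0]]))
        sp.create_dataset("val", data=np.sort(perm[split[0]:split[0] + split[1]]))
        sp.create_dataset("test", data=np.sort(perm[split[0] + split[1]:]))
    return path


def load_dataset(path: str):
    """Read a phantom dataset back as (samples, splits) of plain dicts/arrays."""
    samples = []
    with h5py.File(path, "r") as f:
        h = float(f.attrs["grid_spacing"])
        y = float(f.attrs["power_law_exponent"])
        ids = sorted(f["samples"], key=int)
        for sid in ids:
            g = f["samples"][sid]
            entry = {
                "labels": LabelMap(g["labels"][()], h),
                "medium": AcousticMedium(g["sos"][()].astype(float),
                                         g["density"][()].astype(float),
                                         g["attenuation"][()].astype(float),
                                         y, float(g.attrs["water_sos"]), h),
                "tumors": [TumorSpec((int(r[0]), int(r[1])), (r[2], r[3]), r[4], r[5])
                           for r in g["tumors"][()]],
            }
            if "target_sos" in g:
                entry["target_sos"] = g["target_sos"][()].astype(float)
                entry["target_labels"] = g["target_labels"][()]
            samples.append(entry)
        splits = {k: f["splits"][k][()].tolist() for k in ("train", "val", "test")}
    return samples, splits
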