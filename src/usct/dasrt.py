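"""Delay-and-sum (DAS) reflection tomography on a ring array.

Backscattered signals are Wiener-deconvolved with the source pulse, then each
image pixel k accumulates the apodized sum

    f_k = Σ_m Σ_n a_{m,n} · ĝ_{m,n}( T_m(r_k) + T_n(r_k) ),

where the two-way delay is the sum of one-way first-arrival traveltime fields
(solved from the BRTT slowness estimate) and traces are evaluated at the
delays with modified Akima piecewise-cubic Hermite interpolation.  The binary
apodization a_{m,n} keeps only near-emitter receivers, which carry the
backscatter: by default each emitter uses itself plus seven neighbors per
side (15 receivers); the literal central-angle threshold rule is also
available.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import Akima1DInterpolator

from .brtt import SlownessImage, solve_eikonal
from .gridops import resample_nearest
from .tof import homogeneous_tof
from .wavesim import MeasurementSet, RingArray, SourcePulse

__all__ = ["ReflectivityImage", "ApodizationRule", "apodization_weights", "two_way_delay",
           "deconvolve_source", "mute_direct_arrival", "traveltime_fields", "reconstruct_das"]


@dataclass
class ReflectivityImage:
    f: np.ndarray              # unnormalized reflectivity, 2-D
    grid_spacing: float        # mm
    normalization: float       # max-abs value, recorded (f is stored unnormalized)

    def normalized(self) -> np.ndarray:
        return self.f / self.normalization if self.normalization > 0 else self.f


@dataclass
class ApodizationRule:
    mode: str = "neighbor-count"       # or "angle-threshold"
    k_side: int = 7
    sigma: float = 15 * np.pi / 128    # rad, used by angle-threshold mode


def apodization_weights(array: RingArray, rule: ApodizationRule) -> np.ndarray:
    """Binary [Ne, Nr] matrix selecting the backscatter-carrying receivers.

    neighbor-count mode: emitter m keeps itself plus ``k_side`` neighbors per
    side.  angle-threshold mode: a_{m,n} = 1 iff the central angle between the
    elements is ≤ sigma.  The matrix is symmetric in (m, n) for evenly spaced
    elements.
    """
    n = array.n_elements
    if rule.mode == "neighbor-count":
        if rule.k_side >= n // 2:
            raise ValueError(f"k_side={rule.k_side} must be < n_elements/2={n // 2}")
        idx = np.arange(n)
        d = np.abs(idx[:, None] - idx[None, :])
        d = np.minimum(d, n - d)
        return (d <= rule.k_side).astype(np.int8)
    if rule.mode == "angle-threshold":
        a = array.element_angles
        d = np.abs(a[:, None] - a[None, :])
        d = np.minimum(d, 2 * np.pi - d)
        return (d <= rule.sigma + 1e-12).astype(np.int8)
    raise ValueError(f"unknown apodization mode {rule.mode!r}")


def two_way_delay(T_fields: np.ndarray, m: int, n: int, k=None):
    """Two-way traveltime T_m(r_k) + T_n(r_k), μs.

    ``T_fields`` stacks per-element one-way traveltime grids [Ne, H, W].
    With ``k=None`` the full delay grid is returned; otherwise ``k`` indexes a
    (row, col) pixel.
    """
    tw = T_fields[m] + T_fields[n]
    if k is None:
        return tw
    return tw[k]


def deconvolve_source(ms: MeasurementSet, pulse: SourcePulse, reg: float = 1e-2) -> MeasurementSet:
    """Frequency-domain Wiener deconvolution G·conj(S)/(|S|² + reg·max|S|²).

    Collapses each echo toward a band-limited impulse at its true two-way
    delay (removing the pulse's own onset lag), preserving trace length.
    """
    if reg <= 0:
        raise ValueError("reg must be positive")
    L = ms.n_samples
    s = np.zeros(L)
    w = pulse.waveform[:L]
    s[:len(w)] = w
    S = np.fft.rfft(s)
    p2 = np.abs(S) ** 2
    if p2.max() == 0:
        raise ValueError("all-zero pulse spectrum")
    W = np.conj(S) / (p2 + reg * p2.max())
    g = np.fft.irfft(np.fft.rfft(ms.g, axis=-1) * W, n=L, axis=-1)
    return replace(ms, g=g)


def mute_direct_arrival(ms: MeasurementSet, pad: float) -> MeasurementSet:
    """Zero each trace before the homogeneous direct-arrival time plus ``pad`` μs.

    The transmitted (direct) wave dominates near-emitter receivers; muting it
    leaves the backscattered echoes the DAS sum is built from.
    """
    hom = homogeneous_tof(ms.array, ms.water_sos)
    t = ms.times()[None, None, :]
    keep = t >= (hom.t_obs + pad)[:, :, None]
    return replace(ms, g=ms.g * keep)


def traveltime_fields(b: SlownessImage, array: RingArray, out_shape, out_spacing,
                      elements=None) -> np.ndarray:
    """One-way eikonal traveltime grids [Ne, H, W] on the imaging grid,
    computed from a (BRTT-estimated) slowness model."""
    slow = b.b
    if b.shape != tuple(out_shape) or b.grid_spacing != out_spacing:
        slow = resample_nearest(b.b, b.grid_spacing, tuple(out_shape), out_spacing)
    bi = SlownessImage(slow, out_spacing, b.box)
    pos = array.positions()
    if elements is None:
        elements = range(array.n_elements)
    T = np.zeros((array.n_elements, *out_shape))
    for e in elements:
        T[e] = solve_eikonal(bi, pos[e])
    return T


def reconstruct_das(ms: MeasurementSet, T_fields: np.ndarray, apod: np.ndarray,
                    grid_spacing: float) -> ReflectivityImage:
    """Apodized delay-and-sum image on the grid of ``T_fields``.

    Each contributing trace is interpolated at the two-way delay with modified
    Akima piecewise-cubic Hermite interpolation; delays outside [0, T)
    contribute zero.  Linear in the measurement data.
    """
    if T_fields.shape[0] != ms.array.n_elements:
        raise ValueError("T_fields must hold one traveltime grid per element")
    shape = T_fields.shape[1:]
    t = ms.times()
    f = np.zeros(shape)
    emitters = ms.emitters if ms.emitters is not None else np.arange(ms.array.n_elements)
    for m in emitters:
        active = np.nonzero(apod[m])[0]
        tw = T_fields[active] + T_fields[m][None]     # [n_active, H, W]
        for a_i, n in enumerate(active):
            tr = ms.g[m, n]
            if not np.any(tr):
                continue
            interp = Akima1DInterpolator(t, tr, method="makima", extrapolate=False)
            vals = interp(tw[a_i].ravel())
            f += np.nan_to_num(vals, nan=0.0).reshape(shape)
    norm = float(np.max(np.abs(f))) if f.size else 0.0
    return ReflectivityImage(f=f, grid_spacing=grid_spacing, normalization=norm)
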