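"""Bent-ray traveltime tomography (BRTT) for low-resolution SOS mapping.

Observed first-arrival times t_m^obs are inverted for the slowness image b
(reciprocal SOS) by minimizing Σ_m ‖t_m^obs − L_m(b)·b‖² subject to a box
constraint b_min ≤ b ≤ b_max, with a proximal Gauss–Newton method:

  1. solve the eikonal equation |∇T| = b per emitter (first-arrival fields),
  2. trace rays from each receiver back to the emitter by steepest descent on
     T and accumulate per-pixel arclengths into the sparse ray matrices L_m,
  3. form the data residuals d_m = t_m^obs − L_m b and the gradient
     g = −Σ L_mᵀ d_m,
  4. stop when the proximal gradient b − proj_B(b − g) is small, else solve
     the Gauss–Newton subproblem min_y Σ‖L_m y − d_m‖² by CGLS (fixed inner
     iterations), and
  5. backtrack μ ≤ 1 on b ← proj_B(b + μ y) until the sufficient-descent
     condition F(b_new) ≤ F(b) + μ·gᵀy holds.

The eikonal solver is a fast-marching method with second-order upwind
differences (falling back to first order next to the wavefront) and an
analytically initialized disk around the point source to curb the source
singularity error; both the solver and the ray tracer are numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import sparse

from .gridops import resample_for_network  # re-export: network-grid resampling  # noqa: F401
from .tof import TOFTable
from .wavesim import RingArray

__all__ = ["SlownessImage", "solve_eikonal", "build_ray_matrix", "reconstruct_brtt",
           "slowness_to_sos", "sos_to_slowness", "resample_for_network", "predict_tof"]

DEFAULT_BOX = (1.0 / 1.7, 1.0 / 1.3)  # μs/mm, mirrors the physical SOS bounds


@dataclass
class SlownessImage:
    b: np.ndarray                       # μs/mm, shape (Nk, Nk)
    grid_spacing: float                 # mm
    box: tuple[float, float] = DEFAULT_BOX

    def __post_init__(self):
        if np.any(self.b <= 0):
            raise ValueError("slowness must be strictly positive")

    @property
    def shape(self):
        return self.b.shape


def sos_to_slowness(sos: np.ndarray, grid_spacing: float,
                    box: tuple[float, float] = DEFAULT_BOX) -> SlownessImage:
    return SlownessImage(1.0 / np.asarray(sos, float), grid_spacing, box)


def slowness_to_sos(img: SlownessImage) -> np.ndarray:
    """Elementwise reciprocal; the SOS map corresponding to a slowness image."""
    if np.any(img.b == 0):
        raise ValueError("zero slowness")
    return 1.0 / img.b


# ---------------------------------------------------------------- fast marching

@njit(cache=True)
def _heap_push(hv, hi, hn, v, idx):
    hv[hn] = v
    hi[hn] = idx
    i = hn
    while i > 0:
        p = (i - 1) >> 1
        if hv[p] > hv[i]:
            hv[p], hv[i] = hv[i], hv[p]
            hi[p], hi[i] = hi[i], hi[p]
            i = p
        else:
            break
    return hn + 1


@njit(cache=True)
def _heap_pop(hv, hi, hn):
    v = hv[0]
    idx = hi[0]
    hn -= 1
    hv[0] = hv[hn]
    hi[0] = hi[hn]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        s = i
        if l < hn and hv[l] < hv[s]:
            s = l
        if r < hn and hv[r] < hv[s]:
            s = r
        if s == i:
            break
        hv[s], hv[i] = hv[i], hv[s]
        hi[s], hi[i] = hi[i], hi[s]
        i = s
    return v, idx, hn


@njit(cache=True)
def _fmm_update(T, state, slow, h, i, j, ny, nx):
    """Second-order upwind eikonal update at node (i, j)."""
    f = slow[i, j] * h
    INF = 1e18
    # per-axis upwind value v and weight w (1 first-order, 9/4 second-order)
    va = INF
    wa = 1.0
    vb = INF
    wb = 1.0
    # y axis
    for d in (-1, 1):
        ii = i + d
        if 0 <= ii < ny and state[ii, j] == 2:
            t1 = T[ii, j]
            i2 = i + 2 * d
            if 0 <= i2 < ny and state[i2, j] == 2 and T[i2, j] <= t1:
                v = (4.0 * t1 - T[i2, j]) / 3.0
                w = 2.25
            else:
                v = t1
                w = 1.0
            if v < va or (v == va and w > wa):
                va = v
                wa = w
    # x axis
    for d in (-1, 1):
        jj = j + d
        if 0 <= jj < nx and state[i, jj] == 2:
            t1 = T[i, jj]
            j2 = j + 2 * d
            if 0 <= j2 < nx and state[i, j2] == 2 and T[i, j2] <= t1:
                v = (4.0 * t1 - T[i, j2]) / 3.0
                w = 2.25
            else:
                v = t1
                w = 1.0
            if v < vb or (v == vb and w > wb):
                vb = v
                wb = w
    if va > vb:
        va, vb = vb, va
        wa, wb = wb, wa
    if va >= INF:
        return INF
    # two-axis quadratic: wa(T-va)² + wb(T-vb)² = f²
    if vb < INF:
        a = wa + wb
        bq = -2.0 * (wa * va + wb * vb)
        cq = wa * va * va + wb * vb * vb - f * f
        disc = bq * bq - 4.0 * a * cq
        if disc >= 0.0:
            t = (-bq + np.sqrt(disc)) / (2.0 * a)
            if t >= vb:
                return t
    return va + f / np.sqrt(wa)


@njit(cache=True)
def _fmm(slow, h, si, sj, r0):
    ny, nx = slow.shape
    T = np.full((ny, nx), 1e18)
    state = np.zeros((ny, nx), np.uint8)  # 0 far, 1 trial, 2 known
    cap = 16 * ny * nx + 64
    hv = np.empty(cap)
    hi = np.empty(cap, np.int64)
    hn = 0
    b0 = slow[si, sj]
    ir = int(np.ceil(r0))
    for di in range(-ir, ir + 1):
        for dj in range(-ir, ir + 1):
            i = si + di
            j = sj + dj
            if 0 <= i < ny and 0 <= j < nx:
                d = np.sqrt(di * di + dj * dj)
                if d <= r0:
                    T[i, j] = b0 * d * h
                    state[i, j] = 2
    # seed trial band around the initialized disk
    for i in range(max(0, si - ir - 1), min(ny, si + ir + 2)):
        for j in range(max(0, sj - ir - 1), min(nx, sj + ir + 2)):
            if state[i, j] != 2:
                t = _fmm_update(T, state, slow, h, i, j, ny, nx)
                if t < T[i, j]:
                    T[i, j] = t
                    state[i, j] = 1
                    hn = _heap_push(hv, hi, hn, t, i * nx + j)
    while hn > 0:
        v, idx, hn = _heap_pop(hv, hi, hn)
        i = idx // nx
        j = idx % nx
        if state[i, j] == 2:
            continue
        state[i, j] = 2
        T[i, j] = v
        for d in range(4):
            ii = i + (d == 0) - (d == 1)
            jj = j + (d == 2) - (d == 3)
            if 0 <= ii < ny and 0 <= jj < nx and state[ii, jj] != 2:
                t = _fmm_update(T, state, slow, h, ii, jj, ny, nx)
                if t < T[ii, jj]:
                    T[ii, jj] = t
                    state[ii, jj] = 1
                    if hn >= cap - 1:
                        # heap saturated by stale entries; compact by rebuild
                        k = 0
                        for q in range(hn):
                            qi = hi[q] // nx
                            qj = hi[q] % nx
                            if state[qi, qj] != 2 and hv[q] <= T[qi, qj]:
                                hv[k] = hv[q]
                                hi[k] = hi[q]
                                k += 1
                        hn = k
                        for q in range(hn // 2 - 1, -1, -1):
                            # re-heapify by sift-down from q
                            i2 = q
                            while True:
                                l = 2 * i2 + 1
                                r = l + 1
                                s = i2
                                if l < hn and hv[l] < hv[s]:
                                    s = l
                                if r < hn and hv[r] < hv[s]:
                                    s = r
                                if s == i2:
                                    break
                                hv[s], hv[i2] = hv[i2], hv[s]
                                hi[s], hi[i2] = hi[i2], hi[s]
                                i2 = s
                    hn = _heap_push(hv, hi, hn, t, ii * nx + jj)
    return T


def _to_node(pos_xy, shape, spacing):
    ny, nx = shape
    j = int(round(pos_xy[0] / spacing + (nx - 1) / 2.0))
    i = int(round(pos_xy[1] / spacing + (ny - 1) / 2.0))
    if not (0 <= i < ny and 0 <= j < nx):
        raise ValueError(f"position {pos_xy} outside the reconstruction grid")
    return i, j


def solve_eikonal(b: SlownessImage, source, source_disk: float = 5.0) -> np.ndarray:
    """First-arrival traveltime grid T (μs) with |∇T| = b and T(source) = 0.

    ``source`` is an (x, y) position in mm; it is snapped to the nearest grid
    node.  A disk of radius ``source_disk`` pixels around the source is
    initialized with the exact local solution b·|r − r_src| before marching.
    """
    si, sj = _to_node(source, b.shape, b.grid_spacing)
    return _fmm(np.asarray(b.b, np.float64), b.grid_spacing, si, sj, source_disk)


# ---------------------------------------------------------------- ray tracing

@njit(cache=True)
def _trace_ray(T, gy, gx, h, rx, ry, sx, sy, step, max_steps, pix, seg):
    """Steepest-descent ray from receiver (rx, ry) to source (sx, sy), both mm.

    Accumulates per-step arclength into (pix, seg); returns (n_segments, ok).
    """
    ny, nx = T.shape
    x = rx
    y = ry
    n = 0
    for _ in range(max_steps):
        dxs = sx - x
        dys = sy - y
        dist = np.sqrt(dxs * dxs + dys * dys)
        if dist <= 1.5 * h:
            # final straight segment into the source
            mi = int(round((y + 0.5 * dys) / h + (ny - 1) / 2.0))
            mj = int(round((x + 0.5 * dxs) / h + (nx - 1) / 2.0))
            if mi < 0:
                mi = 0
            if mi > ny - 1:
                mi = ny - 1
            if mj < 0:
                mj = 0
            if mj > nx - 1:
                mj = nx - 1
            pix[n] = mi * nx + mj
            seg[n] = dist
            return n + 1, True
        # bilinear gradient at (x, y)
        fj = x / h + (nx - 1) / 2.0
        fi = y / h + (ny - 1) / 2.0
        if fi < 0.0:
            fi = 0.0
        if fi > ny - 1.001:
            fi = ny - 1.001
        if fj < 0.0:
            fj = 0.0
        if fj > nx - 1.001:
            fj = nx - 1.001
        i0 = int(fi)
        j0 = int(fj)
        wy = fi - i0
        wx = fj - j0
        gxv = (gx[i0, j0] * (1 - wy) * (1 - wx) + gx[i0, j0 + 1] * (1 - wy) * wx
               + gx[i0 + 1, j0] * wy * (1 - wx) + gx[i0 + 1, j0 + 1] * wy * wx)
        gyv = (gy[i0, j0] * (1 - wy) * (1 - wx) + gy[i0, j0 + 1] * (1 - wy) * wx
               + gy[i0 + 1, j0] * wy * (1 - wx) + gy[i0 + 1, j0 + 1] * wy * wx)
        gn = np.sqrt(gxv * gxv + gyv * gyv)
        if gn < 1e-12:
            # flat traveltime (inside the analytic source disk): go straight
            gxv = -dxs / dist
            gyv = -dys / dist
            gn = 1.0
        dx = -gxv / gn * step
        dy = -gyv / gn * step
        xm = x + 0.5 * dx
        ym = y + 0.5 * dy
        mi = int(round(ym / h + (ny - 1) / 2.0))
        mj = int(round(xm / h + (nx - 1) / 2.0))
        if mi < 0 or mi > ny - 1 or mj < 0 or mj > nx - 1:
            return n, False
        pix[n] = mi * nx + mj
        seg[n] = step
        n += 1
        x += dx
        y += dy
    return n, False


def build_ray_matrix(b: SlownessImage, T: np.ndarray, receivers: np.ndarray,
                     source=None, step_frac: float = 0.5):
    """Sparse [Nr, K] matrix of per-pixel ray arclengths (mm) for one emitter.

    Rays run from each receiver to the source by steepest descent on the
    traveltime field T (bilinear-interpolated gradient, steps of half a pixel).
    Rows of rays that fail to reach the source are returned invalid.
    """
    ny, nx = b.shape
    h = b.grid_spacing
    if source is None:
        si, sj = np.unravel_index(int(np.argmin(T)), T.shape)
    else:
        si, sj = _to_node(source, b.shape, h)
    sx = (sj - (nx - 1) / 2.0) * h
    sy = (si - (ny - 1) / 2.0) * h
    gy, gx = np.gradient(T, h)
    step = step_frac * h
    max_steps = int(20 + 8 * (ny + nx) * h / step)
    pix = np.empty(max_steps + 1, np.int64)
    seg = np.empty(max_steps + 1, np.float64)
    rows, cols, vals = [], [], []
    valid = np.zeros(len(receivers), bool)
    for r, pos in enumerate(receivers):
        # snap receivers to grid nodes (consistent with the predicted TOF)
        ri, rj = _to_node(pos, b.shape, h)
        rx = (rj - (nx - 1) / 2.0) * h
        ry = (ri - (ny - 1) / 2.0) * h
        nseg, ok = _trace_ray(T, gy, gx, h, rx, ry, sx, sy, step, max_steps, pix, seg)
        if not ok:
            continue
        valid[r] = True
        rows.append(np.full(nseg, r, np.int64))
        cols.append(pix[:nseg].copy())
        vals.append(seg[:nseg].copy())
    if rows:
        A = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(receivers), ny * nx))
    else:
        A = sparse.csr_matrix((len(receivers), ny * nx))
    return A, valid


def predict_tof(b: SlownessImage, array: RingArray, emitters=None, source_disk: float = 5.0):
    """Ray-predicted TOF table L_m(b)·b for every emitter (bent-ray forward model)."""
    pos = array.positions()
    n = array.n_elements
    if emitters is None:
        emitters = np.arange(n)
    t = np.zeros((n, n))
    valid = np.zeros((n, n), bool)
    bf = b.b.ravel()
    for m in emitters:
        T = solve_eikonal(b, pos[m], source_disk)
        A, ok = build_ray_matrix(b, T, pos, source=pos[m])
        t[m] = A @ bf
        valid[m] = ok
        valid[m, m] = False
    return TOFTable(t_obs=t, valid_mask=valid)


# ------------------------------------------------------------ proximal Gauss-Newton

def _cgls(A, d, n_iter):
    """Conjugate-gradient least squares for min ‖A y − d‖₂, y₀ = 0."""
    y = np.zeros(A.shape[1])
    r = d.copy()
    s = A.T @ r
    p = s.copy()
    gamma = float(s @ s)
    if gamma == 0:
        return y
    for _ in range(n_iter):
        q = A @ p
        qq = float(q @ q)
        if qq == 0:
            break
        alpha = gamma / qq
        y += alpha * p
        r -= alpha * q
        s = A.T @ r
        gamma_new = float(s @ s)
        if gamma_new <= 1e-28:
            break
        p = s + (gamma_new / gamma) * p
        gamma = gamma_new
    return y


@dataclass
class GNResult:
    slowness: SlownessImage
    misfit_per_iter: list = field(default_factory=list)
    status: str = "max_iter"
    n_iter: int = 0


def _linearize(bimg: SlownessImage, array: RingArray, tof: TOFTable, emitters):
    """Eikonal solves + ray matrices at b; returns stacked (A, d, F)."""
    pos = array.positions()
    bf = bimg.b.ravel()
    mats, res = [], []
    for m in emitters:
        T = solve_eikonal(bimg, pos[m])
        A, ok = build_ray_matrix(bimg, T, pos, source=pos[m])
        keep = tof.valid_mask[m] & ok
        A = A[keep]
        d = tof.t_obs[m, keep] - A @ bf
        mats.append(A)
        res.append(d)
    A_all = sparse.vstack(mats, format="csr")
    d_all = np.concatenate(res)
    return A_all, d_all, float(d_all @ d_all)


def reconstruct_brtt(tof: TOFTable, b0: SlownessImage, array: RingArray,
                     box: tuple[float, float] | None = None, tol: float = 1e-3,
                     max_iter: int = 20, cgls_iters: int = 12,
                     max_backtracks: int = 10) -> GNResult:
    """Proximal Gauss–Newton inversion of TOF data with a box constraint.

    ``tol`` is relative: the stopping threshold is tol × the initial proximal
    gradient norm.  Every iterate satisfies the box exactly (projection), the
    data misfit is non-increasing over accepted steps, and invalid TOF entries
    are excluded from all sums.
    """
    box = box or b0.box
    lo, hi = box
    b = np.clip(b0.b.copy(), lo, hi)
    if not np.allclose(b, b0.b):
        raise ValueError("initial slowness must lie inside the box")
    emitters = np.nonzero(tof.valid_mask.any(axis=1))[0]
    bimg = SlownessImage(b, b0.grid_spacing, box)
    A, d, F = _linearize(bimg, array, tof, emitters)
    history = [F]
    tol_abs = None
    status = "max_iter"
    it = 0
    for it in range(max_iter):
        g = -(A.T @ d)
        g_prox = b.ravel() - np.clip(b.ravel() - g, lo, hi)
        gnorm = float(np.linalg.norm(g_prox))
        if tol_abs is None:
            tol_abs = tol * gnorm
        if gnorm <= tol_abs:
            status = "converged"
            break
        y = _cgls(A, d, cgls_iters)
        lam = float(g @ y)
        if lam >= 0:  # not a descent direction; fall back to projected gradient
            y = -g
            lam = float(g @ y)
        mu = 1.0
        accepted = False
        for _ in range(max_backtracks):
            b_new = np.clip(b.ravel() + mu * y, lo, hi).reshape(b.shape)
            bimg_new = SlownessImage(b_new, b0.grid_spacing, box)
            A_new, d_new, F_new = _linearize(bimg_new, array, tof, emitters)
            if F_new <= F + mu * lam + 1e-12 * max(1.0, F):
                accepted = True
                break
            mu *= 0.5
        if not accepted:
            status = "no_descent"
            break
        b, bimg, A, d, F = b_new, bimg_new, A_new, d_new, F_new
        history.append(F)
    else:
        it = max_iter
    return GNResult(slowness=SlownessImage(b, b0.grid_spacing, box),
                    misfit_per_iter=history, status=status, n_iter=it)
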