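# Methods

This package is a virtual imaging testbed for quantitative speed-of-sound
(SOS) reconstruction with ring-array ultrasound computed tomography (USCT),
together with a dual-channel learned reconstructor that maps two cheap
ray-based reconstructions — a low-resolution SOS map from bent-ray traveltime
tomography (BRTT) and a reflectivity image from delay-and-sum (DAS)
beamforming — to a high-resolution SOS estimate. This note records the models,
the numerical choices, and what the desk-scale experiments do and do not show.

Units throughout: mm, μs, MHz, g/cm³; SOS in mm/μs (soft tissue ≈ 1.4–1.6).

## Phantoms

`usct.phantom` generates 2-D breast-like acoustic sections in a water bath:

* **Geometry.** The breast outline is a smooth star-convex curve — a circle
  with a low-order (k ≤ 4) random Fourier perturbation of relative amplitude
  ~7% — filled and wrapped by a thin skin layer. Interior tissue is fat with
  glandular structures obtained by thresholding a smoothed Gaussian field at
  the quantile matching the configured glandular area fraction, plus a thin
  ligament-like rim around the glandular components. Density classes A–D set
  the glandular fraction (0.06, 0.20, 0.40, 0.60); class D additionally
  shrinks the breast (×0.78) and increases texture amplitude (×1.6).
* **Acoustic properties.** Per-tissue means (SOS / density / attenuation):
  fat 1.445 / 0.94 / 0.40, glandular 1.540 / 1.02 / 0.75, ligament
  1.570 / 1.06 / 1.20, skin 1.580 / 1.10 / 1.60, tumor ≈ glandular + 0.02–0.045
  SOS; attenuation in dB·MHz⁻ʸ·cm⁻¹ with a single power-law exponent
  y = 1.5 per phantom. These values are plausible soft-tissue numbers chosen
  once and exposed in the configuration; they are not asserted to match any
  particular measurement campaign. The water-bath SOS varies per sample
  (uniform in 1.48–1.52) to emulate temperature drift between acquisitions —
  this is what the water-offset preprocessing of the learned reconstructor
  must absorb. Tissue SOS is clipped to [1.4, 1.6].
* **Texture.** Within-tissue heterogeneity is a Gaussian random field:
  white noise spectrally shaped by a Gaussian kernel with σ = L/2, giving an
  autocorrelation exp(−r²/L²) whose e-folding length is the configured
  correlation length L (default 4 mm). The perturbation is re-centered per
  tissue class (tissue means are preserved), scales both SOS and density by
  the relative amplitude (default 0.6%), and never touches water.
* **Tumors.** 0–3 elliptical inclusions, rejection-sampled wholly inside the
  interior tissue; placement failure after a bounded number of attempts is an
  error, never silent. `tumor_axes_for_fraction` solves (first moments) for
  the half-axis range that yields a target expected tumor-pixel fraction of
  breast tissue, so rare-prevalence ensembles (e.g. 0.22% of tissue area) can
  be configured directly.

## Wave simulation

`usct.wavesim` solves the first-order lossy acoustic system

    ∂u/∂t = −(1/ρ₀)∇p,   ∂ρ/∂t = −ρ₀∇·u + s,
    p = c²(1 + τ ∂t(−∇²)^{y/2−1} + η(−∇²)^{(y+1)/2−1})ρ

with τ = −2αc^{y−1}, η = 2αc^y tan(πy/2) (α converted from dB·MHz⁻ʸ·cm⁻¹ to
nepers), using a pseudospectral k-space scheme: spatial derivatives in the
Fourier domain with the temporal correction κ = sinc(c_ref k Δt/2),
c_ref = water SOS, which is exact for homogeneous lossless media. Numerical
choices that proved load-bearing:

* **Staggered derivative operators** (±h/2 spectral shifts). Without them the
  Nyquist modes excited by a point source are stationary and contaminate
  traces non-causally along the source axes.
* **Zero-sum source.** The Gaussian-modulated sinusoid (spectral peak at the
  configured center frequency; envelope σ = n_cycles/(4f)) is corrected to an
  exactly zero temporal sum; any residual DC drive leaves a static uniform
  pressure pedestal in the periodic domain. The k = 0 density mode is also
  removed when forming pressure.
* **PML.** Split-field exponential damping, quartic ramp, absorption scale
  α_pml = 2 (damping exp(−α_pml·(c_ref/h)·(d/D)⁴·Δt/2) applied twice per
  update). The PML needs ≥ 5–6 grid points per wavelength: at 3 points per
  wavelength boundary reflections reach several percent, at 6 they are
  < 0.1% of the direct arrival (verified against a double-size domain).
* **Presets.** Full scale: 256 elements on a 110 mm ring, 2560² grid at
  0.1 mm, Δt = 0.02 μs (Courant number 0.32 at c_max = 1.6), T = 170 μs, 4 mm
  PML, 1 MHz pulse. Desk scale: 64 elements on a 22 mm ring, 256² grid at
  0.25 mm, Δt = 0.05 μs, T = 42 μs — one emitter solves in a few seconds on
  one CPU, which is what the test suite uses.
* Sources and point receivers sit on nearest grid nodes; the measurement set
  records the snapped element positions, and all geometric references
  (homogeneous TOF, pick windows) use those effective positions.
* Measurement noise is i.i.d. Gaussian, calibrated per emitter so that the
  noiseless-signal-to-noise power ratio at the diagonally opposite receiver
  equals the requested SNR (36 dB by default).

## First-arrival picking

Traces are low-pass filtered (4th-order Butterworth, 1.5 MHz, applied
forward–backward so picks are not delayed), then picked inside a
±6 μs window around the homogeneous water traveltime with the AIC
changepoint: AIC(k) = k·ln var(x₁..ₖ) + (N−k−1)·ln var(xₖ₊₁..N), earliest
index on ties, variance floored at machine epsilon. Two refinements:

* The raw AIC pick latches where energy exceeds the local noise floor, which
  lags the geometric arrival by an amount that grows as amplitude drops. The
  pick is therefore sharpened to the (sub-sample, linearly interpolated)
  crossing of 25% of the local pulse peak — a time that depends only on pulse
  shape. With this refinement, picks on simulated water data track
  chord/c_w with a spread well under 0.1 sample, noiseless or at 36 dB SNR.
* The remaining constant pulse latency is measured once on a water-only
  calibration shot (`calibrate_onset_offset`) and subtracted before
  inversion. Shallow AIC minima (pure-noise windows) are flagged
  low-confidence rather than silently used.

## Bent-ray traveltime tomography

`usct.brtt` inverts picked TOFs for the slowness image b (reciprocal SOS)
under the box b ∈ [1/1.7, 1/1.3] μs/mm by a proximal Gauss–Newton method:

1. eikonal solve |∇T| = b per emitter — fast marching with second-order
   upwind differences (first-order fallback at the front) and an analytically
   initialized disk of radius 5 pixels around the point source; maximum
   radial error < 0.6% on a homogeneous 256² grid;
2. rays traced from each receiver to the emitter by steepest descent on T
   (bilinear gradient, half-pixel steps), per-pixel arclengths forming the
   sparse ray matrices L_m; predicted TOF is the line integral L_m b, which
   agrees with the eikonal field at the receivers to < 2%;
3. residuals d_m = t_m^obs − L_m b, gradient g = −Σ L_mᵀ d_m, stopping when
   the proximal gradient b − proj(b − g) falls below a relative tolerance
   (10⁻³ of its initial norm, an own default);
4. Gauss–Newton step from CGLS on the stacked ray matrices (12 inner
   iterations), projected-gradient fallback if it is not a descent direction;
5. backtracking μ ≤ 1 with the sufficient-descent test
   F(proj(b + μy)) ≤ F(b) + μ·gᵀy, which an exact linear least-squares step
   satisfies with equality; failure to descend returns the current iterate
   with a status flag rather than looping.

Residuals use the line-integral prediction L_m b for exact consistency
between the misfit, the gradient and the descent test; the eikonal field
enters through the ray geometry. Transducers map to reconstruction-grid
nodes by nearest neighbor. Invalid TOF entries (masked picks, failed rays)
are excluded from every sum.

## DAS reflection tomography

`usct.dasrt` forms f_k = Σ_m Σ_n a_{m,n} ĝ_{m,n}(T_m(r_k) + T_n(r_k)) with
one-way traveltime fields solved on the imaging grid from the BRTT slowness.
Traces are Wiener-deconvolved with the source pulse
(G·conj(S)/(|S|² + λ·max|S|²), λ = 10⁻² by default), which collapses echoes
toward band-limited impulses at their true two-way delays, and evaluated at
the delays with modified Akima (makima) interpolation; delays outside the
acquisition window contribute zero. The default apodization keeps each
emitter plus seven neighbors per side (15 receivers) — the backscatter
carriers; a literal central-angle-threshold mode is retained (note that a
threshold of 15π/128 rad on a 256-element ring admits 15 neighbors per
*side*, so the worked 15-receiver count is the default). A direct-arrival
mute (zeroing t < homogeneous TOF + pad) is provided because the transmitted
wave otherwise dominates near-emitter receivers. Because makima slopes are
data-dependent, DAS is exactly homogeneous of degree one in the data but
additive only to ~0.1% — the linearity tests budget for this.

## Learned reconstruction

`usct.iilr` implements the dual-channel U-Net on a compact pure-NumPy
neural-network engine (`usct.nn`: im2col convolutions, batch normalization,
2×2 average pooling, 2×2 stride-2 transposed convolutions, leaky ReLU 0.2,
Adam, triangular cyclic learning rate). The engine is deliberately
dependency-free and single-threaded-deterministic: given one seed, training
is bit-reproducible on CPU, which the test suite asserts. Gradients of every
layer are verified against finite differences.

* **Inputs/targets.** Channel T is the BRTT SOS minus the known per-sample
  water SOS; channel R is the DAS image scaled by its max-abs; the target is
  the true SOS minus water. Adding the water constant back at inference
  yields the estimate. Both inputs and targets live on the network grid
  (nearest-neighbor upscale of the reconstruction grids, center crop that
  removes the uniform bath).
* **Architecture.** n_blocks contracting blocks (batch norm before each 3×3
  convolution, leaky ReLU, 2×2 average pool), channels doubling from the
  base; mirrored expansion (2×2 transposed convolution, skip concatenation
  with the matching post-pool contracting feature, two convolutions); the
  shallowest expanding block has no skip; a linear 1×1 convolution forms the
  single output channel. At full scale (6 blocks, base 32, 2 inputs) this
  counts 31.13 M trainable parameters. The skip-from-post-pool reading is
  the accounting under which the convolution weights alone total
  31,113,792 ≈ 31.1 M.
* **Training.** MSE loss L(θ) = (1/2I)Σ‖𝒜_θ(xᵢ) − yᵢ‖²_F, Adam with a
  triangular cyclic schedule (full scale 10⁻² → 10⁻⁵ over 2000 iterations),
  on-the-fly augmentation by right-angle rotations and flips applied jointly
  to inputs, target and weight mask at a 1:3 non-augmented:augmented ratio
  (rotations are restricted to multiples of 90° so augmentation is
  grid-exact), best checkpoint by validation loss computed without
  augmentation. Divergent (non-finite) loss aborts with state information.
* **Tumor-weighted fine-tuning.** Starting from the MSE optimum, the WMSE
  loss multiplies the residual elementwise by W (0 in water, w > 1 inside
  square tumor ROIs, 1 elsewhere) with a reduced peak learning rate (10⁻³);
  selection by validation WMSE. Single-channel ablations (T-only, R-only)
  share the protocol with 1-channel inputs.

## Evaluation

`usct.evaltask` provides NRMSE = ‖C − C̄‖_F/‖C − C_w‖_F (region-restricted
variants mask both numerator and denominator — an interpretation choice,
documented here), SSIM with the standard constants (K1 = 0.01, K2 = 0.03,
11-pixel Gaussian window σ = 1.5) on images rescaled from [1.4, 1.6] to
[0, 1], PSNR on the same rescaling (+∞ sentinel for identical images), and
the two-sided Mann–Whitney U-test (exact for small untied samples). Tumor
ROIs are squares of side max(width, height) + 8 centered on each connected
tumor component; the normal-tissue mask is breast minus all ROIs; edge-
clipped ROIs are flagged.

The detection task is patch-based signal-known-stochastically /
background-known-stochastically classification: signal-present patches are
built around a randomly chosen tumor pixel (≥1 tumor pixel by construction),
signal-absent corners are rejection-sampled tumor-free. The numerical
observer is a CNN (three blocks of convolution, batch norm, leaky ReLU, 2×2
average pooling — 64 channels and 5×5 kernels at full scale — and a fully
connected sigmoid head) trained with cross-entropy on patches sampled on the
fly, best checkpoint by validation loss. ROC analysis is empirical
(trapezoidal AUC) with the Hanley–McNeil standard error; a two-parameter
binormal estimate Φ(a/√(1+b²)) is available as a secondary output. The
identity AUC = U/(n₁n₀) is cross-checked against the independent rank-sum
implementation in the tests.

## Desk-scale studies

`usct.studies` runs two ensemble experiments sized for one CPU:

* **Input-modality comparison.** ≥100 training phantoms (default 130 split
  100/10/20); dual-channel, reflectivity-only and traveltime-only models
  trained under one protocol; compared by mean test NRMSE. The expected
  outcome is a direction, not a number: the dual-channel model wins.
* **Tumor-weighted fine-tuning.** The dual-channel model fine-tuned at
  several w; tumor-ROI NRMSE should fall and normal-tissue NRMSE rise as w
  grows (again direction only).

To make ≥100 phantoms tractable, the studies generate their data with
ray-based forward models instead of the full wave solver: TOFs from the
package's own bent-ray predictor (eikonal + ray tracing on the true
slowness) plus Gaussian picking noise (σ = 0.02 μs), and backscatter traces
from a single-scattering (Born-type) model — impulses at the two-way
straight-ray water delays of impedance-gradient scatterers, convolved with
the pulse. Both streams then pass through the *real* reconstruction chain
(proximal GN BRTT; Wiener deconvolution + makima DAS). The learned models
therefore consume inputs with the same information structure as
wave-simulated data — a quantitative low-resolution channel and a
high-resolution boundary channel — but the studies do not exercise
multiple scattering, refraction mismatch between the true and assumed
delays, or attenuation-dependent amplitude effects. Desk geometry: 64²
phantoms at 1.25 mm, 32 elements on a 36 mm ring, BRTT on 32² at 2.5 mm
(6 GN iterations), DAS on 64² at 1.25 mm, network crop 48².

What passing these tests shows: the pipeline is wired correctly end to end,
the dual-channel advantage and the tumor/background trade-off of the
weighted loss reproduce **in direction** under a faithful small-scale
protocol. What it does not show: the absolute accuracy achievable at full
scale (the desk networks are far smaller and trained for minutes, so their
NRMSE values are much larger than a converged full-scale model would reach),
nor robustness to the wave-physics effects excluded by the ray-based data
generation.

## Known limitations

* 2-D only; idealized point transducers; no directivity or finite aperture.
* The density map enters the wave solver unsmoothed and unstaggered;
  strongly discontinuous density would deserve staggered-grid interpolation.
* The power-law dispersion term assumes y ≠ 2 (tan(πy/2) singular at even
  integers); y = 2 media should disable the dispersion correction.
* The Born echo generator of the studies uses water (straight-ray) delays to
  place echoes; DAS re-localizes them with BRTT-based delays, so a small
  systematic mislocation of deep reflectors is part of the study conditions.
* The NumPy network engine targets desk-scale problems; the full-scale
  configuration is instantiated for parameter accounting, but training it on
  592² images is outside this package's intended compute envelope.
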