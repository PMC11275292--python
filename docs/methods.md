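# Methods

## Processing model

All pipelines start from a real 4D raw interference volume `E[k, x, y, n]`
with K wavenumber samples, an X×Y lateral raster and N repeated scans per
location.

**FT-free structural path.** `Proj(x, y) = Σ_k E(x, y, k)` for one repeat.
The identity behind it is exact at the DFT level: the spectral sum is the
zero-frequency DFT coefficient of the A-line, i.e. the depth-integrated
signal power that an en-face projection displays. The sum is taken over raw
signed samples with no windowing, background subtraction or magnitude step
(an optional background-subtraction hook exists but is off by default); the
DC term is not a nuisance here — it carries the image. Output stays in
native float64; quantization (16-bit TIFF with percentile clipping) happens
only at export.

**FT-free angiography.** The N repeat projections form an N×X×Y stack,
flattened to an N×(X·Y) Casorati matrix with frames as rows (the only
orientation that yields the N×N correlation matrix the filter needs).

* Eigen-decomposition (ED) filter: `C = (1/N)·A·Aᴴ`, eigendecomposition
  with eigenvalues sorted decreasingly, removal of the top-r eigenvector
  subspace. The automatic rank is the count of eigenvalues strictly above
  their arithmetic mean; r = 0 (all equal, e.g. pure noise) is allowed and
  logged rather than forced to 1 — forcing removal would silently delete
  signal from clutter-free stacks. The filtered N-frame residual is
  collapsed to one map as the mean of absolute values over repeats: the
  protocol produces a single OCTA image per method, and mean-|·| is a
  symmetric, variance-like collapse that keeps the map nonnegative.
* Speckle variance (SV): per-pixel population variance (divisor N) across
  the repeats. Variance, not standard deviation, is reported — the output
  scaling follows the defining formula.

On this path the frames are real (summation destroys phase), so the
Hermitian transposes degrade to transposes; the implementation still
conjugates so the identical routines serve complex inputs.

**Traditional reference path.** Per A-line: subtract the mean over k
(minimal DC suppression; no spectral window — the acquisition model here
has a flat source envelope, so apodization would only blur the synthetic
fringes), unnormalized forward DFT, keep magnitudes of bins 1…K/2
(real detector signal; the negative-frequency mirror is redundant).
Structural projection is the depth sum. Angiography baselines: 3D speckle
variance (per-voxel variance over repeats, then depth-summed) and a
frame-wise eigen filter (per slow-axis position, the N repeated B-frames
form an N×(Z·X) Casorati matrix filtered exactly like the 2D case, then
collapsed and depth-summed). The frame-wise filter is a *generic* eigen
baseline: published per-A-scan/windowed eigen variants are distinct
algorithms and out of scope.

**Ground truth.** Structural: I(z) averaged over 12 repeats, then
depth-summed. Angiography: the frame-wise eigen baseline run on the
12-repeat reconstruction — a synthetic stand-in chosen because high-repeat
eigen filtering is the best extractor available in-repo; see Limitations.

**Down-sampling.** `downsample_volume_half` keeps every second spectral
sample starting from the first ("odd-numbered" in 1-based counting read as
keep-first-then-every-second). It emulates acquisition-time decimation and
is the only entry point for the "with down-sampling" variants. Halving K
halves the Nyquist depth; the default phantom confines scatterers below
K/4, so one decimation is loss-free apart from noise.

## Evaluation protocol

* MSE: `Σ(a−gt)²/(X·Y)`.
* PSNR: `10·log10(max(a)²/MSE)` — the peak is the *input image's* maximum,
  making PSNR data-dependent and asymmetric; this convention is locked in
  by a test, and a `peak=` override restores the usual constant. Identical
  images report an infinite sentinel rather than failing.
* SSIM: mean over sliding windows of `C_l^α·C_c^β·C_s^γ` with the standard
  stabilized luminance/contrast/structure terms, α=β=γ=1, Gaussian window
  σ=1.5 on an 11×11 support (uniform window available), K1=0.01, K2=0.03,
  C3=C2/2, dynamic range = ground-truth max−min unless given. Border
  pixels whose window leaves the image are excluded, which makes the
  implementation agree with the scikit-image reference parameterization to
  machine precision (cross-checked in a test). For non-unit exponents the
  possibly-negative structure term is exponentiated as sign(x)·|x|^γ to
  stay real; at γ=1 this is exact.
* Pipeline-level comparisons min-max normalize both images to [0, 1]
  first: maps from different methods carry arbitrary method-specific
  scales (variance vs. mean-residual vs. magnitude sums), so unnormalized
  MSE would measure scale, not structure. Raw-value metrics remain
  available with `normalize=False`.

Wall-clock per stage is logged and written to the JSON reports because
speed is the method's point, but no test or threshold ever depends on it.

## Synthetic acquisition model

Each A-line is

```
E(k_i) = B + g·Σ_j a_j(n)² + Σ_j a_j(n)·cos(2π·z_j·i/K + φ_j(n)) + ε_i
```

with integer depth bins z_j ∈ [1, depth_range·K/2), ε ~ N(0, σ²). The
`g·Σa²` term is the sample-power (autocorrelation) DC of interferometric
detection, |E_ref + E_s|² → P_ref + P_s + cross terms: it is what couples
per-pixel reflectivity into the spectral sum and hence what makes the
summation projection an image at all (the cross-term cosines of integer-bin
scatterers sum to exactly zero over a full sweep).

Static scatterers (default 3 per A-line, amplitudes uniform in [0.5, 1.5])
keep amplitude and phase across repeats; computed once and broadcast, so
noise-free static pixels are bit-identical over repeats. Vessel pixels
(tube/disk regions, ~10% of the default grid) add dynamic scatterers
(default 2) that redraw phase uniformly per repeat and jitter amplitude by
±30%: the phase redraw decorrelates the depth-resolved speckle the
traditional baselines see, the amplitude jitter modulates the sample-power
DC the FT-free path sees. Defaults: B=1, g=0.5, σ=0.1 (≈20 dB fringe SNR),
depth_range=0.5 — a bright, superficial, penetration-limited tissue block,
the regime the down-sampling argument assumes. Geometry defaults mirror a
realistic swept-source acquisition (768×400×400×4); tests and the
evaluation script use a 64×64, K=256, N=12 phantom so the full suite runs
in tens of seconds on one core.

Determinism: one `default_rng(seed)` drawn in a fixed order; identical
config + seed is bit-reproducible.

## What the phantom does and does not show

The phantom validates algebra and separability, not in-vivo image quality:

* Static clutter is *perfectly* static (no bulk motion, galvo jitter,
  dispersion or source-envelope structure — deliberately out of scope), so
  the repeat stack's clutter is exactly rank 1 and eigen filtering is
  ideal on it. On real tissue, clutter decorrelates and the phase loss of
  the FT-free path genuinely hurts ED filtering; the phantom cannot
  reproduce that penalty, and quality *rankings* between the angiography
  extractors measured on the phantom therefore do not transfer to real
  data. In particular, the 2D ED map scores above the variance-based maps
  against the in-repo eigen-family ground truth, whereas in-vivo studies
  report the opposite.
* Flow decorrelation is a stand-in (phase redraw + amplitude jitter), not
  a hemodynamic or speckle-statistics model.
* The OCTA ground truth is the package's own 12-repeat frame-wise eigen
  map, not an independently validated reference.

Structural-path conclusions are more robust: the traditional-vs-FT-free
fidelity gap, the down-sampling consistency and the summation identity all
reproduce at the printed tolerances.

## Numerical notes

* Eigendecomposition runs on the small N×N Hermitian Gram matrix
  (`numpy.linalg.eigh`), never on the (X·Y)² covariance; Gram accumulation
  uses `einsum` to stay BLAS-free and reproducible against explicit loops.
* Rank selection uses strict inequality against the mean; ties (all
  eigenvalues equal) give r=0.
* Degenerate inputs are rejected early with specific errors: odd K for
  decimation/FFT, N<2 for any angiography, r≥N, non-finite volumes,
  scatterers at or beyond the Nyquist depth, SSIM windows larger than the
  image.
* A constant image min-max normalizes to zero (no division by zero); zero
  MSE reports infinite PSNR.
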