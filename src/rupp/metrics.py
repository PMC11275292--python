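"""Image-quality metrics: MSE, PSNR and SSIM.

The evaluation protocol scores each fast projection against a
high-repeat ground-truth projection.  Two conventions are locked in
deliberately:

* PSNR uses the *input image's* maximum as the peak value,
  PSNR = 10 log10(max(a)^2 / MSE) — not a bit-depth constant — which
  makes PSNR data-dependent and asymmetric in its arguments.  A ``peak``
  override restores the conventional constant.
* SSIM is the windowed three-component product C_l^alpha C_c^beta
  C_s^gamma (luminance, contrast, structure) with the de-facto standard
  parameters: Gaussian window sigma=1.5 over an 11x11 support,
  stabilizers K1=0.01, K2=0.03, dynamic range taken from the ground
  truth unless given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

__all__ = [
    "MetricsReport",
    "mse",
    "psnr",
    "ssim",
    "normalize_minmax",
    "evaluate",
]


@dataclass
class MetricsReport:
    """One evaluation of a projection against ground truth.

    ``elapsed_seconds`` is informational wall-clock of the evaluated
    method (when measured by the pipeline); it is never asserted.
    """

    psnr: float
    ssim: float
    mse: float
    method: str = ""
    shape: tuple[int, int] | None = None
    elapsed_seconds: float | None = None

    def to_dict(self) -> dict:
        return {
            "psnr": self.psnr,
            "ssim": self.ssim,
            "mse": self.mse,
            "method": self.method,
            "shape": list(self.shape) if self.shape else None,
            "elapsed_seconds": self.elapsed_seconds,
        }


def _check_pair(a: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if a.shape != gt.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {gt.shape}")
    return a, gt


def mse(a: np.ndarray, gt: np.ndarray) -> float:
    """Mean square error, sum((a - gt)^2) / (X*Y)."""
    a, gt = _check_pair(a, gt)
    return float(np.mean((a - gt) ** 2))


def psnr(a: np.ndarray, gt: np.ndarray, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB against a ground-truth image.

    The peak defaults to the maximum of the input image ``a`` (the
    protocol's stated convention); identical images yield ``inf``.
    """
    a, gt = _check_pair(a, gt)
    err = mse(a, gt)
    if peak is None:
        peak = float(np.max(a))
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / err))


def _signed_power(x: np.ndarray, p: float) -> np.ndarray:
    """sign(x)*|x|^p — keeps fractional exponents real for the structure
    term, which can be negative; reduces to x when p == 1."""
    if p == 1.0:
        return x
    return np.sign(x) * np.abs(x) ** p


def ssim(
    a: np.ndarray,
    gt: np.ndarray,
    alpha: float = 1.0,
    beta: float = 1.0,
    gamma: float = 1.0,
    window: str = "gaussian",
    win_size: int = 11,
    sigma: float = 1.5,
    K1: float = 0.01,
    K2: float = 0.03,
    data_range: float | None = None,
) -> float:
    """Structural similarity index between two images.

    Mean over sliding windows of C_l^alpha * C_c^beta * C_s^gamma where

        C_l = (2 mu_a mu_g + C1) / (mu_a^2 + mu_g^2 + C1)
        C_c = (2 s_a s_g + C2) / (s_a^2 + s_g^2 + C2)
        C_s = (cov + C3) / (s_a s_g + C3),  C3 = C2 / 2

    with weighted local means/variances/covariance from either a
    Gaussian window (sigma, truncated to ``win_size``) or a uniform
    ``win_size`` x ``win_size`` window.  C1 = (K1*L)^2, C2 = (K2*L)^2
    where L is ``data_range`` (ground-truth max - min by default).
    Border pixels whose window leaves the image are excluded.
    """
    a, gt = _check_pair(a, gt)
    if alpha <= 0 or beta <= 0 or gamma <= 0:
        raise ValueError("SSIM exponents must be positive")
    if win_size % 2 == 0 or win_size < 3:
        raise ValueError("win_size must be odd and >= 3")
    if min(a.shape) < win_size:
        raise ValueError(
            f"window size {win_size} exceeds image extent {min(a.shape)}"
        )
    if data_range is None:
        data_range = float(gt.max() - gt.min())
        if data_range == 0.0:
            data_range = float(np.abs(gt).max()) or 1.0

    radius = (win_size - 1) // 2
    if window == "gaussian":
        truncate = radius / sigma

        def filt(img: np.ndarray) -> np.ndarray:
            return gaussian_filter(img, sigma=sigma, truncate=truncate)

    elif window == "uniform":

        def filt(img: np.ndarray) -> np.ndarray:
            return uniform_filter(img, size=win_size)

    else:
        raise ValueError(f"unknown window {window!r}")

    ua = filt(a)
    ug = filt(gt)
    uaa = filt(a * a)
    ugg = filt(gt * gt)
    uag = filt(a * gt)
    va = uaa - ua * ua
    vg = ugg - ug * ug
    cov = uag - ua * ug
    # weighted variances are nonnegative up to rounding
    sa = np.sqrt(np.maximum(va, 0.0))
    sg = np.sqrt(np.maximum(vg, 0.0))

    C1 = (K1 * data_range) ** 2
    C2 = (K2 * data_range) ** 2
    C3 = C2 / 2.0
    Cl = (2.0 * ua * ug + C1) / (ua**2 + ug**2 + C1)
    Cc = (2.0 * sa * sg + C2) / (sa**2 + sg**2 + C2)
    Cs = (cov + C3) / (sa * sg + C3)

    smap = _signed_power(Cl, alpha) * _signed_power(Cc, beta) * _signed_power(Cs, gamma)
    crop = smap[radius:-radius, radius:-radius] if radius else smap
    return float(crop.mean())


def normalize_minmax(img: np.ndarray) -> np.ndarray:
    """Affine rescale of an image to [0, 1]; a constant image maps to 0."""
    img = np.asarray(img, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def evaluate(
    a: np.ndarray,
    gt: np.ndarray,
    method: str = "",
    normalize: bool = True,
    elapsed_seconds: float | None = None,
    **ssim_kwargs,
) -> MetricsReport:
    """Score a projection against ground truth.

    By default both images are min-max normalized to [0, 1] first:
    projections from different pipelines carry arbitrary, method-specific
    scales and offsets, so fidelity is compared on their common
    normalized range (the dynamic range and PSNR peak are then 1).
    """
    a, gt = _check_pair(a, gt)
    if normalize:
        a = normalize_minmax(a)
        gt = normalize_minmax(gt)
    return MetricsReport(
        psnr=psnr(a, gt),
        ssim=ssim(a, gt, **ssim_kwargs),
        mse=mse(a, gt),
        method=method,
        shape=a.shape,  # type: ignore[arg-type]
        elapsed_seconds=elapsed_seconds,
    )
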