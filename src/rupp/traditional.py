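"""Traditional FFT-based reference pipeline.

The conventional FD-OCT route: per-A-line DFT turns the spectral
interferogram E(k) into a depth-resolved intensity profile I(z); depth
summation of I(z) gives the structural en-face projection; volume-level
angiography baselines (3D speckle variance, frame-wise eigen filtering)
operate on the reconstructed intensity before the depth collapse.  A
high-repeat average provides the ground-truth projections that the fast
pipelines are scored against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angio import AngioProjection, eigen_clutter_filter
from .projection import StructuralProjection
from .volume import RawVolume

__all__ = [
    "IntensityVolume",
    "GroundTruthProjection",
    "fft_reconstruct",
    "traditional_summation_projection",
    "ground_truth_structural",
    "ground_truth_angio",
    "sv3d",
    "frame_ed",
    "GROUND_TRUTH_REPEATS",
]

#: repeats averaged for ground-truth generation
GROUND_TRUTH_REPEATS = 12


@dataclass
class IntensityVolume:
    """Z x X x Y x N reconstructed intensity magnitudes, Z = K/2."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"intensity volume must be 4D, got {self.data.shape}")
        if np.any(self.data < 0):
            raise ValueError("intensity magnitudes must be nonnegative")

    @property
    def Z(self) -> int:
        return self.data.shape[0]

    @property
    def N(self) -> int:
        return self.data.shape[3]


@dataclass
class GroundTruthProjection:
    """Structural projection averaged over a high-repeat acquisition."""

    values: np.ndarray
    n_repeats_used: int = GROUND_TRUTH_REPEATS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ground-truth projection must be 2D")


def fft_reconstruct(vol: RawVolume) -> IntensityVolume:
    """A-line reconstruction: I(z) = |F{E(k) - mean_k E}|, z = 1..K/2.

    The per-A-line mean is subtracted first (DC/background removal, the
    minimal step that keeps the zero bin from dominating every depth
    sum), then an unnormalized forward DFT is applied along k and the
    magnitudes of the positive-frequency bins 1..K/2 are kept as the
    depth profile.
    """
    if vol.K % 2 != 0:
        raise ValueError(f"K must be even, got {vol.K}")
    E = vol.data
    Em = E - E.mean(axis=0, keepdims=True)
    spectrum = np.fft.fft(Em, axis=0)
    intensity = np.abs(spectrum[1 : vol.K // 2 + 1])
    return IntensityVolume(intensity)


def traditional_summation_projection(
    ivol: IntensityVolume, repeat_index: int = 0
) -> StructuralProjection:
    """Depth-summed structural projection, Proj(x, y) = sum_z I(z)."""
    if not 0 <= repeat_index < ivol.N:
        raise IndexError(f"repeat_index {repeat_index} out of range for N={ivol.N}")
    values = ivol.data[:, :, :, repeat_index].sum(axis=0)
    return StructuralProjection(values, source="traditional")


def ground_truth_structural(
    vol: RawVolume, n_repeats: int = GROUND_TRUTH_REPEATS
) -> GroundTruthProjection:
    """Ground-truth structural projection from a high-repeat acquisition.

    The per-A-line intensity I(z) is averaged over the first ``n_repeats``
    repeats (12 by default; multi-repeat averaging suppresses noise),
    then depth-summed like any structural projection.
    """
    if vol.N < n_repeats:
        raise ValueError(
            f"ground truth needs at least {n_repeats} repeats, volume has N={vol.N}"
        )
    ivol = fft_reconstruct(vol.subset_repeats(n_repeats))
    mean_intensity = ivol.data.mean(axis=3)  # (Z, X, Y)
    values = mean_intensity.sum(axis=0)
    return GroundTruthProjection(values, n_repeats_used=n_repeats)


def sv3d(ivol: IntensityVolume) -> AngioProjection:
    """Traditional 3D speckle-variance angiography.

    Per-voxel population variance of the reconstructed intensity across
    the N repeats, then depth-summed to an en-face map.
    """
    if ivol.N < 2:
        raise ValueError("speckle variance requires N >= 2")
    mean = ivol.data.mean(axis=3, keepdims=True)
    var = ((ivol.data - mean) ** 2).mean(axis=3)  # (Z, X, Y)
    return AngioProjection(var.sum(axis=0), method="sv3d")


def frame_ed(ivol: IntensityVolume, r: int | str = "auto") -> AngioProjection:
    """Frame-wise eigen-decomposition angiography baseline.

    For each slow-axis position y the N repeated B-frames are flattened
    to an N x (Z*X) Casorati matrix, clutter-filtered by removing the
    dominant eigenvector subspace (automatic rank by default), collapsed
    over repeats as mean absolute residual, and depth-summed to one row
    of the en-face map.

    This is a generic frame-wise eigen baseline; published windowed or
    per-A-scan eigen variants are separate algorithms and intentionally
    not reimplemented here.
    """
    if ivol.N < 2:
        raise ValueError("eigen filtering requires N >= 2")
    Z, X, Y, N = ivol.data.shape
    out = np.empty((X, Y), dtype=np.float64)
    for y in range(Y):
        frames = ivol.data[:, :, y, :]  # (Z, X, N)
        cas = np.moveaxis(frames, -1, 0).reshape(N, Z * X)
        residual, _, _, _, _ = eigen_clutter_filter(cas, r)
        collapsed = np.abs(residual).mean(axis=0).reshape(Z, X)
        out[:, y] = collapsed.sum(axis=0)
    return AngioProjection(out, method="frame_ed")


def ground_truth_angio(
    vol: RawVolume, n_repeats: int = GROUND_TRUTH_REPEATS
) -> AngioProjection:
    """Synthetic stand-in OCTA ground truth: the frame-wise eigen baseline
    run on a high-repeat (12 by default) reconstruction.

    High-repeat eigen filtering gives high-quality angiography extraction;
    the windowed eigen variant used for in-vivo references elsewhere is
    out of scope, so this stand-in is the repository's reference map.
    """
    if vol.N < n_repeats:
        raise ValueError(
            f"angio ground truth needs at least {n_repeats} repeats, "
            f"volume has N={vol.N}"
        )
    ivol = fft_reconstruct(vol.subset_repeats(n_repeats))
    out = frame_ed(ivol, r="auto")
    return AngioProjection(out.values, method="ground_truth_ed")
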