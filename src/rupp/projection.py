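"""FT-free structural projections.

The en-face structural image of an FD-OCT volume is conventionally the
depth sum of the reconstructed intensity signal, sum_z I(z).  Because the
raw interferogram E(k) is a superposition of periodic fringes, the
Poisson summation argument equates sum_z I(z) with the plain spectral sum
sum_k E(k) — so a structural projection can be formed by summing the raw
detector samples directly, skipping the Fourier transform entirely.
Equivalently: sum_k E(k) is exactly the zero-frequency DFT coefficient
of the interferogram, the depth-integrated power the en-face image shows.

This module is the summation-only path: no Fourier transform is invoked
anywhere in it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import RawVolume

__all__ = [
    "StructuralProjection",
    "ProjectionStack",
    "rupp_structural_projection",
    "rupp_projection_stack",
]


@dataclass
class StructuralProjection:
    """X x Y en-face structural map Proj(x, y)."""

    values: np.ndarray
    source: str = "rupp"  # rupp | traditional | ground_truth
    downsampled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"projection must be 2D, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("projection contains non-finite values")


@dataclass
class ProjectionStack:
    """N x X x Y stack of repeat-resolved structural projections.

    Frame n is the structural projection of repeat n, in acquisition
    order.  Semantically each frame is the sum of a static clutter
    component, an angiography component that varies over repeats, and
    noise; the angiography extractors in :mod:`rupp.angio` separate them.
    """

    frames: np.ndarray
    source: str = "rupp"
    downsampled: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"stack must be 3D (N, X, Y), got {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("projection stack needs at least 2 repeats")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("projection stack contains non-finite values")

    @property
    def N(self) -> int:
        return self.frames.shape[0]

    @property
    def lateral_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]


def rupp_structural_projection(
    vol: RawVolume,
    repeat_index: int = 0,
    background: np.ndarray | float | None = None,
) -> StructuralProjection:
    """Structural projection by direct spectral summation.

    Proj(x, y) = sum_k E_{x,y}(k) for the selected repeat (0-based).

    Parameters
    ----------
    vol
        Raw interference volume.
    repeat_index
        Which repeat to project, 0-based.
    background
        Optional reference/background spectrum (scalar, or K-vector, or a
        full (K, X, Y) field) subtracted before summation.  Off by
        default: the bare sum is the method; the DC term carries the
        depth-integrated power that forms the image.
    """
    aline = vol.repeat(repeat_index)
    if background is not None:
        bg = np.asarray(background, dtype=np.float64)
        if bg.ndim == 1:
            bg = bg[:, None, None]
        aline = aline - bg
    values = aline.sum(axis=0)
    return StructuralProjection(values, source="rupp", downsampled=vol.downsampled)


def rupp_projection_stack(vol: RawVolume) -> ProjectionStack:
    """Repeat-resolved stack of summation projections, acquisition order."""
    if vol.N < 2:
        raise ValueError(
            f"angiography requires at least 2 repeats, volume has N={vol.N}"
        )
    frames = vol.data.sum(axis=0)  # (X, Y, N)
    frames = np.moveaxis(frames, -1, 0)
    return ProjectionStack(frames, source="rupp", downsampled=vol.downsampled)
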