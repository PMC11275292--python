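"""Raw FD-OCT interference volumes.

A swept-source acquisition is a 4D real array ordered (K, X, Y, N):
wavenumber samples along the sweep, fast and slow lateral scan axes, and
repeated scans at the same location.  The raw volume is the sole measured
input of every pipeline in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RawVolume:
    """K x X x Y x N real interference samples.

    Parameters
    ----------
    data
        Real detector samples, axis order fixed as
        (wavenumber, fast lateral, slow lateral, repeat).
    center_wavelength_nm, sweep_rate_hz
        Optional acquisition metadata; carried through I/O but never used
        by any computation.
    downsampled
        True if the volume was produced by :func:`rupp.simulate.downsample_volume_half`.
    """

    data: np.ndarray
    center_wavelength_nm: float | None = None
    sweep_rate_hz: float | None = None
    downsampled: bool = False
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"raw volume must be 4D (K, X, Y, N), got shape {self.data.shape}"
            )
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("raw volume contains non-finite samples")

    @property
    def K(self) -> int:
        return self.data.shape[0]

    @property
    def X(self) -> int:
        return self.data.shape[1]

    @property
    def Y(self) -> int:
        return self.data.shape[2]

    @property
    def N(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def repeat(self, repeat_index: int) -> np.ndarray:
        """Return the (K, X, Y) sub-volume of one repeat (0-based index)."""
        if not 0 <= repeat_index < self.N:
            raise IndexError(
                f"repeat_index {repeat_index} out of range for N={self.N}"
            )
        return self.data[:, :, :, repeat_index]

    def subset_repeats(self, n: int) -> "RawVolume":
        """Keep only the first ``n`` repeats (acquisition order preserved)."""
        if not 1 <= n <= self.N:
            raise ValueError(f"cannot take {n} repeats from a volume with N={self.N}")
        return RawVolume(
            self.data[:, :, :, :n],
            center_wavelength_nm=self.center_wavelength_nm,
            sweep_rate_hz=self.sweep_rate_hz,
            downsampled=self.downsampled,
            attrs=dict(self.attrs),
        )
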