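"""Synthetic swept-source OCT interferogram simulator.

Generates raw interference volumes with known structure and flow so the
projection pipelines can be exercised and scored against ground truth.
Each A-line is a sum of cosine fringes from a handful of discrete
scatterers plus a DC term and additive white Gaussian detector noise:

    E_{x,y,n}(k_i) = B + g * sum_j a_j(n)^2
                       + sum_j a_j(n) * cos(2*pi * z_j * i / K + phi_j(n))
                       + eps_i,     eps_i ~ N(0, sigma^2)

where i = 0..K-1 indexes the wavenumber sweep and z_j is the scatterer's
integer depth bin (the magnitude DFT of a noise-free A-line peaks at bin
z_j).  B is the reference-arm background and the ``g * sum a^2`` term is
the sample-power (autocorrelation) contribution of interferometric
detection, |E_ref + E_s|^2 -> P_ref + P_s + cross terms: it is this
per-pixel DC component that a plain spectral summation integrates into a
structural image.

Static scatterers keep (a_j, phi_j) fixed across the N repeats; dynamic
scatterers inside the configured vessel regions redraw their phase
uniformly per repeat and jitter their amplitude, emulating the temporal
decorrelation of moving blood cells that angiography reconstruction
exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .volume import RawVolume

__all__ = [
    "Disk",
    "Tube",
    "SimConfig",
    "PhantomTruth",
    "simulate_volume",
    "downsample_volume_half",
    "default_vessel_spec",
    "default_test_config",
]


# --------------------------------------------------------------------------
# vessel geometry


@dataclass(frozen=True)
class Disk:
    """Circular dynamic region (a vessel cross-section) in the X-Y plane."""

    cx: float
    cy: float
    radius: float

    def mask(self, X: int, Y: int) -> np.ndarray:
        xx, yy = np.meshgrid(np.arange(X), np.arange(Y), indexing="ij")
        return (xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.radius**2


@dataclass(frozen=True)
class Tube:
    """Straight vessel running across the full grid along one lateral axis.

    ``axis`` is the axis the tube runs *along* ('x' or 'y'); ``center`` and
    ``half_width`` position it on the perpendicular axis.
    """

    axis: str
    center: float
    half_width: float

    def mask(self, X: int, Y: int) -> np.ndarray:
        if self.axis not in ("x", "y"):
            raise ValueError(f"tube axis must be 'x' or 'y', got {self.axis!r}")
        out = np.zeros((X, Y), dtype=bool)
        if self.axis == "x":
            coord = np.arange(Y)
            sel = np.abs(coord - self.center) <= self.half_width
            out[:, sel] = True
        else:
            coord = np.arange(X)
            sel = np.abs(coord - self.center) <= self.half_width
            out[sel, :] = True
        return out


VesselShape = Disk | Tube


def default_vessel_spec(X: int, Y: int) -> tuple[VesselShape, ...]:
    """A simple vascular layout scaled to the grid: two crossing straight
    vessels plus two round vessel cross-sections (~10% of pixels)."""
    return (
        Tube("x", center=0.3 * Y, half_width=max(1.0, 0.02 * Y)),
        Tube("y", center=0.65 * X, half_width=max(1.0, 0.02 * X)),
        Disk(cx=0.25 * X, cy=0.7 * Y, radius=max(2.0, 0.06 * min(X, Y))),
        Disk(cx=0.8 * X, cy=0.2 * Y, radius=max(2.0, 0.05 * min(X, Y))),
    )


def _rasterize(shapes: tuple[VesselShape, ...], X: int, Y: int) -> np.ndarray:
    mask = np.zeros((X, Y), dtype=bool)
    for s in shapes:
        m = s.mask(X, Y)
        if m.shape != (X, Y):
            raise ValueError("vessel region mask has wrong shape")
        mask |= m
    return mask


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class SimConfig:
    """Simulator configuration.

    Defaults mirror a realistic in-vivo swept-source acquisition geometry:
    768 wavenumber samples, a 400x400 lateral raster and 4 repeats.  Tests
    override the lateral grid down to 32x32.

    Attributes
    ----------
    K, X, Y, N
        Volume geometry (wavenumber samples, lateral grid, repeats).
    n_static_scatterers
        Static tissue scatterers per A-line.
    n_dynamic_scatterers
        Dynamic (flow) scatterers added per vessel pixel.
    depth_range
        Fraction of the Nyquist depth K/2 that scatterers may occupy.
        The default 0.5 confines them to the superficial lower half of the
        imaging depth, where penetration-limited tissue signal lives.
    dc_offset
        Reference-arm background level B (>= 0).
    sample_dc_gain
        Gain g of the per-pixel sample-power DC term g * sum_j a_j^2.
    amplitude_range
        Uniform draw range for fringe amplitudes a_j.
    vessels
        Geometric dynamic regions; ``None`` selects
        :func:`default_vessel_spec`, ``()`` disables flow entirely.
    dynamic_amplitude_jitter
        Fractional uniform amplitude jitter of dynamic scatterers per
        repeat: a_j(n) = a_j * (1 + jitter * U(-1, 1)).
    dynamic_phase_mode
        'redraw' (uniform random phase per repeat, full decorrelation) or
        'fixed' (phase frozen; only amplitude jitter varies).
    noise_sigma
        Additive white Gaussian noise standard deviation on detector samples.
    seed
        Seed for all randomness; identical seed + config is bit-reproducible.
    """

    K: int = 768
    X: int = 400
    Y: int = 400
    N: int = 4
    n_static_scatterers: int = 3
    n_dynamic_scatterers: int = 2
    depth_range: float = 0.5
    dc_offset: float = 1.0
    sample_dc_gain: float = 0.5
    amplitude_range: tuple[float, float] = (0.5, 1.5)
    vessels: tuple[VesselShape, ...] | None = None
    dynamic_amplitude_jitter: float = 0.3
    dynamic_phase_mode: str = "redraw"
    noise_sigma: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 8 or self.K % 2 != 0:
            raise ValueError(f"K must be even and >= 8, got {self.K}")
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if self.X < 1 or self.Y < 1:
            raise ValueError("X and Y must be >= 1")
        if self.dc_offset < 0:
            raise ValueError("dc_offset must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.dynamic_phase_mode not in ("redraw", "fixed"):
            raise ValueError("dynamic_phase_mode must be 'redraw' or 'fixed'")
        if not 0 < self.depth_range:
            raise ValueError("depth_range must be positive")
        # scatterer depths live in [1, depth_range*K/2); anything at or
        # beyond the Nyquist depth K/2 would alias
        if self.max_depth_bin() >= self.K // 2:
            raise ValueError(
                f"depth_range {self.depth_range} places scatterers at or beyond "
                f"the Nyquist depth bin {self.K // 2} (aliasing misconfiguration)"
            )
        if (self.n_static_scatterers or self.n_dynamic_scatterers) and (
            self.max_depth_bin() < 2
        ):
            raise ValueError("depth range too shallow: no valid depth bins")

    def max_depth_bin(self) -> int:
        """Exclusive upper bound of scatterer depth bins."""
        return math.ceil(self.depth_range * self.K / 2)

    def resolved_vessels(self) -> tuple[VesselShape, ...]:
        if self.vessels is None:
            return default_vessel_spec(self.X, self.Y)
        return self.vessels


def default_test_config(seed: int = 0, **overrides) -> SimConfig:
    """The default seeded phantom used throughout tests and evaluation:
    a 64x64 lateral grid with K=256 and N=4."""
    base = SimConfig(K=256, X=64, Y=64, N=4, seed=seed)
    return replace(base, **overrides) if overrides else base


# --------------------------------------------------------------------------
# ground truth


@dataclass
class PhantomTruth:
    """Simulator ground truth for parameter-recovery tests.

    ``reflectivity_map`` is the per-pixel sum of scatterer amplitudes
    (static plus base dynamic); ``vessel_mask`` is True exactly where at
    least one dynamic scatterer exists.  The per-pixel scatterer layout is
    retrievable through :meth:`scatterer_table`.
    """

    reflectivity_map: np.ndarray
    vessel_mask: np.ndarray
    static_depths: np.ndarray  # (X, Y, Js) int
    static_amplitudes: np.ndarray  # (X, Y, Js)
    dynamic_depths: np.ndarray  # (X, Y, Jd) int; valid only inside vessel_mask
    dynamic_amplitudes: np.ndarray  # (X, Y, Jd)

    def __post_init__(self) -> None:
        if np.any(self.reflectivity_map < 0):
            raise ValueError("reflectivity map must be nonnegative")

    def scatterer_table(self, x: int, y: int) -> list[tuple[int, float, bool]]:
        """List of (depth bin, amplitude, is_dynamic) at pixel (x, y)."""
        rows = [
            (int(z), float(a), False)
            for z, a in zip(self.static_depths[x, y], self.static_amplitudes[x, y])
        ]
        if self.vessel_mask[x, y]:
            rows += [
                (int(z), float(a), True)
                for z, a in zip(
                    self.dynamic_depths[x, y], self.dynamic_amplitudes[x, y]
                )
            ]
        return rows


# --------------------------------------------------------------------------
# forward model


def simulate_volume(config: SimConfig) -> tuple[RawVolume, PhantomTruth]:
    """Generate a raw interference volume and its ground truth.

    The static fringe field is computed once and broadcast over repeats, so
    with ``noise_sigma=0`` static pixels are bit-identical across repeats.
    All randomness derives from ``config.seed``.
    """
    K, X, Y, N = config.K, config.X, config.Y, config.N
    Js, Jd = config.n_static_scatterers, config.n_dynamic_scatterers
    rng = np.random.default_rng(config.seed)
    zhi = config.max_depth_bin()
    lo, hi = config.amplitude_range

    vessel_mask = _rasterize(config.resolved_vessels(), X, Y)

    # draw layout up front in a fixed order (determinism contract)
    z_s = rng.integers(1, zhi, size=(X, Y, Js)) if Js else np.zeros((X, Y, 0), int)
    a_s = rng.uniform(lo, hi, size=(X, Y, Js))
    p_s = rng.uniform(0, 2 * np.pi, size=(X, Y, Js))
    z_d = rng.integers(1, zhi, size=(X, Y, Jd)) if Jd else np.zeros((X, Y, 0), int)
    a_d = rng.uniform(lo, hi, size=(X, Y, Jd))
    p_d0 = rng.uniform(0, 2 * np.pi, size=(X, Y, Jd))

    k = np.arange(K, dtype=np.float64)
    w = 2.0 * np.pi / K

    # static field (K, X, Y): DC + fringes, identical for every repeat
    static = np.full((X, Y), config.dc_offset, dtype=np.float64)
    static = static + config.sample_dc_gain * (a_s**2).sum(axis=-1)
    static = np.broadcast_to(static, (K, X, Y)).copy()
    for j in range(Js):
        phase = w * k[:, None, None] * z_s[None, :, :, j] + p_s[None, :, :, j]
        static += a_s[None, :, :, j] * np.cos(phase)

    data = np.empty((K, X, Y, N), dtype=np.float64)
    has_flow = Jd > 0 and vessel_mask.any()
    maskf = vessel_mask.astype(np.float64)
    for n in range(N):
        frame = static.copy()
        if has_flow:
            if config.dynamic_phase_mode == "redraw":
                p_dn = rng.uniform(0, 2 * np.pi, size=(X, Y, Jd))
            else:
                p_dn = p_d0
            if config.dynamic_amplitude_jitter > 0:
                u = rng.uniform(-1.0, 1.0, size=(X, Y, Jd))
                a_dn = a_d * (1.0 + config.dynamic_amplitude_jitter * u)
            else:
                a_dn = a_d
            dyn = np.zeros((K, X, Y), dtype=np.float64)
            dyn += config.sample_dc_gain * (a_dn**2).sum(axis=-1)[None, :, :]
            for j in range(Jd):
                phase = w * k[:, None, None] * z_d[None, :, :, j] + p_dn[None, :, :, j]
                dyn += a_dn[None, :, :, j] * np.cos(phase)
            frame += dyn * maskf[None, :, :]
        data[:, :, :, n] = frame

    if config.noise_sigma > 0:
        data += rng.normal(0.0, config.noise_sigma, size=data.shape)

    reflectivity = a_s.sum(axis=-1) + a_d.sum(axis=-1) * maskf
    truth = PhantomTruth(
        reflectivity_map=reflectivity,
        vessel_mask=vessel_mask,
        static_depths=z_s,
        static_amplitudes=a_s,
        dynamic_depths=z_d,
        dynamic_amplitudes=a_d,
    )
    vol = RawVolume(
        data,
        center_wavelength_nm=1300.0,
        attrs={"seed": config.seed},
    )
    return vol, truth


def downsample_volume_half(vol: RawVolume) -> RawVolume:
    """Keep every second wavenumber sample, starting from the first.

    Emulates acquisition-time down-sampling in which only odd-numbered
    (1-based) detector samples are stored; halves the spectral axis and
    with it the Nyquist depth, leaving the lateral and repeat axes
    untouched.  This is the only entry point for the "with down-sampling"
    pipeline variants.
    """
    if vol.K % 2 != 0:
        raise ValueError(f"K must be even to down-sample by half, got K={vol.K}")
    return RawVolume(
        vol.data[::2].copy(),
        center_wavelength_nm=vol.center_wavelength_nm,
        sweep_rate_hz=vol.sweep_rate_hz,
        downsampled=True,
        attrs=dict(vol.attrs),
    )
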