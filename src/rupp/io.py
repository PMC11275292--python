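"""Volume and image I/O.

Raw volumes (and optional phantom ground truth) live in an HDF5
container: dataset ``raw`` with attributes K/X/Y/N plus acquisition
metadata, datasets ``reflectivity`` and ``vessel_mask`` alongside when a
simulator truth is saved.  Projections are exported as 16-bit TIFF for
display (percentile-clipped) or 32-bit float TIFF for lossless
round-tripping.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .simulate import PhantomTruth
from .volume import RawVolume

__all__ = [
    "VolumeFormatError",
    "write_volume",
    "read_volume",
    "read_truth",
    "write_projection_tiff",
    "read_projection_tiff",
]


class VolumeFormatError(ValueError):
    """A volume container is missing datasets, malformed or inconsistent."""


def write_volume(
    vol: RawVolume,
    path: str | Path,
    truth: PhantomTruth | None = None,
    config_echo: dict | None = None,
) -> None:
    """Write a raw volume (and optional phantom truth) to an HDF5 file."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("raw", data=vol.data)
        ds.attrs["K"], ds.attrs["X"], ds.attrs["Y"], ds.attrs["N"] = vol.shape
        ds.attrs["downsampled"] = vol.downsampled
        if vol.center_wavelength_nm is not None:
            ds.attrs["center_wavelength_nm"] = vol.center_wavelength_nm
        if vol.sweep_rate_hz is not None:
            ds.attrs["sweep_rate_hz"] = vol.sweep_rate_hz
        for key, val in vol.attrs.items():
            ds.attrs[key] = val
        if config_echo is not None:
            ds.attrs["config_echo"] = json.dumps(config_echo)
        if truth is not None:
            f.create_dataset("reflectivity", data=truth.reflectivity_map)
            f.create_dataset("vessel_mask", data=truth.vessel_mask)


def read_volume(path: str | Path) -> RawVolume:
    """Read a raw volume, validating shape against its declared attributes."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise VolumeFormatError(f"cannot open volume container {path}: {exc}") from exc
    with f:
        if "raw" not in f:
            raise VolumeFormatError(f"{path}: missing dataset 'raw'")
        ds = f["raw"]
        data = np.asarray(ds)
        if data.ndim != 4:
            raise VolumeFormatError(
                f"{path}: dataset 'raw' must be 4D (K, X, Y, N) including the "
                f"repeat axis, got shape {data.shape}"
            )
        declared = tuple(
            int(ds.attrs[key]) for key in ("K", "X", "Y", "N") if key in ds.attrs
        )
        if len(declared) == 4 and declared != data.shape:
            raise VolumeFormatError(
                f"{path}: declared shape {declared} does not match stored "
                f"shape {data.shape}"
            )
        extra = {
            k: v
            for k, v in ds.attrs.items()
            if k
            not in {
                "K",
                "X",
                "Y",
                "N",
                "downsampled",
                "center_wavelength_nm",
                "sweep_rate_hz",
                "config_echo",
            }
        }
        return RawVolume(
            data,
            center_wavelength_nm=ds.attrs.get("center_wavelength_nm"),
            sweep_rate_hz=ds.attrs.get("sweep_rate_hz"),
            downsampled=bool(ds.attrs.get("downsampled", False)),
            attrs={k: (v.item() if hasattr(v, "item") else v) for k, v in extra.items()},
        )


def read_truth(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read (reflectivity_map, vessel_mask) saved next to a simulated volume."""
    with h5py.File(path, "r") as f:
        if "reflectivity" not in f or "vessel_mask" not in f:
            raise VolumeFormatError(f"{path}: no phantom truth datasets present")
        return np.asarray(f["reflectivity"]), np.asarray(f["vessel_mask"]).astype(bool)


def write_projection_tiff(
    values: np.ndarray,
    path: str | Path,
    mode: str = "uint16",
    clip_percentiles: tuple[float, float] = (0.1, 99.9),
    png_preview: str | Path | None = None,
) -> None:
    """Export a projection as TIFF.

    ``mode='float32'`` stores the unquantized values for round-tripping;
    ``mode='uint16'`` percentile-clips and rescales to the full 16-bit
    display range.  An optional 8-bit PNG preview can be written too.
    """
    values = np.asarray(values, dtype=np.float64)
    if mode == "float32":
        tifffile.imwrite(path, values.astype(np.float32))
    elif mode == "uint16":
        lo, hi = np.percentile(values, clip_percentiles)
        if hi <= lo:
            scaled = np.zeros_like(values)
        else:
            scaled = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
        tifffile.imwrite(path, (scaled * 65535.0 + 0.5).astype(np.uint16))
    else:
        raise ValueError(f"unknown TIFF mode {mode!r}")
    if png_preview is not None:
        from PIL import Image

        lo, hi = np.percentile(values, clip_percentiles)
        scaled = (
            np.zeros_like(values)
            if hi <= lo
            else np.clip((values - lo) / (hi - lo), 0.0, 1.0)
        )
        Image.fromarray((scaled * 255.0 + 0.5).astype(np.uint8)).save(png_preview)


def read_projection_tiff(path: str | Path) -> np.ndarray:
    """Read a projection TIFF back as float64."""
    return np.asarray(tifffile.imread(path), dtype=np.float64)
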