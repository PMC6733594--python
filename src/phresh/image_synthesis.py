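"""Synthetic confocal rendering and reslicing.

Cells are rendered as Gaussian intensity blobs into a lateral-view voxel
grid with axes Z = mediolateral imaging depth, Y = dorsoventral (ventral at
low Y), X = anterior-posterior, matching the lateral-mount confocal
convention.  Photon shot noise (Poisson) and camera read noise (additive
Gaussian) are applied on top of a linear photon gain, then a constant
background offset.  ``reslice_transverse`` reorders the voxels into
DV × ML transverse sections indexed by AP position without interpolation,
mirroring the Fiji "reslice" step used on real stacks.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .errors import InvalidParameterError
from .synthetic_embryo import SpinalCordGeometry

__all__ = [
    "OpticsModel",
    "NoiseModel",
    "ImageStack",
    "render_stack",
    "reslice_transverse",
    "unreslice",
    "write_stack",
    "read_stack",
]


@dataclass(frozen=True)
class OpticsModel:
    """Voxel grid and point-spread function (all lengths in µm).

    ``voxel_size`` and ``psf_sigma`` are (Z, Y, X) per-axis values;
    ``background_offset`` is a constant added to every voxel (counts).
    """

    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    psf_sigma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_offset: float = 0.0

    def __post_init__(self):
        if any(v <= 0 for v in self.voxel_size):
            raise InvalidParameterError("voxel_size must be > 0")
        if any(s < 0 for s in self.psf_sigma):
            raise InvalidParameterError("psf_sigma must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Shot + read noise: counts = Poisson(gain·signal) + N(0, read σ)."""

    photon_gain: float = 50.0
    read_noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.photon_gain <= 0:
            raise InvalidParameterError("photon_gain must be > 0")
        if self.read_noise_sigma < 0:
            raise InvalidParameterError("read_noise_sigma must be >= 0")


@dataclass
class ImageStack:
    """Two-channel (or single-channel) voxel array plus imaging metadata.

    ``data`` has shape (C, Z, Y, X); ``origin`` gives the µm coordinate of
    the centre of voxel (0, 0, 0) as (z0, y0, x0); ``channels`` names the
    leading axis; ``converted_ap_window`` is the photoconverted AP span in
    µm (or None for un-photoconverted scenes such as marker stains).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channels: tuple[str, ...] = ("green", "red")
    converted_ap_window: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise InvalidParameterError("stack data must be (C, Z, Y, X)")
        if self.data.shape[0] != len(self.channels):
            raise InvalidParameterError(
                "channel axis does not match channel names")
        if np.any(self.data < 0):
            raise InvalidParameterError("intensities must be >= 0")
        if self.converted_ap_window is not None:
            lo, hi = self.converted_ap_window
            ap = self.ap_coords()
            if lo >= hi or lo > ap.max() or hi < ap.min():
                raise InvalidParameterError(
                    "converted window must lie within the AP extent")

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    def ap_coords(self) -> np.ndarray:
        """µm AP coordinate of each X voxel column (voxel centres)."""
        return self.origin[2] + np.arange(self.data.shape[3]) * self.voxel_size[2]

    def dv_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.data.shape[2]) * self.voxel_size[1]

    def ml_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.data.shape[1]) * self.voxel_size[0]

    def cord_section_mask(self, geometry: SpinalCordGeometry) -> np.ndarray:
        """Boolean (Y, Z) mask of the spinal-cord cross-section."""
        dv = self.dv_coords()
        ml = self.ml_coords()
        return ((dv >= 0) & (dv <= geometry.dv_height))[:, None] \
            & ((ml >= 0) & (ml <= geometry.ml_width))[None, :]


def render_stack(states: pd.DataFrame,
                 population: pd.DataFrame,
                 geometry: SpinalCordGeometry,
                 optics: OpticsModel | None = None,
                 noise: NoiseModel | None = None,
                 channels: tuple[str, ...] = ("green", "red"),
                 pad_um: float = 2.0,
                 sample_noise: bool = True,
                 converted_ap_window: tuple[float, float] | None = None,
                 grid_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0),
                 meta: dict | None = None) -> ImageStack:
    """Render per-cell channel amounts into a lateral-view stack.

    ``states`` must be index-aligned with ``population`` and carry one
    column per entry of ``channels``.  Each cell deposits its amount at its
    nearest voxel; the deposit image is blurred with the Gaussian PSF (which
    preserves the summed intensity), scaled by the photon gain, corrupted
    with Poisson + read noise (if ``noise`` given and ``sample_noise``), and
    offset by the background.  Deterministic for a given noise seed.
    """
    optics = optics or OpticsModel()
    if len(states) != len(population):
        raise InvalidParameterError(
            "states and population must be index-aligned (equal length)")
    for ch in channels:
        if ch not in states.columns:
            raise InvalidParameterError(f"states lacks channel column {ch!r}")

    vz, vy, vx = optics.voxel_size
    # sub-voxel grid offset: a mounted embryo is never aligned with the
    # voxel raster, and dithering the phase debiases edge-row rounding
    z0, y0 = -pad_um + grid_offset_um[0], -pad_um + grid_offset_um[1]
    x0 = grid_offset_um[2]
    nz = int(np.ceil((geometry.ml_width + 2 * pad_um) / vz))
    ny = int(np.ceil((geometry.dv_height + 2 * pad_um) / vy))
    nx = int(np.ceil(geometry.ap_length / vx))

    xs = population["x_um"].to_numpy()
    ys = population["y_um"].to_numpy()
    zs = population["z_um"].to_numpy()
    iz = np.round((zs - z0) / vz).astype(int)
    iy = np.round((ys - y0) / vy).astype(int)
    ix = np.round((xs - x0) / vx).astype(int)
    inside = ((iz >= 0) & (iz < nz) & (iy >= 0) & (iy < ny)
              & (ix >= 0) & (ix < nx))

    gain = noise.photon_gain if noise is not None else 1.0
    sigma_vox = (optics.psf_sigma[0] / vz, optics.psf_sigma[1] / vy,
                 optics.psf_sigma[2] / vx)
    rng = np.random.default_rng(noise.seed) if noise is not None else None

    data = np.empty((len(channels), nz, ny, nx))
    for c, ch in enumerate(channels):
        scene = np.zeros((nz, ny, nx))
        amounts = states[ch].to_numpy(float)
        np.add.at(scene, (iz[inside], iy[inside], ix[inside]),
                  amounts[inside])
        if any(s > 0 for s in sigma_vox):
            scene = gaussian_filter(scene, sigma=sigma_vox)
        expected = gain * scene
        if noise is not None and sample_noise:
            counts = rng.poisson(np.clip(expected, 0, None)).astype(float)
            if noise.read_noise_sigma > 0:
                counts += rng.normal(0.0, noise.read_noise_sigma,
                                     size=counts.shape)
        else:
            counts = expected
        data[c] = np.clip(counts + optics.background_offset, 0.0, None)

    info = {"geometry": dataclasses.asdict(geometry), "pad_um": pad_um}
    if meta:
        info.update(meta)
    return ImageStack(data=data, voxel_size=optics.voxel_size,
                      origin=(z0, y0, x0), channels=tuple(channels),
                      converted_ap_window=converted_ap_window, meta=info)


def reslice_transverse(stack) -> np.ndarray:
    """Reorder a lateral stack into transverse DV × ML sections along AP.

    Accepts an ImageStack or a raw (C, Z, Y, X) / (Z, Y, X) array. Returns
    an array of shape (X, C, Y, Z) (or (X, Y, Z) for single-channel input):
    a pure axis permutation of the voxels, no interpolation.
    """
    if isinstance(stack, ImageStack):
        arr = stack.data
    else:
        arr = np.asarray(stack)
    if arr.ndim == 3:
        return np.transpose(arr, (2, 1, 0))
    if arr.ndim == 4:
        return np.transpose(arr, (3, 0, 2, 1))
    raise InvalidParameterError(
        "expected (C, Z, Y, X) or (Z, Y, X) axis order")


def unreslice(sections: np.ndarray) -> np.ndarray:
    """Inverse of :func:`reslice_transverse` on raw arrays."""
    arr = np.asarray(sections)
    if arr.ndim == 3:  # (X, Y, Z) -> (Z, Y, X)
        return np.transpose(arr, (2, 1, 0))
    if arr.ndim == 4:  # (X, C, Y, Z) -> (C, Z, Y, X)
        return np.transpose(arr, (1, 3, 2, 0))
    raise InvalidParameterError("expected resliced (X, [C,] Y, Z) array")


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page float32 TIFF plus a JSON sidecar
    (``<path>.json``) carrying voxel size, axes, origin and metadata."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32))
    sidecar = {
        "axes": "CZYX",
        "channels": list(stack.channels),
        "voxel_size_um": list(stack.voxel_size),
        "origin_um": list(stack.origin),
        "converted_ap_window_um": (list(stack.converted_ap_window)
                                   if stack.converted_ap_window else None),
        "meta": stack.meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2))


def read_stack(path, sidecar_path=None) -> ImageStack:
    """Read a stack written by :func:`write_stack`."""
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else \
        path.with_suffix(path.suffix + ".json")
    info = json.loads(sidecar_path.read_text())
    if info.get("axes") != "CZYX":
        raise InvalidParameterError(
            f"unknown axis order {info.get('axes')!r} in sidecar")
    data = tifffile.imread(path).astype(float)
    window = info.get("converted_ap_window_um")
    return ImageStack(
        data=data,
        voxel_size=tuple(info["voxel_size_um"]),
        origin=tuple(info["origin_um"]),
        channels=tuple(info["channels"]),
        converted_ap_window=tuple(window) if window else None,
        meta=info.get("meta", {}),
    )
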