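"""Theoretical PSF/OTF of the wide-field detection path from the Ewald sphere.

The coherent transfer function of an aberration-free detection objective is a
spherical cap: the portion of the Ewald sphere of radius n/λ within the
aperture half-angle θ = asin(NA/n) about the optical (+z) axis.  The 3D
intensity PSF is the squared modulus of the 3D Fourier transform of that cap,
and the OTF (its Fourier transform, equivalently the autocorrelation of the
cap) shows the characteristic "missing cone" of axial frequencies that makes
a single wide-field view unable to section optically.

Two cap constructions are provided:

* ``ewald_cap`` — a binary shell one frequency step thick on the full 3D
  frequency grid, carrier included.  Faithful to the geometric construction,
  but the sphere radius n/λ must fit inside the axial Nyquist range, which
  forces axial voxels finer than λ/(2n).
* ``psf_3d(..., demodulate=True)`` — the cap is built as a height field
  k_z(k_x, k_y) = sqrt((n/λ)² − k_r²) over the pupil disk with the axial
  carrier (band centre) subtracted before transforming.  The intensity PSF is
  unchanged by this global k_z translation, but the construction only needs
  the axial *bandwidth* NA²/(2λn)·... to fit, so PSFs spanning hundreds of µm
  of defocus can be generated on coarse axial grids without aliasing.

All grids are centred: the zero frequency / PSF peak sits at index
``shape//2`` per axis, so odd shapes are recommended.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import OpticalParams

__all__ = ["PSFGrid", "OTFGrid", "ResolutionError", "ewald_cap", "psf_3d",
           "psf_2d_central", "otf_3d", "frequency_axes"]


class ResolutionError(ValueError):
    """The requested frequency-space construction does not fit on the grid."""


@dataclass(frozen=True)
class PSFGrid:
    """3D intensity PSF sampled on a regular grid.

    ``values`` is (z, y, x), non-negative, unit sum; ``voxel_size`` is
    (dz, dy, dx) in µm; ``center_index`` marks the PSF peak/origin.
    """

    values: np.ndarray
    voxel_size: tuple[float, float, float]
    center_index: tuple[int, int, int]


@dataclass(frozen=True)
class OTFGrid:
    """3D OTF on the centred frequency grid matching a :class:`PSFGrid`.

    ``values`` is complex with the zero-frequency voxel at ``center_index``
    normalised to 1; ``frequency_step`` is (dk_z, dk_y, dk_x) in 1/µm.
    """

    values: np.ndarray
    frequency_step: tuple[float, float, float]
    center_index: tuple[int, int, int]


def frequency_axes(shape, voxel_size):
    """Centred frequency axes (1/µm) for each array dimension."""
    return [np.fft.fftshift(np.fft.fftfreq(n, d=v)) for n, v in zip(shape, voxel_size)]


def _check_shapes(grid_shape, voxel_size):
    grid_shape = tuple(int(s) for s in grid_shape)
    voxel_size = tuple(float(v) for v in voxel_size)
    if len(grid_shape) != 3 or len(voxel_size) != 3:
        raise ValueError("grid_shape and voxel_size must have length 3 (z, y, x)")
    if any(s < 3 for s in grid_shape):
        raise ValueError(f"grid too small: {grid_shape}")
    if any(v <= 0 for v in voxel_size):
        raise ValueError(f"voxel sizes must be positive: {voxel_size}")
    return grid_shape, voxel_size


def ewald_cap(params: OpticalParams, grid_shape, voxel_size) -> np.ndarray:
    """Binary Ewald-sphere cap indicator on the centred 3D frequency grid.

    Marks voxels whose distance to the sphere |k| = n/λ is below half the
    local (direction-projected) frequency step and whose polar angle from the
    +k_z axis is within the aperture half-angle asin(NA/n).

    Raises :class:`ResolutionError` naming the offending axis when the cap
    exceeds the grid's Nyquist extent.
    """
    grid_shape, voxel_size = _check_shapes(grid_shape, voxel_size)
    n = params.refractive_index
    radius = n / params.wavelength
    sin_t = params.na_det / n
    kz, ky, kx = frequency_axes(grid_shape, voxel_size)

    for name, ax, extent in (
        ("z", kz, radius), ("y", ky, radius * sin_t), ("x", kx, radius * sin_t)
    ):
        if extent > ax.max() * (1 + 1e-12):
            raise ResolutionError(
                f"Ewald cap (needs |k_{name}| up to {extent:.4g}/µm) exceeds the "
                f"{name}-axis Nyquist extent {ax.max():.4g}/µm; use finer "
                f"{name} voxels or a larger grid"
            )

    kzg, kyg, kxg = np.meshgrid(kz, ky, kx, indexing="ij", sparse=True)
    kmag = np.sqrt(kzg**2 + kyg**2 + kxg**2)
    dkz, dky, dkx = (1.0 / (s * v) for s, v in zip(grid_shape, voxel_size))
    with np.errstate(invalid="ignore", divide="ignore"):
        # frequency step projected on the radial direction at each voxel
        local_step = np.sqrt((dkz * kzg) ** 2 + (dky * kyg) ** 2 + (dkx * kxg) ** 2)
        local_step = np.where(kmag > 0, local_step / np.where(kmag > 0, kmag, 1.0),
                              max(dkz, dky, dkx))
        cos_polar = np.where(kmag > 0, kzg / np.where(kmag > 0, kmag, 1.0), 0.0)
    on_shell = np.abs(kmag - radius) <= 0.5 * local_step
    in_aperture = cos_polar >= math.cos(math.asin(min(sin_t, 1.0))) - 1e-12
    return (on_shell & in_aperture).astype(np.float64)


def _demodulated_cap(params: OpticalParams, grid_shape, voxel_size) -> np.ndarray:
    """Pupil height-field cap with the axial carrier removed (see module docs)."""
    grid_shape, voxel_size = _check_shapes(grid_shape, voxel_size)
    n = params.refractive_index
    radius = n / params.wavelength
    sin_t = min(params.na_det / n, 1.0)
    cos_t = math.sqrt(1.0 - sin_t**2)
    kz, ky, kx = frequency_axes(grid_shape, voxel_size)

    kr_max = radius * sin_t
    half_band = radius * (1.0 - cos_t) / 2.0
    for name, ax, extent in (("z", kz, half_band), ("y", ky, kr_max), ("x", kx, kr_max)):
        if extent > ax.max() * (1 + 1e-12):
            raise ResolutionError(
                f"demodulated Ewald cap (needs |k_{name}| up to {extent:.4g}/µm) "
                f"exceeds the {name}-axis Nyquist extent {ax.max():.4g}/µm"
            )

    kyg, kxg = np.meshgrid(ky, kx, indexing="ij")
    kr2 = kyg**2 + kxg**2
    inside = kr2 <= kr_max**2 * (1 + 1e-12)
    kz_sphere = np.sqrt(np.maximum(radius**2 - kr2, 0.0))
    kz_centered = kz_sphere - radius * (1.0 + cos_t) / 2.0  # band centred on 0

    dkz = 1.0 / (grid_shape[0] * voxel_size[0])
    pos = kz_centered / dkz + grid_shape[0] // 2  # fractional k_z bin
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    cap = np.zeros(grid_shape)
    iy, ix = np.nonzero(inside)
    # deposit each pupil sample into the two nearest k_z bins (linear interp)
    for off in (0, 1):
        b = lo[iy, ix] + off
        w = (1.0 - frac if off == 0 else frac)[iy, ix]
        ok = (b >= 0) & (b < grid_shape[0])
        np.add.at(cap, (b[ok], iy[ok], ix[ok]), w[ok])
    return cap


def psf_3d(params: OpticalParams, grid_shape, voxel_size,
           demodulate: bool = False) -> PSFGrid:
    """3D intensity PSF: |FFT of the Ewald cap|², unit sum, peak centred.

    ``demodulate=True`` selects the band-limited cap construction that allows
    coarse axial voxels (see module docstring); the default is the binary
    shell on the full frequency grid.
    """
    grid_shape, voxel_size = _check_shapes(grid_shape, voxel_size)
    cap = (_demodulated_cap if demodulate else ewald_cap)(
        params, grid_shape, voxel_size)
    if not np.any(cap):
        raise ResolutionError("Ewald cap is empty on this grid; refine the sampling")
    amp = np.fft.fftn(np.fft.ifftshift(cap))
    psf = np.fft.fftshift(np.abs(amp) ** 2)
    psf /= psf.sum()
    center = tuple(s // 2 for s in grid_shape)
    return PSFGrid(values=psf, voxel_size=voxel_size, center_index=center)


def psf_2d_central(psf: PSFGrid) -> np.ndarray:
    """Central xz section of a 3D PSF, renormalised to unit sum.

    This is the 2D kernel used for plane-by-plane deconvolution of resliced
    xz sections.  Returned as a (z, x) array.
    """
    sl = psf.values[:, psf.center_index[1], :]
    total = sl.sum()
    if total <= 0:
        raise ValueError("central PSF section has zero energy")
    return sl / total


def otf_3d(psf: PSFGrid) -> OTFGrid:
    """3D OTF of a PSF, normalised so the zero-frequency value is 1."""
    vals = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(psf.values)))
    center = tuple(s // 2 for s in vals.shape)
    dc = vals[center]
    if abs(dc) == 0:
        raise ValueError("PSF has zero total energy")
    vals = vals / dc
    steps = tuple(1.0 / (s * v) for s, v in zip(vals.shape, psf.voxel_size))
    return OTFGrid(values=vals, frequency_step=steps, center_index=center)
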