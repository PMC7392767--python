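"""Forward simulator: multi-view trans-illumination stacks from a phantom.

The contrast model is linear attenuation imaged through the incoherent 3D
detection PSF:

    I(r) = I₀ · (1 − (A_α ⊛ PSF)(r)),   A_α = phantom rotated by −α

about the rotation axis (x_c, z_c).  The reconstruction rotation by +α then
undoes the sample rotation.  The phantom is blurred at full axial resolution
and only then sampled at the M acquisition planes spaced Δz, emulating a
continuously translating stage.  For weak absorbers (attenuation ≤ 1 and
small filling fraction) this first-order model keeps the whole pipeline
linear, which is exactly what averaging recorded intensities over views
assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy import ndimage

from .params import OpticalParams, AcquisitionGeometry, ValidationError
from .optics import PSFGrid
from .phantom import Phantom, rotate_volume_about_y

__all__ = ["NoiseSpec", "ViewStack", "MultiViewDataset",
           "simulate_view_stack", "simulate_dataset"]

_NOISE_MODELS = ("none", "gaussian", "poisson")


@dataclass(frozen=True)
class NoiseSpec:
    """Detector noise model: additive Gaussian read noise and/or Poisson shot
    noise at ``photon_scale`` counts per intensity unit."""

    model: str = "none"
    gaussian_sigma: float = 0.0
    photon_scale: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _NOISE_MODELS:
            raise ValidationError(f"noise model must be one of {_NOISE_MODELS}")
        if self.gaussian_sigma < 0:
            raise ValidationError("gaussian_sigma must be >= 0")
        if not self.photon_scale > 0:
            raise ValidationError("photon_scale must be > 0")


@dataclass
class ViewStack:
    """One angular view: ``intensity`` (z, y, x) with M pages spaced
    ``axial_step`` µm, lateral ``pixel_size`` µm, bright background I₀."""

    intensity: np.ndarray
    angle: float
    axial_step: float
    pixel_size: float
    background_level: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intensity.ndim != 3:
            raise ValidationError("intensity must be 3D (z, y, x)")
        if np.any(self.intensity < 0):
            raise ValidationError("intensity must be non-negative")
        if not 0.0 <= self.angle < 360.0:
            raise ValidationError(f"angle must be in [0, 360), got {self.angle}")


@dataclass
class MultiViewDataset:
    """A full multi-angle acquisition: one :class:`ViewStack` per angle."""

    views: list[ViewStack]
    params: OpticalParams
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        if len(self.views) != len(self.geometry.angles):
            raise ValidationError("one view per geometry angle is required")
        shapes = {v.intensity.shape for v in self.views}
        if len(shapes) > 1:
            raise ValidationError(f"views must share one shape, got {shapes}")
        for v, a in zip(self.views, self.geometry.angles):
            if abs((v.angle - a) % 360.0) > 1e-9:
                raise ValidationError("view angles must match geometry.angles order")


def _apply_noise(intensity: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    if noise.model == "none":
        return intensity
    rng = np.random.default_rng(noise.seed)
    if noise.model == "gaussian":
        out = intensity + rng.normal(0.0, noise.gaussian_sigma, intensity.shape)
    else:  # poisson
        out = rng.poisson(intensity * noise.photon_scale) / noise.photon_scale
    return np.clip(out, 0.0, None)


def _sample_z_planes(volume: np.ndarray, stride: float, num: int) -> np.ndarray:
    """Sample ``num`` planes at fractional z indices 0, stride, 2·stride, …
    (linear interpolation along z)."""
    positions = np.arange(num) * stride
    if positions[-1] > volume.shape[0] - 1 + 1e-9:
        raise ValidationError(
            f"acquisition spans z index {positions[-1]:.2f} but the phantom has "
            f"only {volume.shape[0]} planes")
    lo = np.floor(positions).astype(int)
    hi = np.minimum(lo + 1, volume.shape[0] - 1)
    w = (positions - lo)[:, None, None]
    return (1.0 - w) * volume[lo] + w * volume[hi]


def simulate_view_stack(phantom: Phantom, psf: PSFGrid, params: OpticalParams,
                        angle: float, geometry: AcquisitionGeometry,
                        axis, background: float = 1.0,
                        noise: NoiseSpec | None = None) -> ViewStack:
    """Simulate the stack recorded at one view angle.

    ``axis`` is anything with ``x_c``/``z_c`` attributes or an (x_c, z_c)
    pair, in phantom pixel coordinates.  The sample is rotated by −angle
    (stage rotation), blurred with the 3D PSF, converted to intensity on the
    bright background, sampled at the M acquisition planes and clipped at 0;
    noise is applied last with the seed in ``noise``.
    """
    noise = noise or NoiseSpec()
    x_c, z_c = (axis.x_c, axis.z_c) if hasattr(axis, "x_c") else axis
    vz, vy, vx = phantom.voxel_size
    if not (np.isclose(vz, psf.voxel_size[0]) and np.isclose(vy, psf.voxel_size[1])
            and np.isclose(vx, psf.voxel_size[2])):
        raise ValidationError(
            f"phantom voxels {phantom.voxel_size} must match PSF voxels "
            f"{psf.voxel_size}")
    if not np.isclose(vx, params.pixel_size):
        raise ValidationError(
            f"phantom lateral voxel {vx} µm must equal pixel_size "
            f"{params.pixel_size} µm")

    rotated = rotate_volume_about_y(phantom, -angle, (x_c, z_c))
    if rotated.attenuation.shape[1] == 1 and psf.values.shape[1] % 2 == 1:
        # single-y-section phantom: the central output plane of the 3D
        # convolution reduces exactly to a 2D convolution with the PSF's
        # central y slice
        blurred = fftconvolve(rotated.attenuation[:, 0, :],
                              psf.values[:, psf.center_index[1], :],
                              mode="same")[:, None, :]
    else:
        blurred = fftconvolve(rotated.attenuation, psf.values, mode="same")
    intensity = background * (1.0 - blurred)

    meta: dict = {"noise_seed": noise.seed, "noise_model": noise.model}
    floor = intensity.min()
    if floor < -1e-6 * background:
        meta["negative_intensity_warning"] = float(floor)

    stride = geometry.axial_step / vz
    stack = _sample_z_planes(intensity, stride, geometry.num_z_steps)
    stack = np.clip(stack, 0.0, None)
    stack = _apply_noise(stack, noise)
    return ViewStack(intensity=stack, angle=float(angle) % 360.0,
                     axial_step=geometry.axial_step,
                     pixel_size=params.pixel_size,
                     background_level=background, meta=meta)


def _child_seed(base: int, index: int) -> int:
    # deterministic per-view stream, kept below 2**31
    return int(np.random.SeedSequence([int(base), int(index)]).generate_state(1)[0]
               % (2**31))


def simulate_dataset(phantom: Phantom, psf: PSFGrid, params: OpticalParams,
                     geometry: AcquisitionGeometry, axis,
                     background: float = 1.0,
                     noise: NoiseSpec | None = None) -> MultiViewDataset:
    """Simulate one :class:`ViewStack` per angle in ``geometry.angles``.

    Per-view noise seeds are derived deterministically from the base seed and
    the view index, so a dataset is reproducible end to end.
    """
    noise = noise or NoiseSpec()
    views = []
    for i, angle in enumerate(geometry.angles):
        view_noise = NoiseSpec(model=noise.model,
                               gaussian_sigma=noise.gaussian_sigma,
                               photon_scale=noise.photon_scale,
                               seed=_child_seed(noise.seed, i))
        views.append(simulate_view_stack(phantom, psf, params, angle, geometry,
                                         axis, background, view_noise))
    return MultiViewDataset(views=views, params=params, geometry=geometry)
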