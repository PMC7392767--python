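"""Sampling-design calculator for multi-view bright-field acquisition.

The angular step matches the angular extent of the wide-field OTF so that
adjacent rotated OTF copies tile frequency space, and the axial step follows
Nyquist sampling of the axial cutoff of the detection OTF:

    Δα = θ ≈ NA/n            (paraxial aperture angle, radians)
    N  = 2π/Δα = 2π n/NA     (views over 360°)
    Δk_z = NA² / (2 λ n)     (axial cutoff frequency, 1/µm)
    Δz = 1/(2 Δk_z) = λ n/NA²  (axial scan step, µm)
    M  = L/Δz                (planes per stack for thickness L)
    N_TOT = N·M = 2π L NA/λ  (total images)

The paraxial form NA/n is the default for the aperture angle so that the
standard printed design values (e.g. N = 48 at NA = 0.13, n = 1) reproduce
exactly; pass ``exact=True`` for asin(NA/n).
"""

from __future__ import annotations

import math

import numpy as np

from .params import OpticalParams, ValidationError

__all__ = [
    "angular_step",
    "num_views",
    "axial_cutoff",
    "axial_step",
    "num_z_steps",
    "total_images",
    "make_angle_list",
    "design_summary",
]

# relative slack when a thickness is an exact multiple of the axial step,
# so float round-off does not push ceil() one step up
_CEIL_RTOL = 1e-9


def angular_step(params: OpticalParams, exact: bool = False) -> float:
    """Angular step Δα between views, in radians.

    Paraxial by default (NA/n); ``exact=True`` uses asin(NA/n).
    """
    ratio = params.na_det / params.refractive_index
    return math.asin(ratio) if exact else ratio


def num_views(params: OpticalParams, exact: bool = False) -> int:
    """Number of views N = 2π/Δα covering 360°, rounded to nearest, min 1."""
    return max(1, round(2.0 * math.pi / angular_step(params, exact=exact)))


def axial_cutoff(params: OpticalParams) -> float:
    """Maximum axial cutoff frequency Δk_z = NA²/(2λn), in 1/µm."""
    return params.na_det**2 / (2.0 * params.wavelength * params.refractive_index)


def axial_step(params: OpticalParams) -> float:
    """Axial scan step Δz = 1/(2Δk_z) = λn/NA², in µm."""
    return 1.0 / (2.0 * axial_cutoff(params))


def num_z_steps(params: OpticalParams, thickness: float) -> int:
    """Number of z planes M covering ``thickness`` (µm): ceil(L/Δz), min 1."""
    if not thickness > 0:
        raise ValidationError(f"thickness must be > 0, got {thickness}")
    ratio = thickness / axial_step(params)
    return max(1, math.ceil(ratio * (1.0 - _CEIL_RTOL)))


def total_images(params: OpticalParams, thickness: float) -> int:
    """Total acquisition count N_TOT = N·M."""
    return num_views(params) * num_z_steps(params, thickness)


def make_angle_list(n_views: int, full_circle: bool = True) -> np.ndarray:
    """Equally spaced view angles in degrees, starting at 0.

    ``full_circle=True`` spaces ``n_views`` over 360° (step 360/N);
    otherwise over 180° (step 180/N), exploiting the inversion symmetry of
    the OTF.  All angles lie in [0, 360).
    """
    if n_views < 1:
        raise ValidationError(f"n_views must be >= 1, got {n_views}")
    arc = 360.0 if full_circle else 180.0
    return np.arange(n_views) * (arc / n_views)


def design_summary(params: OpticalParams, thickness: float) -> dict:
    """All design quantities in one mapping (used by the CLI)."""
    return {
        "angular_step_deg": math.degrees(angular_step(params)),
        "num_views": num_views(params),
        "axial_cutoff_per_um": axial_cutoff(params),
        "axial_step_um": axial_step(params),
        "num_z_steps": num_z_steps(params, thickness),
        "total_images": total_images(params, thickness),
    }
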