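"""Core parameter containers for the imaging system and the acquisition.

Units at the interface are micrometres for lengths and degrees for angles.
Angles are converted to radians only inside computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when a parameter container violates its invariants."""


@dataclass(frozen=True)
class OpticalParams:
    """Optical parameters of the trans-illumination wide-field system.

    Parameters
    ----------
    wavelength : float
        Illumination/detection wavelength in µm.
    na_det : float
        Detection numerical aperture (dimensionless).
    na_ill : float, optional
        Illumination numerical aperture; defaults to ``na_det`` (matched
        Köhler illumination).
    refractive_index : float
        Refractive index ``n`` of the immersion medium.
    pixel_size : float
        Lateral pixel size at the sample plane, µm.
    magnification : float or None
        Optical magnification; metadata only, not used in any formula.
    """

    wavelength: float
    na_det: float
    na_ill: float | None = None
    refractive_index: float = 1.0
    pixel_size: float = 1.0
    magnification: float | None = None

    def __post_init__(self) -> None:
        if self.na_ill is None:
            object.__setattr__(self, "na_ill", self.na_det)
        if not self.wavelength > 0:
            raise ValidationError(f"wavelength must be > 0, got {self.wavelength}")
        if not self.pixel_size > 0:
            raise ValidationError(f"pixel_size must be > 0, got {self.pixel_size}")
        n = self.refractive_index
        for name, na in (("na_det", self.na_det), ("na_ill", self.na_ill)):
            if not 0 < na <= n:
                raise ValidationError(
                    f"{name} must satisfy 0 < NA <= n (n={n}), got {na}"
                )


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Geometry of a multi-view acquisition.

    ``angles`` are the view angles in degrees (each in ``[0, 360)``),
    ``axial_step`` is the z scan step Δz in µm, ``num_z_steps`` the number M
    of planes per stack, ``thickness`` the sample extent L in µm (optional
    metadata).
    """

    angles: tuple[float, ...]
    axial_step: float
    num_z_steps: int
    thickness: float | None = None

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles)
        object.__setattr__(self, "angles", angles)
        if len(angles) < 1:
            raise ValidationError("at least one view angle is required")
        reduced = [round(a % 360.0, 9) for a in angles]
        if len(set(reduced)) != len(reduced):
            raise ValidationError("view angles must be pairwise distinct modulo 360")
        if not all(0.0 <= a < 360.0 for a in angles):
            raise ValidationError("angles must lie in [0, 360) degrees")
        if not self.axial_step > 0:
            raise ValidationError(f"axial_step must be > 0, got {self.axial_step}")
        if self.num_z_steps < 1:
            raise ValidationError(f"num_z_steps must be >= 1, got {self.num_z_steps}")
        if self.thickness is not None and not self.thickness > 0:
            raise ValidationError(f"thickness must be > 0, got {self.thickness}")

    @property
    def num_views(self) -> int:
        return len(self.angles)
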