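"""Rotation-axis localisation.

The axis must be known to pixel accuracy before views can be fused.  It is
found in two steps:

1. **x_c by flip-registration.**  Min- (or mean-) intensity projections of two
   opposite views (0° and 180°) are mirror images about the axis.  Flipping
   one along x and registering it to the other yields a shift Δx, and
   x_c = (W−1)/2 + Δx/2.
2. **z_c by contrast maximisation.**  A single xz section is reconstructed for
   a range of candidate z_c values; the correct axis gives the least blurred,
   highest-contrast reconstruction.  Contrast is the Fourier energy of the
   section excluding the DC term, i.e. Σ|F|² − |F₀|² with the unnormalised
   DFT, which by Parseval equals N_pix·Σx² − (Σx)².

For a tilted axis the estimates at two or more y positions are interpolated
linearly in y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.registration import phase_cross_correlation

from .params import ValidationError
from .simulate import ViewStack, MultiViewDataset

__all__ = ["RotationAxis", "RegistrationResult", "NoSignalError",
           "intensity_projection", "estimate_xc", "reconstruction_contrast",
           "estimate_zc", "fit_axis_tilt"]


class NoSignalError(ValueError):
    """The data carry no contrast signal usable for axis localisation."""


@dataclass(frozen=True)
class RotationAxis:
    """Rotation-axis position in continuous 0-based pixel coordinates of the
    resliced isotropic xz frame.  ``per_y_model`` optionally holds linear
    coefficients ``{"x": (slope, intercept), "z": (slope, intercept)}`` for a
    tilted axis."""

    x_c: float
    z_c: float
    per_y_model: dict | None = None

    def at_y(self, y: float) -> tuple[float, float]:
        """(x_c, z_c) at row ``y``; constant when no tilt model is present."""
        if self.per_y_model is None:
            return self.x_c, self.z_c
        sx, bx = self.per_y_model["x"]
        sz, bz = self.per_y_model["z"]
        return sx * y + bx, sz * y + bz


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of the flip-registration: signed shift Δx (pixels), the
    normalised correlation score at the optimum, and the method used."""

    shift_x: float
    score: float
    method: str = "phase_correlation"
    low_confidence: bool = False


def intensity_projection(stack: ViewStack, mode: str = "min") -> np.ndarray:
    """Per-pixel ``min`` or ``mean`` projection along z, returned as (y, x).

    Minimum projection is the default for bright-field data: absorbing
    structures are dark on the bright background, and the minimum keeps the
    best-focused, darkest silhouette.
    """
    if stack.intensity.size == 0:
        raise ValidationError("empty stack")
    if mode == "min":
        return stack.intensity.min(axis=0)
    if mode == "mean":
        return stack.intensity.mean(axis=0)
    raise ValidationError(f"mode must be 'min' or 'mean', got {mode!r}")


def _normalized_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.vdot(a, b).real / denom)


def estimate_xc(stack_0: ViewStack, stack_180: ViewStack, mode: str = "min",
                upsample_factor: int = 1, score_floor: float = 0.2
                ) -> tuple[float, RegistrationResult]:
    """Transverse axis position from two opposite views.

    The 180° projection is flipped along x and registered to the 0°
    projection (phase correlation; integer pixels by default, subpixel via
    ``upsample_factor``).  With Δx the x translation that overlaps the two,
    x_c = (W−1)/2 + Δx/2 in 0-based pixel coordinates.
    """
    if stack_0.intensity.shape != stack_180.intensity.shape:
        raise ValidationError("opposite views must share one shape")
    ref = intensity_projection(stack_0, mode)
    mov = intensity_projection(stack_180, mode)[:, ::-1]
    shift, _, _ = phase_cross_correlation(ref, mov,
                                          upsample_factor=upsample_factor)
    dx = float(shift[1])
    if abs(dx) >= ref.shape[1]:
        raise ValidationError(f"registration shift {dx} exceeds image width")
    aligned = np.roll(mov, int(round(dx)), axis=1)
    score = _normalized_correlation(ref, aligned)
    result = RegistrationResult(shift_x=dx, score=score,
                                low_confidence=score < score_floor)
    width = ref.shape[1]
    x_c = (width - 1) / 2.0 + dx / 2.0
    return x_c, result


def reconstruction_contrast(image: np.ndarray) -> float:
    """Fourier energy of an image excluding DC (unnormalised forward DFT).

    Satisfies the Parseval identity  N_pix·Σx² − (Σx)²  exactly, which pins
    the DFT normalisation and makes the metric invariant to adding a
    constant.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValidationError("image must be finite-valued")
    spectrum = np.fft.fft2(image)
    energy = float(np.sum(np.abs(spectrum) ** 2))
    dc = float(np.abs(spectrum[0, 0]) ** 2)
    return energy - dc


def estimate_zc(dataset: MultiViewDataset, y_index: int, x_c: float,
                candidates, deconv=None, psf2d=None
                ) -> tuple[float, np.ndarray]:
    """Axial axis position by contrast maximisation.

    ``candidates`` are z_c offsets (isotropic resliced pixels) relative to
    the resliced section's z centre.  For each candidate the y section is
    fused from all views and scored with :func:`reconstruction_contrast`;
    the absolute z_c of the best candidate and the full contrast curve are
    returned.  Ties break toward the candidate nearest the z centre.
    """
    from .recon import reslice_to_planes, fuse_plane  # avoid import cycle

    candidates = np.asarray(list(candidates), dtype=float)
    if candidates.size == 0:
        raise ValidationError("candidate list must be non-empty")
    planes = []
    for view in dataset.views:
        sections = reslice_to_planes(view)
        if not 0 <= y_index < len(sections):
            raise ValidationError(f"y_index {y_index} out of range")
        planes.append(sections[y_index])
    z_center = (planes[0].values.shape[0] - 1) / 2.0

    scores = np.empty(candidates.size)
    for i, off in enumerate(candidates):
        fused = fuse_plane(planes, (x_c, z_center + off), deconv=deconv,
                           psf2d=psf2d)
        scores[i] = reconstruction_contrast(fused.values)

    spread = scores.max() - scores.min()
    if spread <= 1e-12 * max(1.0, abs(scores.max())):
        raise NoSignalError("contrast curve is flat; no structure to focus on")
    best = scores == scores.max()
    idx = np.flatnonzero(best)
    # tie-break toward the candidate nearest the z centre (offset 0)
    winner = idx[np.argmin(np.abs(candidates[idx]))]
    return z_center + float(candidates[winner]), scores


def fit_axis_tilt(samples) -> RotationAxis:
    """Linear axis-tilt model from per-y estimates.

    ``samples`` is an iterable of (y_index, x_c, z_c) at ≥ 2 distinct y
    locations; x_c(y) and z_c(y) are fitted by least squares (exact
    interpolation for two samples).  The returned axis carries the line
    coefficients in ``per_y_model`` and its midpoint values in x_c/z_c.
    """
    pts = [(float(y), float(x), float(z)) for y, x, z in samples]
    ys = np.array([p[0] for p in pts])
    if len(pts) < 2:
        raise ValidationError("at least two y samples are required")
    if len(np.unique(ys)) != len(ys):
        raise ValidationError("y locations must be distinct")
    xs = np.array([p[1] for p in pts])
    zs = np.array([p[2] for p in pts])
    sx, bx = np.polyfit(ys, xs, 1)
    sz, bz = np.polyfit(ys, zs, 1)
    y_mid = ys.mean()
    return RotationAxis(x_c=float(sx * y_mid + bx), z_c=float(sz * y_mid + bz),
                        per_y_model={"x": (float(sx), float(bx)),
                                     "z": (float(sz), float(bz))})
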