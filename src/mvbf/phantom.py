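"""3D attenuation phantoms for the forward simulator.

A phantom holds a per-voxel attenuation amplitude in [0, 1] on a (z, y, x)
grid.  The available families emulate the geometries used to characterise
trans-illumination tomography systems: point absorbers at controlled (x, z)
offsets from the grid centre, a hollow agarose-like tube along the rotation
(y) axis, random absorbing beads, and a radial spoke resolution target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ValidationError
from ._transform import rotate_volume_values

__all__ = ["Phantom", "make_phantom", "rotate_volume_about_y"]


@dataclass(frozen=True)
class Phantom:
    """Attenuation volume: ``attenuation`` (z, y, x) in [0, 1], voxel_size (dz, dy, dx) µm."""

    attenuation: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        a = self.attenuation
        if a.ndim != 3:
            raise ValidationError(f"attenuation must be 3D (z, y, x), got ndim={a.ndim}")
        if np.any(a < 0):
            raise ValidationError("attenuation must be non-negative")
        if np.any(a > 1.0 + 1e-9):
            raise ValidationError(
                "attenuation must not exceed 1 (linear contrast model)")


def make_phantom(kind: str, shape, spec: dict | None = None, seed: int = 0,
                 voxel_size=(1.0, 1.0, 1.0)) -> Phantom:
    """Build a named phantom on a (z, y, x) grid.  Deterministic per seed.

    Kinds and their ``spec`` keys (all optional unless noted):

    - ``points``: ``positions`` — list of (x_off, z_off) offsets in pixels
      from the grid centre (required); ``amplitude``.  Absorbers are single
      voxels at the central y plane.
    - ``tube``: hollow cylinder along y; ``inner_radius``, ``outer_radius``
      (pixels), ``amplitude``, ``center_xz``.
    - ``beads``: ``n_beads`` random spheres of ``radius`` px, ``amplitude``,
      kept ``margin`` px from the volume faces.
    - ``spokes``: ``n_spokes`` radial bars in the xz plane, uniform along y,
      ``amplitude``, ``outer_radius``.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 1 for s in shape):
        raise ValidationError(f"shape must be a positive (z, y, x) triple, got {shape}")
    spec = dict(spec or {})
    amp = float(spec.get("amplitude", 0.5))
    nz, ny, nx = shape
    vol = np.zeros(shape)
    zc, yc, xc = nz // 2, ny // 2, nx // 2

    if kind == "points":
        positions = spec.get("positions", [(0.0, 0.0)])
        for x_off, z_off in positions:
            iz, ix = zc + int(round(z_off)), xc + int(round(x_off))
            if not (0 <= iz < nz and 0 <= ix < nx):
                raise ValidationError(
                    f"point offset (x={x_off}, z={z_off}) falls outside the grid")
            vol[iz, yc, ix] = amp
    elif kind == "tube":
        r1 = float(spec.get("inner_radius", min(nx, nz) * 0.25))
        r2 = float(spec.get("outer_radius", min(nx, nz) * 0.35))
        if not 0 <= r1 < r2:
            raise ValidationError(f"need 0 <= inner_radius < outer_radius, got {r1}, {r2}")
        cx, cz = spec.get("center_xz", (xc, zc))
        zi, xi = np.meshgrid(np.arange(nz) - cz, np.arange(nx) - cx, indexing="ij")
        r2d = np.hypot(zi, xi)
        ring = ((r2d >= r1) & (r2d <= r2)).astype(float) * amp
        vol[:] = ring[:, None, :]
    elif kind == "beads":
        rng = np.random.default_rng(seed)
        n_beads = int(spec.get("n_beads", 10))
        radius = float(spec.get("radius", 2.0))
        margin = float(spec.get("margin", radius + 1))
        zi, yi, xi = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                                 indexing="ij", sparse=True)
        for _ in range(n_beads):
            pz = rng.uniform(margin, nz - 1 - margin)
            y_lo = min(margin, (ny - 1) / 2.0)
            py = rng.uniform(y_lo, max(ny - 1 - margin, y_lo)) if ny > 1 else 0
            px = rng.uniform(margin, nx - 1 - margin)
            d2 = (zi - pz) ** 2 + (yi - py) ** 2 + (xi - px) ** 2
            vol[d2 <= radius**2] = amp
    elif kind == "spokes":
        n_spokes = int(spec.get("n_spokes", 8))
        r_out = float(spec.get("outer_radius", 0.45 * min(nx, nz)))
        zi, xi = np.meshgrid(np.arange(nz) - zc, np.arange(nx) - xc, indexing="ij")
        theta = np.arctan2(zi, xi)
        r2d = np.hypot(zi, xi)
        bars = (np.cos(n_spokes * theta) > 0) & (r2d <= r_out) & (r2d >= 2)
        vol[:] = (bars.astype(float) * amp)[:, None, :]
    else:
        raise ValidationError(f"unknown phantom kind {kind!r}")

    return Phantom(attenuation=vol, voxel_size=tuple(float(v) for v in voxel_size))


def rotate_volume_about_y(phantom: Phantom, angle: float,
                          center_xz: tuple[float, float]) -> Phantom:
    """Rotate each xz slice of the phantom by ``angle`` degrees about
    ``center_xz = (x_c, z_c)`` (continuous pixel coordinates), bilinear
    interpolation, zero attenuation outside the grid."""
    rotated = rotate_volume_values(phantom.attenuation, angle, center_xz, fill=0.0)
    # bilinear interpolation can overshoot the [0, 1] envelope by float fuzz
    np.clip(rotated, 0.0, 1.0, out=rotated)
    return Phantom(attenuation=rotated, voxel_size=phantom.voxel_size)
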