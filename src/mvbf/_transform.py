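"""In-plane (xz) rotation about a continuous centre, shared by the forward
simulator and the reconstruction.

Convention (pinned by the round-trip tests): arrays are indexed (z, x) for
planes and (z, y, x) for volumes; a rotation by +α maps content as

    x' = cos α · (x − x_c) − sin α · (z − z_c) + x_c
    z' = sin α · (x − x_c) + cos α · (z − z_c) + z_c

i.e. rotation from +x towards +z.  Resampling is bilinear (inverse mapping);
out-of-support samples take the fill value.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

__all__ = ["rotate_plane_values", "rotate_volume_values", "border_median"]


def _inverse_matrix(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    # snap float fuzz at multiples of 90° so on-grid samples stay on-grid
    if abs(c) < 1e-12:
        c = 0.0
    if abs(s) < 1e-12:
        s = 0.0
    # output (z, x) -> input (z, x) coordinates for a content rotation by +a
    return np.array([[c, -s], [s, c]])


def rotate_plane_values(values: np.ndarray, angle_deg: float,
                        center_xz: tuple[float, float], fill: float = 0.0,
                        order: int = 1) -> np.ndarray:
    """Rotate a (z, x) plane by ``angle_deg`` about ``center_xz = (x_c, z_c)``."""
    if angle_deg % 360.0 == 0.0:
        return values.copy()
    x_c, z_c = center_xz
    m = _inverse_matrix(angle_deg)
    center = np.array([z_c, x_c])
    offset = center - m @ center
    return ndimage.affine_transform(values, m, offset=offset, order=order,
                                    mode="constant", cval=fill)


def rotate_volume_values(values: np.ndarray, angle_deg: float,
                         center_xz: tuple[float, float], fill: float = 0.0,
                         order: int = 1) -> np.ndarray:
    """Rotate every xz slice of a (z, y, x) volume about the y axis."""
    if angle_deg % 360.0 == 0.0:
        return values.copy()
    x_c, z_c = center_xz
    m2 = _inverse_matrix(angle_deg)
    m = np.array([[m2[0, 0], 0.0, m2[0, 1]],
                  [0.0, 1.0, 0.0],
                  [m2[1, 0], 0.0, m2[1, 1]]])
    center = np.array([z_c, 0.0, x_c])
    offset = center - m @ center
    return ndimage.affine_transform(values, m, offset=offset, order=order,
                                    mode="constant", cval=fill)


def border_median(values: np.ndarray) -> float:
    """Median of the outermost pixel ring — background estimate for
    trans-illumination planes, whose borders are dominated by the bright
    background."""
    edges = np.concatenate([
        values[0, :], values[-1, :], values[1:-1, 0], values[1:-1, -1]
    ])
    return float(np.median(edges))
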