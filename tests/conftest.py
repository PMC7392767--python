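import numpy as np
import pytest

from mvbf import (OpticalParams, AcquisitionGeometry, Phantom, make_phantom,
                  psf_3d, psf_2d_central, simulate_dataset, NoiseSpec)
from mvbf import design


@pytest.fixture(scope="session")
def na05_params():
    """Moderate-NA system with a compact PSF, used by most simulations."""
    return OpticalParams(wavelength=0.5, na_det=0.5, refractive_index=1.0,
                         pixel_size=0.25)


@pytest.fixture(scope="session")
def psf_na05(na05_params):
    return psf_3d(na05_params, (65, 33, 65), (0.25, 0.25, 0.25),
                  demodulate=True)


@pytest.fixture(scope="session")
def psf2d_na05(psf_na05):
    return psf_2d_central(psf_na05)


@pytest.fixture(scope="session")
def point_dataset_factory(na05_params, psf_na05):
    """Simulate a small multi-view dataset of point absorbers.

    ``positions`` are (x_off, z_off) from the grid centre; ``axis`` is
    (x_c, z_c) in phantom pixels.  Defaults follow the design formulas for
    the fixture optics.
    """
    def factory(positions, axis, n_views=12, shape=(97, 1, 97),
                amplitude=0.6, noise=None, thickness=None):
        params = na05_params
        vox = (0.25, 0.25, 0.25)
        phantom = make_phantom("points", shape,
                               {"positions": positions, "amplitude": amplitude},
                               voxel_size=vox)
        dz = design.axial_step(params)
        length = thickness if thickness is not None else (shape[0] - 1) * vox[0]
        m = design.num_z_steps(params, length)
        geometry = AcquisitionGeometry(
            angles=tuple(design.make_angle_list(n_views)),
            axial_step=dz, num_z_steps=m)
        return simulate_dataset(phantom, psf_na05, params, geometry, axis,
                                background=1.0, noise=noise)
    return factory
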