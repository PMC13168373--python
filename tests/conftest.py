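import numpy as np
import pytest

from spectqc.calibration import ICFResult
from spectqc.phantoms import PhantomSpec
from spectqc.simulate import ReconstructionModel, simulate_phantom


@pytest.fixture(scope="session")
def cyl_spec():
    return PhantomSpec.uniform_cylinder(total_activity=812.0)


@pytest.fixture(scope="session")
def nema_spec():
    return PhantomSpec.nema_iq()


@pytest.fixture(scope="session")
def cyl_poisson_4mm(cyl_spec):
    """7 MCts Poisson cylinder image at 4 mm, true ICF 20 cps/MBq."""
    model = ReconstructionModel(psf_fwhm=12.0, icf_true=20.0,
                                count_target=7e6, noise="poisson", seed=1)
    return simulate_phantom(cyl_spec, model, spacing=4.0)


@pytest.fixture(scope="session")
def nema_noiseless_4mm(nema_spec):
    """Noiseless Gaussian-PSF (12 mm) NEMA image at 4 mm voxels."""
    model = ReconstructionModel(psf_fwhm=12.0, icf_true=20.0,
                                count_target=3e6, noise="none")
    return simulate_phantom(nema_spec, model, spacing=4.0)


def exact_icf(image, icf=20.0):
    """ICF result carrying the simulator's ground-truth calibration."""
    return ICFResult(icf=icf, counts_concentration=icf * image.duration,
                     duration=image.duration, ref_concentration=1.0,
                     voi_voxel_count=1, voi_sd=0.0, rr_scale=image.rr_scale)


@pytest.fixture(scope="session")
def true_icf():
    return exact_icf
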