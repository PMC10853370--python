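import numpy as np
import pytest

from alpskit.alps import RoiSet
from alpskit.gradients import make_gradient_scheme
from alpskit.phantom import build_tensor_field, simulate_dwi, small_phantom_spec


@pytest.fixture(scope="session")
def scheme31():
    """The default acquisition: one b=0 plus 30 directions at b=1000."""
    return make_gradient_scheme(30, 1000.0)


@pytest.fixture(scope="session")
def small_spec():
    return small_phantom_spec()


@pytest.fixture(scope="session")
def small_rois(small_spec):
    return RoiSet.from_centers(small_spec.region_centers, diameter=5.0)


@pytest.fixture(scope="session")
def noiseless_study(small_spec, scheme31):
    """Noiseless DWI of the reduced phantom plus its ground-truth field."""
    field, _ = build_tensor_field(small_spec)
    study = simulate_dwi(field, scheme31, small_spec.s0, 0.0, seed=0)
    return study, field


def random_spd_tensors(rng, n, scale=1e-3):
    """Random symmetric positive-definite tensors, water-like scale."""
    a = rng.standard_normal((n, 3, 3))
    spd = np.einsum("nij,nkj->nik", a, a) * scale / 3.0
    spd += np.eye(3) * scale * 1e-3
    return spd
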