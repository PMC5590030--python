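import numpy as np
import pytest

from mpioquant.synthetic import ContrastSpec, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom(default_spec):
    """(true_t2_map, s0_map, base_rois) for the default phantom."""
    return make_phantom(default_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_contrast(**kwargs) -> ContrastSpec:
    defaults = dict(ce_fraction_per_roi={"lesion": 0.10}, ce_amplitude=0.3, seed=7)
    defaults.update(kwargs)
    return ContrastSpec(**defaults)
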