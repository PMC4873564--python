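import warnings

import numpy as np
import pytest

from foldmatch.synthetic import FoldingSpec, fixture_suite, \
    generate_longitudinal_pair


@pytest.fixture(scope="session")
def fixtures():
    """Deterministic analytic meshes shared across the suite."""
    return fixture_suite()


@pytest.fixture(scope="session")
def longitudinal_pair():
    """Default synthetic early/late pair with ground truth (seed 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_longitudinal_pair(FoldingSpec(seed=0), subdivision=3)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def rotation_matrix(degrees_xyz):
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler("xyz", degrees_xyz, degrees=True).as_matrix()
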