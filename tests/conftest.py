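import numpy as np
import pytest

from slidemil import synthetic_data as sd
from slidemil import tiling_qc as tq


@pytest.fixture(scope="session")
def fixture_slide():
    """The canonical 12-cell QC fixture (4 white, 2 defocused, 6 sharp)."""
    spec = sd.twelve_cell_fixture_spec()
    img, region_map = sd.make_fixture_slide(spec)
    return spec, img, region_map


@pytest.fixture(scope="session")
def qc_results(fixture_slide):
    _, img, _ = fixture_slide
    return tq.run_qc_pipeline(img, "fixture", tq.QCConfig(), "40x")


@pytest.fixture(scope="session")
def small_cohort():
    """A quick slide-level witness cohort for training-machinery tests."""
    spec = sd.BagCohortSpec(n_patients=60, seed=11)
    return sd.make_bag_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
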