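import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cladesel as cs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def primate_model() -> cs.PhyloModel:
    """The packaged 14-taxon primate-like neutral model."""
    return cs.load_default_model().to_phylo_model()


@pytest.fixture(scope="session")
def jc_model() -> cs.PhyloModel:
    """Jukes-Cantor on a 3-leaf tree (uniform frequencies, symmetric rates)."""
    tree = cs.PhyloTree.from_newick("((A:0.1,B:0.2):0.05,C:0.3);")
    Q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(Q, -1.0)
    return cs.PhyloModel(tree, Q, np.full(4, 0.25))


@pytest.fixture(scope="session")
def thresholds_200k(primate_model) -> cs.ThresholdTable:
    """Thresholds calibrated on a 200k-column neutral simulation; shared by
    the detector-level tests (calibration itself is tested separately)."""
    codes = cs.simulate_alignment(primate_model, 200_000, seed=7)
    return cs.calibrate_thresholds(codes, primate_model, target_fpr=1e-3)
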