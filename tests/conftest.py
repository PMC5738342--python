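import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from phasetrack.blobs import BlobHypothesis
from phasetrack.segmentation import Frame, MrfParams, segment_frame
from phasetrack.tracking import CollectionPrior, MotionModel


@pytest.fixture(scope="session", autouse=True)
def _warm_numba():
    """Compile the Gibbs kernel once up front so timings are per-test fair."""
    f = Frame(np.arange(16.0).reshape(4, 4), 1.0, 0)
    segment_frame(f, MrfParams(feature_radius=1, n_burn=2, n_sweeps=2, n_cliques=2))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_hyp(hid, frame, cx, cy, a=6.0, b=5.0, theta=0.0, support=0.9):
    from phasetrack._geometry import Ellipse

    return BlobHypothesis(
        id=hid, frame=frame, ellipse=Ellipse(cx, cy, a, b, theta), support=support
    )


@pytest.fixture
def hyp_factory():
    return make_hyp


@pytest.fixture
def linky_prior():
    """Prior under which even a two-frame link beats the empty collection."""
    return CollectionPrior(log_birth=-1.0, log_death=-0.5, log_coverage=2.0, kappa_overlap=0.01)


@pytest.fixture
def motion():
    return MotionModel()
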