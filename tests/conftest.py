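import numpy as np
import pytest

from tpinfer.generative import AgentParams, GenerativeParams
from tpinfer.pipeline import run_study

STUDY_SEED = 20260920
N_SUBJECTS = 18
N_BLOCKS = 4


@pytest.fixture(scope="session")
def study():
    """18 simulated subjects x 4 blocks under the study conditions.

    Each block carries a full 380-stimulus session through the
    forward-backward observer (filtered series + jump-posterior matrix),
    the Gibbs observer at question times (chunk-length statistics), the
    0.25-threshold jump discretization, and a noisy-readout agent.  Built
    once per test session: this is the heavy shared computation.
    """
    return run_study(N_SUBJECTS, N_BLOCKS, STUDY_SEED, agent=AgentParams())


@pytest.fixture(scope="session")
def cohort(study):
    """All block runs, flattened (for block-level checks)."""
    return [run for runs in study for run in runs]


@pytest.fixture(scope="session")
def default_params():
    return GenerativeParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
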