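import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def toy_pool():
    """Three-site zero-sum pool used by the hand-worked tuning examples."""
    from traitscape import DistributionSpec, GAUSSIAN, SMEPool

    return SMEPool(h=np.array([0.5, 0.4, -0.9]), spec=DistributionSpec(GAUSSIAN))


@pytest.fixture
def pareto_spec():
    from traitscape import DistributionSpec, PARETO_CUTOFF

    return DistributionSpec(PARETO_CUTOFF, alpha=0.7, xm=0.1, cutoff=2.0)
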