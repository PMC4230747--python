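import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20140920)


@pytest.fixture
def balanced_counts():
    from asepg.datamodel import AlleleCounts

    return AlleleCounts("exon_bal", x=[150, 145, 155], y=[148, 152, 150])


@pytest.fixture
def skewed_counts():
    from asepg.datamodel import AlleleCounts

    return AlleleCounts("exon_skew", x=[120, 130, 110], y=[60, 70, 65])


@pytest.fixture
def balanced_dna():
    from asepg.datamodel import DnaCounts

    return DnaCounts("exon_bal", x_star=[151, 149, 150], y_star=[150, 148, 152])
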