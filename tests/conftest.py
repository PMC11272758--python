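import pytest

from stpdosim import CohortConfig, MonoExpFit, run_study


@pytest.fixture
def fit_56() -> MonoExpFit:
    """A reference fit: A0 = 100 MBq, T_eff = 56 h."""
    import math

    return MonoExpFit(A0_MBq=100.0, lambda_per_h=math.log(2) / 56.0, n_points=3)


@pytest.fixture(scope="session")
def default_study():
    """The default stochastic study used by the acceptance checks.

    300 patients x 4 cycles x 2 kidneys = 2400 kidney-cycles at the package
    default kinetics (T_eff ~ N(56, 13) h truncated to [25, 110] h, 6%
    multiplicative measurement noise, scans at 4/96/168 h), seed 0.
    """
    return run_study(CohortConfig(n_patients=300, seed=0))
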