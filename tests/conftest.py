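import pytest

from grenzray import pipeline


@pytest.fixture(scope="session")
def survival_report_full():
    """One calibrated end-to-end survival report shared across tests.

    Session-scoped because it calibrates the damage simulator and runs
    one simulation per oxygen condition.
    """
    return pipeline.survival_report(seed=20260926, calibrate=True, n_samples=2000)
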