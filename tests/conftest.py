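import pytest

from breathsim.experiments import run_series_1, run_series_2, run_series_3


@pytest.fixture(scope="session")
def series1():
    return run_series_1(check=False)


@pytest.fixture(scope="session")
def series2():
    return run_series_2(check=False)


@pytest.fixture(scope="session")
def series3():
    return run_series_3(check=False)
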