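import pytest

from qams import synthetic_data as synth


@pytest.fixture(scope="session")
def contents():
    """The packaged 55-batch content matrix (mg/g), totals column dropped."""
    return synth.fixture_content_matrix()


@pytest.fixture(scope="session")
def table4():
    """Content matrix including the printed totals column."""
    return synth.load_fixture("table4")


@pytest.fixture(scope="session")
def printed_curves():
    return synth.fixture_calibration_curves()


@pytest.fixture(scope="session")
def truth():
    return synth.ResponseTruth.default()


@pytest.fixture(scope="session")
def noiseless_truth():
    return synth.ResponseTruth.default().noiseless()
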