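import pytest

from qppr_pbpk import datasets, workflows


@pytest.fixture(scope="session")
def calibration():
    return datasets.load_calibration_set()


@pytest.fixture(scope="session")
def evaluation():
    return datasets.load_evaluation_set()


@pytest.fixture(scope="session")
def all_records(calibration, evaluation):
    return calibration + evaluation


@pytest.fixture(scope="session")
def cal_fit(calibration):
    """The calibrated three-descriptor clearance model."""
    return workflows.calibration_fit(calibration)


@pytest.fixture(scope="session")
def physiology():
    return datasets.PhysiologySpec()


def by_name(records):
    return {r.name: r for r in records}
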