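import pytest

from cpdeficits import synthetic
from cpdeficits.calibration import attach_covariates


@pytest.fixture(scope="session")
def default_config():
    return synthetic.GenerativeConfig()


@pytest.fixture(scope="session")
def design():
    return synthetic.StudyDesign()


@pytest.fixture(scope="session")
def cohort(default_config, design):
    """One simulated study-sized cohort (25 controls, 13 CPs), shared
    across tests that only read from it."""
    participants = synthetic.generate_participants(default_config, seed=42)
    trials = synthetic.simulate_experiment(
        participants, design, default_config, "faces_longterm", seed=42
    )
    data = attach_covariates(trials, participants)
    return {"participants": participants, "trials": trials, "data": data}


@pytest.fixture(scope="session")
def control_data(cohort):
    d = cohort["data"]
    return d[d["group"] == "control"]
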