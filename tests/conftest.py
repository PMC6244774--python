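import numpy as np
import pytest

from oscillomark.cohort import load_patient_table


@pytest.fixture(scope="session")
def cohort():
    """The packaged 24-patient diffuse-glioma cohort table."""
    return load_patient_table()


@pytest.fixture(scope="session")
def tier_groups(cohort):
    """Global-activity z-scores split by NLGN3 expression tier (12/6/3)."""
    z = cohort["oba_global_z"].to_numpy()
    return {
        name: z[(cohort["nlgn3_tier"] == name).to_numpy()]
        for name in ("low", "moderate", "high")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
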