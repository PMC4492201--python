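import pytest

import chemorad as cr


@pytest.fixture(scope="session")
def fixtures():
    return cr.load_fixtures()


@pytest.fixture(scope="session")
def pooled_cohorts(fixtures):
    return tuple(c for table in fixtures.values() for c in table)


@pytest.fixture(scope="session")
def published_xray_chemo_params():
    return cr.ModelParameters(gamma50=1.2, d50=107.0, cs=0.36)


@pytest.fixture(scope="session")
def recovery_study():
    """200-replicate parameter-recovery study on the mirrored fixture design.

    Session-scoped: shared by the headline recovery check and the interval
    calibration check.
    """
    return cr.parameter_recovery_study(n_replicates=200, seed=1234)
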