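import pytest
from hypothesis import HealthCheck, settings


def toy_inputs(sigma_soil=9.6, nonsoil_sigmas=(0.0, 0.0), sigma_obs=0.0):
    """Forward-mixed toy for uncertainty checks: non-soil (10, 4) at
    (−2.5, −16.5), inventory soil 1.0, E_inv 15, δ_obs the exact mixture
    with true soil 5 (E_s = 4 by the offset identity)."""
    from isonox.uncertainty import UncertaintyInputs

    return UncertaintyInputs(
        delta_obs=-257.0 / 19.0,
        nonsoil_alphas=(10 / 15, 4 / 15),
        nonsoil_deltas=(-2.5, -16.5),
        nonsoil_sigmas=nonsoil_sigmas,
        alpha_soil=1 / 15,
        delta_soil=-33.2,
        sigma_soil=sigma_soil,
        e_inv=15.0,
        sigma_obs=sigma_obs,
    )

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def samples():
    from isonox.io import load_fixture_samples

    return load_fixture_samples()


@pytest.fixture(scope="session")
def signatures():
    from isonox.io import load_fixture_signatures

    return load_fixture_signatures()


@pytest.fixture(scope="session")
def inventories():
    from isonox.io import load_fixture_inventories

    return load_fixture_inventories()


@pytest.fixture(scope="session")
def study():
    from isonox.io import load_study_config

    return load_study_config()
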