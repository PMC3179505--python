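import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

BASE_SEED = 0


@pytest.fixture(scope="session")
def dw_study():
    """Three seeded metadynamics reconstructions of the 6 kcal/mol double well."""
    from pathmeta.validation import double_well_fes_study

    return double_well_fes_study(BASE_SEED)


@pytest.fixture(scope="session")
def pocket_study():
    """Equilibrated pocket + five steered pulls + lowest-work frameset."""
    from pathmeta.validation import build_pocket_study

    return build_pocket_study(BASE_SEED)


@pytest.fixture(scope="session")
def pocket_oracle(pocket_study):
    """300 ns unbiased run: histogram profile along S and its ΔG."""
    from pathmeta.validation import pocket_unbiased_profile

    dg, centers, prof, round_trips = pocket_unbiased_profile(pocket_study, BASE_SEED)
    return {"dg": dg, "centers": centers, "profile": prof, "round_trips": round_trips}


@pytest.fixture(scope="session")
def pocket_metad(pocket_study):
    """Three 20 ns path-CV metadynamics estimates of the pocket ΔG."""
    from pathmeta.validation import pocket_metad_delta_g

    mean, per_seed = pocket_metad_delta_g(pocket_study, BASE_SEED)
    return {"dg": mean, "per_seed": per_seed}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
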