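import pytest
from hypothesis import HealthCheck, settings

import iimcoal as ic

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: generating values of the canonical simulation study, mutation-scaled
STUDY_PHI = ic.PhiVector(
    theta_a=1.5,
    theta=2.0,
    theta_b=2.5,
    theta_c1=3.0,
    theta_c2=4.0,
    T1=2.0,
    V=2.0,
    M1=0.5,
    M2=0.75,
)


@pytest.fixture(scope="session")
def study_phi():
    return STUDY_PHI


@pytest.fixture(scope="session")
def study_params():
    params, _ = STUDY_PHI.to_coalparams()
    return params


def draw_params(rng, regime):
    """Random coalescent parameters in one of the four migration regimes."""
    M1, M2 = rng.uniform(0.1, 2.0, 2)
    if regime in ("uni_M1_zero", "none"):
        M1 = 0.0
    if regime in ("uni_M2_zero", "none"):
        M2 = 0.0
    tau1 = rng.uniform(0.0, 1.5)
    return ic.CoalParams(
        a=rng.uniform(0.3, 2.0),
        b=rng.uniform(0.3, 2.5),
        c1=rng.uniform(0.3, 2.5),
        c2=rng.uniform(0.3, 2.5),
        tau1=tau1,
        tau0=tau1 + rng.uniform(0.05, 2.0),
        M1=M1,
        M2=M2,
    )


REGIMES = ("bidirectional", "uni_M1_zero", "uni_M2_zero", "none")


@pytest.fixture(scope="session")
def iso_phi():
    return ic.MODELS["ISO"].build_phi(
        {"theta_a": 1.8, "theta": 2.2, "theta_b": 1.4, "V": 4.0}
    )


@pytest.fixture(scope="session")
def iso_data(iso_phi):
    return ic.simulate_dataset(ic.SimConfig(phi=iso_phi, n_loci=8000, seed=2024))


@pytest.fixture(scope="session")
def iso_fit(iso_data):
    return ic.fit(iso_data, "ISO", n_starts=3, seed=11)
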