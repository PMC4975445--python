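import pytest

from peroxidyn import (
    KineticParameters,
    PopulationModel,
    Scenario,
    StrainConfig,
    simulate,
)

PER_ML = 1e3  # cells/mL -> cells/L


@pytest.fixture(scope="session")
def params():
    return KineticParameters()


@pytest.fixture(scope="session")
def wild_type():
    return StrainConfig.wild_type()


def make_stress_scenario(
    external0,
    n_per_ml=1.45e7,
    strain=None,
    t_end=1200.0,
    params=None,
    **kwargs,
):
    """One-strain scenario with a single H2O2 addition at t=0."""
    return Scenario(
        params=params or KineticParameters(),
        strains=((strain or StrainConfig.wild_type(), n_per_ml * PER_ML),),
        population=PopulationModel(),
        stress_events=((0.0, external0),),
        t_end=t_end,
        **kwargs,
    )


@pytest.fixture(scope="session")
def fig7_trajectory():
    """Wild type, 1.5 uM stress at OD 0.1 (1.45e7 cells/mL)."""
    return simulate(make_stress_scenario(1.5e-6, t_end=1200.0))


@pytest.fixture(scope="session")
def fig10_trajectory():
    """Wild type, 1 mM stress at 1.45e7 cells/mL."""
    return simulate(make_stress_scenario(1e-3, t_end=2400.0))
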