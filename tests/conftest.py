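import pytest

from thermoflux.core import MetabolicModel, Metabolite, Reaction
from thermoflux.fba import FbaProblem, apply_medium, solve_fba
from thermoflux.synth import FIXTURE_NGAM, build_thermophile_fixture


@pytest.fixture(scope="session")
def fixture():
    """The deterministic thermophile-style test network + media."""
    return build_thermophile_fixture()


@pytest.fixture(scope="session")
def fixture_growth(fixture):
    """{medium name: (constrained model, optimal FluxSolution)}."""
    out = {}
    for medium in (fixture.dmm, fixture.tm):
        constrained = apply_medium(fixture.model, medium, FIXTURE_NGAM)
        sol = solve_fba(constrained)
        assert sol.status == "optimal"
        out[medium.name] = (constrained, sol)
    return out


def linear_chain_model(uptake: float = 10.0) -> MetabolicModel:
    """EX_A -(A[e])-> A[c] -> biomass, the simplest growing network."""
    m = MetabolicModel("chain")
    m.add_metabolite(Metabolite("A[e]"))
    m.add_metabolite(Metabolite("A[c]"))
    m.add_reaction(Reaction("EX_A", {"A[e]": -1.0}, lower_bound=-uptake,
                            subsystem="exchange"))
    m.add_reaction(Reaction("TA", {"A[e]": -1.0, "A[c]": 1.0},
                            subsystem="transport", gpr="g1"))
    m.add_reaction(Reaction("BIOMASS", {"A[c]": -1.0}, subsystem="biomass"))
    m.set_objective("BIOMASS")
    return m


@pytest.fixture
def chain_model():
    return linear_chain_model()
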