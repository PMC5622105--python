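import hypothesis
import pytest

from ecmbind import fixtures

hypothesis.settings.register_profile(
    "ecmbind", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ecmbind")


@pytest.fixture(scope="session")
def abundance_table():
    return fixtures.abundance_table()


@pytest.fixture(scope="session")
def fixture_scenarios():
    return fixtures.binding_scenarios()


@pytest.fixture(scope="session")
def scenario_for(fixture_scenarios):
    def pick(ligand: str, group: str):
        for sc in fixture_scenarios:
            if sc.ligand == ligand and sc.group == group:
                return sc
        raise KeyError((ligand, group))

    return pick
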