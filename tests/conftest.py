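import numpy as np
import pytest

import scfsol as s


@pytest.fixture(scope="session")
def co2():
    return s.carbon_dioxide()


@pytest.fixture(scope="session")
def retinol():
    return s.default_retinol()


@pytest.fixture(scope="session")
def fixture_ds():
    return s.load_dataset("bundled:table2")


@pytest.fixture(scope="session")
def pr():
    return s.get_eos("pr")


@pytest.fixture(scope="session")
def srk():
    return s.get_eos("srk")


def random_binary_state(rng, retinol, co2):
    """One random feasible mixture state for fugacity property checks."""
    eos_id = rng.choice(["srk", "pr", "sv", "dptg"])
    rule_id = rng.choice(["vdw1", "vdw2"])
    rule = s.MixingRuleSpec(
        rule_id, kij=float(rng.uniform(-0.3, 0.6)),
        lij=float(rng.uniform(-0.3, 0.6)) if rule_id == "vdw2" else 0.0)
    T = float(rng.uniform(290.0, 420.0))
    P = float(rng.uniform(1.0, 300.0))
    x1 = float(10 ** rng.uniform(-6, -0.1))
    return T, P, (x1, 1.0 - x1), s.get_eos(eos_id), rule
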