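import numpy as np
import pytest

from confbias import MisclassSpec, ScenarioParams

# Table-1 parameter sets of the simulation study, keyed by explicit values.
SCENARIO_PARAMS = {
    "no_error": (ScenarioParams(pL=0.50, p0=0.50, p1=0.75, beta=1.0, lam=2.0),
                 MisclassSpec(sens=1.0, spec=1.0)),
    "negative_bias": (ScenarioParams(pL=0.50, p0=0.90, p1=0.45, beta=1.0, lam=2.0),
                      MisclassSpec(sens=0.90, spec=0.95)),
    "strong_positive": (ScenarioParams(pL=0.80, p0=0.25, p1=0.75, beta=1.0, lam=2.0),
                        MisclassSpec(sens=0.90, spec=0.95)),
    "moderate_positive": (ScenarioParams(pL=0.80, p0=0.50, p1=0.75, beta=1.0, lam=2.0),
                          MisclassSpec(sens=0.90, spec=0.95)),
    "equal_bias": (ScenarioParams(pL=0.45, p0=0.50, p1=0.75, beta=1.0, lam=2.0),
                   MisclassSpec(sens=0.90, spec=0.95)),
}


@pytest.fixture
def scenario1():
    return SCENARIO_PARAMS["negative_bias"]


@pytest.fixture
def scenario0():
    return SCENARIO_PARAMS["no_error"]


def random_valid_draws(n: int, seed: int):
    """Random parameter/misclassification pairs over the admissible region.

    Probabilities in (0.05, 0.95), sens/spec in (0.5, 1], lam in [-5, 5] —
    a region where classification is better than chance and positivity is
    comfortable.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        pL, p0, p1 = 0.05 + 0.9 * rng.random(3)
        sens, spec = 0.5 + 0.5 * rng.random(2)
        lam = rng.uniform(-5.0, 5.0)
        out.append((
            ScenarioParams(pL=pL, p0=p0, p1=p1, beta=rng.uniform(-2, 2), lam=lam),
            MisclassSpec(sens=sens, spec=spec),
        ))
    return out
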