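import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import carepath as cp

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

SEED = 2019  # fixed study seed for the session-scoped synthetic survey


@pytest.fixture(scope="session")
def diagram():
    return cp.build_paper_diagram()


@pytest.fixture(scope="session")
def fixture_source():
    return cp.FixtureCoefficients(cp.load_coefficient_fixture())


@pytest.fixture(scope="session")
def design():
    return cp.PopulationDesign(seed=SEED, n_records=17251)


@pytest.fixture(scope="session")
def true_params(diagram, design):
    params = cp.default_true_params(diagram)
    return cp.calibrate_intercepts(params, cp.default_endogenous_targets(),
                                   design, diagram)


@pytest.fixture(scope="session")
def survey(diagram, true_params, design):
    return cp.generate_population(diagram, true_params, design)


@pytest.fixture(scope="session")
def system_fit(diagram, survey):
    return cp.fit_system(survey, diagram)


def make_binary_diagram(n_predictors: int = 1) -> cp.PathDiagram:
    """Minimal diagram: binary exogenous x1..xk -> binary endogenous y."""
    variables = [
        cp.VariableSpec(f"x{i}", "exogenous", "binary", levels=("no", "yes"),
                        reference_level="no")
        for i in range(1, n_predictors + 1)
    ]
    variables.append(
        cp.VariableSpec("y", "endogenous", "binary", family="binomial",
                        levels=("no", "yes"), reference_level="no"))
    edges = [cp.EdgeSpec(f"x{i}", "y") for i in range(1, n_predictors + 1)]
    return cp.PathDiagram(variables=variables, edges=edges, outcome="y")


def make_gaussian_diagram() -> cp.PathDiagram:
    variables = [
        cp.VariableSpec("x", "exogenous", "continuous",
                        predictor_encoding="as_continuous"),
        cp.VariableSpec("y", "endogenous", "continuous", family="gaussian",
                        predictor_encoding="as_continuous"),
    ]
    return cp.PathDiagram(variables=variables, edges=[cp.EdgeSpec("x", "y")],
                          outcome="y")


def two_by_two(a: int, b: int, c: int, d: int) -> pd.DataFrame:
    """Records for a 2x2 table: a=(x=1,y=1), b=(x=1,y=0), c=(x=0,y=1), d=(x=0,y=0)."""
    rows = ([("yes", "yes")] * a + [("yes", "no")] * b
            + [("no", "yes")] * c + [("no", "no")] * d)
    return pd.DataFrame(rows, columns=["x1", "y"])
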