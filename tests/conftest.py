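import pytest

from nestdyn import ModelParams, NestScenario


@pytest.fixture(scope="session")
def small_params():
    """A small, quick nest in the single-queen regime."""
    return ModelParams(N=8, alpha=20.0, lambda_asym=80.0, m=5, n_ss=50)


@pytest.fixture(scope="session")
def scenario_long():
    """Synthetic scenario with day-long observation windows for statistics."""
    return NestScenario(seed=11, phase_hours=(24.0,) * 5)


@pytest.fixture(scope="session")
def expression_table():
    from nestdyn import generate_expression

    return generate_expression(
        NestScenario(seed=7, n_genes=2000, n_queen_genes=80)
    )
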