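"""Shared fixtures: the planted-module recovery dataset and derived network.

The heavy consensus-network fixtures are session-scoped so the recovery
experiment is computed once and shared between the unit and acceptance
tests.
"""

import pytest

from migmod.coexpression import consensus_tom, detect_modules, pick_soft_threshold
from migmod.synthetic import simulate_modular_expression

#: Study conditions of the planted-module recovery experiment: five blocks
#: of 50 genes at within-block correlation 0.7 on 200 background genes,
#: observed over 100 samples.
PLANTED = dict(
    n_background=200,
    module_sizes=[50, 50, 50, 50, 50],
    n_samples=100,
    within_module_cor=0.7,
    seed=1,
)


@pytest.fixture(scope="session")
def planted_expression():
    expr, truth = simulate_modular_expression(**PLANTED)
    return expr, truth


@pytest.fixture(scope="session")
def soft_threshold_fit(planted_expression):
    expr, _ = planted_expression
    return pick_soft_threshold(expr, list(range(1, 21)), r2_target=0.8)


@pytest.fixture(scope="session")
def recovery_network(planted_expression, soft_threshold_fit):
    expr, _ = planted_expression
    return consensus_tom(
        expr,
        beta=soft_threshold_fit.chosen_power,
        n_resamples=100,
        leave_out_fraction=0.1,
        seed=11,
    )


@pytest.fixture(scope="session")
def recovery_modules(recovery_network):
    return detect_modules(recovery_network, min_module_size=30)
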