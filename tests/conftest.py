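import pytest

from rpsmeta.dynamics import Rates
from rpsmeta.experiments import preset, run_experiment
from rpsmeta.graphs import complete_graph, path_graph, star_graph


@pytest.fixture(scope="session")
def unit_rates():
    return Rates(1.0, 1.0, 1.0)


@pytest.fixture(scope="session")
def triangle():
    return complete_graph(3)


@pytest.fixture(scope="session")
def path3():
    return path_graph(3)


@pytest.fixture(scope="session")
def star4():
    return star_graph(4)


# The preset runs are deterministic and moderately expensive, so they are
# integrated once per session and shared between the unit and acceptance
# tests.

@pytest.fixture(scope="session")
def fig2a_result():
    """Homogeneous triangle, unit rates: sustained synchronized oscillation."""
    return run_experiment(preset("fig2a"), write_outputs=False)


@pytest.fixture(scope="session")
def fig2b_result():
    """Single well-mixed habitat, unit rates: the no-migration baseline."""
    return run_experiment(preset("fig2b"), write_outputs=False)


@pytest.fixture(scope="session")
def fig4_result():
    """Heterogeneous path, unit rates: damped oscillation to a stable focus."""
    return run_experiment(preset("fig4"), write_outputs=False)
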