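import pytest

from polyedit import SimulationConfig, simulate_reads
from polyedit.datasets import example_assay, example_reference, recovery_population, single_wt_population


@pytest.fixture(scope="session")
def reference():
    return example_reference()


@pytest.fixture(scope="session")
def assay():
    return example_assay()


@pytest.fixture(scope="session")
def wt_population():
    return single_wt_population()


@pytest.fixture(scope="session")
def planted_population():
    return recovery_population()


@pytest.fixture(scope="session")
def planted_reads(planted_population):
    """20k forward reads from the {+1: 30%, -3: 15%} population under the
    default background error model, fixed seed."""
    cfg = SimulationConfig(n_reads=20_000, seed=42)
    return [str(r.seq) for r in simulate_reads(planted_population, cfg)]
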