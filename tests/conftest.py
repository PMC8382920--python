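import numpy as np
import pytest

from tandemcn import pipeline, simulate


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated 26-lineage cohort with the default template, reused widely."""
    return simulate.simulate_all(simulate.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def long_gene_cohort():
    """Cohort in which every unit gene is >= 1 kb (estimator benchmarks)."""
    return simulate.simulate_all(
        simulate.SimulationConfig(seed=13), template=simulate.long_gene_template()
    )


@pytest.fixture(scope="session")
def default_products(default_cohort):
    """(copy-number table, proportions, selection result) for the default cohort."""
    return pipeline.quantify(default_cohort)


@pytest.fixture(scope="session")
def long_gene_products(long_gene_cohort):
    return pipeline.quantify(long_gene_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
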