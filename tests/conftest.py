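import numpy as np
import pytest

from palm_ltr.io import load_domain_library, load_trna_library
from palm_ltr.pipeline import RunConfig, simulate


@pytest.fixture(scope="session")
def domain_library():
    return load_domain_library()


@pytest.fixture(scope="session")
def trna_library():
    return load_trna_library()


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study genome shared across tests.

    Two 400 kb scaffolds, ten planted elements of mixed superfamily with
    LTR divergence up to 10 %, gene intervals with a density gradient and
    Copia placement bias.
    """
    cfg = RunConfig(seed=42, n_scaffolds=2, scaffold_length=400_000,
                    n_elements=10, n_genes=30, placement_bias=0.8,
                    run_expression=False)
    return simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
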