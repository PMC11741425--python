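import numpy as np
import pytest

from repeatflux.mutation_kernel import ContextRates, InstabilityParams
from repeatflux.repeat_catalog import motif_class
from repeatflux.synthetic_data import SyntheticTruth, generate_iid_genome


@pytest.fixture(scope="session")
def mono_class():
    return motif_class("A")


@pytest.fixture(scope="session")
def small_genome():
    """2 Mb i.i.d. genome (A at 0.3, remainder on C/G) shared across tests."""
    return {"chr1": generate_iid_genome(2_000_000, p_a=0.3, seed=11)}


@pytest.fixture(scope="session")
def boosted_truth():
    """Truth with rates boosted so a 2 Mb genome x 150 offspring yields
    informative event counts in every estimable bin."""
    ctx = ContextRates(lengthen=3e-7, shorten=5e-7, fusion=1e-6,
                      fission=2e-6, create_a1=2.5e-7, destroy_a1=4e-7)
    eps = np.array([1e-7, 2e-7, 5e-7, 1.2e-6, 3e-6, 8e-6, 2e-5, 5e-5])
    return SyntheticTruth(
        p_a=0.3, context=ctx, denovo_eps=eps, denovo_kappa=eps * 0.7,
        denovo_iota=np.array([8e-8, 1.5e-7, 3e-7, 6e-7, 1.5e-6, 4e-6,
                              1e-5, 2.5e-5]),
        params=InstabilityParams(2.0, 1.5, 1.8))
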