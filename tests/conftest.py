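import numpy as np
import pytest

from cuspkit.simulator import (GeneNetworkParams, SimParams, TissueParams,
                               load_preset, simulate)
from cuspkit.synthetic import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def shark_params() -> SimParams:
    return load_preset("shark")


@pytest.fixture(scope="session")
def shark_run(shark_params):
    """Baseline shark simulation, shared across tests (deterministic)."""
    return simulate(shark_params)


@pytest.fixture(scope="session")
def synthetic_default():
    """One synthetic dataset drawn under the default study design."""
    return generate_dataset(GeneratorConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_params(**kw) -> SimParams:
    """Small, fast parameter set for unit-level simulator tests."""
    gene = dict(act=1.2, inh=10.4, deg=0.03, da=0.01, di=0.4, sec=0.3)
    tissue = dict(bwi=15, bgr=0.005, bia=1.0, pro=0.001)
    extra = dict(bas=4.5e-4, kap=0.15, dega=0.03)
    other = dict(n_iter=2000, seed=0)
    for k, v in kw.items():
        if k in gene:
            gene[k] = v
        elif k in tissue:
            tissue[k] = v
        elif k in other:
            other[k] = v
        else:
            extra[k] = v
    return SimParams(GeneNetworkParams(**gene, extra=extra),
                     TissueParams(**tissue), **other)
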