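import numpy as np
import pytest

from hbirt.data import ResponseMatrix
from hbirt.diagnostics import ConvergenceConfig
from hbirt.model import ModelSpec, PriorConfig
from hbirt.sampler import SamplerConfig, run_chunked
from hbirt.simulation import generate_replicate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_data():
    """3 persons x 3 items with one missing cell."""
    vals = np.array([[1.0, 0.0, 1.0],
                     [0.0, 1.0, np.nan],
                     [1.0, 1.0, 0.0]])
    return ResponseMatrix(vals, person_ids=["p1", "p2", "p3"],
                          item_names=["y1", "y2", "y3"])


@pytest.fixture(scope="session")
def user_fit():
    """A fixed-length user-prior 2PL fit shared across tests.

    N=150 persons, 10 items, informative constant priors, no tuning,
    1500 burn-in + 3000 kept iterations.
    """
    rep = generate_replicate(150, 10, seed=101)
    spec = ModelSpec(item_names=list(rep.data.item_names))
    priors = PriorConfig(priors="user", prior_mean_a=1.0, prior_var_a=4.0,
                         prior_mean_d=0.0, prior_var_d=4.0)
    config = SamplerConfig(nbi=1500, iterationsteps=3000, maxtune=0)
    conv = ConvergenceConfig(psr_conv=0.0, ess_conv=0.0)
    draws, report, state = run_chunked(rep.data, spec, priors, config, conv, seed=7)
    return {"replicate": rep, "spec": spec, "priors": priors,
            "config": config, "draws": draws, "report": report, "state": state}


@pytest.fixture(scope="session")
def hier_fit():
    """A hierarchical-prior 2PL fit with PSR < 1.1 stopping.

    N=500 persons, 25 items so the adaptive priors have items to pool over.
    """
    rep = generate_replicate(500, 25, seed=202)
    spec = ModelSpec(item_names=list(rep.data.item_names))
    priors = PriorConfig()
    config = SamplerConfig(nbi=2000, iterationsteps=2500, hmaxtune=20, hntu=300)
    conv = ConvergenceConfig(psr_conv=1.1)
    draws, report, state = run_chunked(rep.data, spec, priors, config, conv, seed=8)
    return {"replicate": rep, "spec": spec, "priors": priors,
            "config": config, "draws": draws, "report": report, "state": state}
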