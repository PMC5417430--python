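import numpy as np
import pytest

import reefstress as rs
from reefstress import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def campaign():
    """One moderate synthetic survey campaign shared across test modules."""
    cfg = rs.SimConfig(n_sites=500, seed=42)
    obs, env = rs.simulate_dataset(cfg)
    kept, log, mapping = synthdata.assemble_analysis_table(cfg, obs, env)
    return {"cfg": cfg, "obs": obs, "env": env, "kept": kept, "log": log, "mapping": mapping}


@pytest.fixture(scope="session")
def bleaching_fit(campaign):
    dm = rs.build_design(campaign["kept"], rs.BLEACHING_SPEC)
    return dm, rs.fit_fractional_logit(dm)


def make_logistic_design(n=80, p=4, seed=0, zero_share=0.15):
    """Small fractional-response design drawn from a logistic-mean DGP."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta = rng.normal(0, 0.8, p)
    mu = rs.inv_logit(X @ beta)
    y = rng.beta(mu * 5, (1 - mu) * 5)
    y[rng.random(n) < zero_share] = 0.0
    names = ["const"] + [f"x{j}" for j in range(1, p)]
    return rs.DesignMatrix(X=X, y=y, column_names=names), beta
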