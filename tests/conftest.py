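import numpy as np
import pytest

import genlottery as gl


@pytest.fixture(scope="session")
def null_pop():
    """Small all-channels-off population reused across test modules."""
    cfg = gl.preset("null", n_families=4000, seed=101, twin_prob=0.10,
                    genotyped_family_prob=1.0)
    return gl.simulate_population(cfg)


@pytest.fixture(scope="session")
def null_samples(null_pop):
    samples, _ = gl.build_samples(null_pop)
    return samples


@pytest.fixture(scope="session")
def genotyped(null_samples):
    return null_samples["genotyped"]


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def make_summary(b, gamma, se_exp, se_out, Gamma=None):
    """Assemble a summary-statistics frame from arrays (test helper)."""
    import pandas as pd

    gamma = np.asarray(gamma, dtype=float)
    Gamma = np.asarray(Gamma if Gamma is not None else b * gamma, dtype=float)
    m = len(gamma)
    return pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(m)],
        "EA": ["A"] * m, "NEA": ["G"] * m, "EAF": np.full(m, 0.5),
        "BETA_EXP": gamma, "SE_EXP": np.broadcast_to(se_exp, (m,)).astype(float),
        "BETA_OUT": Gamma, "SE_OUT": np.broadcast_to(se_out, (m,)).astype(float),
    })
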