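import numpy as np
import pytest

from mrnastab import SynthParams, generate_chase, generate_paired_conditions


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small chase with no intensity noise and no batch gains."""
    params = SynthParams(n_genes=60, noise_sd_ln=0.0, batch_gain_sd_ln=0.0,
                         frac_extremely_stable=0.1, seed=42)
    return generate_chase(params)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Mid-size chase at the default 10% multiplicative noise."""
    params = SynthParams(n_genes=300, noise_sd_ln=0.1, seed=7)
    return generate_chase(params)


@pytest.fixture(scope="session")
def paired_noiseless():
    """Two noiseless steady states with known per-gene rho_D targets."""
    n = 200
    rng = np.random.default_rng(5)
    targets = np.where(rng.random(n) < 0.9,
                       rng.uniform(-2.0, -0.2, n),
                       rng.uniform(0.2, 2.0, n))
    pa = SynthParams(n_genes=n, mu=0.51, frac_extremely_stable=0.0,
                     noise_sd_ln=0.0, batch_gain_sd_ln=0.0, seed=11)
    pb = SynthParams(n_genes=n, mu=0.11, frac_extremely_stable=0.0,
                     noise_sd_ln=0.0, batch_gain_sd_ln=0.0, seed=12)
    return generate_paired_conditions(pa, pb, targets), targets
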