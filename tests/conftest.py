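import numpy as np
import pytest

from agexpr.simulate import default_architectures, simulate_tissue


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_tissue():
    """A modest synthetic tissue shared by read-only tests."""
    return simulate_tissue(
        n_samples=300,
        architectures=default_architectures(
            20, h2=0.3, r2_age=0.1, n_causal_snps=2, seed=7
        ),
        n_snps_per_gene=8,
        seed=11,
        constraint_correlation=-0.5,
    )
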