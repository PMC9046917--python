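import numpy as np
import pytest

from aquagp import mixedmodel as mm
from aquagp import simdata

# The "standard" test population: salmon-like scale — 84 full-sib families
# from 2 factorial blocks of 5 dams × 10 sires, negative-binomial family
# sizes around 12 (n ≈ 900–1000), founder LD from a 30-ancestor mosaic,
# h² = 0.25 with two batch-like fixed factors.
STANDARD = dict(
    n_sires=10,
    n_dams=5,
    n_blocks=2,
    n_families=84,
    family_size_law=("negative_binomial", 12, 3),
)


def standard_dataset(n_markers=3000, arch=None, seed=42):
    return simdata.simulate_dataset(
        n_markers=n_markers, arch=arch, seed=seed, **STANDARD
    )


@pytest.fixture(scope="session")
def std_ds():
    """Shared standard simulation at 3K markers."""
    return standard_dataset()


@pytest.fixture(scope="session")
def std_spec(std_ds):
    return mm.ModelSpec("y", std_ds.fixed_factors, [])


@pytest.fixture(scope="session")
def small_ds():
    """Tiny dataset (n=200, m=500) for algebraic identities."""
    return simdata.simulate_dataset(
        n_sires=5,
        n_dams=4,
        n_blocks=1,
        n_families=20,
        family_size_law=("constant", 10),
        n_markers=500,
        seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
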