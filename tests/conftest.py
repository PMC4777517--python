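"""Shared fixtures: small spaces and maps generated at test time."""

import numpy as np
import pytest

from gpcorr.space import GenotypeSpace, GPMap
from gpcorr.synth import SpectrumSpec, generate_random_map


@pytest.fixture(scope="session")
def binary_space_10():
    return GenotypeSpace("01", 10)


@pytest.fixture(scope="session")
def ball_map(binary_space_10):
    """Exact Hamming ball of radius 2 (56 genotypes) around 0...0 as one
    phenotype, everything else as background: the canonical positively
    correlated construction."""
    sp = binary_space_10
    dist = sp.digits(np.arange(sp.n_genotypes)).sum(axis=1)
    codes = (dist <= 2).astype(np.int32)
    return GPMap(sp, codes=codes, labels=["bg", "ball"])


@pytest.fixture(scope="session")
def random_map_k4():
    """Frequency-matched random map, K=4 L=8, three phenotypes spanning the
    thresholds (f = 0.5 above lambda, f ~ 0.001 below delta)."""
    spec = SpectrumSpec(K=4, L=8, counts=(32768, 65536 - 32768 - 66, 66))
    return generate_random_map(spec, seed=0)


@pytest.fixture(scope="session")
def small_random_map():
    """K=2, L=6 random map used for oracle-equivalence checks."""
    spec = SpectrumSpec(K=2, L=6, counts=(20, 12, 32))
    return generate_random_map(spec, seed=42)
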