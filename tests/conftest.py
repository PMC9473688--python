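import numpy as np
import pytest

from hemegeom import FilamentSpec, PairSpec, ideal_porphyrin, make_filament, make_pair

SEED = 20220905


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture
def ring():
    return ideal_porphyrin()


@pytest.fixture
def rare_pair():
    """Two hemes at the unusual combination: θ = 56°, 4.8 Å edge-to-edge."""
    return make_pair(PairSpec(theta=56.0, target_min_distance=4.8))


@pytest.fixture
def branched_filament():
    """Three octaheme subunits: seven chain hemes plus one pendant each."""
    return make_filament(FilamentSpec())
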