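import random
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture
def small_family():
    """A 3-gene simulated family with modest divergence, no motif."""
    from ugtevol.simulate import SimConfig, simulate_family

    cfg = SimConfig(n_codons=120, omega=0.3, times_mya=[5.0, 20.0], seed=11,
                    chromosomes=["Chr1", "Chr2", "Chr1"])
    genes, truth = simulate_family(cfg)
    return genes, truth
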