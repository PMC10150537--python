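import pytest

from casdms.codons import random_reference_cds
from casdms.synthetic import (
    EffectConfig,
    random_spec_truth,
    simulate_screen,
)

TARGET_24 = "TTTACCCAGTAGCTGACGTCAATG"  # TTTA PAM + 20-nt protospacer


@pytest.fixture(scope="session")
def reference_small():
    return random_reference_cds(12, seed=7, id="ref12")


@pytest.fixture(scope="session")
def small_screen():
    """Desk-scale screen: 50 codons, 3 replicates, depth 2e5, fixed seed."""
    return simulate_screen(
        n_codons=50, effect_config=EffectConfig(), depth=200_000, seed=11
    )


@pytest.fixture(scope="session")
def spec_truth():
    return random_spec_truth(TARGET_24, seed=3)
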