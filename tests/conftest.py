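import numpy as np
import pytest

from ggapsvm.sequence_io import ACIDIC, ALKALINE
from ggapsvm.synthetic_data import PlantedPair, SyntheticSpec, generate

# Mirrored planted pairs: RL/LR and DT/TD keep the per-residue marginals of
# the two classes identical, so the discriminative signal lives only at the
# planted gap; KE adds a fifth, unmirrored pair.
PLANTED_GAP2 = (
    PlantedPair("RL", 2, ACIDIC),
    PlantedPair("LR", 2, ALKALINE),
    PlantedPair("DT", 2, ACIDIC),
    PlantedPair("TD", 2, ALKALINE),
    PlantedPair("KE", 2, ALKALINE),
)


@pytest.fixture(scope="session")
def signal_dataset():
    """50/class dataset with strong gap-2 dipeptide enrichment."""
    spec = SyntheticSpec(n_per_class=50, planted=PLANTED_GAP2, enrichment=8.0, seed=11)
    return generate(spec)


@pytest.fixture(scope="session")
def small_signal_dataset():
    """20/class dataset with very strong gap-2 signal (fast tests)."""
    spec = SyntheticSpec(
        n_per_class=20,
        length_range=(100, 200),
        planted=PLANTED_GAP2,
        enrichment=16.0,
        seed=5,
    )
    return generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
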